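# Methods

## Model and procedure

A community's sequencing output is summarized as genus-level read counts
`c_g`, including a reserved `Unidentified` category for reads not assigned
at genus level. Two relative-abundance profiles are derived:

* **raw** — `c_g / Σ c_g`;
* **GCN-corrected** — `(c_g / k_g) / Σ (c_h / k_h)`, where `k_g` is the
  genus's mean 16S gene copy number from a lookup table and any genus
  absent from the table (including `Unidentified`) receives the table's
  default (1.8 unless configured otherwise).

Each profile is scored against the known mock composition by the residual
sum of squares over the aligned union of categories, zeros filled on the
side lacking a category and the mock side of `Unidentified` fixed at 0.
RSS lies in [0, 2] for simplex profiles; the pipeline with the strictly
smaller RSS is flagged the better fit, with ties credited to raw — the
correction must strictly improve fit to be credited.

Assumptions worth stating: counts are already aggregated to genus level
(ASV/OTU resolution is upstream and out of scope); a single mean copy
number per genus is meaningful even though copy number varies within
genera; and the mock's designed composition is the ground truth, so every
deviation — classifier error, primer bias, chimeras — lands in the
observed profile.

## Renormalization choice

GCN-corrected counts are renormalized by the **corrected** total, not the
raw read total. Dividing by the raw total would leave the corrected vector
off the simplex and make RSS values incomparable between pipelines; the
corrected-total convention is the one under which both profiles are
compositions. This is the only genuinely open design point in the
correction itself and is fixed package-wide.

## Metrics

* **Shannon diversity** `H = −Σ p ln p`, natural log (the vegan
  convention; `base` is a parameter for sensitivity checks). The
  unidentified category counts as one category when present — it is part
  of the composition the sequencer delivered. Computed for the mock, raw
  and corrected profiles.
* **Richness** — number of *named* genera with abundance > 0;
  `Unidentified` is excluded, since it is not a genus.
* **Misidentification** — the unassigned fraction (`na_frac`) and the
  fraction assigned to named genera absent from the mock (`other_frac`),
  both measured on the **raw** profile only: they describe the taxonomic
  assignment, and reweighting by copy numbers would distort them.
* **Exclusion rule** — a community is dropped when its raw Shannon
  diversity is strictly below 25% of the mock's. A collapse to a fifth of
  the designed diversity indicates a failed library rather than anything
  the normalization could cause. The threshold is configurable and strict
  (`<`), so a ratio exactly at the threshold keeps the community.

## Cohort aggregation

Over retained communities: mean of `100·(RSS_GCN − RSS_raw)` (percentage
points on the relative-abundance scale; positive = raw fits better), mean
richness overrepresentation `100·(S_raw − S_mock)/S_mock`, and mean
misidentification percentages. Every standard error is the sample standard
deviation (n−1 denominator) divided by √n; at least two retained
communities are required. Sums use compensated (`fsum`) summation, making
the aggregates exactly permutation-invariant.

## The reference benchmark

`reference_evaluations()` bundles, as data, the per-community measurements
of eleven mockrobiota-derived mock communities (Mock-12 … Mock-23; nine
assembled from purified genomic DNA, two from 16S genes cloned in pUC19)
profiled with a DADA2/SILVA genus-level pipeline and RDP copy numbers.
Recomputing these rows requires the raw FASTQ archives and the external
taxonomy and copy-number databases, so the rows are fixed at their full
four-decimal precision; everything derived from them — exclusion, best-fit
flags, cohort aggregates — is recomputed at run time by the package's own
rules. On this benchmark the aggregates are: raw fits 7.1 percentage
points better (n = 10), richness overrepresented by 27.4% (SE 12.1%),
unidentified reads 4.0% (SE 3.1%), wrong-genus reads 1.4%, raw the better
fit in 7 of 10 communities, Mock-12 the unique exclusion. Recomputing the
SE of the RSS difference from the rounded rows gives 3.69, and of the
wrong-genus fraction 0.90; published summaries of this benchmark quote 3.6
and 0.1 for these, the latter irreconcilable with the rounded rows, so
neither SE is treated as a hard expectation.

## Synthetic data generator

`simulate_mock` draws one experiment: designed genera with composition
uniform, geometric, or explicit; copy numbers explicit or integer-uniform
on [1, 15] (the observed span across bacteria); sampling weights
proportional to abundance × copy number, rescaled so the unidentified
category receives its stated fraction and spurious (wrong-genus)
categories share their stated mass; counts multinomial at fixed depth. All
randomness flows through an explicit seed. Defaults: depth 10⁵ reads
(typical for a modern amplicon library), no unidentified or spurious mass.

Spurious genera receive copy numbers drawn like real ones — they are real
organisms, merely not designed in — but their observed mass is the stated
one, and `SyntheticMock.gcn_database()` deliberately omits them so that
evaluation applies the default, as a real lookup would.

What the generator does **not** emulate: read-level error, chimera
formation, primer bias, overdispersion beyond multinomial noise (a
Dirichlet-multinomial hook exists, default off), or within-genus
copy-number variation. Passing tests therefore certify the arithmetic of
correction and scoring under the stated bias model, not the behaviour of a
wet-lab pipeline.

The high-copy preset (`scenario_mock19`) fixes seven equally abundant
genera with copy numbers (4.9, 5.5, 6.2, 6.6, 7.0, 7.6, 8.4) — mean
exactly 6.6, spread matching a reported SE of ~0.9 for such communities —
and a 30% unidentified fraction. Analytically, correcting with default 1.8
multiplies the unidentified share by (0.3/1.8)/(0.3/1.8 + 0.7/6.6) ≈ 2×
relative to raw, so the corrected RSS (≈0.43) must exceed the raw one
(≈0.11) at any realistic depth; raising the default to 6.6 restores parity.
The direction of this effect is forced, not tuned.

## Numerical choices

* Profiles must sum to 1 within 1e-9; sums within 1e-6 are renormalized
  exactly (taxonomy files carry rounding); taxonomy files are accepted up
  to 1e-3 off and renormalized, beyond that rejected as corrupt.
* Genus names are matched case-sensitively after trimming whitespace and
  stripping one leading rank prefix (`g__` etc.); mockrobiota lineages
  carry prefixes, RDP-style tables do not.
* Duplicate rows in a copy-number table are averaged, consistent with a
  genus-level mean over genomes.
* Category order in aligned vectors and reports is lexicographic with
  `Unidentified` last — deterministic, diff-stable output; report writers
  are byte-deterministic.
* Richness uses strict `> 0`; zero-abundance padding categories never
  count.

## Problem sizes

Simulator-based tests and the reproduction script use depth 10⁶ for
parameter-recovery checks (multinomial error ~10⁻³ per category, RSS
~10⁻⁶) and 10⁵ elsewhere; the monotonicity property uses 30 replicates per
copy-number spread. These sizes put sampling error well below every margin
tested while keeping runs near-instant.

## Known limitations

* Genus-level only; sub-genus copy-number variation is averaged away by
  construction.
* The 1.8 default is a convention, not an estimate for any particular
  community; the high-copy preset shows it can invert the benchmark's
  conclusion for communities rich in high-copy taxa or unassigned reads.
* The reference benchmark is a single sequencing campaign; its aggregates
  carry its pipeline's assignment errors.
* Whether published Shannon values for such benchmarks include the
  unidentified category is not always stated; this package includes it,
  and `shannon` takes the profile you give it, so either convention is
  reachable.
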