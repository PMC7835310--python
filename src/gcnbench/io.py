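"""Readers and writers for the external table formats.

Formats handled:

* mockrobiota-style expected-composition taxonomy files — two columns,
  semicolon-delimited lineage and relative abundance;
* genus count tables — two columns, genus and read count, with a reserved
  token (default ``Unidentified``) for reads unassigned at genus level;
* GCN tables (see :mod:`gcnbench.gcn_db`);
* benchmark report TSVs mirroring the per-community evaluation plus the
  cohort summary.

Readers reject malformed input rather than silently repairing it; writers
are deterministic (identical inputs give identical bytes). Comma and tab
delimiters are auto-detected on read; writers emit tabs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from gcnbench.benchmark import CohortSummary, EvaluationResult
from gcnbench.profiles import UNIDENTIFIED, CountTable, TaxonProfile, normalize_genus

logger = logging.getLogger(__name__)

#: Abundance columns of taxonomy files must total 1 within this (files carry
#: rounding); anything further off is treated as corrupt.
TAXONOMY_SUM_ATOL = 1e-3


class TableFormatError(ValueError):
    """Raised when an input table is malformed."""


@dataclass
class RunConfig:
    """Paths and policy knobs for one evaluation run."""

    counts_path: Path
    mock_path: Path
    gcn_path: Path | None = None
    default_gcn: float = 1.8
    exclusion_threshold: float = 0.25
    shannon_base: float | None = None
    unidentified_token: str = UNIDENTIFIED
    output_dir: Path = Path(".")

    def __post_init__(self) -> None:
        if self.default_gcn <= 0:
            raise ValueError("default_gcn must be > 0")
        if not 0.0 < self.exclusion_threshold < 1.0:
            raise ValueError("exclusion_threshold must lie in (0, 1)")


def _rows(path: Path, *, skip_header: bool) -> list[tuple[int, list[str]]]:
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[tuple[int, list[str]]] = []
    with path.open() as fh:
        pending_header = skip_header
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if pending_header:
                pending_header = False
                continue
            sep = "\t" if "\t" in line else ","
            out.append((lineno, line.split(sep)))
    return out


def _lineage_genus(lineage: str) -> str:
    """Last non-empty rank at or above genus, rank prefixes stripped."""
    ranks = [r.strip() for r in lineage.split(";")]
    genus = ""
    for rank in ranks:
        if rank.startswith("s__"):  # species and below do not name a genus
            continue
        name = normalize_genus(rank)
        if name:
            genus = name
    return genus


def read_mockrobiota_taxonomy(path: str | Path) -> TaxonProfile:
    """Expected mock composition from a lineage/abundance table.

    Entries collapsing to the same genus (e.g. strains of one species) are
    summed; the result is renormalized to exactly 1. Abundance totals outside
    1 +/- ``TAXONOMY_SUM_ATOL`` indicate a corrupt file and raise.
    """
    path = Path(path)
    abundances: dict[str, float] = {}
    rows = _rows(path, skip_header=False)
    for lineno, fields in rows:
        if len(fields) < 2:
            raise TableFormatError(f"{path}:{lineno}: expected lineage and abundance")
        # tolerate a header row: skip the first row iff its abundance is non-numeric
        try:
            abundance = float(fields[-1])
        except ValueError:
            if not abundances and lineno == rows[0][0]:
                continue
            raise TableFormatError(f"{path}:{lineno}: non-numeric abundance {fields[-1]!r}")
        if abundance < 0:
            raise TableFormatError(f"{path}:{lineno}: negative abundance {abundance}")
        genus = _lineage_genus(fields[0])
        if not genus:
            raise TableFormatError(f"{path}:{lineno}: lineage has no genus-level rank")
        abundances[genus] = abundances.get(genus, 0.0) + abundance
    if not abundances:
        raise TableFormatError(f"{path}: empty taxonomy file")
    total = sum(abundances.values())
    if abs(total - 1.0) > TAXONOMY_SUM_ATOL:
        raise TableFormatError(f"{path}: abundances sum to {total}, expected 1")
    abundances = {g: a / total for g, a in abundances.items()}
    return TaxonProfile(abundances=abundances, community_id=path.stem)


def read_count_table(
    path: str | Path, unidentified_token: str = UNIDENTIFIED
) -> CountTable:
    """Genus count table: header row, then ``genus<TAB>count`` rows.

    The configured unidentified token (case as given) maps to the reserved
    category. Negative or non-numeric counts raise, naming the line.
    """
    path = Path(path)
    counts: dict[str, float] = {}
    for lineno, fields in _rows(path, skip_header=True):
        if len(fields) < 2:
            raise TableFormatError(f"{path}:{lineno}: expected genus and count")
        try:
            count = float(fields[1])
        except ValueError:
            raise TableFormatError(f"{path}:{lineno}: non-numeric count {fields[1]!r}")
        if count < 0:
            raise TableFormatError(f"{path}:{lineno}: negative count {count}")
        genus = fields[0].strip()
        if genus == unidentified_token:
            genus = UNIDENTIFIED
        genus = normalize_genus(genus)
        if genus in counts:
            raise TableFormatError(f"{path}:{lineno}: duplicate genus {genus!r}")
        counts[genus] = count
    if not counts:
        raise TableFormatError(f"{path}: empty count table")
    return CountTable(counts=counts, community_id=path.stem)


def write_count_table(counts: CountTable, path: str | Path) -> None:
    """Write ``genus<TAB>count`` with the unidentified category last."""
    path = Path(path)
    keys = sorted(k for k in counts.counts if k != UNIDENTIFIED)
    if UNIDENTIFIED in counts.counts:
        keys.append(UNIDENTIFIED)
    with path.open("w") as fh:
        fh.write("genus\tcount\n")
        for g in keys:
            fh.write(f"{g}\t{counts.counts[g]:g}\n")


def write_taxonomy(profile: TaxonProfile, path: str | Path) -> None:
    """Write a truth composition in the mockrobiota two-column dialect."""
    path = Path(path)
    with path.open("w") as fh:
        for g in sorted(profile.abundances):
            fh.write(f"g__{g}\t{profile.abundances[g]:.10g}\n")


_REPORT_COLUMNS = [
    "community",
    "na_frac",
    "other_frac",
    "shannon_mock",
    "shannon_raw",
    "shannon_gcn",
    "richness_mock",
    "richness_raw",
    "rss_raw",
    "rss_gcn",
    "best_fit",
    "excluded",
]


def write_report(
    results: Sequence[EvaluationResult],
    summary: CohortSummary | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the per-community report TSV and (optionally) the cohort summary.

    Returns the paths written, keyed ``"communities"`` / ``"summary"``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    comm = out_dir / "communities.tsv"
    with comm.open("w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                f"{r.community_id}\t{r.na_frac:.4f}\t{r.other_frac:.4f}\t"
                f"{r.shannon_mock:.4f}\t{r.shannon_raw:.4f}\t{r.shannon_gcn:.4f}\t"
                f"{r.richness_mock}\t{r.richness_raw}\t"
                f"{r.rss_raw:.4f}\t{r.rss_gcn:.4f}\t{r.best_fit}\t"
                f"{'yes' if r.excluded else 'no'}\n"
            )
    paths["communities"] = comm

    if summary is not None:
        summ = out_dir / "summary.tsv"
        fields = [
            ("n", f"{summary.n}"),
            ("mean_rss_diff_pct", f"{summary.mean_rss_diff_pct:.4f}"),
            ("se_rss_diff_pct", f"{summary.se_rss_diff_pct:.4f}"),
            ("mean_richness_overrep_pct", f"{summary.mean_richness_overrep_pct:.4f}"),
            ("se_richness_overrep_pct", f"{summary.se_richness_overrep_pct:.4f}"),
            ("mean_na_pct", f"{summary.mean_na_pct:.4f}"),
            ("se_na_pct", f"{summary.se_na_pct:.4f}"),
            ("mean_other_pct", f"{summary.mean_other_pct:.4f}"),
            ("se_other_pct", f"{summary.se_other_pct:.4f}"),
            ("n_raw_better", f"{summary.n_raw_better}"),
        ]
        with summ.open("w") as fh:
            fh.write("metric\tvalue\n")
            for k, v in fields:
                fh.write(f"{k}\t{v}\n")
        paths["summary"] = summ

    logger.info("wrote report to %s", out_dir)
    return paths
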