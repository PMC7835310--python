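"""Diversity, richness and misidentification metrics, and the exclusion rule.

All metrics operate at genus level. Shannon diversity treats the unidentified
category as one more category when present — it is part of the read
composition the sequencer actually delivered — while richness excludes it,
counting only named genera. Misidentification is always measured on the raw
(uncorrected) relative profile: it describes the classifier's output, not the
normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from gcnbench.profiles import UNIDENTIFIED, TaxonProfile


@dataclass
class MisidSummary:
    """Fractions of the observed composition that are misassigned.

    ``na_frac``: reads unassigned at genus level. ``other_frac``: reads
    assigned to named genera that are not in the mock. Together they cannot
    exceed 1.
    """

    na_frac: float
    other_frac: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.na_frac <= 1.0 and 0.0 <= self.other_frac <= 1.0):
            raise ValueError("misidentification fractions must lie in [0, 1]")
        if self.na_frac + self.other_frac > 1.0 + 1e-9:
            raise ValueError("na_frac + other_frac cannot exceed 1")


def shannon(profile: TaxonProfile, base: float | None = None) -> float:
    """Shannon diversity H = -sum p ln p over categories with p > 0.

    Natural log by default (the vegan convention); pass ``base`` for other
    units. The unidentified category counts as a category when present.
    """
    h = -sum(p * math.log(p) for p in profile.abundances.values() if p > 0)
    if base is not None:
        h /= math.log(base)
    return h


def richness(profile: TaxonProfile) -> int:
    """Number of named genera with abundance > 0 (unidentified excluded)."""
    return sum(
        1 for g, p in profile.abundances.items() if p > 0 and g != UNIDENTIFIED
    )


def misidentification(observed: TaxonProfile, mock: TaxonProfile) -> MisidSummary:
    """Unassigned and wrong-genus fractions of an observed profile.

    ``observed`` must be the raw relative profile; GCN correction reweights
    reads and would distort what is a property of taxonomic assignment alone.
    """
    na = observed.abundances.get(UNIDENTIFIED, 0.0)
    other = sum(
        p
        for g, p in observed.abundances.items()
        if g != UNIDENTIFIED and mock.abundances.get(g, 0.0) == 0.0
    )
    return MisidSummary(na_frac=na, other_frac=other)


def exclusion_filter(
    shannon_raw: float, shannon_mock: float, threshold: float = 0.25
) -> bool:
    """Whether a community's sequencing run should be excluded as failed.

    Returns True (exclude) iff the observed raw Shannon diversity recovers
    strictly less than ``threshold`` of the mock's diversity. A run whose
    diversity collapses to a fifth of the designed community indicates a
    failed library, not a normalization effect. Ratio exactly at the
    threshold keeps the community.
    """
    if shannon_mock <= 0:
        raise ValueError(f"mock Shannon diversity must be > 0, got {shannon_mock}")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return shannon_raw / shannon_mock < threshold
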