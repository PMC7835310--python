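"""Genus-level count tables, relative-abundance profiles, and the RSS fit statistic.

The central comparison is between an observed genus profile (raw, or after
division of counts by gene copy numbers) and the known composition of a mock
community, via the residual sum of squares

    RSS = sum_i (y_i - f(x_i))^2

over the aligned union of genus categories, where y_i is the mock's relative
abundance of category i and f(x_i) the observed one. The reserved
``Unidentified`` category participates with expected abundance 0, since mock
communities contain no unidentified member by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from gcnbench.gcn_db import GCNDatabase

#: Reserved category for reads not assigned at genus level.
UNIDENTIFIED = "Unidentified"

#: Profiles must sum to 1 within this tolerance to be valid.
SIMPLEX_ATOL = 1e-9
#: Inputs are renormalized on construction if their sum is within this of 1.
RENORM_ATOL = 1e-6

_RANK_PREFIXES = ("d__", "k__", "p__", "c__", "o__", "f__", "g__", "s__")


def normalize_genus(name: str) -> str:
    """Trim whitespace and strip a leading rank prefix such as ``g__``.

    Matching thereafter is case-sensitive: mockrobiota lineages carry rank
    prefixes while RDP-style copy-number tables do not, and both use
    capitalized genus names.
    """
    name = name.strip()
    for prefix in _RANK_PREFIXES:
        if name.startswith(prefix):
            return name[len(prefix):].strip()
    return name


@dataclass
class CountTable:
    """Nonnegative read counts per genus for one community."""

    counts: dict[str, float]
    community_id: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for genus, c in self.counts.items():
            name = normalize_genus(genus)
            if not name:
                raise ValueError("empty genus name in count table")
            if name in clean:
                raise ValueError(f"duplicate genus {name!r} after normalization")
            if c < 0:
                raise ValueError(f"negative count for {name!r}: {c}")
            clean[name] = float(c)
        if not any(c > 0 for c in clean.values()):
            raise ValueError("count table must contain at least one positive count")
        self.counts = clean

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))


@dataclass
class TaxonProfile:
    """Relative abundances per genus; sums to 1 on the simplex.

    Sums within ``RENORM_ATOL`` of 1 are renormalized exactly (taxonomy files
    carry rounding); anything further off is rejected.
    """

    abundances: dict[str, float]
    community_id: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for genus, a in self.abundances.items():
            name = normalize_genus(genus)
            if not name:
                raise ValueError("empty genus name in profile")
            if name in clean:
                raise ValueError(f"duplicate genus {name!r} after normalization")
            if a < 0:
                raise ValueError(f"negative abundance for {name!r}: {a}")
            clean[name] = float(a)
        total = sum(clean.values())
        if abs(total - 1.0) > SIMPLEX_ATOL:
            if abs(total - 1.0) <= RENORM_ATOL:
                clean = {g: a / total for g, a in clean.items()}
            else:
                raise ValueError(
                    f"abundances must sum to 1 (got {total!r}) for {self.community_id or 'profile'}"
                )
        self.abundances = clean

    def get(self, genus: str, default: float = 0.0) -> float:
        return self.abundances.get(normalize_genus(genus), default)


@dataclass
class AlignedPair:
    """Expected and observed abundance vectors on a shared category order.

    Categories are the sorted union of both supports, lexicographic with
    ``Unidentified`` last, so outputs are deterministic and diff-stable.
    """

    categories: list[str]
    expected: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.expected = np.asarray(self.expected, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        if not (len(self.categories) == self.expected.size == self.observed.size):
            raise ValueError("categories and vectors must have equal length")


def _sorted_union(keys_a: Iterable[str], keys_b: Iterable[str]) -> list[str]:
    union = set(keys_a) | set(keys_b)
    has_unid = UNIDENTIFIED in union
    cats = sorted(union - {UNIDENTIFIED})
    if has_unid:
        cats.append(UNIDENTIFIED)
    return cats


def align_profiles(observed: TaxonProfile, expected: TaxonProfile) -> AlignedPair:
    """Put two profiles on the common category union; missing entries are 0.

    The mock side of ``Unidentified`` is always 0: mocks are assembled from
    known organisms.
    """
    cats = _sorted_union(observed.abundances, expected.abundances)
    obs = np.array([observed.abundances.get(c, 0.0) for c in cats])
    exp = np.array([expected.abundances.get(c, 0.0) for c in cats])
    return AlignedPair(categories=cats, expected=exp, observed=obs)


def rss(observed: TaxonProfile, expected: TaxonProfile) -> float:
    """Residual sum of squares between two profiles over their aligned union.

    Bounded by [0, 2] for profiles on the simplex; 0 iff the profiles agree on
    every category, 2 at disjoint supports. Symmetric in its arguments.
    """
    pair = align_profiles(observed, expected)
    return float(np.sum((pair.expected - pair.observed) ** 2))


def gcn_correct(counts: CountTable, db: "GCNDatabase") -> CountTable:
    """Divide each genus count by its 16S gene copy number.

    Genera absent from ``db`` (including the unidentified category) are
    divided by the database default. The output has exactly the input's keys;
    counts become real-valued genome-equivalents.
    """
    from gcnbench.gcn_db import lookup_gcn

    corrected = {g: c / lookup_gcn(db, g) for g, c in counts.counts.items()}
    return CountTable(counts=corrected, community_id=counts.community_id)


def to_relative(counts: CountTable) -> TaxonProfile:
    """Convert counts to relative abundances by dividing by the table's own total.

    For raw counts this is the raw read total; for GCN-corrected counts the
    corrected total, so both profiles live on the simplex and are comparable
    by RSS.
    """
    total = counts.total
    if total <= 0:
        raise ValueError(f"cannot normalize zero-total count table {counts.community_id!r}")
    return TaxonProfile(
        abundances={g: c / total for g, c in counts.counts.items()},
        community_id=counts.community_id,
    )
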