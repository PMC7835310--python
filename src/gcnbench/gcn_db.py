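"""Genus-level 16S rRNA gene copy number (GCN) lookup.

A :class:`GCNDatabase` maps genus names to mean copy numbers (copies per
genome), typically derived from an RDP/rrnDB-style release, and carries a
configurable default applied to genera without a reported copy number, to
unidentified reads, and to genera absent from the mock. The conventional
default is 1.8, the mean copy number over genera commonly lacking a reported
value; it is an argument rather than a constant because that convention is
itself under debate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from gcnbench.profiles import UNIDENTIFIED, normalize_genus

logger = logging.getLogger(__name__)

DEFAULT_GCN = 1.8


class GCNParseError(ValueError):
    """Raised when a copy-number table cannot be parsed."""


@dataclass
class GCNDatabase:
    """Mapping genus -> mean 16S gene copy number, with a default for unknowns.

    Parameters
    ----------
    entries
        Genus name (normalized: whitespace trimmed, rank prefix stripped)
        to mean copy number, copies per genome; every value must be > 0.
    default_gcn
        Copy number used for any genus not in ``entries`` and for the
        unidentified category. Must be > 0.
    source_label
        Free-text provenance of the table.
    """

    entries: dict[str, float] = field(default_factory=dict)
    default_gcn: float = DEFAULT_GCN
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.default_gcn > 0:
            raise ValueError(f"default_gcn must be > 0, got {self.default_gcn}")
        normalized: dict[str, float] = {}
        for genus, cn in self.entries.items():
            name = normalize_genus(genus)
            if not name:
                raise ValueError("empty genus name in GCN entries")
            if not cn > 0:
                raise ValueError(f"copy number for {name!r} must be > 0, got {cn}")
            normalized[name] = float(cn)
        self.entries = normalized

    def lookup(self, genus: str) -> float:
        return lookup_gcn(self, genus)


def lookup_gcn(db: GCNDatabase, genus: str) -> float:
    """Copy number for ``genus``; the configured default if unlisted.

    Total over genus names: unidentified reads and genera without a reported
    copy number both receive ``db.default_gcn``.
    """
    name = normalize_genus(genus)
    if name == UNIDENTIFIED:
        return db.default_gcn
    return db.entries.get(name, db.default_gcn)


def load_gcn_table(
    path: str | Path,
    default_gcn: float = DEFAULT_GCN,
    *,
    delimiter: str | None = None,
) -> GCNDatabase:
    """Load a genus/copy-number table (TSV or CSV with header).

    Lines starting with ``#`` are comments. Duplicate genus rows are averaged
    (arithmetic mean), reflecting that a single genus aggregates genomes with
    differing copy numbers. Non-numeric or non-positive copy numbers raise
    :class:`GCNParseError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    with path.open() as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # header row, content not interpreted
                continue
            sep = delimiter if delimiter is not None else ("\t" if "\t" in line else ",")
            fields = line.split(sep)
            if len(fields) < 2:
                raise GCNParseError(f"{path}:{lineno}: expected 2+ columns, got {len(fields)}")
            genus = normalize_genus(fields[0])
            if not genus:
                raise GCNParseError(f"{path}:{lineno}: empty genus name")
            try:
                cn = float(fields[1])
            except ValueError as exc:
                raise GCNParseError(f"{path}:{lineno}: non-numeric copy number {fields[1]!r}") from exc
            if not cn > 0:
                raise GCNParseError(f"{path}:{lineno}: copy number must be > 0, got {cn}")
            sums[genus] = sums.get(genus, 0.0) + cn
            counts[genus] = counts.get(genus, 0) + 1
    if not header_seen:
        raise GCNParseError(f"{path}: empty table")
    entries = {g: sums[g] / counts[g] for g in sums}
    dups = [g for g, k in counts.items() if k > 1]
    if dups:
        logger.info("averaged duplicate GCN rows for: %s", ", ".join(sorted(dups)))
    return GCNDatabase(entries=entries, default_gcn=default_gcn, source_label=str(path))
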