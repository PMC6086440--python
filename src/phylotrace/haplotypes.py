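"""Haplotype collapsing, per-group tabulation and the ITS1 length
diagnostic.

A haplotype is an equivalence class of identical aligned sequences
(exact string equality after uppercasing).  IUPAC ambiguity codes are
*not* expanded — an ``N`` mismatching an ``A`` makes two distinct
haplotypes; this conservative choice is surfaced by a strict-mode
warning listing records carrying ambiguity codes.  Gap characters, when
present, are treated as ordinary characters.

The length classifier implements the ITS1 amplicon-size diagnostic for
the studied black fly species: fragment sizes 82, 110, 111 and 116 bp
map to S. triplex, S. ruficorne, Simulium sp. 1 (Seychelles) and
S. borbonense respectively.  At tolerance 0 the mapping is injective;
any positive tolerance makes 110/111 collide — they are likewise
indistinguishable on agarose gels.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import InputError

__all__ = [
    "Alignment",
    "GroupEntry",
    "HaplotypeTable",
    "LengthClassifier",
    "DEFAULT_LENGTH_CLASSIFIER",
    "read_fasta",
    "read_group_table",
    "groups_from_ids",
    "collapse_haplotypes",
    "haplotype_table",
    "shared_haplotypes",
    "classify_by_length",
]

logger = logging.getLogger(__name__)

_AMBIGUOUS = re.compile(r"[^ACGT\-]")


@dataclass
class Alignment:
    """Aligned sequence records: (id, residues) pairs of equal length,
    with an optional id -> group mapping."""

    records: list[tuple[str, str]]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("alignment contains no records")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate sequence ids: {', '.join(dupes)}")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) > 1:
            off = [rid for rid, seq in self.records
                   if len(seq) != len(self.records[0][1])]
            raise InputError(
                f"unequal sequence lengths; offending ids: {', '.join(off)}"
            )

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GroupEntry:
    """Haplotype summary of one group (species x locality)."""

    group: str
    n_sequences: int
    n_haplotypes: int
    haplotypes: dict[str, list[str]]  # residue string -> member ids

    def haplotype_strings(self) -> set[str]:
        return set(self.haplotypes)


#: table mirroring the published per-group layout
HaplotypeTable = dict


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no sequences found in {path}")
    return records


def read_group_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping sequence id to group label."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"group table not found: {path}")
    groups: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InputError(f"{path}:{lineno}: expected 'id<TAB>group'")
        groups[parts[0]] = parts[1]
    return groups


#: sample ids like ``GY018_borb`` carry the group as a suffix
DEFAULT_ID_PATTERN = re.compile(r"_([A-Za-z0-9.]+)$")


def groups_from_ids(
    ids: Iterable[str], pattern: re.Pattern | str = DEFAULT_ID_PATTERN
) -> dict[str, str]:
    """Derive group labels from id suffixes (``GY018_borb`` -> ``borb``)."""
    if isinstance(pattern, str):
        pattern = re.compile(pattern)
    groups = {}
    for rid in ids:
        m = pattern.search(rid)
        if not m:
            raise InputError(f"cannot derive a group from id {rid!r}")
        groups[rid] = m.group(1)
    return groups


def collapse_haplotypes(
    records: Sequence[tuple[str, str]], group: str = ""
) -> GroupEntry:
    """Collapse identical sequences into haplotypes.

    Identity is exact string equality after uppercasing; haplotypes are
    numbered deterministically by first occurrence.  Records carrying
    IUPAC ambiguity codes are reported with a warning (they are matched
    literally, never expanded).
    """
    if not records:
        raise InputError(f"group {group!r} is empty")
    lengths = {len(seq) for _, seq in records}
    if len(lengths) > 1:
        ref = len(records[0][1])
        off = [rid for rid, seq in records if len(seq) != ref]
        raise InputError(
            f"group {group!r}: unequal sequence lengths "
            f"(offending ids: {', '.join(off)})"
        )
    ambiguous = [rid for rid, seq in records if _AMBIGUOUS.search(seq.upper())]
    if ambiguous:
        logger.warning(
            "group %r: %d record(s) carry IUPAC ambiguity codes, matched "
            "literally: %s", group, len(ambiguous), ", ".join(ambiguous)
        )
    haplotypes: dict[str, list[str]] = {}
    for rid, seq in records:
        haplotypes.setdefault(seq.upper(), []).append(rid)
    return GroupEntry(
        group=group,
        n_sequences=len(records),
        n_haplotypes=len(haplotypes),
        haplotypes=haplotypes,
    )


def haplotype_table(
    alignment: Alignment, groups: Mapping[str, str] | None = None
) -> HaplotypeTable:
    """Per-group haplotype collapse, one entry per group in first-seen
    order.  Every record must be grouped."""
    groups = dict(groups) if groups is not None else dict(alignment.groups)
    ungrouped = [rid for rid, _ in alignment.records if rid not in groups]
    if ungrouped:
        raise InputError(f"ungrouped records: {', '.join(ungrouped)}")
    by_group: dict[str, list[tuple[str, str]]] = {}
    for rid, seq in alignment.records:
        by_group.setdefault(groups[rid], []).append((rid, seq))
    return {
        g: collapse_haplotypes(recs, group=g) for g, recs in by_group.items()
    }


def shared_haplotypes(a: GroupEntry, b: GroupEntry) -> set[str]:
    """Haplotype strings present in both groups (e.g. to detect a shared
    nuclear sequence between island and continental populations)."""
    strings_a, strings_b = a.haplotype_strings(), b.haplotype_strings()
    len_a = {len(s) for s in strings_a}
    len_b = {len(s) for s in strings_b}
    if len_a != len_b:
        raise InputError(
            f"groups {a.group!r} and {b.group!r} have different sequence "
            f"lengths; not the same locus"
        )
    return strings_a & strings_b


@dataclass
class LengthClassifier:
    """Fragment length (bp) -> species label lookup with a tolerance."""

    table: dict[int, str]
    tolerance: int = 0

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.table):
            raise InputError("fragment lengths must be positive")
        if self.tolerance > 0:
            lengths = sorted(self.table)
            for a, b in zip(lengths, lengths[1:]):
                if b - a <= self.tolerance:
                    logger.warning(
                        "length classes %d and %d bp overlap at tolerance "
                        "%d; queries between them will be ambiguous",
                        a, b, self.tolerance,
                    )


DEFAULT_LENGTH_CLASSIFIER = LengthClassifier(
    table={
        82: "S. triplex",
        110: "S. ruficorne",
        111: "Simulium sp. 1",
        116: "S. borbonense",
    },
    tolerance=0,
)
# 110 vs 111 bp cannot be told apart on an agarose gel; any tolerance > 0
# makes them formally ambiguous too.


def classify_by_length(
    length: int, classifier: LengthClassifier = DEFAULT_LENGTH_CLASSIFIER
) -> str:
    """Species label for an amplicon length; ``"unknown"`` when no class
    matches, ``"ambiguous{a, b}"`` when several do within tolerance."""
    if length <= 0:
        raise InputError(f"fragment length must be positive; got {length}")
    matches = [
        label
        for ref, label in sorted(classifier.table.items())
        if abs(length - ref) <= classifier.tolerance
    ]
    if not matches:
        return "unknown"
    if len(matches) > 1:
        return "ambiguous{" + ", ".join(matches) + "}"
    return matches[0]
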