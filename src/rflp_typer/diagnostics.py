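"""Diagnostic-SNP discovery and enzyme screening on grouped alignments.

A *fixed diagnostic SNP* is an alignment column where every member of a
target group carries one base and every member of every other group
carries something else — the signal an RFLP assay is built on. Columns
containing gaps are excluded by default (an indel shifts every
downstream restriction coordinate), and ambiguity codes are treated as
missing data rather than as alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .enzymes import (
    FragmentPattern,
    RestrictionEnzyme,
    Tolerance,
    digest,
    patterns_compatible,
)
from .iupac import CONCRETE_BASES

__all__ = [
    "AlignedRecord",
    "GroupedAlignment",
    "DiagnosticSite",
    "AssayCandidate",
    "CodonReport",
    "find_fixed_snps",
    "find_shared_snps",
    "screen_enzymes",
    "annotate_snp_in_orf",
]

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class AlignedRecord:
    id: str
    group: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def ungapped(self) -> str:
        return "".join(c for c in self.seq if c not in GAP_CHARS)


class GroupedAlignment:
    """Aligned sequences partitioned into species/haplotype groups."""

    def __init__(self, records: Sequence[AlignedRecord]):
        if not records:
            raise ValueError("alignment needs at least one record")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
        if any(not r.group for r in records):
            raise ValueError("every record needs a group label")
        self.records: tuple[AlignedRecord, ...] = tuple(records)
        self.length: int = lengths.pop()

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.group, None)
        return tuple(seen)

    def records_in(self, group: str) -> tuple[AlignedRecord, ...]:
        return tuple(r for r in self.records if r.group == group)

    def column(self, col: int) -> tuple[str, ...]:
        """Characters at 1-based alignment column *col*, record order."""
        if not 1 <= col <= self.length:
            raise ValueError(f"column {col} outside 1..{self.length}")
        return tuple(r.seq[col - 1] for r in self.records)

    def ungapped_position(self, record: AlignedRecord, col: int) -> int | None:
        """1-based ungapped coordinate of alignment column *col* in *record*.

        None when the record has a gap at that column.
        """
        if record.seq[col - 1] in GAP_CHARS:
            return None
        return sum(1 for c in record.seq[:col] if c not in GAP_CHARS)

    @classmethod
    def from_fasta(
        cls,
        path: "str | Path",
        groups: "str | Path | Mapping[str, str] | None" = None,
    ) -> "GroupedAlignment":
        """Load a FASTA alignment; group labels come from a two-column
        TSV (id, group) or, failing that, the second header token."""
        mapping: dict[str, str] = {}
        if groups is not None and not isinstance(groups, Mapping):
            with open(groups, encoding="utf-8") as fh:
                for line in fh:
                    line = line.strip()
                    if not line or line.startswith("#"):
                        continue
                    parts = line.split("\t")
                    if parts[0].lower() == "id":
                        continue
                    mapping[parts[0]] = parts[1]
        elif isinstance(groups, Mapping):
            mapping = dict(groups)
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in mapping:
                group = mapping[rec.id]
            else:
                tokens = rec.description.split(None, 1)
                group = tokens[1].strip() if len(tokens) > 1 else ""
            records.append(AlignedRecord(rec.id, group, str(rec.seq)))
        return cls(records)


@dataclass(frozen=True)
class DiagnosticSite:
    """An alignment column diagnostic for a (set of) group(s)."""

    column: int
    target_groups: tuple[str, ...]
    target_allele: str
    other_alleles: frozenset[str]
    site_type: str  # "group-fixed-unique" | "shared-by-subset"

    @property
    def target_group(self) -> str:
        return self.target_groups[0]


def _column_tallies(
    aln: GroupedAlignment, subset: frozenset[str], col: int, allow_gaps: bool
) -> tuple[set[str], set[str]] | None:
    """(target bases, other bases) at *col*, or None if the column is
    excluded (gap) / uninformative (all-missing on either side)."""
    chars = aln.column(col)
    if not allow_gaps and any(c in GAP_CHARS for c in chars):
        return None
    target: set[str] = set()
    other: set[str] = set()
    for rec, c in zip(aln.records, chars):
        if c not in CONCRETE_BASES:
            continue  # ambiguity or gap: missing data at this column
        (target if rec.group in subset else other).add(c)
    if not target or not other:
        return None
    return target, other


def find_shared_snps(
    aln: GroupedAlignment,
    group_subset: Iterable[str],
    allow_gaps: bool = False,
) -> list[DiagnosticSite]:
    """Columns fixed within *group_subset* for an allele absent elsewhere.

    With a single-group subset this is exactly the fixed-SNP scan; with
    several groups it finds the markers they jointly share (e.g. a site
    two sibling haplotypes both carry).
    """
    subset = frozenset(group_subset)
    known = set(aln.groups)
    unknown = subset - known
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    if not subset:
        raise ValueError("group subset must be non-empty")
    if subset == known:
        raise ValueError("group subset must be a proper subset of the groups")
    site_type = "group-fixed-unique" if len(subset) == 1 else "shared-by-subset"
    sites = []
    for col in range(1, aln.length + 1):
        tallies = _column_tallies(aln, subset, col, allow_gaps)
        if tallies is None:
            continue
        target, other = tallies
        if len(target) == 1 and not (target & other):
            sites.append(
                DiagnosticSite(
                    column=col,
                    target_groups=tuple(sorted(subset)),
                    target_allele=next(iter(target)),
                    other_alleles=frozenset(other),
                    site_type=site_type,
                )
            )
    return sites


def find_fixed_snps(
    aln: GroupedAlignment, target_group: str, allow_gaps: bool = False
) -> list[DiagnosticSite]:
    """Columns where *target_group* is fixed for an allele no other
    group carries."""
    return find_shared_snps(aln, {target_group}, allow_gaps=allow_gaps)


@dataclass(frozen=True)
class AssayCandidate:
    """One enzyme's predicted per-group patterns and the split it induces."""

    amplicon_label: str
    enzyme: RestrictionEnzyme
    per_group_patterns: Mapping[str, FragmentPattern]
    partition: tuple[tuple[str, ...], ...]
    reliable: bool
    unreliable_groups: tuple[str, ...] = ()

    @property
    def n_blocks(self) -> int:
        return len(self.partition)


def _partition_groups(
    patterns: Mapping[str, FragmentPattern],
    min_detect: float,
    tolerance: Tolerance,
) -> tuple[tuple[str, ...], ...]:
    """Greedy partition of groups into gel-indistinguishable blocks."""
    blocks: list[tuple[FragmentPattern, list[str]]] = []
    for group in patterns:
        for rep, members in blocks:
            if patterns_compatible(rep, patterns[group], min_detect, tolerance):
                members.append(group)
                break
        else:
            blocks.append((patterns[group], [group]))
    return tuple(tuple(sorted(members)) for _, members in blocks)


def screen_enzymes(
    aln: GroupedAlignment,
    enzymes: Mapping[str, RestrictionEnzyme],
    min_detect: float = 0.0,
    tolerance: Tolerance = Tolerance(),
    amplicon_label: str = "amplicon",
) -> list[AssayCandidate]:
    """Digest every group's sequences with every enzyme and rank the
    enzymes by how many groups their band patterns separate.

    Each record is digested on its ungapped sequence. A group whose
    records disagree among themselves marks the candidate unreliable
    (the group's first pattern still represents it) rather than being
    silently merged or dropped.
    """
    tolerance = Tolerance.parse(tolerance)
    candidates = []
    for enzyme in sorted(enzymes.values(), key=lambda e: e.name):
        per_group: dict[str, FragmentPattern] = {}
        unreliable: list[str] = []
        for group in aln.groups:
            pats = [digest(r.ungapped, enzyme) for r in aln.records_in(group)]
            if any(p != pats[0] for p in pats[1:]):
                unreliable.append(group)
            per_group[group] = pats[0]
        candidates.append(
            AssayCandidate(
                amplicon_label=amplicon_label,
                enzyme=enzyme,
                per_group_patterns=per_group,
                partition=_partition_groups(per_group, min_detect, tolerance),
                reliable=not unreliable,
                unreliable_groups=tuple(unreliable),
            )
        )
    return sorted(candidates, key=lambda c: (-c.n_blocks, c.enzyme.name))


@dataclass(frozen=True)
class CodonReport:
    """Where a SNP falls within a reading frame, and its protein effect."""

    codon_index: int  # 1-based codon number from orf_start
    position_in_codon: int  # 1, 2 or 3
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa


def annotate_snp_in_orf(
    sequence: str, orf_start: int, column: int, alt_base: str
) -> CodonReport:
    """Translate the reference and alternate codons spanning a SNP.

    *orf_start* and *column* are 1-based positions on the ungapped
    sequence; the standard genetic code is used.
    """
    seq = sequence.upper()
    if column < orf_start:
        raise ValueError(f"column {column} upstream of orf_start {orf_start}")
    if column > len(seq):
        raise ValueError(f"column {column} beyond sequence end {len(seq)}")
    alt_base = alt_base.upper()
    if alt_base not in CONCRETE_BASES:
        raise ValueError(f"alternate base must be A/C/G/T, got {alt_base!r}")
    codon_index = (column - orf_start) // 3
    codon_start = orf_start + 3 * codon_index  # 1-based
    if codon_start + 2 > len(seq):
        raise ValueError("codon truncated by sequence end")
    ref_codon = seq[codon_start - 1 : codon_start + 2]
    pos_in_codon = column - codon_start + 1
    alt_codon = (
        ref_codon[: pos_in_codon - 1] + alt_base + ref_codon[pos_in_codon:]
    )
    return CodonReport(
        codon_index=codon_index + 1,
        position_in_codon=pos_in_codon,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=str(Seq(ref_codon).translate()),
        alt_aa=str(Seq(alt_codon).translate()),
    )
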