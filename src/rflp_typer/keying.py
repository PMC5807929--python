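"""Stepwise identification keys over digest-pattern tables.

The key is a decision tree: each internal node names one assay
(amplicon x enzyme) and branches on the distinguishable band-pattern
classes of the groups still in play; leaves hold the surviving species
set. Construction is greedy — at every node the assay splitting the
remaining groups into the most blocks wins, with a deterministic
tie-break — which on the reference table reproduces the hand-built
laboratory cascade's resolving power in three steps. The published
cascade itself (SacI first, then XhoI / AlwNI / AciI / NlaIV / Tsp45I)
is available as a fixed profile for faithful replication.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .enzymes import (
    DEFAULT_ENZYMES,
    FragmentPattern,
    RestrictionEnzyme,
    Tolerance,
    digest,
    patterns_compatible,
)

__all__ = [
    "Assay",
    "PatternTable",
    "KeyNode",
    "IdentificationKey",
    "SpeciesCall",
    "NeedsAmpliconError",
    "build_key",
    "published_key",
    "build_pattern_table",
    "classify_sequence",
    "classify_observed",
]


@dataclass(frozen=True, order=True)
class Assay:
    """One diagnostic step: digest a named amplicon with one enzyme."""

    amplicon: str
    enzyme: str

    def __str__(self) -> str:
        return f"{self.amplicon}:{self.enzyme}"

    @classmethod
    def parse(cls, text: str) -> "Assay":
        amplicon, _, enzyme = text.partition(":")
        if not enzyme:
            raise ValueError(f"assay must look like 'amplicon:enzyme', got {text!r}")
        return cls(amplicon, enzyme)


class PatternTable:
    """Predicted fragment pattern for every (group, assay) pair."""

    def __init__(
        self,
        patterns: Mapping[tuple[str, Assay], FragmentPattern],
    ):
        groups = sorted({g for g, _ in patterns})
        assays = sorted({a for _, a in patterns})
        missing = [
            (g, str(a)) for g in groups for a in assays if (g, a) not in patterns
        ]
        if missing:
            raise ValueError(f"pattern table incomplete; missing {missing}")
        self.groups: tuple[str, ...] = tuple(groups)
        self.assays: tuple[Assay, ...] = tuple(assays)
        self._patterns = dict(patterns)

    def __getitem__(self, key: tuple[str, Assay]) -> FragmentPattern:
        return self._patterns[key]

    def pattern(self, group: str, assay: Assay) -> FragmentPattern:
        return self._patterns[(group, assay)]

    def to_json(self) -> dict:
        return {
            "groups": list(self.groups),
            "assays": [str(a) for a in self.assays],
            "patterns": {
                g: {str(a): list(self.pattern(g, a)) for a in self.assays}
                for g in self.groups
            },
        }

    @classmethod
    def from_json(cls, data: dict) -> "PatternTable":
        patterns = {}
        for g, per_assay in data["patterns"].items():
            for assay_text, lengths in per_assay.items():
                patterns[(g, Assay.parse(assay_text))] = FragmentPattern(
                    tuple(int(x) for x in lengths)
                )
        return cls(patterns)


def build_pattern_table(
    sequences: Mapping[str, Mapping[str, str]],
    assays: Sequence[Assay],
    enzymes: Mapping[str, RestrictionEnzyme] = DEFAULT_ENZYMES,
) -> PatternTable:
    """Digest every group's amplicons to fill a pattern table.

    *sequences* maps group -> {amplicon label -> amplicon sequence}.
    An amplicon with no cut site yields the one-band pattern equal to
    its full length, mirroring how uncut lanes are scored.
    """
    patterns = {}
    for group, amplicons in sequences.items():
        for assay in assays:
            if assay.amplicon not in amplicons:
                raise ValueError(
                    f"group {group!r} lacks amplicon {assay.amplicon!r}"
                )
            patterns[(group, assay)] = digest(
                amplicons[assay.amplicon], enzymes[assay.enzyme]
            )
    return PatternTable(patterns)


@dataclass(frozen=True)
class KeyNode:
    """Internal node (assay + pattern-labelled branches) or leaf (species)."""

    species: tuple[str, ...] = ()
    assay: Assay | None = None
    branches: tuple[tuple[FragmentPattern, "KeyNode"], ...] = ()

    @property
    def is_leaf(self) -> bool:
        return self.assay is None

    def to_json(self) -> dict:
        if self.is_leaf:
            return {"species": list(self.species)}
        return {
            "assay": str(self.assay),
            "branches": [
                {"pattern": list(p), "node": child.to_json()}
                for p, child in self.branches
            ],
        }

    @classmethod
    def from_json(cls, data: dict) -> "KeyNode":
        if "assay" in data:
            return cls(
                assay=Assay.parse(data["assay"]),
                branches=tuple(
                    (
                        FragmentPattern(tuple(int(x) for x in b["pattern"])),
                        cls.from_json(b["node"]),
                    )
                    for b in data["branches"]
                ),
            )
        return cls(species=tuple(data["species"]))


@dataclass(frozen=True)
class IdentificationKey:
    root: KeyNode
    min_detect: float = 0.0
    tolerance: Tolerance = Tolerance()

    def leaves(self) -> list[tuple[str, ...]]:
        out: list[tuple[str, ...]] = []

        def walk(node: KeyNode) -> None:
            if node.is_leaf:
                out.append(node.species)
            else:
                for _, child in node.branches:
                    walk(child)

        walk(self.root)
        return out

    def assay_paths(self) -> list[tuple[tuple[Assay, ...], tuple[str, ...]]]:
        """(assay sequence, leaf species) for every root-to-leaf path."""
        out = []

        def walk(node: KeyNode, path: tuple[Assay, ...]) -> None:
            if node.is_leaf:
                out.append((path, node.species))
            else:
                for _, child in node.branches:
                    walk(child, path + (node.assay,))

        walk(self.root, ())
        return out

    @property
    def depth(self) -> int:
        return max((len(p) for p, _ in self.assay_paths()), default=0)

    def to_json(self) -> dict:
        return {
            "min_detect": self.min_detect,
            "tolerance": {"bp": self.tolerance.bp, "frac": self.tolerance.frac},
            "root": self.root.to_json(),
        }

    @classmethod
    def from_json(cls, data: dict) -> "IdentificationKey":
        tol = data.get("tolerance", {})
        return cls(
            root=KeyNode.from_json(data["root"]),
            min_detect=float(data.get("min_detect", 0.0)),
            tolerance=Tolerance(float(tol.get("bp", 0)), float(tol.get("frac", 0))),
        )

    def dumps(self) -> str:
        return json.dumps(self.to_json(), indent=2, sort_keys=True)

    @classmethod
    def loads(cls, text: str) -> "IdentificationKey":
        return cls.from_json(json.loads(text))

    def render_text(self) -> str:
        """Indented plain-text dichotomous key."""
        lines: list[str] = []

        def walk(node: KeyNode, depth: int) -> None:
            pad = "  " * depth
            if node.is_leaf:
                label = ", ".join(node.species) if node.species else "(no species)"
                lines.append(f"{pad}=> {label}")
                return
            lines.append(f"{pad}[{node.assay}]")
            for pattern, child in node.branches:
                lines.append(f"{pad}  bands {pattern}:")
                walk(child, depth + 2)

        walk(self.root, 0)
        return "\n".join(lines)


def _blocks_for(
    table: PatternTable,
    groups: Sequence[str],
    assay: Assay,
    min_detect: float,
    tolerance: Tolerance,
) -> list[list[str]]:
    blocks: list[tuple[FragmentPattern, list[str]]] = []
    for g in groups:
        pat = table.pattern(g, assay)
        for rep, members in blocks:
            if patterns_compatible(rep, pat, min_detect, tolerance):
                members.append(g)
                break
        else:
            blocks.append((pat, [g]))
    return [members for _, members in blocks]


def build_key(
    table: PatternTable,
    min_detect: float = 0.0,
    tolerance: Tolerance = Tolerance(),
) -> IdentificationKey:
    """Greedy decision tree over the pattern table.

    At each node the assay splitting the remaining groups into the most
    distinguishable blocks is chosen; ties go to the assay leaving the
    fewest groups in unresolved (non-singleton) blocks, then to the
    lexicographically first enzyme, then amplicon. Groups identical
    across all assays end in a shared ambiguous leaf (with a warning).
    """
    tolerance = Tolerance.parse(tolerance)
    if len(table.groups) < 2:
        return IdentificationKey(
            KeyNode(species=table.groups), min_detect, tolerance
        )

    def grow(groups: tuple[str, ...], used: frozenset[Assay]) -> KeyNode:
        if len(groups) == 1:
            return KeyNode(species=groups)
        best: tuple | None = None
        for assay in table.assays:
            if assay in used:
                continue
            blocks = _blocks_for(table, groups, assay, min_detect, tolerance)
            if len(blocks) < 2:
                continue
            unresolved = sum(len(b) for b in blocks if len(b) > 1)
            score = (-len(blocks), unresolved, assay.enzyme, assay.amplicon)
            if best is None or score < best[0]:
                best = (score, assay, blocks)
        if best is None:
            warnings.warn(
                f"groups {groups} share identical patterns across all assays; "
                "ambiguous leaf",
                stacklevel=2,
            )
            return KeyNode(species=tuple(sorted(groups)))
        _, assay, blocks = best
        branches = tuple(
            (
                table.pattern(block[0], assay),
                grow(tuple(block), used | {assay}),
            )
            for block in blocks
        )
        return KeyNode(assay=assay, branches=branches)

    return IdentificationKey(
        grow(tuple(table.groups), frozenset()), min_detect, tolerance
    )


#: The laboratory cascade: mtORF+SacI first; type-1 colonies move to
#: PocHistone+XhoI; everything else runs AlwNI, then AciI, then the
#: NlaIV confirmation, then Tsp45I.
PUBLISHED_ASSAY_ORDER: tuple[Assay, ...] = (
    Assay("mtORF", "SacI"),
    Assay("PocHistone", "XhoI"),
    Assay("mtORF", "AlwNI"),
    Assay("mtORF", "AciI"),
    Assay("mtORF", "NlaIV"),
    Assay("mtORF", "Tsp45I"),
)


def published_key(
    table: PatternTable,
    min_detect: float = 0.0,
    tolerance: Tolerance = Tolerance(),
) -> IdentificationKey:
    """The fixed published cascade rendered over *table*'s patterns.

    Assays are applied in the laboratory order. An assay that does not
    split the remaining groups is normally skipped, but is kept as a
    single-branch *confirmation* step when its shared pattern still
    distinguishes the remaining groups from every group excluded
    earlier on the path — this is exactly the role of the NlaIV digest
    run before Tsp45I, which confirms a colony is acuta/damicornis
    without separating the two.
    """
    tolerance = Tolerance.parse(tolerance)

    def discriminates_excluded(
        groups: tuple[str, ...], excluded: tuple[str, ...], assay: Assay
    ) -> bool:
        shared = table.pattern(groups[0], assay)
        return bool(excluded) and all(
            not patterns_compatible(
                shared, table.pattern(g, assay), min_detect, tolerance
            )
            for g in excluded
        )

    def grow(
        groups: tuple[str, ...],
        order: tuple[Assay, ...],
        excluded: tuple[str, ...],
    ) -> KeyNode:
        if len(groups) == 1 or not order:
            return KeyNode(species=tuple(sorted(groups)))
        assay, rest = order[0], order[1:]
        if assay not in table.assays:
            return grow(groups, rest, excluded)
        blocks = _blocks_for(table, groups, assay, min_detect, tolerance)
        if len(blocks) < 2 and not discriminates_excluded(groups, excluded, assay):
            return grow(groups, rest, excluded)
        branches = tuple(
            (
                table.pattern(block[0], assay),
                grow(
                    tuple(block),
                    rest,
                    excluded + tuple(g for g in groups if g not in block),
                ),
            )
            for block in blocks
        )
        return KeyNode(assay=assay, branches=branches)

    return IdentificationKey(
        grow(tuple(table.groups), PUBLISHED_ASSAY_ORDER, ()), min_detect, tolerance
    )


@dataclass(frozen=True)
class SpeciesCall:
    """Outcome of classifying one sample.

    ``outcome`` is ``"species"`` (single group), ``"ambiguous"``
    (several groups remain) or ``"no-match"``; ``assay_path`` records
    every assay consulted with the pattern observed or predicted there.
    """

    outcome: str
    species: tuple[str, ...]
    assay_path: tuple[tuple[Assay, FragmentPattern], ...] = ()
    missing_amplicon: str | None = None

    @property
    def is_single(self) -> bool:
        return self.outcome == "species"


class NeedsAmpliconError(ValueError):
    """Traversal requires an amplicon the caller did not provide."""

    def __init__(self, amplicon: str):
        self.amplicon = amplicon
        super().__init__(
            f"identification requires the {amplicon!r} amplicon sequence"
        )


def _call_from_groups(
    groups: tuple[str, ...],
    path: tuple[tuple[Assay, FragmentPattern], ...],
    missing: str | None = None,
) -> SpeciesCall:
    if not groups:
        return SpeciesCall("no-match", (), path, missing)
    outcome = "species" if len(groups) == 1 else "ambiguous"
    return SpeciesCall(outcome, tuple(sorted(groups)), path, missing)


def classify_sequence(
    seqs: Mapping[str, str],
    key: IdentificationKey,
    enzymes: Mapping[str, RestrictionEnzyme] = DEFAULT_ENZYMES,
    raise_on_missing: bool = False,
) -> SpeciesCall:
    """Traverse *key*, digesting the sample's amplicons in silico.

    *seqs* maps amplicon label -> amplicon sequence. When a needed
    amplicon is absent the call returns the still-possible species as an
    ambiguous outcome naming the missing amplicon (or raises
    :class:`NeedsAmpliconError` with ``raise_on_missing=True``). A
    pattern matching no branch yields a no-match call.
    """
    node = key.root
    path: list[tuple[Assay, FragmentPattern]] = []
    while not node.is_leaf:
        assay = node.assay
        if assay.amplicon not in seqs:
            if raise_on_missing:
                raise NeedsAmpliconError(assay.amplicon)
            reachable = tuple(
                sp for _, child in node.branches for sp in _leaf_species(child)
            )
            return _call_from_groups(reachable, tuple(path), assay.amplicon)
        observed = digest(seqs[assay.amplicon], enzymes[assay.enzyme])
        path.append((assay, observed))
        for pattern, child in node.branches:
            if patterns_compatible(
                pattern, observed, key.min_detect, key.tolerance
            ):
                node = child
                break
        else:
            return SpeciesCall("no-match", (), tuple(path))
    return _call_from_groups(node.species, tuple(path))


def _leaf_species(node: KeyNode) -> tuple[str, ...]:
    if node.is_leaf:
        return node.species
    return tuple(
        sp for _, child in node.branches for sp in _leaf_species(child)
    )


def classify_observed(
    bands: Sequence[tuple[Assay, Sequence[int]]],
    table: PatternTable,
    min_detect: float = 0.0,
    tolerance: Tolerance = Tolerance(),
) -> SpeciesCall:
    """Score observed gel bands against every group's predictions.

    Keeps every group whose predicted pattern is compatible with *every*
    observation under (min_detect, tolerance); a singleton survivor is
    a species call, several survivors an ambiguous set, none a
    no-match.
    """
    tolerance = Tolerance.parse(tolerance)
    if not bands:
        raise ValueError("at least one assay observation is required")
    observations: list[tuple[Assay, FragmentPattern]] = []
    for assay, lengths in bands:
        if not lengths:
            raise ValueError(f"empty band list for assay {assay}")
        if assay not in table.assays:
            raise ValueError(f"assay {assay} not in the pattern table")
        observations.append((assay, FragmentPattern(tuple(int(x) for x in lengths))))
    survivors = [
        g
        for g in table.groups
        if all(
            patterns_compatible(
                table.pattern(g, assay), obs, min_detect, tolerance
            )
            for assay, obs in observations
        )
    ]
    return _call_from_groups(tuple(survivors), tuple(observations))
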