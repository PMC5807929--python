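"""Synthetic Pocillopora haplotype generator.

Builds the two marker amplicons — mtORF (978 bp, FatP6.1/RORF) and
PocHistone (669 bp, PocHistoneF/R) — for the six Hawaiian species, as
constraint-satisfying sequences rather than biological mimics: every
published fragment multiset, diagnostic SNP column and primer footprint
is implanted on a shared random background, and rejection resampling
scrubs the background of any unintended recognition site of the six
assay enzymes (and of any stray primer hit). Species differ from the
shared master only at the declared override columns, so the alignments
are gap-free and alignment columns equal ungapped positions.

Coordinate anchors (1-based on the amplicon):

======================  =======================================================
mtORF
  SacI site 676-681     type 1 only; diagnostic adenine at column 677 (the
                        site's second base); cut after 680 -> 298 + 680
  AciI site 209-212     verrucosa only (C/G SNPs at 210-211); shared AciI site
                        at 547-550 in every species; cuts 209(+547) ->
                        209 + 338 + 431, others 547 + 431
  AlwNI site 462-470    ligulata (and mtORF type 11): C SNP at 462; cut after
                        467 -> 467 + 511
  NlaIV sites 313/343/514 (cuts 315/345/516): 313+514 in type 1, ligulata,
                        acuta, damicornis; 343 in acuta+damicornis only;
                        514 in all -> 30/171/315/462, 201/315/462, 462/516
  Tsp45I site 449-453   damicornis only (cut after 448 -> 448 + 530);
                        independent damicornis C SNP at 534
PocHistone
  XhoI site 287-292     eydouxi only; cut after 287 -> 287 + 382
  SNP column 279        eydouxi T (leucine, codon position 2), others G
                        (arginine); reading frame anchored at 5
======================  =======================================================

The 534 SNP and the Tsp45I footprint, and the 279 SNP and the XhoI
footprint, cannot be co-located under the printed fragment sizes; each
pair is implanted independently and flagged in the consistency report.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .diagnostics import AlignedRecord, GroupedAlignment, find_shared_snps
from .enzymes import DEFAULT_ENZYMES, digest, find_cut_sites
from .iupac import EXPANSION, reverse_complement
from .keying import Assay, PatternTable, build_pattern_table
from .pcr import PRIMERS, amplify, find_primer_sites

__all__ = [
    "CORE_SPECIES",
    "EXTRA_HAPLOTYPES",
    "MTORF_LENGTH",
    "POCHISTONE_LENGTH",
    "POCHISTONE_ORF_START",
    "EXPECTED_MTORF_FRAGMENTS",
    "EXPECTED_POCHISTONE_FRAGMENTS",
    "FixtureGenerationError",
    "generate_fixture_set",
    "mtorf_alignment",
    "pochistone_alignment",
    "assert_fixture_consistency",
    "default_assays",
    "default_pattern_table",
    "write_fixture_files",
]

MTORF_LENGTH = 978
POCHISTONE_LENGTH = 669
POCHISTONE_ORF_START = 5  # 1-based; puts column 279 at codon position 2

CORE_SPECIES: tuple[str, ...] = (
    "P. eydouxi",
    "P. meandrina",
    "P. verrucosa",
    "P. ligulata",
    "P. acuta",
    "P. damicornis",
)

#: Additional mtORF haplotypes behind the include_extra_haplotypes flag,
#: used for the cross-cutting pattern checks.
EXTRA_HAPLOTYPES: tuple[str, ...] = (
    "mtORF type 8",
    "mtORF type 11",
    "mtORF type 3i",
    "mtORF type 3f",
)


class FixtureGenerationError(RuntimeError):
    """A constraint collision the generator could not repair."""


def _concretize(primer_seq: str) -> str:
    """Resolve degenerate primer positions to fixed template bases."""
    return "".join(
        c if c in "ACGT" else sorted(EXPANSION[c])[-1] for c in primer_seq
    )


# --- mtORF layout -----------------------------------------------------------

_MTORF_FWD = _concretize(PRIMERS["FatP6.1"].sequence)  # columns 1-20
_MTORF_REV = reverse_complement(_concretize(PRIMERS["RORF"].sequence))  # 955-978

#: master-sequence implants: 1-based start -> fixed bases. The master
#: carries the *broken* variant of every polymorphic site; overrides
#: below switch individual columns to create sites per species.
_MTORF_IMPLANTS: dict[int, str] = {
    1: _MTORF_FWD,
    192: "GG",  # type 3i NlaIV site, first half (GGxxCA in master)
    196: "CA",
    205: "GTAA",  # type 3f Tsp45I site broken at 207 (S position)
    209: "CAAC",  # verrucosa AciI site broken at 210-211
    313: "GG",  # NlaIV site shared by type 1/8/11, ligulata, acuta, damicornis
    317: "CC",
    343: "GA",  # acuta+damicornis NlaIV site broken at 344
    347: "CC",
    449: "GTAAC",  # damicornis Tsp45I site broken at 451 (S position)
    462: "AAG",  # ligulata AlwNI site broken at 462
    468: "CTG",
    514: "GG",  # NlaIV site shared by every haplotype
    518: "CC",
    534: "A",  # damicornis diagnostic column (C in damicornis)
    547: "CCGC",  # AciI site shared by every haplotype
    676: "GGGCTC",  # SacI site broken at 677; type 1 adenine restores GAGCTC
    955: _MTORF_REV,
}

#: per-haplotype column overrides (1-based column -> base)
_TYPE1 = {677: "A"}
_VERRUCOSA = {210: "C", 211: "G", 314: "A"}
_MTORF_OVERRIDES: dict[str, dict[int, str]] = {
    "P. eydouxi": _TYPE1,
    "P. meandrina": _TYPE1,
    "P. verrucosa": _VERRUCOSA,
    "P. ligulata": {462: "C"},
    "P. acuta": {344: "G"},
    "P. damicornis": {344: "G", 451: "G", 534: "C"},
    "mtORF type 8": {},
    "mtORF type 11": {462: "C"},
    "mtORF type 3i": {**_VERRUCOSA, 515: "A", 197: "C"},
    "mtORF type 3f": {**_VERRUCOSA, 207: "G"},
}

#: intended top-strand cut positions per haplotype per enzyme; the
#: generator scrubs the background until these are the only cuts.
_MTORF_CUTS: dict[str, dict[str, frozenset[int]]] = {
    "P. eydouxi": {"SacI": frozenset({680}), "AciI": frozenset({547}),
                   "NlaIV": frozenset({315, 516})},
    "P. meandrina": {"SacI": frozenset({680}), "AciI": frozenset({547}),
                     "NlaIV": frozenset({315, 516})},
    "P. verrucosa": {"AciI": frozenset({209, 547}), "NlaIV": frozenset({516})},
    "P. ligulata": {"AlwNI": frozenset({467}), "AciI": frozenset({547}),
                    "NlaIV": frozenset({315, 516})},
    "P. acuta": {"AciI": frozenset({547}), "NlaIV": frozenset({315, 345, 516})},
    "P. damicornis": {"AciI": frozenset({547}),
                      "NlaIV": frozenset({315, 345, 516}),
                      "Tsp45I": frozenset({448})},
    "mtORF type 8": {"AciI": frozenset({547}), "NlaIV": frozenset({315, 516})},
    "mtORF type 11": {"AlwNI": frozenset({467}), "AciI": frozenset({547}),
                      "NlaIV": frozenset({315, 516})},
    "mtORF type 3i": {"AciI": frozenset({209, 547}), "NlaIV": frozenset({194})},
    "mtORF type 3f": {"AciI": frozenset({209, 547}), "NlaIV": frozenset({516}),
                      "Tsp45I": frozenset({204})},
}

# --- PocHistone layout ------------------------------------------------------

_HIST_FWD = _concretize(PRIMERS["PocHistoneF"].sequence)  # columns 1-24
_HIST_REV = reverse_complement(_concretize(PRIMERS["PocHistoneR"].sequence))  # 646-669

_HIST_IMPLANTS: dict[int, str] = {
    1: _HIST_FWD,
    278: "CGA",  # arginine codon CGA; eydouxi T at 279 makes leucine CTA
    287: "CACGAG",  # XhoI site broken at 288; eydouxi T restores CTCGAG
    646: _HIST_REV,
}

_HIST_OVERRIDES: dict[str, dict[int, str]] = {
    species: ({279: "T", 288: "T"} if species == "P. eydouxi" else {})
    for species in CORE_SPECIES
}

_HIST_CUTS: dict[str, dict[str, frozenset[int]]] = {
    species: ({"XhoI": frozenset({287})} if species == "P. eydouxi" else {})
    for species in CORE_SPECIES
}

# --- Expected band patterns (the assay's published truth table) -------------

_UNCUT_MTORF = (MTORF_LENGTH,)
EXPECTED_MTORF_FRAGMENTS: dict[str, dict[str, tuple[int, ...]]] = {
    "P. eydouxi": {"SacI": (680, 298), "XhoI": _UNCUT_MTORF,
                   "AciI": (547, 431), "AlwNI": _UNCUT_MTORF,
                   "NlaIV": (462, 315, 201), "Tsp45I": _UNCUT_MTORF},
    "P. meandrina": {"SacI": (680, 298), "XhoI": _UNCUT_MTORF,
                     "AciI": (547, 431), "AlwNI": _UNCUT_MTORF,
                     "NlaIV": (462, 315, 201), "Tsp45I": _UNCUT_MTORF},
    "P. verrucosa": {"SacI": _UNCUT_MTORF, "XhoI": _UNCUT_MTORF,
                     "AciI": (431, 338, 209), "AlwNI": _UNCUT_MTORF,
                     "NlaIV": (516, 462), "Tsp45I": _UNCUT_MTORF},
    "P. ligulata": {"SacI": _UNCUT_MTORF, "XhoI": _UNCUT_MTORF,
                    "AciI": (547, 431), "AlwNI": (511, 467),
                    "NlaIV": (462, 315, 201), "Tsp45I": _UNCUT_MTORF},
    "P. acuta": {"SacI": _UNCUT_MTORF, "XhoI": _UNCUT_MTORF,
                 "AciI": (547, 431), "AlwNI": _UNCUT_MTORF,
                 "NlaIV": (462, 315, 171, 30), "Tsp45I": _UNCUT_MTORF},
    "P. damicornis": {"SacI": _UNCUT_MTORF, "XhoI": _UNCUT_MTORF,
                      "AciI": (547, 431), "AlwNI": _UNCUT_MTORF,
                      "NlaIV": (462, 315, 171, 30), "Tsp45I": (530, 448)},
    "mtORF type 8": {"SacI": _UNCUT_MTORF, "XhoI": _UNCUT_MTORF,
                     "AciI": (547, 431), "AlwNI": _UNCUT_MTORF,
                     "NlaIV": (462, 315, 201), "Tsp45I": _UNCUT_MTORF},
    "mtORF type 11": {"SacI": _UNCUT_MTORF, "XhoI": _UNCUT_MTORF,
                      "AciI": (547, 431), "AlwNI": (511, 467),
                      "NlaIV": (462, 315, 201), "Tsp45I": _UNCUT_MTORF},
    "mtORF type 3i": {"SacI": _UNCUT_MTORF, "XhoI": _UNCUT_MTORF,
                      "AciI": (431, 338, 209), "AlwNI": _UNCUT_MTORF,
                      "NlaIV": (784, 194), "Tsp45I": _UNCUT_MTORF},
    "mtORF type 3f": {"SacI": _UNCUT_MTORF, "XhoI": _UNCUT_MTORF,
                      "AciI": (431, 338, 209), "AlwNI": _UNCUT_MTORF,
                      "NlaIV": (516, 462), "Tsp45I": (774, 204)},
}

_UNCUT_HIST = (POCHISTONE_LENGTH,)
EXPECTED_POCHISTONE_FRAGMENTS: dict[str, dict[str, tuple[int, ...]]] = {
    species: {
        enz: ((382, 287) if species == "P. eydouxi" and enz == "XhoI"
              else _UNCUT_HIST)
        for enz in DEFAULT_ENZYMES
    }
    for species in CORE_SPECIES
}

#: diagnostic columns the fixture alignments must recover (haplotype
#: grouping for mtORF). The published coordinates 676 (SacI adenine) and
#: 530/534 (Tsp45I cut / damicornis SNP) are mutually inconsistent with
#: the printed fragment sizes by 1-2 bp; see the module docstring.
DECLARED_MTORF_SNPS: dict[str, dict[int, str]] = {
    "mtORF type 1": {677: "A"},
    "P. verrucosa": {210: "C", 211: "G"},
    "P. ligulata": {462: "C"},
    "P. damicornis": {534: "C"},
}
DECLARED_POCHISTONE_SNPS: dict[str, dict[int, str]] = {
    "P. eydouxi": {279: "T"},
}


def _protected_columns(
    implants: dict[int, str], overrides: dict[str, dict[int, str]]
) -> set[int]:
    cols: set[int] = set()
    for start, bases in implants.items():
        cols.update(range(start, start + len(bases)))
    for per_species in overrides.values():
        cols.update(per_species)
    return cols


def _realize(master: list[str], overrides: dict[int, str]) -> str:
    seq = list(master)
    for col, base in overrides.items():
        seq[col - 1] = base
    return "".join(seq)


def _intended_primer_hits(length: int, fwd_len: int, rev_len: int):
    return {( 1, "+"), (length - rev_len + 1, "-")}


def _build_amplicon(
    length: int,
    implants: dict[int, str],
    overrides: dict[str, dict[int, str]],
    intended_cuts: dict[str, dict[str, frozenset[int]]],
    fwd_primer,
    rev_primer,
    rng: random.Random,
    max_rounds: int = 400,
) -> dict[str, str]:
    """Random master + implants, scrubbed until every haplotype shows
    exactly its intended cut sites and primer hits."""
    protected = _protected_columns(implants, overrides)
    master = [rng.choice("ACGT") for _ in range(length)]
    for start, bases in implants.items():
        master[start - 1 : start - 1 + len(bases)] = list(bases)

    primer_hits = _intended_primer_hits(length, len(fwd_primer), len(rev_primer))

    for _ in range(max_rounds):
        offending: list[tuple[int, int]] = []  # footprint (start, end), 1-based
        for label, per_species in overrides.items():
            seq = _realize(master, per_species)
            intended = intended_cuts.get(label, {})
            for enz in DEFAULT_ENZYMES.values():
                want = intended.get(enz.name, frozenset())
                for site in find_cut_sites(seq, enz):
                    if site.cut_after not in want:
                        offending.append(
                            (site.site_start, site.site_start + enz.site_length - 1)
                        )
                found = {
                    s.cut_after for s in find_cut_sites(seq, enz)
                } & want
                if found != want:
                    raise FixtureGenerationError(
                        f"{label}/{enz.name}: implanted cuts {sorted(want)} "
                        f"not realised (found {sorted(found)})"
                    )
            for primer in (fwd_primer, rev_primer):
                for pos, strand in find_primer_sites(seq, primer, 0):
                    if (pos, strand) not in primer_hits:
                        m = len(primer)
                        offending.append((pos, pos + m - 1))
        if not offending:
            return {
                label: _realize(master, per_species)
                for label, per_species in overrides.items()
            }
        start, end = offending[0]
        free = [c for c in range(start, end + 1) if c not in protected]
        if not free:
            raise FixtureGenerationError(
                f"unintended site at {start}-{end} overlaps only protected "
                "columns; cannot repair"
            )
        col = rng.choice(free)
        master[col - 1] = rng.choice(
            [b for b in "ACGT" if b != master[col - 1]]
        )
    raise FixtureGenerationError("background scrubbing did not converge")


def generate_fixture_set(
    seed: int = 1, include_extra_haplotypes: bool = False
) -> dict[tuple[str, str], str]:
    """Generate all fixture amplicons.

    Returns a map ``(label, amplicon) -> sequence`` with the six core
    species for both amplicons (mtORF 978 bp, PocHistone 669 bp) and,
    optionally, the extra mtORF haplotypes. Same seed, same sequences;
    the implanted constraints are seed-independent.
    """
    rng = random.Random(seed)
    mtorf_labels = list(CORE_SPECIES) + (
        list(EXTRA_HAPLOTYPES) if include_extra_haplotypes else []
    )
    mtorf = _build_amplicon(
        MTORF_LENGTH,
        _MTORF_IMPLANTS,
        {label: _MTORF_OVERRIDES[label] for label in mtorf_labels},
        _MTORF_CUTS,
        PRIMERS["FatP6.1"],
        PRIMERS["RORF"],
        rng,
    )
    hist = _build_amplicon(
        POCHISTONE_LENGTH,
        _HIST_IMPLANTS,
        _HIST_OVERRIDES,
        _HIST_CUTS,
        PRIMERS["PocHistoneF"],
        PRIMERS["PocHistoneR"],
        rng,
    )
    fixtures: dict[tuple[str, str], str] = {}
    for label, seq in mtorf.items():
        fixtures[(label, "mtORF")] = seq
    for label, seq in hist.items():
        fixtures[(label, "PocHistone")] = seq
    return fixtures


_MTORF_HAPLOTYPE_LABEL = {
    "P. eydouxi": "mtORF type 1",
    "P. meandrina": "mtORF type 1",
}


def mtorf_alignment(
    fixtures: dict[tuple[str, str], str] | None = None,
    seed: int = 1,
    n_per_group: int = 3,
    group_by: str = "species",
    include_extra_haplotypes: bool = False,
) -> GroupedAlignment:
    """Gap-free mtORF alignment over the fixture haplotypes.

    ``group_by="haplotype"`` pools eydouxi and meandrina into their
    shared "mtORF type 1" group (their mtORF sequences are identical);
    ``"species"`` keeps six species labels.
    """
    if fixtures is None:
        fixtures = generate_fixture_set(
            seed, include_extra_haplotypes=include_extra_haplotypes
        )
    records = []
    for (label, amplicon), seq in sorted(fixtures.items()):
        if amplicon != "mtORF":
            continue
        group = (
            _MTORF_HAPLOTYPE_LABEL.get(label, label)
            if group_by == "haplotype"
            else label
        )
        stem = label.replace("P. ", "").replace(" ", "_")
        for i in range(n_per_group):
            records.append(AlignedRecord(f"{stem}_{i + 1}", group, seq))
    return GroupedAlignment(records)


def pochistone_alignment(
    fixtures: dict[tuple[str, str], str] | None = None,
    seed: int = 1,
    n_per_group: int = 3,
) -> GroupedAlignment:
    """Gap-free PocHistone alignment over the six species."""
    if fixtures is None:
        fixtures = generate_fixture_set(seed)
    records = []
    for (label, amplicon), seq in sorted(fixtures.items()):
        if amplicon != "PocHistone":
            continue
        stem = label.replace("P. ", "").replace(" ", "_")
        for i in range(n_per_group):
            records.append(AlignedRecord(f"{stem}_h{i + 1}", label, seq))
    return GroupedAlignment(records)


def default_assays() -> list[Assay]:
    """The six published assays (five mtORF digests + PocHistone XhoI)."""
    return [
        Assay("mtORF", "SacI"),
        Assay("mtORF", "AciI"),
        Assay("mtORF", "AlwNI"),
        Assay("mtORF", "NlaIV"),
        Assay("mtORF", "Tsp45I"),
        Assay("PocHistone", "XhoI"),
    ]


def default_pattern_table(
    fixtures: dict[tuple[str, str], str] | None = None, seed: int = 1
) -> PatternTable:
    """Pattern table over the six core species, computed by digestion."""
    if fixtures is None:
        fixtures = generate_fixture_set(seed)
    sequences = {
        species: {
            "mtORF": fixtures[(species, "mtORF")],
            "PocHistone": fixtures[(species, "PocHistone")],
        }
        for species in CORE_SPECIES
    }
    return build_pattern_table(sequences, default_assays())


@dataclass
class ConsistencyReport:
    """Pass/fail entry per fixture constraint, plus standing caveats."""

    checks: list[dict] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def add(self, name: str, expected, observed) -> None:
        self.checks.append(
            {
                "constraint": name,
                "expected": expected,
                "observed": observed,
                "passed": expected == observed,
            }
        )

    @property
    def passed(self) -> bool:
        return all(c["passed"] for c in self.checks)

    @property
    def failures(self) -> list[dict]:
        return [c for c in self.checks if not c["passed"]]

    def to_json(self) -> dict:
        return {
            "passed": self.passed,
            "checks": self.checks,
            "flags": self.flags,
        }


_STANDING_FLAGS = [
    "AciI cross-cut cell '(430, 548)' is not reproduced: the shared site at "
    "547 bp gives fragments 547 + 431 (sums to 978, matching the verrucosa "
    "row 209 + 338 + 431).",
    "The published type-1 adenine coordinate 676 is realised at column 677: "
    "fragment sizes 298 + 680 pin the GAGCTC footprint to 676-681 and the "
    "adenine is the site's second base.",
    "PocHistone: the XhoI site (fragments 287 + 382, footprint 287-292) and "
    "the eydouxi SNP at 279 cannot be co-located; both are implanted "
    "independently.",
    "mtORF: the damicornis SNP at 534 and a Tsp45I cut after 530 (footprint "
    "531-535, whose fourth base must be A) are mutually exclusive; the site "
    "is placed at 449-453 (cut after 448), preserving fragments 530 + 448, "
    "and the 534 SNP is implanted independently.",
]


def assert_fixture_consistency(
    fixtures: dict[tuple[str, str], str]
) -> ConsistencyReport:
    """Verify every in-scope published constraint against the fixtures.

    Checks amplicon lengths, primer amplifiability, all fragment
    multisets (both amplicons, all six enzymes, including extra
    haplotypes when present) and diagnostic-SNP recovery. Failures are
    report entries, not exceptions.
    """
    report = ConsistencyReport(flags=list(_STANDING_FLAGS))
    labels_mtorf = [l for (l, a) in fixtures if a == "mtORF"]
    labels_hist = [l for (l, a) in fixtures if a == "PocHistone"]

    for label in labels_mtorf:
        seq = fixtures[(label, "mtORF")]
        report.add(f"mtORF[{label}] length", MTORF_LENGTH, len(seq))
        for enz_name, expected in EXPECTED_MTORF_FRAGMENTS[label].items():
            observed = digest(seq, DEFAULT_ENZYMES[enz_name])
            report.add(
                f"mtORF[{label}] x {enz_name}",
                tuple(sorted(expected, reverse=True)),
                observed.lengths,
            )
    for label in labels_hist:
        seq = fixtures[(label, "PocHistone")]
        report.add(f"PocHistone[{label}] length", POCHISTONE_LENGTH, len(seq))
        for enz_name, expected in EXPECTED_POCHISTONE_FRAGMENTS[label].items():
            observed = digest(seq, DEFAULT_ENZYMES[enz_name])
            report.add(
                f"PocHistone[{label}] x {enz_name}",
                tuple(sorted(expected, reverse=True)),
                observed.lengths,
            )

    for label in labels_mtorf[:1]:
        try:
            amp = amplify(
                fixtures[(label, "mtORF")], PRIMERS["FatP6.1"], PRIMERS["RORF"]
            )
            report.add("mtORF amplicon via FatP6.1/RORF", MTORF_LENGTH, len(amp))
        except ValueError as exc:  # pragma: no cover - defect path
            report.add("mtORF amplicon via FatP6.1/RORF", MTORF_LENGTH, str(exc))
    for label in labels_hist[:1]:
        try:
            amp = amplify(
                fixtures[(label, "PocHistone")],
                PRIMERS["PocHistoneF"],
                PRIMERS["PocHistoneR"],
            )
            report.add(
                "PocHistone amplicon via PocHistoneF/R", POCHISTONE_LENGTH, len(amp)
            )
        except ValueError as exc:  # pragma: no cover - defect path
            report.add(
                "PocHistone amplicon via PocHistoneF/R", POCHISTONE_LENGTH, str(exc)
            )

    core = {k: v for k, v in fixtures.items() if k[0] in CORE_SPECIES}
    aln = mtorf_alignment(core, n_per_group=2, group_by="haplotype")
    for group, expected_cols in DECLARED_MTORF_SNPS.items():
        sites = {
            s.column: s.target_allele for s in find_shared_snps(aln, {group})
        }
        for col, allele in expected_cols.items():
            report.add(
                f"mtORF diagnostic column {col} ({group})",
                allele,
                sites.get(col),
            )
    hist_aln = pochistone_alignment(core, n_per_group=2)
    for group, expected_cols in DECLARED_POCHISTONE_SNPS.items():
        sites = {
            s.column: s.target_allele
            for s in find_shared_snps(hist_aln, {group})
        }
        for col, allele in expected_cols.items():
            report.add(
                f"PocHistone diagnostic column {col} ({group})",
                allele,
                sites.get(col),
            )
    return report


def write_fixture_files(
    outdir: "str | Path",
    seed: int = 1,
    include_extra_haplotypes: bool = False,
) -> dict[str, Path]:
    """Write per-amplicon multi-FASTA, a groups TSV and the constraints
    report (JSON) into *outdir*; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixtures = generate_fixture_set(
        seed, include_extra_haplotypes=include_extra_haplotypes
    )
    paths: dict[str, Path] = {}
    groups_rows: list[tuple[str, str]] = []
    for amplicon in ("mtORF", "PocHistone"):
        fasta = outdir / f"{amplicon}.fasta"
        with open(fasta, "w", encoding="utf-8") as fh:
            for (label, amp), seq in sorted(fixtures.items()):
                if amp != amplicon:
                    continue
                rec_id = label.replace("P. ", "").replace(" ", "_")
                fh.write(f">{rec_id} {label}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
                groups_rows.append((rec_id, label))
        paths[amplicon] = fasta
    groups = outdir / "groups.tsv"
    with open(groups, "w", encoding="utf-8") as fh:
        fh.write("id\tgroup\n")
        for rec_id, label in sorted(set(groups_rows)):
            fh.write(f"{rec_id}\t{label}\n")
    paths["groups"] = groups
    report = assert_fixture_consistency(fixtures)
    constraints = outdir / "constraints.json"
    constraints.write_text(json.dumps(report.to_json(), indent=2))
    paths["constraints"] = constraints
    return paths
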