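"""IUPAC nucleotide alphabet helpers.

Degenerate codes appear in two places in a PCR-RFLP assay: enzyme
recognition sites (e.g. Tsp45I GTSAC, AlwNI CAGNNNCTG) and primers
(e.g. FatP6.1 carries an S = G/C). Matching is deliberately asymmetric:
a degenerate code in the *query* (site or primer) matches any base of
its expansion, while an ambiguity code in the *subject* sequence never
matches anything — an uncertain base must not predict a gel band.
"""

from __future__ import annotations

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement as _bio_revcomp

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")
CONCRETE_BASES = frozenset("ACGT")

#: code -> frozenset of concrete bases it stands for
EXPANSION: dict[str, frozenset[str]] = {
    code: frozenset(ambiguous_dna_values[code]) for code in IUPAC_CODES
}


def is_valid_iupac(seq: str) -> bool:
    """True if every character of *seq* is an IUPAC nucleotide code."""
    return bool(seq) and all(c in IUPAC_CODES for c in seq.upper())


def iupac_match(code: str, base: str) -> bool:
    """Does concrete *base* fall inside the expansion of IUPAC *code*?

    Ambiguity codes on the subject side (``base``) are rejected: only
    A/C/G/T can ever match, so uncertain template bases never create
    phantom cut sites or primer hits.

    Raises
    ------
    ValueError
        If *code* is not an IUPAC symbol or *base* is not a single
        A/C/G/T character.
    """
    code = code.upper()
    base = base.upper()
    if code not in IUPAC_CODES:
        raise ValueError(f"invalid IUPAC symbol: {code!r}")
    if base not in CONCRETE_BASES:
        if base in IUPAC_CODES or base == "-":
            return False  # ambiguous/gap subject base: conservative no-match
        raise ValueError(f"invalid subject base: {base!r}")
    return base in EXPANSION[code]


def codes_compatible(a: str, b: str) -> bool:
    """True if the expansions of two IUPAC codes intersect."""
    return bool(EXPANSION[a.upper()] & EXPANSION[b.upper()])


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (S<->S, R<->Y, N<->N, ...)."""
    return str(_bio_revcomp(seq))


def normalize_sequence(seq: str, *, allow_ambiguity: bool = True) -> str:
    """Uppercase *seq* and validate its alphabet.

    Gap characters are not accepted here; strip them before digestion.
    """
    seq = seq.upper()
    allowed = IUPAC_CODES if allow_ambiguity else CONCRETE_BASES
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return seq
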