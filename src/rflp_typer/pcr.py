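"""Degenerate-primer binding and amplicon extraction (in-silico PCR).

A primer binds where every position is IUPAC-compatible with the
template (primer expansion contains the template base; ambiguous
template bases count as mismatches) and the 3'-terminal base matches
with no slack — extension from a mismatched 3' end is not modelled.
The predicted product spans both primer footprints inclusively, which
is what makes the 978 bp mtORF / 669 bp PocHistone totals consistent
with their digest fragment sums.
"""

from __future__ import annotations

from dataclasses import dataclass

from .iupac import (
    CONCRETE_BASES,
    EXPANSION,
    is_valid_iupac,
    normalize_sequence,
    reverse_complement,
)

__all__ = [
    "Primer",
    "Amplicon",
    "NoAmplificationError",
    "MultipleProductsError",
    "find_primer_sites",
    "amplify",
    "PRIMERS",
]


@dataclass(frozen=True)
class Primer:
    """A named oligo, written 5'->3', possibly degenerate."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not is_valid_iupac(seq):
            raise ValueError(f"{self.name}: invalid primer sequence {seq!r}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


#: Published primer set for the two marker amplicons.
PRIMERS: dict[str, Primer] = {
    p.name: p
    for p in [
        Primer("FatP6.1", "TTTGGGSATTCGTTTAGCAG"),
        Primer("RORF", "SCCAATATGTTAAACASCATGTCA"),
        Primer("PocHistoneF", "ATTCAGTCTCACTCACTCACTCAC"),
        Primer("PocHistoneR", "TATCTTCGAACAGACCCACCAAAT"),
    ]
}


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product, inclusive of both primer footprints."""

    sequence: str
    template_id: str
    start: int  # 1-based inclusive template coordinate
    end: int
    fwd_primer: str
    rev_primer: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("amplicon coordinates do not match its length")

    def __len__(self) -> int:
        return len(self.sequence)


class NoAmplificationError(ValueError):
    """No primer pair orientation yields a product."""


class MultipleProductsError(ValueError):
    """More than one candidate product; names all candidate pairs."""

    def __init__(self, candidates: list[tuple[int, int]]):
        self.candidates = candidates
        pairs = ", ".join(f"({a}..{b})" for a, b in candidates)
        super().__init__(f"multiple candidate products: {pairs}")


def _mismatches(template: str, i: int, pattern: str, three_prime_index: int,
                max_mismatch: int) -> int | None:
    """Mismatch count of *pattern* at 0-based template offset *i*.

    Returns None when the window exceeds max_mismatch or the 3' anchor
    (index *three_prime_index* within the pattern) is not a perfect
    IUPAC-compatible match.
    """
    mm = 0
    for k, code in enumerate(pattern):
        base = template[i + k]
        ok = base in CONCRETE_BASES and base in EXPANSION[code]
        if not ok:
            if k == three_prime_index:
                return None
            mm += 1
            if mm > max_mismatch:
                return None
    return mm


def find_primer_sites(
    template: str, primer: Primer, max_mismatch: int = 0
) -> list[tuple[int, str]]:
    """All binding footprints of *primer* on *template*.

    Returns ``(position, strand)`` pairs, where *position* is the 1-based
    top-strand start of the footprint and *strand* is ``"+"`` (primer as
    given) or ``"-"`` (primer binds the bottom strand; its footprint on
    the top strand is the primer's reverse complement). The 3'-terminal
    base must match exactly on either strand.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    tpl = normalize_sequence(template)
    m = len(primer)
    if m > len(tpl):
        raise ValueError(
            f"primer {primer.name} ({m} nt) longer than template ({len(tpl)} nt)"
        )
    hits: list[tuple[int, str]] = []
    fwd = primer.sequence
    rev = reverse_complement(primer.sequence)
    for i in range(len(tpl) - m + 1):
        if _mismatches(tpl, i, fwd, m - 1, max_mismatch) is not None:
            hits.append((i + 1, "+"))
        # on the bottom strand the primer's 3' end sits at the footprint's
        # first top-strand base
        if _mismatches(tpl, i, rev, 0, max_mismatch) is not None:
            hits.append((i + 1, "-"))
    return hits


def amplify(
    template: str,
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = 0,
    template_id: str = "template",
) -> Amplicon:
    """Predict the single PCR product of a primer pair on a template.

    Requires exactly one forward-strand hit of *fwd* and one
    bottom-strand hit of *rev*, with the forward footprint 5' of the
    reverse footprint. The product includes both footprints.

    Raises
    ------
    NoAmplificationError
        If no valid product exists.
    MultipleProductsError
        If more than one (fwd, rev) footprint pairing is productive.
    """
    tpl = normalize_sequence(template)
    fwd_hits = [p for p, s in find_primer_sites(tpl, fwd, max_mismatch) if s == "+"]
    rev_hits = [p for p, s in find_primer_sites(tpl, rev, max_mismatch) if s == "-"]
    products = [
        (f, r + len(rev) - 1)
        for f in fwd_hits
        for r in rev_hits
        if f < r + len(rev) - 1 and (r + len(rev) - f) >= len(fwd) + len(rev)
    ]
    if not products:
        raise NoAmplificationError(
            f"no product for {fwd.name} x {rev.name} on {template_id}"
        )
    if len(products) > 1:
        raise MultipleProductsError(products)
    start, end = products[0]
    return Amplicon(
        sequence=tpl[start - 1 : end],
        template_id=template_id,
        start=start,
        end=end,
        fwd_primer=fwd.name,
        rev_primer=rev.name,
    )
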