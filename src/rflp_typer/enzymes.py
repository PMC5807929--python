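"""Restriction enzymes with degenerate recognition sites and linear digestion.

The cut notation follows the convention used on enzyme datasheets:
``GAGCT'C / C'TCGAG`` means the top strand is cleaved after the 5th
recognition base and the bottom strand (read 5'->3') after the 1st.
Fragment lengths on a gel are governed by the top-strand cuts only,
so a staggered bottom-strand cut never changes a predicted pattern;
it matters solely for locating reverse-orientation matches of
non-palindromic sites (e.g. AciI C'CGC, whose complement-strand match
appears as GCGG on the top strand).

All reported coordinates are 1-based on the top strand: a ``cut_after``
of 680 severs the bond between positions 680 and 681.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .iupac import (
    CONCRETE_BASES,
    EXPANSION,
    is_valid_iupac,
    normalize_sequence,
    reverse_complement,
)

__all__ = [
    "RestrictionEnzyme",
    "CutSite",
    "FragmentPattern",
    "Tolerance",
    "find_cut_sites",
    "digest",
    "pattern_distinguishable",
    "patterns_compatible",
    "collapse_bands",
    "DEFAULT_ENZYMES",
    "load_enzyme_db",
    "write_enzyme_db",
]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type II restriction enzyme cutting within its recognition site.

    Parameters
    ----------
    name : str
        Enzyme name, e.g. ``"SacI"``.
    recognition : str
        IUPAC recognition sequence, length >= 4.
    cut_offset_top : int
        Number of recognition bases 5' of the top-strand cut for a
        forward-orientation match (``GAGCT'C`` -> 5).
    cut_offset_bottom : int
        Same offset read on the bottom strand 5'->3' (``C'TCGAG`` -> 1).
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        if len(rec) < 4 or not is_valid_iupac(rec):
            raise ValueError(
                f"{self.name}: recognition must be an IUPAC string of length >= 4, "
                f"got {rec!r}"
            )
        L = len(rec)
        for label, off in (
            ("cut_offset_top", self.cut_offset_top),
            ("cut_offset_bottom", self.cut_offset_bottom),
        ):
            if not 0 <= off <= L:
                raise ValueError(f"{self.name}: {label}={off} outside 0..{L}")

    @property
    def site_length(self) -> int:
        return len(self.recognition)

    @property
    def overhang(self) -> int:
        """Signed single-strand overhang left by the cut.

        Positive for 5' overhangs (Tsp45I +5, XhoI +4), negative for 3'
        overhangs (SacI -4, AlwNI -3), zero for blunt ends (NlaIV).
        Staggered ends are why the top-strand length of a terminal
        fragment changes by exactly this amount when the opposite strand
        is digested instead.
        """
        return self.cut_offset_bottom - self.cut_offset_top

    @property
    def palindromic(self) -> bool:
        """True iff the recognition equals its own IUPAC reverse complement."""
        return reverse_complement(self.recognition) == self.recognition


@dataclass(frozen=True, order=True)
class CutSite:
    """A single double-strand cut located on the top strand.

    ``cut_after`` is the 1-based top-strand position immediately 5' of
    the scissile bond; ``site_start`` is where the matched recognition
    footprint begins on the top strand.
    """

    cut_after: int
    site_start: int
    orientation: str  # "forward" | "reverse"


@dataclass(frozen=True)
class FragmentPattern:
    """Multiset of fragment lengths from one complete linear digest."""

    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(x <= 0 for x in self.lengths):
            raise ValueError("fragment lengths must be positive")
        object.__setattr__(
            self, "lengths", tuple(sorted(self.lengths, reverse=True))
        )

    @property
    def total(self) -> int:
        return sum(self.lengths)

    @property
    def n_fragments(self) -> int:
        return len(self.lengths)

    def __iter__(self):
        return iter(self.lengths)

    def __str__(self) -> str:
        return ", ".join(str(x) for x in self.lengths)


@dataclass(frozen=True)
class Tolerance:
    """Band-sizing tolerance: the larger of an absolute and a relative term.

    The default gel model (``Tolerance(bp=10, frac=0.05)``) treats two
    bands as co-migrating when they differ by at most max(10 bp, 5%);
    ``Tolerance.exact()`` demands identical lengths.
    """

    bp: float = 0.0
    frac: float = 0.0

    def __post_init__(self) -> None:
        if self.bp < 0 or self.frac < 0:
            raise ValueError("tolerance terms must be non-negative")

    @classmethod
    def exact(cls) -> "Tolerance":
        return cls(0.0, 0.0)

    @classmethod
    def gel_default(cls) -> "Tolerance":
        return cls(10.0, 0.05)

    @classmethod
    def parse(cls, text: "str | float | int | Tolerance") -> "Tolerance":
        """Parse ``"5%"``, ``"10"``, ``"10,5%"`` or a bare number (bp)."""
        if isinstance(text, Tolerance):
            return text
        if isinstance(text, (int, float)):
            return cls(bp=float(text))
        bp = 0.0
        frac = 0.0
        for part in str(text).split(","):
            part = part.strip()
            if not part:
                continue
            if part.endswith("%"):
                frac = float(part[:-1]) / 100.0
            else:
                bp = float(part.removesuffix("bp"))
        return cls(bp=bp, frac=frac)

    def for_length(self, length: float) -> float:
        return max(self.bp, self.frac * length)


def _matches_at(seq: str, i: int, pattern: str) -> bool:
    """Exact-window IUPAC match; ambiguous subject bases never match."""
    for k, code in enumerate(pattern):
        base = seq[i + k]
        if base not in CONCRETE_BASES or base not in EXPANSION[code]:
            return False
    return True


def find_cut_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[CutSite]:
    """All top-strand cut positions of *enzyme* on a linear *sequence*.

    Forward-orientation matches of the recognition are always scanned;
    for non-palindromic enzymes the reverse complement of the recognition
    is scanned as well, with the top-strand cut placed ``L -
    cut_offset_bottom`` bases into the footprint. Overlapping matches are
    all reported; duplicate cut positions are collapsed downstream in
    :func:`digest`.
    """
    seq = normalize_sequence(sequence)
    if not seq:
        raise ValueError("sequence must be non-empty")
    rec = enzyme.recognition
    L = enzyme.site_length
    sites: list[CutSite] = []
    for i in range(len(seq) - L + 1):
        if _matches_at(seq, i, rec):
            sites.append(
                CutSite(
                    cut_after=i + enzyme.cut_offset_top,
                    site_start=i + 1,
                    orientation="forward",
                )
            )
    if not enzyme.palindromic:
        rc = reverse_complement(rec)
        for i in range(len(seq) - L + 1):
            if _matches_at(seq, i, rc):
                sites.append(
                    CutSite(
                        cut_after=i + (L - enzyme.cut_offset_bottom),
                        site_start=i + 1,
                        orientation="reverse",
                    )
                )
    return sorted(sites)


def digest(
    sequence: str,
    enzymes: "RestrictionEnzyme | Iterable[RestrictionEnzyme]",
) -> FragmentPattern:
    """Complete digestion of a linear sequence by one or more enzymes.

    Fragments are the intervals between the distinct top-strand cut
    positions (cuts flush with either end produce no fragment); their
    lengths always sum to ``len(sequence)``.
    """
    if isinstance(enzymes, RestrictionEnzyme):
        enzymes = [enzymes]
    seq = normalize_sequence(sequence)
    n = len(seq)
    cuts = sorted(
        {
            site.cut_after
            for enz in enzymes
            for site in find_cut_sites(seq, enz)
            if 0 < site.cut_after < n
        }
    )
    bounds = [0, *cuts, n]
    return FragmentPattern(
        tuple(b - a for a, b in zip(bounds, bounds[1:]))
    )


def collapse_bands(
    lengths: Sequence[int],
    min_detect: float,
    tolerance: Tolerance,
) -> list[float]:
    """Reduce predicted fragment lengths to the bands a gel would show.

    Fragments below *min_detect* are dropped (they run off or are too
    faint to score) and lengths within *tolerance* of each other are
    merged into one co-migrating band, represented by their mean.
    Returned sorted descending.
    """
    if min_detect < 0:
        raise ValueError("min_detect must be non-negative")
    kept = sorted(x for x in lengths if x >= min_detect)
    bands: list[list[int]] = []
    for x in kept:
        if bands and x - bands[-1][-1] <= tolerance.for_length(x):
            bands[-1].append(x)
        else:
            bands.append([x])
    return sorted((sum(b) / len(b) for b in bands), reverse=True)


def patterns_compatible(
    a: "FragmentPattern | Sequence[int]",
    b: "FragmentPattern | Sequence[int]",
    min_detect: float = 0.0,
    tolerance: Tolerance = Tolerance(),
) -> bool:
    """Would two fragment patterns look identical on a gel?

    Both patterns are collapsed with :func:`collapse_bands`; they are
    compatible when the band counts agree and every size-ordered pair of
    bands differs by no more than the tolerance.
    """
    tolerance = Tolerance.parse(tolerance)
    ba = collapse_bands(tuple(a), min_detect, tolerance)
    bb = collapse_bands(tuple(b), min_detect, tolerance)
    if len(ba) != len(bb):
        return False
    return all(
        abs(x - y) <= tolerance.for_length(max(x, y)) for x, y in zip(ba, bb)
    )


def pattern_distinguishable(
    a: "FragmentPattern | Sequence[int]",
    b: "FragmentPattern | Sequence[int]",
    min_detect: float = 0.0,
    tolerance: Tolerance = Tolerance(),
) -> bool:
    """True iff the two band patterns can be told apart on a gel."""
    return not patterns_compatible(a, b, min_detect, tolerance)


# ---------------------------------------------------------------------------
# Enzyme database
# ---------------------------------------------------------------------------

#: The six assay enzymes, offsets transcribed from the duplex cut notation
#: (top-strand apostrophe / bottom-strand apostrophe read 5'->3').
DEFAULT_ENZYMES: dict[str, RestrictionEnzyme] = {
    e.name: e
    for e in [
        RestrictionEnzyme("AciI", "CCGC", 1, 3),
        RestrictionEnzyme("AlwNI", "CAGNNNCTG", 6, 3),
        RestrictionEnzyme("NlaIV", "GGNNCC", 3, 3),
        RestrictionEnzyme("SacI", "GAGCTC", 5, 1),
        RestrictionEnzyme("Tsp45I", "GTSAC", 0, 5),
        RestrictionEnzyme("XhoI", "CTCGAG", 1, 5),
    ]
}


def load_enzyme_db(path: "str | Path") -> dict[str, RestrictionEnzyme]:
    """Read a TSV enzyme table: name, recognition, cut_top, cut_bottom.

    Lines starting with ``#`` are comments; a header row with those
    column names is accepted and skipped.
    """
    enzymes: dict[str, RestrictionEnzyme] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "name":
                continue
            if len(parts) < 4:
                raise ValueError(f"malformed enzyme row: {line!r}")
            name, rec, top, bottom = parts[:4]
            enzymes[name] = RestrictionEnzyme(name, rec, int(top), int(bottom))
    if not enzymes:
        raise ValueError(f"no enzymes found in {path}")
    return enzymes


def write_enzyme_db(
    enzymes: dict[str, RestrictionEnzyme], path: "str | Path"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\trecognition\tcut_top\tcut_bottom\n")
        for enz in enzymes.values():
            fh.write(
                f"{enz.name}\t{enz.recognition}\t{enz.cut_offset_top}\t"
                f"{enz.cut_offset_bottom}\n"
            )
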