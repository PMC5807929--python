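"""Enzyme model, IUPAC matching, site finding and digestion."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rflp_typer.enzymes import (
    DEFAULT_ENZYMES,
    FragmentPattern,
    RestrictionEnzyme,
    Tolerance,
    collapse_bands,
    digest,
    find_cut_sites,
    load_enzyme_db,
    pattern_distinguishable,
    patterns_compatible,
    write_enzyme_db,
)
from rflp_typer.iupac import EXPANSION, iupac_match, reverse_complement

dna = st.text(alphabet="ACGT", min_size=20, max_size=400)


# ---------------------------------------------------------------------------
# IUPAC matching
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "code, base, expected",
    [
        ("S", "G", True),  # FatP6.1's degenerate position
        ("S", "C", True),
        ("S", "A", False),
        ("N", "T", True),
        ("R", "A", True),
        ("R", "C", False),
        ("A", "A", True),
        ("A", "G", False),
    ],
)
def test_iupac_match_expansion(code, base, expected):
    assert iupac_match(code, base) is expected


def test_iupac_match_rejects_invalid_symbols():
    with pytest.raises(ValueError):
        iupac_match("Z", "A")
    with pytest.raises(ValueError):
        iupac_match("A", "Z")


def test_ambiguous_subject_bases_never_match():
    """An uncertain template base must not create a phantom site."""
    assert not iupac_match("N", "N")
    assert not iupac_match("S", "S")
    # a site window containing an N in the subject is not a cut site
    seq = "AAAGAGNTCAAA"
    assert find_cut_sites(seq, DEFAULT_ENZYMES["SacI"]) == []


# ---------------------------------------------------------------------------
# Enzyme model
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "recognition, expected",
    [("GAGCTC", True), ("GTSAC", True), ("CCGC", False), ("CAGNNNCTG", True),
     ("GGNNCC", True), ("CTCGAG", True)],
)
def test_palindromy_under_iupac_expansion(recognition, expected):
    enz = RestrictionEnzyme("x", recognition, 1, 1)
    assert enz.palindromic is expected


def test_enzyme_validation_rejects_bad_offsets_and_alphabet():
    with pytest.raises(ValueError):
        RestrictionEnzyme("bad", "GAGCTC", 7, 1)
    with pytest.raises(ValueError):
        RestrictionEnzyme("bad", "GAXCTC", 1, 1)
    with pytest.raises(ValueError):
        RestrictionEnzyme("bad", "GAG", 1, 1)  # too short


def test_enzyme_db_round_trip(tmp_path):
    path = tmp_path / "enzymes.tsv"
    write_enzyme_db(DEFAULT_ENZYMES, path)
    loaded = load_enzyme_db(path)
    assert loaded == DEFAULT_ENZYMES


# ---------------------------------------------------------------------------
# Site finding
# ---------------------------------------------------------------------------


def test_sacI_single_site_on_type1_mtorf(fixture_set):
    sites = find_cut_sites(fixture_set[("P. eydouxi", "mtORF")],
                           DEFAULT_ENZYMES["SacI"])
    assert len(sites) == 1
    assert sites[0].cut_after == 680
    assert sites[0].site_start == 676
    assert sites[0].orientation == "forward"


def test_no_compatible_window_yields_empty_list():
    assert find_cut_sites("ATATATATATAT", DEFAULT_ENZYMES["SacI"]) == []


def test_acil_reverse_orientation_site():
    """AciI is non-palindromic: GCGG on the top strand is a bottom-strand
    CCGC and must be cut, at one base into the footprint."""
    seq = "AAAAAGCGGAAAAA"
    sites = find_cut_sites(seq, DEFAULT_ENZYMES["AciI"])
    # top-strand cut L - cut_offset_bottom = 1 base into the footprint
    assert [(s.orientation, s.site_start, s.cut_after) for s in sites] == [
        ("reverse", 6, 6)
    ]


def _brute_force_cuts(seq, enzyme):
    """Independent oracle: expand the recognition into every concrete
    string and scan each window by string equality."""
    L = enzyme.site_length
    cuts = set()
    patterns = [
        ("".join(p), enzyme.cut_offset_top)
        for p in itertools.product(*(EXPANSION[c] for c in enzyme.recognition))
    ]
    if not enzyme.palindromic:
        rc = reverse_complement(enzyme.recognition)
        patterns += [
            ("".join(p), L - enzyme.cut_offset_bottom)
            for p in itertools.product(*(EXPANSION[c] for c in rc))
        ]
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        for pat, off in patterns:
            if window == pat:
                cuts.add(i + off)
    return sorted(cuts)


@pytest.mark.parametrize("name", sorted(DEFAULT_ENZYMES))
def test_site_finding_agrees_with_brute_force_oracle(name):
    enzyme = DEFAULT_ENZYMES[name]
    rng = random.Random(hash(name) % 2**31)
    for length in (40, 200, 2000):
        for _ in range(20):
            seq = "".join(rng.choice("ACGT") for _ in range(length))
            mine = sorted({s.cut_after for s in find_cut_sites(seq, enzyme)})
            assert mine == _brute_force_cuts(seq, enzyme)


@pytest.mark.parametrize("name", sorted(DEFAULT_ENZYMES))
def test_site_finding_agrees_with_reference_implementation(name):
    """Cross-check against Bio.Restriction's independent digestion engine
    (it reports the first base after the cut, hence the -1)."""
    from Bio import Restriction
    from Bio.Seq import Seq

    enzyme = DEFAULT_ENZYMES[name]
    reference = getattr(Restriction, name)
    rng = random.Random(20_000 + len(name))
    for _ in range(50):
        seq = "".join(rng.choice("ACGT") for _ in range(500))
        mine = sorted({s.cut_after for s in find_cut_sites(seq, enzyme)})
        theirs = sorted({p - 1 for p in reference.search(Seq(seq), linear=True)})
        assert mine == theirs


def test_palindromic_forward_scan_equals_both_strand_scan():
    """For palindromic sites, an explicit reverse-orientation scan adds
    no cut positions beyond the forward scan (dedup is a no-op)."""
    rng = random.Random(7)
    for name in ("SacI", "NlaIV", "Tsp45I", "AlwNI", "XhoI"):
        enz = DEFAULT_ENZYMES[name]
        L = enz.site_length
        rc = reverse_complement(enz.recognition)
        for _ in range(30):
            seq = "".join(rng.choice("ACGT") for _ in range(300))
            fwd_only = {s.cut_after for s in find_cut_sites(seq, enz)}
            # manual reverse-orientation scan with the bottom-strand
            # cut transform
            rev = {
                i + (L - enz.cut_offset_bottom)
                for i in range(len(seq) - L + 1)
                if all(
                    seq[i + k] in EXPANSION[code] for k, code in enumerate(rc)
                )
            }
            assert fwd_only | rev == fwd_only


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------


def test_digest_reproduces_type1_sacI_fragments(fixture_set):
    assert digest(fixture_set[("P. eydouxi", "mtORF")],
                  DEFAULT_ENZYMES["SacI"]).lengths == (680, 298)


def test_uncut_amplicon_is_single_full_length_fragment(fixture_set):
    pat = digest(fixture_set[("P. acuta", "mtORF")], DEFAULT_ENZYMES["Tsp45I"])
    assert pat.lengths == (978,)


def test_verrucosa_acil_three_fragments(fixture_set):
    assert digest(fixture_set[("P. verrucosa", "mtORF")],
                  DEFAULT_ENZYMES["AciI"]).lengths == (431, 338, 209)


@given(dna)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_length_conservation(seq):
    for enz in DEFAULT_ENZYMES.values():
        assert digest(seq, enz).total == len(seq)


def _ordered_fragments(seq, enzyme):
    """Fragments in template order (not size order)."""
    n = len(seq)
    cuts = sorted(
        {s.cut_after for s in find_cut_sites(seq, enzyme) if 0 < s.cut_after < n}
    )
    bounds = [0, *cuts, n]
    return [b - a for a, b in zip(bounds, bounds[1:])]


@given(dna)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_strand_symmetry_of_digestion(seq):
    """Digesting the reverse complement reproduces the fragments up to
    the enzyme's staggered ends: interior fragments are identical and
    the two terminal fragments shift by exactly the signed overhang
    (every cut moves by cut_offset_bottom - cut_offset_top when read on
    the other strand). Blunt cutters are exactly symmetric."""
    for enz in DEFAULT_ENZYMES.values():
        fwd = _ordered_fragments(seq, enz)
        rev = _ordered_fragments(reverse_complement(seq), enz)
        if len(fwd) == 1:
            assert rev == fwd
            continue
        # ignore cases where a shifted terminal cut falls off an end
        if min(fwd[0], fwd[-1]) <= abs(enz.overhang) or len(fwd) != len(rev):
            continue
        mirrored = rev[::-1]
        assert mirrored[1:-1] == fwd[1:-1]
        assert mirrored[0] - fwd[0] == enz.overhang
        assert mirrored[-1] - fwd[-1] == -enz.overhang
        if enz.overhang == 0:  # blunt: exact multiset symmetry
            assert digest(seq, enz).lengths == digest(
                reverse_complement(seq), enz
            ).lengths


@given(dna)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_multi_enzyme_digest_monotonicity(seq):
    """Adding an enzyme never decreases the fragment count."""
    enzymes = list(DEFAULT_ENZYMES.values())
    for k in range(1, len(enzymes)):
        fewer = digest(seq, enzymes[:k]).n_fragments
        more = digest(seq, enzymes[: k + 1]).n_fragments
        assert more >= fewer


def test_fragment_count_equals_distinct_cuts_plus_one(fixture_set):
    seq = fixture_set[("P. acuta", "mtORF")]
    enz = DEFAULT_ENZYMES["NlaIV"]
    interior = {
        s.cut_after for s in find_cut_sites(seq, enz) if 0 < s.cut_after < len(seq)
    }
    assert digest(seq, enz).n_fragments == len(interior) + 1


# ---------------------------------------------------------------------------
# Pattern comparison
# ---------------------------------------------------------------------------


def test_distinguishable_cut_vs_uncut():
    assert pattern_distinguishable(
        (680, 298), (978,), 50, Tolerance(0, 0.05)
    )


def test_identical_patterns_never_distinguishable():
    assert not pattern_distinguishable((462, 315, 201), (462, 315, 201), 50,
                                       Tolerance(10, 0.05))


def test_small_band_dropped_but_patterns_still_differ():
    """After losing the 30 bp band, 171 vs 201 is still beyond 5%."""
    assert pattern_distinguishable(
        (462, 315, 171, 30), (462, 315, 201), 50, Tolerance(0, 0.05)
    )


def test_negative_tolerance_rejected():
    with pytest.raises(ValueError):
        pattern_distinguishable((100,), (100,), 0, Tolerance(-1, 0))
    with pytest.raises(ValueError):
        collapse_bands([100], -5, Tolerance(0, 0))


def test_comigrating_bands_merge():
    # 448 vs 462 differ by ~3%: one band at 5% tolerance, two at 0%
    assert collapse_bands([448, 462], 50, Tolerance(0, 0.05)) == [455.0]
    assert collapse_bands([448, 462], 50, Tolerance(0, 0)) == [462, 448]


def test_fragment_pattern_sorted_and_total():
    pat = FragmentPattern((298, 680))
    assert pat.lengths == (680, 298)
    assert pat.total == 978
    with pytest.raises(ValueError):
        FragmentPattern((0, 10))


def test_tolerance_parsing():
    assert Tolerance.parse("5%") == Tolerance(0, 0.05)
    assert Tolerance.parse("10,5%") == Tolerance(10, 0.05)
    assert Tolerance.parse(7) == Tolerance(7, 0)
    assert Tolerance.parse("0") == Tolerance(0, 0)
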