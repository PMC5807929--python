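# Methods

This note documents the models and conventions behind rflp-typer: how
digestion, primer binding, diagnostic-SNP scanning, key construction and
gel scoring are defined; what the synthetic reference sequences do and do
not emulate; and the choices made where the design was genuinely open.

## Restriction digestion

An enzyme is `(recognition, cut_offset_top, cut_offset_bottom)`. The
recognition is an IUPAC string (length ≥ 4); the offsets transcribe the
datasheet apostrophe notation — `GAGCT'C` means the top strand is cleaved
after the 5th recognition base; `C'TCGAG` is the same cut read on the
other strand. The bundled database holds the six assay enzymes:

| enzyme | site | top/bottom offset | overhang |
|--------|-----------|------|----------|
| SacI   | GAGCTC    | 5/1  | 4 nt 3′  |
| XhoI   | CTCGAG    | 1/5  | 4 nt 5′  |
| AciI   | CCGC      | 1/3  | 2 nt 5′  |
| AlwNI  | CAGNNNCTG | 6/3  | 3 nt 3′  |
| NlaIV  | GGNNCC    | 3/3  | blunt    |
| Tsp45I | GTSAC     | 0/5  | 5 nt 5′  |

**Matching.** A window matches when every template base lies in the IUPAC
expansion of the corresponding recognition code. The asymmetry is
deliberate: degenerate codes in the recognition (or a primer) match any
base of their expansion, but an ambiguity code in the *template* never
matches anything. A gel assay must not predict bands from uncertain bases,
so the scanner is conservative — no phantom cuts.

**Orientation.** Palindromic sites (recognition equal to its own IUPAC
reverse complement, which holds for five of the six enzymes) are scanned in
the forward orientation only; an explicit both-strand scan with
deduplication provably adds nothing, and this is property-tested. AciI is
the exception (CCGC ≠ GCGG): the reverse complement of the recognition is
scanned too, and a reverse-orientation match starting at top-strand
position *s* cuts after `s − 1 + (L − cut_offset_bottom)` — one base into
GCGG, which agrees exactly with an independent digestion engine
(Bio.Restriction) on random sequences, as does every forward cut.

**Fragments.** Complete digestion is assumed (no partial-digest ladders,
no circular topology, no methylation or buffer effects). Fragment lengths
are the intervals between distinct top-strand cut positions; cuts flush
with either molecule end produce no fragment; lengths always sum to the
input length. Staggered bottom-strand cuts never change a pattern — the
published fragment sums (298 + 680 = 978, etc.) confirm this accounting.

**Strand symmetry is exact only for blunt cutters.** Reading the opposite
strand moves every cut of a staggered enzyme by its signed overhang
(`cut_offset_bottom − cut_offset_top`: −4 for SacI, +5 for Tsp45I, ...).
Interior fragments are unchanged but the two terminal fragments shift by
exactly that amount, so requiring identical multisets from a sequence and
its reverse complement is chemically impossible for five of the six
enzymes under top-strand accounting. The property suite therefore asserts
the attainable invariant — interior fragments identical, terminal
fragments offset by exactly the overhang, exact equality for NlaIV — and
the amplicon fixtures place all diagnostic sites far from the molecule
ends, where the distinction is invisible.

## Gel model

Two parameters translate predicted fragments into scoreable bands:

- `min_detect` (default 50 bp): fragments below it are dropped before
  comparison. The published NlaIV pattern contains a 30 bp fragment that a
  2% agarose gel will not show; the default makes its loss harmless.
- `tolerance` (default max(10 bp, 5%) of the band length): bands within
  tolerance co-migrate and are merged (represented by their mean); two
  patterns are distinguishable when, after dropping and merging, the band
  lists differ in count or any size-ordered pair differs by more than the
  tolerance.

Purely in-silico comparisons (key construction, sequence classification)
default to exact matching (0 bp / 0%). How a gel-scored pattern with a
missing small band should be adjudicated is this package's decision, not
something the assay's designers specified; `min_detect` is that rule.

## In-silico PCR

A primer binds where every position is IUPAC-compatible with the template
(template ambiguity codes count as mismatches) and the 3′-terminal base
matches with no slack, whatever `max_mismatch` (default 0) allows
elsewhere — polymerases do not extend mismatched 3′ ends. `amplify`
demands exactly one forward and one reverse footprint in productive
orientation and returns the product *inclusive of both primer footprints*;
that convention is what makes the 978 bp mtORF and 669 bp PocHistone totals
agree with their digest fragment sums. Multiple candidate products raise an
error naming every (start, end) pair. Melting temperature, dimers and
cycling conditions are out of scope.

## Diagnostic sites

A column is diagnostic for a group subset when all counted subset records
share one base that no counted outside record carries. Columns containing
a gap are excluded by default (`allow_gaps` overrides): an indel shifts
every downstream restriction coordinate, so indel-bearing columns make
unreliable assay anchors. Ambiguity codes are treated as missing data —
the record is skipped at that column — rather than as mismatches; a column
where either side has only missing data is uninformative. All coordinates
are reported 1-based, both as alignment columns and as ungapped positions
per record (identical on the gap-free fixture alignments).

`screen_enzymes` digests every record's ungapped sequence, partitions the
groups into gel-indistinguishable blocks per enzyme, and ranks enzymes by
block count. A group whose own records disagree marks the candidate
*unreliable* rather than being dropped — regional haplotype variation is
exactly what a user needs to see, not have hidden.

## Identification keys

`build_key` grows a greedy decision tree: at each node the assay with the
most distinguishable pattern classes among the remaining groups wins; ties
go to the assay leaving the fewest groups in unresolved blocks, then to
lexicographic enzyme and amplicon name, making the tree a deterministic
function of the table. Greedy rather than exhaustive-optimal: the tables
are tiny, and determinism matters more than saving a step. Groups
identical across every assay end in a shared ambiguous leaf with a
warning. Uncut amplicons count as a one-band pattern equal to the amplicon
length, matching how the published table treats them.

`published_key` reproduces the fixed laboratory cascade instead: SacI
first; type 1 colonies continue to PocHistone × XhoI; all others run
AlwNI, then AciI, then NlaIV, then Tsp45I. The NlaIV step does not split
*P. acuta* from *P. damicornis* — it is kept as a single-branch
*confirmation* node because its pattern still distinguishes the pair from
every species excluded earlier on the path; a non-splitting assay without
that property (e.g. XhoI on non-type-1 colonies) is skipped.

Classification is a traversal digesting the supplied amplicons at each
node. A missing amplicon returns an ambiguous call listing the still-
possible species and naming the amplicon (or raises with
`raise_on_missing=True`); a pattern matching no branch is a first-class
*no-match* outcome, not an error — the assay is regional and out-of-panel
haplotypes are expected elsewhere. `classify_observed` scores observed
bands against the full pattern table instead, keeping every group
compatible with every observation; shrinking the tolerance can only shrink
that candidate set.

## Synthetic reference sequences

The fixture generator builds gap-free amplicon sets — mtORF (978 bp) and
PocHistone (669 bp) for the six species, plus optional extra mtORF
haplotypes (types 8, 11, 3i, 3f) for the cross-cutting checks — as
*constraint-satisfying strings, not biological mimics*: background
composition is uniform random under the seed, with no attempt at real
codon usage, GC content or phylogenetic signal. Passing tests therefore
demonstrate the machinery (site finding, digestion, scanning, keying) on
sequences with exactly the published coordinate structure; they say
nothing about alignment quality or marker variability in real specimens.

Construction: one master sequence per amplicon carries the primer
footprints verbatim (degenerate primer positions fixed to one concrete
base), the shared sites, and the *broken* variant of every polymorphic
site; each haplotype differs from the master only at declared override
columns, which switch individual sites on. Rejection resampling then
mutates unprotected background positions until no haplotype shows any
unintended enzyme site or stray primer hit, so every digest is exactly its
intended pattern; an unrepairable collision raises a generation error.
Same seed, same sequences; the fragment patterns are seed-independent.

Site placements follow the rule that **published fragment sizes outrank
published single coordinates** wherever the two disagree by 1–2 bp —
fragment sizes are cross-checkable (they sum to the amplicon length),
single coordinates are not. Concretely:

- SacI footprint at 676–681 (cut after 680 → 298 + 680); the type-1
  diagnostic adenine is the site's *second* base, so it sits at column
  677, one base past its published coordinate.
- NlaIV footprints at 313/343/514 (cuts after 315/345/516), one base off
  the published site coordinates, so the fragments come out exactly
  30/171/315/462 and 201/315/462.
- AciI footprints at 209 and 547; the shared-site fragments are 547 + 431
  (summing to 978), not the published cross-cut cell "(430, 548)", which
  is internally inconsistent and flagged rather than reproduced.
- The damicornis Tsp45I site is placed at 449–453 (cut after 448 →
  448 + 530). A cut after 530 would put the footprint at 531–535, whose
  fourth base must be A — incompatible with the damicornis-diagnostic C at
  column 534; the site and the SNP are implanted independently.
- The PocHistone XhoI site (287–292, fragments 287 + 382) likewise cannot
  contain the eydouxi SNP at 279; both are implanted independently, with
  the reading frame anchored at position 5 so that column 279 is the
  second position of a leucine codon (CTA) in eydouxi and an arginine
  codon (CGA) elsewhere.

All of these caveats are emitted in the machine-readable constraints
report (`assert_fixture_consistency`, also written by
`rflp-typer fixtures`), which re-verifies every fragment multiset, both
amplicon lengths, primer amplifiability and diagnostic-SNP recovery after
generation. A side effect of single-column site switching is that a few
site-breaking columns (e.g. 288 in the XhoI footprint, 314 and 451 in
mtORF) are themselves fixed differences and show up as additional
diagnostic columns; they are real properties of the synthetic alignment
and are documented rather than suppressed.

## Problem sizes and numerical notes

All computations are desk-scale: amplicons under 1 kb, alignments of a
few dozen records, pattern tables of 6 × 6. The property suites run a few
hundred seeded random sequences per invariant (length conservation uses
1,000 draws) and finish in seconds. Band merging uses single-linkage
clustering on sorted lengths with the tolerance evaluated at the larger
band; block partitions use greedy first-fit against block representatives,
which is exact for zero tolerance (pattern equality is then transitive).
Ties everywhere break lexicographically, so all outputs are byte-stable
given the inputs and seed.

## Known limitations

- Partial digestion, heteroplasmy/mixtures, methylation sensitivity and
  probabilistic band-calling are not modelled.
- Non-palindromic enzymes other than AciI are supported by the same
  reverse-orientation machinery but only AciI ships in the default
  database.
- The identification key is only as regional as its pattern table: taxa
  absent from the table yield no-match or a wrong neighbour, which is why
  no-match is surfaced prominently.
- Gel tolerance is a fixed rule, not a migration model; smeared or
  saturated lanes are out of scope.
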