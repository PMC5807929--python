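# rflp-typer

Design and run **in-silico PCR-RFLP species-identification assays**: find
fixed diagnostic SNPs in grouped sequence alignments, predict
restriction-digest band patterns with degenerate recognition sites, build a
stepwise identification key, and classify unknown sequences or observed gel
bands.

The package ships, as its reference workflow, the six-species *Pocillopora*
coral assay: Hawaiian *P. eydouxi*, *P. meandrina*, *P. verrucosa*,
*P. ligulata*, *P. acuta* and *P. damicornis* are told apart by digesting two
PCR amplicons — the 978 bp mitochondrial open reading frame (**mtORF**,
primers FatP6.1/RORF) and a 669 bp histone 3 region (**PocHistone**, primers
PocHistoneF/R) — with six enzymes (SacI, XhoI, AciI, AlwNI, NlaIV, Tsp45I)
chosen so that every species produces a unique cascade of band patterns.
It is aimed at molecular ecologists who need cheap, gel-readable species
assignment for taxa that cannot be identified morphologically.

## The method

1. **Diagnostic SNPs.** In an alignment partitioned into groups (species or
   haplotypes), a column is *diagnostic* for a group when every member
   carries one base and every non-member carries something else — e.g. the
   adenine inside the type-1 SacI site GAGCTC, or the cytosine at mtORF
   column 462 that creates *P. ligulata*'s AlwNI site CAGNNNCTG.
2. **In-silico digestion.** An enzyme is a degenerate IUPAC recognition
   sequence plus strand-specific cut offsets in datasheet notation
   (SacI GAGCT'C / C'TCGAG). Both orientations of non-palindromic sites are
   scanned (AciI C'CGC appears as GCGG on the other strand); ambiguity codes
   in the *subject* never match, so uncertain bases cannot predict phantom
   bands. Fragments are the intervals between top-strand cuts and always sum
   to the amplicon length.
3. **Assay screening and keying.** Each enzyme induces a partition of the
   groups by distinguishable band patterns; a greedy decision tree picks, at
   every step, the assay splitting the remaining groups into the most
   blocks. The hand-designed laboratory cascade (SacI first; then XhoI,
   AlwNI, AciI, the NlaIV confirmation, Tsp45I) is also available as a fixed
   profile.
4. **Gel-aware scoring.** Observed bands are matched to predictions under a
   detection limit (`min_detect`, default 50 bp — a 30 bp fragment is
   invisible on a 2% agarose gel) and a sizing tolerance
   (default max(10 bp, 5%)), with co-migrating bands merged.

Because the original alignments are not bundled, a **constraint-satisfying
synthetic fixture generator** builds both amplicons for all six species
(plus optional extra mtORF haplotypes): every published fragment multiset,
SNP column, and primer footprint is implanted on a random background that is
scrubbed of unintended sites, then verified by an independent self-check.

## Worked example

```bash
# write synthetic reference amplicons + groups table + constraints report
rflp-typer fixtures --seed 1 --out fixtures/

# digest the mtORF amplicons with SacI
rflp-typer digest fixtures/mtORF.fasta -e SacI
```

```text
record	enzyme	cut_positions	fragments
acuta	SacI		978
damicornis	SacI		978
eydouxi	SacI	680	680,298
ligulata	SacI		978
meandrina	SacI	680	680,298
verrucosa	SacI		978
```

Only the two mtORF type 1 species (eydouxi, meandrina) carry the GAGCTC
site: their 978 bp amplicon cuts after position 680 into 680 + 298 bp bands,
while everything else runs as a single uncut band — the first fork of the
identification cascade.

```bash
# diagnostic sites, ranked assay candidates, and the identification key
rflp-typer design \
    --alignment mtORF=fixtures/mtORF.fasta \
    --alignment PocHistone=fixtures/PocHistone.fasta \
    --groups fixtures/groups.tsv --out design/
# -> key resolves 6/6 groups to singleton leaves

# classify an observed gel: three NlaIV bands, the 30 bp one undetected
rflp-typer identify --key design/key.json \
    --bands "mtORF:NlaIV=460,320,170" --min-detect 50 --tolerance "10,5%"
```

```text
input	outcome	species	assay_path	missing_amplicon
bands	ambiguous	P. acuta; P. damicornis	mtORF:NlaIV=460, 320, 170
```

The observed bands are compatible with the predicted 462/315/171(/30)
pattern shared by *P. acuta* and *P. damicornis*; a Tsp45I digest
(uncut vs 530 + 448) would resolve the pair. The published cascade itself
renders as a dichotomous key with
`rflp-typer key-build --table design/key.json --published --format text`:

```text
[mtORF:SacI]
  bands 978:
    [mtORF:AlwNI]
      bands 978:
        [mtORF:AciI]
          bands 547, 431:
            [mtORF:NlaIV]
              bands 462, 315, 171, 30:
                [mtORF:Tsp45I]
                  bands 978:      => P. acuta
                  bands 530, 448: => P. damicornis
          bands 431, 338, 209:    => P. verrucosa
      bands 511, 467:             => P. ligulata
  bands 680, 298:
    [PocHistone:XhoI]
      bands 382, 287:             => P. eydouxi
      bands 669:                  => P. meandrina
```

The same operations are available as a library
(`rflp_typer.digest`, `amplify`, `find_fixed_snps`, `screen_enzymes`,
`build_key`, `classify_sequence`, `classify_observed`, ...); see
`docs/methods.md` for the model details and design choices.

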