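# mitorearr

Comparative analysis of animal mitochondrial genomes at desk scale:
nucleotide composition and strand skews, relative synonymous codon usage
(RSCU), overlap/spacer geometry of the circular annotation, and gene-order
rearrangement under the tandem-duplication/random-loss (TDRL) +
translocation model.

The package grew out of the comparative study of the porcelain crab
*Pisidia serratifrons* mitogenome (15,344 bp, 13 protein-coding genes,
22 tRNAs, 2 rRNAs, one AT-rich control region; GenBank OM461359), whose
annotation tables, codon-usage counts and inferred rearrangement history
are packaged as reference data. Everything is, however, written for any
metazoan mitogenome: you supply a FASTA plus a feature table, or generate
a seeded synthetic genome with known ground truth.

## What it computes

**Composition and skews.** For a region with base counts A, T, G, C:

    AT-skew = (A − T) / (A + T)        GC-skew = (G − C) / (G + C)

computed over the whole circle, each protein-coding gene (on its coding
strand — light-strand genes are reverse-complemented first), the
concatenated PCG/tRNA/rRNA sets and the control region. Ambiguity code N
is excluded from numerators and denominators.

**Codon usage.** For codon *c* in synonymous family *F*:

    RSCU(c) = n_c · |F| / Σ_{c'∈F} n_{c'}        CDspT(c) = 1000 · n_c / N

with the family grouping mitogenome papers conventionally print (leucine
split UUR/CUN, serine UCN/AGY, arginine CGN/AGR, stops as one family), or
the invertebrate-mitochondrial grouping (table 5) as an alternative.

**Annotation geometry.** Pairwise arc overlaps on the circle, rank-adjacent
intergenic spacers (gap = next.start − this.end − 1, wrapping the origin),
and coverage totals.

**Gene orders and rearrangements.** Signed circular permutations with
adjacency sets, breakpoint distances and similarity matrices; TDRL events
(tandem block duplication + per-gene random loss) and block translocations
that can be applied, verified against a target order, or searched — the
search enumerates *all* minimal-event scenarios between two orders by
meet-in-the-middle breadth-first search.

**Synthetic data.** A seeded generator for annotated circular genomes
(study-shaped by default: same feature lengths, strands, gaps and AT-rich
composition as the reference annotation) and for gene orders derived from
a reference by a known number of planted events.

## Worked example

Replaying the inferred rearrangement history of *P. serratifrons* — two
TDRL events plus four translocations applied to the pancrustacean ground
pattern:

```python
from mitorearr import reference
from mitorearr.rearrangement import verify_scenario

scen = reference.published_scenario()
verdict = verify_scenario(scen)
print(verdict.success, verdict.involved_tally)
```

```
True {'tRNA': 11, 'PCG': 4}
```

The scenario reproduces the observed gene order exactly, and the genes
carried by duplicated or translocated blocks are 11 tRNAs (D, G, A, R, N,
S1, E, I, Q, M, P) and 4 PCGs (atp8, atp6, cox3, nad3).

The numbered scripts under `analysis/` run each stage over the packaged
data and write their tables under `results/`. For instance
`python analysis/04_gene_order_comparison.py` prints:

```
shared adjacencies (of 38): 25; breakpoint distance: 13
conserved clusters intact: {'F-nad5': True, 'nad5-H': True, 'H-nad4': True,
 'nad4-nad4l': True, 'rrnL-V': True, 'V-rrnS': True}
```

i.e. the observed order keeps 25 of 38 ancestral adjacencies, and the two
classically conserved clusters (F–nad5–H–nad4–nad4L and rrnL–V–rrnS) are
intact.

## Layout

    src/mitorearr/      library: genome model, composition, codon usage,
                        geometry, gene orders, rearrangement, simulator,
                        packaged reference data, CLI
    analysis/           numbered narrative drivers writing results/
    tests/              pytest suite (unit + property + reproduction)
    scripts/            acceptance recomputation
    docs/methods.md     models, conventions, design choices, limitations
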