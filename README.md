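# rasevol

Comparative sequence analysis of RAS GTPase ortholog families.

RAS oncoproteins (HRAS, NRAS, KRAS4A, KRAS4B and relatives across the
eukaryotes) consist of a highly conserved catalytic G-domain (residues
1–166) and a short, unstructured C-terminal hypervariable region (HVR,
~18–23 residues) that carries all of the membrane-targeting information:
a terminal CaaX prenylation box plus a "second signal" that is either
palmitoylatable cysteines with short polybasic regions, or a strongly
basic polybasic domain with a phosphorylation-acceptor serine/threonine.
Comparing these architectures — together with intron positions/phases and
G-domain sequence signatures — across species is how the evolutionary
history of the isoform family is reconstructed.

`rasevol` implements that comparative pipeline as a tested, reusable
library for molecular evolution work on this family (and as a template
for similar small-GTPase analyses):

- **HVR motif annotation** (`rasevol.hvr`) — domain split at residue 166
  (or anchored by alignment to a reference for proteins with extended
  termini), CaaX classification with the L/F geranylgeranyl rule,
  detection of PBR1/PBR2 (`[KR][hydrophobic][KR][KR]`, net charge +3),
  NB (`[KR][ED][KR]`, +1), PBD (≥4 K/R immediately before the CaaX
  cysteine, charge ≥ +4; +8 in the KRAS4B-type polylysine), palmitoyl
  cysteines and the c−4 phospho acceptor; classification into six HVR
  archetypes (KRAS4B-, KRASBL-, HRAS-, NRAS-, KRAS4A-, invertebrate-like).
- **Intron structure** (`rasevol.introns`) — intron phases from coding
  exon lengths, projection of intron positions onto a protein alignment,
  and exact-position/same-phase homology clustering with `a, b, c, …`
  labels.
- **Signature scanning** (`rasevol.signature`) — Hamming scans for the two
  switch-region signature blocks (EYDPTIEDSYRK at 31–42, AGQEEYSAMRDQYM at
  59–72) and gap-free 100%-conserved column runs in alignments.
- **Identity and alignment** (`rasevol.align`) — affine-gap global
  alignment (BLOSUM62, gap open 11 / extend 1, BLAST-style), percent
  identity with the gapped-column denominator, records × references
  identity matrices, and a small progressive MSA for near-identical
  families.
- **Phylogenies** (`rasevol.phylo`) — gap-fraction alignment curation,
  p / Poisson / Kimura protein distances, BioNJ tree reconstruction with
  column-bootstrap support, Newick output.
- **Simulation** (`rasevol.simulate`) — archetype templates evolved along
  a tree under per-position constraint masks, with gene models and full
  truth tables, so every stage is testable without any sequence download.

## Worked example

Simulate a 6-leaf KRAS4B-like ortholog family and run the whole analysis:

```bash
python -c "
from rasevol.simulate import archetype, balanced_tree, simulate_dataset
simulate_dataset('sim', archetype('KRAS4B-like'), balanced_tree(6, 0.1),
                 rate=0.1, seed=7)"
rasevol run --fasta sim/family.fasta --genes sim/genes.tsv \
            --bootstrap 100 --seed 7 --out-dir out
```

`out/motif_table.tsv` (columns abridged) shows every leaf keeping the
KRAS4B architecture — a farnesylated CVIM CaaX, the KEK neutralized-basic
triplet, the +8 polylysine PBD, and the phospho acceptor at position 181
(c−4 of the CaaX cysteine at 185):

```
record_id  archetype    caax_peptide  prenyl_type  nb   pbd         pbd_charge  phospho_position  hvr_charge
leaf_1     KRAS4B-like  CVIM          farnesyl     KEK  KKKKKKSKTK  8           181               8
leaf_2     KRAS4B-like  CVIM          farnesyl     KEK  KKKKKKSKTK  8           181               8
```

`out/intron_homology.tsv` recovers the canonical three-intron gene
structure — coding offsets 93, 272 and 432, phases 0, 2, 0, clustering
into homology groups `a`, `b`, `c` across all six genes:

```
gene_id  ordinal  cds_offset  phase  protein_position  column  group_label
leaf_1   1        93          0      32                31      a
leaf_1   2        272         2      91                90      b
leaf_1   3        432         0      145               144     c
```

`out/identity_matrix.tsv` has a 100.0 diagonal with off-diagonal
identities of 96–99% at this simulated divergence, and `out/tree.nwk` is
the bootstrapped BioNJ tree:

```
(leaf_2:0.0108964,(leaf_3:0.00525863,leaf_4:0.0108793)99:0.0164798,
 (leaf_1:0,(leaf_5:0.016347,leaf_6:0.0107542)94:0.0110983)45:0);
```

Internal node labels are bootstrap percentages (here 100 replicates);
short sister branches at low divergence carry low support, exactly as
they should.

## Command-line interface

`rasevol` exposes each stage as a subcommand: `annotate-hvr`,
`intron-homology`, `signature-scan`, `identity`, `msa`, `tree`,
`simulate` and `run` (the full pipeline, configurable by YAML with flag
overrides). Exit codes: 0 ok, 2 input error, 3 stage failure.

See `docs/methods.md` for the models, parameter choices, numerical
details and known limitations.
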