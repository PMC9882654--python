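# Methods

This note documents the models and procedures implemented in `rasevol`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Domain model

A RAS-family protein is treated as a G-domain of exactly 166 residues
followed by the hypervariable region (HVR). The default split cuts after
residue 166; full-length orthologs are then 184–189 residues with HVRs of
18–23 residues. For proteins whose absolute numbering is shifted by
extended N-/C-termini (fungal orthologs run to 213–322 residues), the
anchored mode pairwise-aligns the sequence to a user-supplied reference
and cuts after the column aligned to reference residue 166. Anchoring is
refused when that column falls inside a gap run longer than 10 columns in
the query — at that point the boundary is not meaningfully transferable.

Coordinate conventions throughout: genomic spans are 0-based half-open
(length arithmetic stays trivial), protein positions are 1-based (so
"residues 1–166" and "S181" read naturally).

## HVR motif grammar

- **Charge model.** +1 per K/R, −1 per D/E, 0 otherwise; histidine is
  treated as neutral at physiological pH. This reproduces the canonical
  +8 for the KRAS4B polylysine stretch and +3 for every PBR consensus
  match. No pKa machinery: charge at arbitrary pH is out of scope.
- **CaaX.** The last four residues; valid iff position −4 is cysteine.
  The terminal residue selects the prenyl lipid: L or F directs
  geranylgeranylation, anything else farnesylation. The call is a pure
  function of the last four residues.
- **PBR1/PBR2.** Consensus `[KR][hydrophobic][KR][KR]` with the
  hydrophobic set {A,V,L,I,M,F,W,Y} (the standard strongly hydrophobic
  residues; the consensus itself fixes the other three slots, so the set
  only has to separate hydrophobics from polar residues). PBR1 is sought
  strictly upstream of the first palmitoyl cysteine (or of the PBD/CaaX
  in architectures without palmitoylation), PBR2 strictly between the
  last palmitoyl cysteine and the CaaX cysteine. Leftmost match wins;
  the consensus forces a net charge of exactly +3.
- **NB.** `[KR][ED][KR]`, net charge +1, sought upstream of the PBD
  (falling back to the first palmitoyl cysteine or the CaaX cysteine when
  no PBD exists). The NB position is not constrained to the
  PBR1-homologous slot; the whole upstream region is scanned.
- **PBD.** The window of at most 10 residues ending immediately before
  the CaaX cysteine, left-trimmed of non-basic residues so the reported
  motif starts on a K/R; reported iff it contains ≥4 K/R and has net
  charge ≥ +4. Interspersed S/T/G are permitted implicitly; acidic
  residues are permitted only insofar as the charge gate still passes.
  Reporting the full trimmed window (rather than a minimal basic core)
  is deliberate: it makes the canonical KRAS4B decapeptide KKKKKKSKTK
  come out whole, with its +8 charge.
- **Phospho acceptor.** S or T at position c−4, i.e. exactly three
  residues between the acceptor and the CaaX cysteine — the geometry of
  S181 relative to C185 in human KRAS4B. The offset is fixed; it is
  measured to the cysteine, not to the start of the CaaX box.
- **Palmitoyl cysteines.** Every HVR cysteine except the CaaX cysteine.
  This is sequence bookkeeping, not enzymology: no claim is made that a
  listed cysteine is actually palmitoylated.

An invalid CaaX blocks PBD and PBR2 (both are defined relative to the
CaaX cysteine) but PBR1 and NB are still searched; batch annotation never
aborts on a single bad sequence, it emits a profile flagged invalid.

**Archetype classification** is a fixed-precedence decision table over
the profile: PBD ∧ NB ∧ phospho ∧ no palmitoyl cysteines → KRAS4B-like
(farnesyl) or, with a geranylgeranyl CaaX, KRASBL-like for vertebrate
records and invertebrate-like otherwise; PBR1 with two palmitoyl
cysteines → HRAS-like; with one and a PBR2 → KRAS4A-like; with one and
no PBR2 → NRAS-like; anything else → unclassified. The clade label is
metadata on the record, not inferred. When both a PBD and a PBR1 are
present the PBD branch wins and a note records the tie.

## Intron phases and homology

Phase = cumulative coding length upstream of the junction, mod 3. Phase-0
introns fall between codons and are flagged as boundaries; phase-1/2
introns interrupt residue ⌊offset/3⌋+1. Projection onto an alignment is
per-row through the residue↔column maps; a phase-0 intron is keyed by the
column of the residue following the boundary. Homology clustering is
exact: same alignment column and same phase, with the boundary flag
implied by the phase, so a phase-0 junction can never merge with an
interrupted residue. No fuzz window is applied — near-miss columns (±1)
stay separate. Groups are labelled a, b, c, … by ascending column
(double letters after z), ties at equal column ordered by phase.
Non-coding exons are carried through parsing but never contribute to
phase computation.

## Signature scanning

The two signature blocks are fixed 12- and 14-mers at canonical positions
31 and 59. Scanning is ungapped (Hamming distance, 'X' always counts as
a mismatch, including against itself): in near-identical G-domains the
signature is a fixed-length block and edit-distance flexibility would
only blur the mismatch counts that distinguish orthologs (0) from the
nearest paralogs (2–3). Conserved-run detection requires columns that
are gap-free and identical across all rows; a column with any gap can
never be "100% identical".

## Alignment and identity

Global alignment is Gotoh affine-gap Needleman–Wunsch under BLOSUM62 with
BLAST-style gap costs (a gap of length k costs 11 + k·1). Traceback
tie-breaking is fixed — diagonal over gap, gap-in-a over gap-in-b — so
outputs are deterministic. Percent identity divides by all alignment
columns including gapped ones (the BLAST "Identities = n/m" convention);
an ungapped denominator is available as an option. The aligner is
cross-checked in the test suite against an independently written
brute-force DP oracle and against Biopython's `PairwiseAligner`.

The progressive MSA exists to make the pipeline self-contained for
near-identical families: guide order from single-linkage clustering of
pairwise p-distances, profile-to-profile Gotoh merges under the same
scoring, fully deterministic. It is not a general-purpose aligner — for
divergent sets supply an external alignment.

## Distances, BioNJ and bootstrap

Alignment curation drops columns whose gap fraction exceeds 0.2 (a
simple stand-in for block-based curation). The mismatch fraction p is
computed over pairwise gap-free columns; corrections: Poisson
d = −ln(1−p) and Kimura d = −ln(1 − p − 0.2p²) (default). The Kimura
correction approximates empirical-matrix ML distances closely in the
regime these analyses occupy (near-identical sequences, p ≲ 0.3), which
is why full rate-matrix ML distances were not implemented; a
Jukes–Cantor option covers nucleotide alignments routed through the same
machinery. Saturated pairs (correction argument ≤ 0) are set to a
ceiling of 10 substitutions/site and flagged.

BioNJ: standard NJ Q-criterion for pair selection (ties → lowest index
pair), NJ split formula for branch lengths (negatives clamped to 0 with
a warning), and the variance-weighted reduction step with λ clamped to
[0,1] (λ = ½ when the pair variance is 0). On additive matrices the
reduction is exact for any λ, so the generating topology and branch
lengths are recovered exactly — the test suite verifies RF distance 0
and path-length agreement within 1e-9 on random 5–8-leaf trees. Two
taxa yield a single edge split evenly; three taxa use the closed-form
star lengths.

Bootstrap: columns resampled with replacement, distances and BioNJ
recomputed per replicate, and each internal edge of the full-data tree
annotated with the percentage of replicates containing the same
bipartition (canonicalised, so the rooting of replicate trees is
irrelevant). All randomness flows from one integer seed through one
generator; the same seed gives bit-identical Newick output. Trees are
unrooted (root trifurcation); Newick output prints branch lengths to six
significant digits and quotes labels containing metacharacters.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:
ortholog families with a frozen 166-residue G-domain scaffold carrying
the two signature blocks at 31–42 and 59–72, archetype-specific HVRs
realizing each motif grammar, and per-leaf gene models with introns
planted at chosen coding offsets (the default plan is the canonical
four-exon structure: introns a, b, c at offsets 93, 272, 432, phases
0, 2, 0; the CDS includes the stop codon, so a 188-residue protein has
a 567 nt CDS).

Evolution along a (Newick) tree mutates each position independently with
probability branch length × rate, capped at 1. With the constraint mask
respected, frozen positions (signature blocks, initiator methionine,
cysteines, the CaaX terminal residue) never change and class-constrained
positions resample within their class (basic, acidic, hydrophobic, S/T);
free HVR positions draw from the 19 non-cysteine residues so drift
cannot invent spurious palmitoylation sites and silently change the
architecture. This is a uniform kernel within allowed classes, not an
empirical rate matrix — sufficient to exercise every downstream
statistic, but not a realistic substitution process: simulated
divergences should not be read as calibrated evolutionary distances.
Indels are not simulated (simulated families are gap-free, so alignment
stress comes only from user data), and the G-domain scaffold outside the
signature blocks is arbitrary synthetic sequence, not a natural RAS
G-domain. The KRAS4B polylysine decapeptide KKKKKKSKTK is the one
verbatim natural fixture, retained because the +8 charge claim anchors
to it. Consequently, passing tests demonstrate the correctness of the
annotators and tree machinery under the assumed structure; they do not
demonstrate recovery performance on real, indel-containing, rate-
heterogeneous data.

Defaults used by the tests and the acceptance script: 12-leaf balanced
trees with branch lengths 0.1, rate 0.1 substitutions/site (masked), 200
bootstrap replicates for support checks and 10–100 for smoke tests —
sizes chosen so the whole suite exercises every stage in under a minute
on a single CPU while keeping the statistical checks (e.g. ≥95% support
for a true split across a 0.5-substitutions/site internal branch)
comfortably away from their thresholds.

## Known limitations

- No ML or Bayesian tree inference, no empirical-matrix (JTT/WAG) ML
  distances, no aLRT supports; distance methods only.
- The progressive MSA degrades on divergent or indel-rich input; it is a
  convenience, not a MAFFT/MUSCLE replacement.
- Palmitoylation/phosphorylation calls are positional grammar, not
  biochemistry.
- The PBR1 variant with the hydrophobic residue in the third position
  (seen in cartilaginous-fish NRAS) is not matched by the default
  consensus; a relaxed class could be added behind an option but is off
  by default, so such sequences classify as unclassified.
- Gene models represent alternative last exons (the KRAS 4A/4B case)
  only as two gene models sharing upstream exons; splicing mechanics are
  out of scope.
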