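"""Synthetic ortholog-family generator.

Generates RAS-like ortholog families, gene models, and truth tables with
the statistical structure the analysis pipeline assumes, so every stage is
testable without external sequence retrieval.  A family is produced by
evolving an archetype template along a phylogeny under a per-position
constraint mask:

* ``frozen`` / ``cysteine-frozen`` positions never mutate (the switch-region
  signature blocks, the CaaX cysteine, palmitoyl cysteines);
* class-constrained positions (``basic-only``, ``hydrophobic-only``,
  ``acidic-only``, ``S/T-only``) resample within their residue class, which
  preserves the motif grammar while letting the sequence drift;
* ``free`` positions substitute uniformly over the 20 amino acids.

The G-domain scaffold is a fixed synthetic 166-residue sequence carrying
the two signature blocks at their canonical positions (31-42 and 59-72);
apart from the KRAS4B polylysine decapeptide KKKKKKSKTK, which anchors the
printed +8 charge, all templates are synthetic look-alikes rather than
copies of natural sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .hvr import profile_hvr
from .introns import compute_introns
from .io import GeneModel, ProteinRecord, RasevolError, write_fasta, write_gene_models
from .phylo import read_newick, write_newick

# constraint classes
FROZEN = "frozen"
CYS_FROZEN = "cysteine-frozen"
BASIC_ONLY = "basic-only"
HYDRO_ONLY = "hydrophobic-only"
ACIDIC_ONLY = "acidic-only"
ST_ONLY = "S/T-only"
FREE = "free"
#: free HVR positions exclude cysteine so that drift cannot invent
#: spurious palmitoylation sites and flip the archetype
FREE_NONCYS = "free-noncys"

AMINO_ACIDS_20 = "ACDEFGHIKLMNPQRSTVWY"
CLASS_ALPHABET = {
    BASIC_ONLY: "KR",
    HYDRO_ONLY: "AVLIMFWY",
    ACIDIC_ONLY: "DE",
    ST_ONLY: "ST",
    FREE: AMINO_ACIDS_20,
    FREE_NONCYS: AMINO_ACIDS_20.replace("C", ""),
}

#: Fixed synthetic G-domain scaffold (166 aa); positions 31-42 and 59-72
#: (1-based) carry the signature blocks, everything else is arbitrary.
GDOMAIN_SCAFFOLD = (
    "MRCEHRIFKWKQFKYDYHAWYHIYLLKRSWEYDPTIEDSYRKRLFCAIVFYQTPAQSIAG"
    "QEEYSAMRDQYMQLAHHDTSYNDIANPMQWEHYTQEHDKKSYTHDHIFCVAIKNTACNCW"
    "DAQSKMGRPDGRCWEFFVEAIRRWFGFEPLTIKNDFDENCDAHIFS"
)
SIGNATURE_SPANS = ((31, 42), (59, 72))  # 1-based inclusive


@dataclass(frozen=True)
class ArchetypeTemplate:
    """A full-length archetype sequence with its per-position constraints."""

    label: str
    gdomain: str
    hvr: str
    hvr_mask: tuple[str, ...]
    clade: str

    @property
    def sequence(self) -> str:
        return self.gdomain + self.hvr

    @property
    def mask(self) -> tuple[str, ...]:
        gmask = [FREE] * len(self.gdomain)
        gmask[0] = FROZEN  # initiator methionine
        for start, end in SIGNATURE_SPANS:
            for i in range(start - 1, end):
                gmask[i] = FROZEN
        return tuple(gmask) + self.hvr_mask


def _hvr_mask(hvr: str, caax_x_frozen: bool = True) -> list[str]:
    """Default per-position classes for an HVR template.

    Basic residues stay basic, acidic stay acidic, the phospho S/T slot
    stays S/T, cysteines are frozen (palmitoylation sites and the CaaX
    cysteine), the CaaX terminal residue is frozen to preserve the prenyl
    signal, and everything else is free.
    """
    mask = []
    n = len(hvr)
    for i, aa in enumerate(hvr):
        if aa == "C":
            mask.append(CYS_FROZEN)
        elif i >= n - 4:
            # CaaX box: keep aliphatics within the hydrophobic class, freeze X
            if i == n - 1:
                mask.append(FROZEN if caax_x_frozen else FREE)
            else:
                mask.append(HYDRO_ONLY if aa in CLASS_ALPHABET[HYDRO_ONLY] else FROZEN)
        elif aa in "KR":
            mask.append(BASIC_ONLY)
        elif aa in "DE":
            mask.append(ACIDIC_ONLY)
        elif aa in "ST":
            mask.append(ST_ONLY)
        elif aa in CLASS_ALPHABET[HYDRO_ONLY]:
            mask.append(HYDRO_ONLY)
        else:
            mask.append(FREE_NONCYS)
    return mask


def build_archetypes() -> list[ArchetypeTemplate]:
    """The six HVR architecture archetypes.

    Each template, annotated by :mod:`rasevol.hvr`, classifies as its own
    label (checked by the test suite):

    * KRAS4B-like — NB + PBD (+8 polylysine) + phospho S + farnesyl CaaX,
      no palmitoyl cysteines;
    * KRASBL-like — same architecture with a geranylgeranyl CaaX (vertebrate);
    * invertebrate-like — NB + PBD + single (CaaX) cysteine + geranylgeranyl;
    * HRAS-like — PBR1 + two palmitoyl cysteines;
    * NRAS-like — PBR1 + one palmitoyl cysteine, no PBR2;
    * KRAS4A-like — PBR1 + one palmitoyl cysteine + PBR2.
    """
    g = GDOMAIN_SCAFFOLD
    specs = [
        ("KRAS4B-like", "TGKEKDSN" + "KKKKKKSKTK" + "CVIM", "vertebrate"),
        ("KRASBL-like", "TGKEKDSN" + "KKKKKKSKTK" + "CVIL", "vertebrate"),
        ("invertebrate-like", "NGREKTSA" + "KRKKSKSKTK" + "CTIL", "invertebrate"),
        ("HRAS-like", "KLRK" + "ESGPG" + "C" + "MS" + "C" + "K" + "CVLS", "vertebrate"),
        ("NRAS-like", "KLRK" + "DTENSG" + "C" + "GLP" + "CVVM", "vertebrate"),
        ("KRAS4A-like", "KIRK" + "ESNTG" + "C" + "S" + "KIKK" + "CIIM", "vertebrate"),
    ]
    return [
        ArchetypeTemplate(label=label, gdomain=g, hvr=hvr,
                          hvr_mask=tuple(_hvr_mask(hvr)), clade=clade)
        for label, hvr, clade in specs
    ]


def archetype(label: str) -> ArchetypeTemplate:
    for template in build_archetypes():
        if template.label == label or template.label.lower().startswith(label.lower()):
            return template
    raise RasevolError(f"unknown archetype {label!r}")


# ---------------------------------------------------------------------------
# Sequence evolution along a tree
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated family."""

    tree_newick: str
    archetypes: dict[str, str]                 # record_id → archetype label
    motif_spans: dict[str, list[tuple[str, int, int]]]  # record_id → (kind, start, end)
    introns: dict[str, list[tuple[str, int, int]]]      # gene_id → (label, cds_offset, phase)
    seed: int
    parameters: dict = field(default_factory=dict)


def _mutate(seq: list[str], mask, p: float, mask_respect: bool,
            rng: np.random.Generator) -> None:
    if p <= 0:
        return
    p = min(1.0, p)
    draws = rng.random(len(seq))
    for i, u in enumerate(draws):
        if u >= p:
            continue
        cls = mask[i] if mask_respect else FREE
        if cls in (FROZEN, CYS_FROZEN):
            continue
        allowed = CLASS_ALPHABET[cls]
        choices = [aa for aa in allowed if aa != seq[i]]
        if not choices:
            continue
        seq[i] = choices[rng.integers(0, len(choices))]


def evolve_family(template: ArchetypeTemplate, tree_newick: str,
                  subs_per_site_per_branch: float = 1.0,
                  mask_respect: bool = True,
                  seed: int = 0) -> tuple[list[ProteinRecord], SimTruth]:
    """Evolve an archetype template along a tree.

    Along each branch every position mutates independently with probability
    ``branch length × subs_per_site_per_branch`` (capped at 1).  When
    ``mask_respect`` is set, frozen positions never change and constrained
    positions resample within their class.  A fixed seed reproduces the
    family exactly.
    """
    if subs_per_site_per_branch < 0:
        raise RasevolError("substitution rate must be ≥ 0")
    tree = read_newick(tree_newick)
    rng = np.random.default_rng(seed)
    mask = template.mask
    tree.seq = list(template.sequence)
    records: list[ProteinRecord] = []
    for node in tree.preorder(include_self=False):
        seq = list(node.parent.seq)
        bl = node.length or 0.0
        _mutate(seq, mask, bl * subs_per_site_per_branch, mask_respect, rng)
        node.seq = seq
        if node.is_tip():
            if not node.name:
                raise RasevolError("tree has unnamed leaves")
            records.append(ProteinRecord(
                id=node.name, residues="".join(seq),
                species=node.name.replace("_", " "),
                clade_label=template.clade,
            ))
    if not records:
        raise RasevolError("tree has no leaves")
    template_profile = profile_hvr(ProteinRecord(
        id="template", residues=template.sequence,
        clade_label=template.clade))
    spans = [(h.kind, h.start, h.end) for h in template_profile.hits]
    truth = SimTruth(
        tree_newick=write_newick(tree),
        archetypes={rec.id: template.label for rec in records},
        motif_spans={rec.id: list(spans) for rec in records},
        introns={},
        seed=seed,
        parameters={
            "archetype": template.label,
            "rate": subs_per_site_per_branch,
            "mask_respect": mask_respect,
        },
    )
    return records, truth


def balanced_tree(n_leaves: int, branch_length: float = 0.1,
                  prefix: str = "leaf") -> str:
    """Newick for a balanced (successively paired) tree with uniform
    branch lengths; leaves are ``{prefix}_1 .. {prefix}_n``."""
    if n_leaves < 2:
        raise RasevolError("balanced_tree requires ≥2 leaves")
    nodes = [f"{prefix}_{i + 1}:{branch_length:g}" for i in range(n_leaves)]
    while len(nodes) > 2:
        paired = []
        for i in range(0, len(nodes) - 1, 2):
            paired.append(f"({nodes[i]},{nodes[i + 1]}):{branch_length:g}")
        if len(nodes) % 2:
            paired.append(nodes[-1])
        nodes = paired
    return f"({nodes[0]},{nodes[1]});"


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlannedIntron:
    """One intron of an intron plan.

    ``lineages=None`` plants the intron in every gene; otherwise only in
    the named records.  ``lost`` removes it from specific records (intron
    loss events).
    """

    label: str
    cds_offset: int
    lineages: frozenset | None = None
    lost: frozenset = frozenset()

    @property
    def phase(self) -> int:
        return self.cds_offset % 3


def vertebrate_intron_plan(protein_length: int = 188) -> list[PlannedIntron]:
    """The canonical three-intron plan: introns a, b, c at coding offsets
    93, 272 and 432 (phases 0, 2, 0) within a four-exon gene."""
    cds_len = 3 * (protein_length + 1)
    offsets = (93, 272, 432)
    if any(off >= cds_len for off in offsets):
        raise RasevolError("protein too short for the canonical intron plan")
    return [PlannedIntron(label, off) for label, off in zip("abc", offsets)]


def make_gene_models(family: list[ProteinRecord],
                     intron_plan: list[PlannedIntron],
                     intron_length: int = 200,
                     seed: int = 0) -> tuple[list[GeneModel], dict]:
    """Per-leaf gene models whose computed introns reproduce the plan.

    Exon genomic spans are laid out on a per-gene synthetic region with
    fixed-length introns; the CDS length is 3×(protein length + 1) (stop
    codon included).  Returns the models and a truth mapping
    gene_id → list of (label, cds_offset, phase).
    """
    del seed  # deterministic; kept for interface symmetry
    seen = set()
    for intron in intron_plan:
        if intron.cds_offset in seen:
            raise RasevolError(f"duplicate planned intron offset {intron.cds_offset}")
        seen.add(intron.cds_offset)
    models = []
    truth: dict[str, list[tuple[str, int, int]]] = {}
    for rec in family:
        cds_len = 3 * (len(rec.residues) + 1)
        applicable = []
        for intron in intron_plan:
            if intron.cds_offset >= cds_len:
                raise RasevolError(
                    f"planned intron {intron.label!r} at offset "
                    f"{intron.cds_offset} beyond the {cds_len} nt CDS of {rec.id!r}"
                )
            if intron.lineages is not None and rec.id not in intron.lineages:
                continue
            if rec.id in intron.lost:
                continue
            applicable.append(intron)
        applicable.sort(key=lambda x: x.cds_offset)
        boundaries = [0] + [x.cds_offset for x in applicable] + [cds_len]
        spans = []
        genomic = 0
        for start, end in zip(boundaries, boundaries[1:]):
            spans.append((genomic, genomic + (end - start)))
            genomic += (end - start) + intron_length
        models.append(GeneModel(gene_id=rec.id, region_id=f"region_{rec.id}",
                                strand="+", coding_exons=spans))
        truth[rec.id] = [(x.label, x.cds_offset, x.phase) for x in applicable]
    # sanity: computed introns reproduce the plan
    for model in models:
        got = [(r.cds_offset, r.phase) for r in compute_introns(model)]
        want = [(off, ph) for _, off, ph in truth[model.gene_id]]
        assert got == want
    return models, truth


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------

def simulate_dataset(out_dir, template: ArchetypeTemplate, tree_newick: str,
                     rate: float = 0.1, mask_respect: bool = True,
                     seed: int = 0,
                     intron_plan: list[PlannedIntron] | None = None) -> dict:
    """Simulate one family and write FASTA, gene models and truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth = evolve_family(template, tree_newick, rate,
                                   mask_respect, seed)
    if intron_plan is None:
        intron_plan = vertebrate_intron_plan(len(records[0].residues))
    models, intron_truth = make_gene_models(records, intron_plan)
    truth.introns = intron_truth
    write_fasta(records, out / "family.fasta")
    write_gene_models(models, out / "genes.tsv")
    (out / "truth_tree.nwk").write_text(truth.tree_newick + "\n")
    with open(out / "truth_motifs.tsv", "w") as fh:
        fh.write("record_id\tarchetype\tmotif\tstart\tend\n")
        for rid in sorted(truth.archetypes):
            for kind, start, end in truth.motif_spans[rid]:
                fh.write(f"{rid}\t{truth.archetypes[rid]}\t{kind}\t{start}\t{end}\n")
    with open(out / "truth_introns.tsv", "w") as fh:
        fh.write("gene_id\tlabel\tcds_offset\tphase\n")
        for gid in sorted(intron_truth):
            for label, off, phase in intron_truth[gid]:
                fh.write(f"{gid}\t{label}\t{off}\t{phase}\n")
    params = dict(truth.parameters, seed=seed, tree=tree_newick.strip(),
                  n_leaves=len(records))
    (out / "params.yaml").write_text(yaml.safe_dump(params, sort_keys=True))
    return {"records": records, "gene_models": models, "truth": truth}
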