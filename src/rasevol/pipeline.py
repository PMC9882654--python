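"""End-to-end orchestration: motif table, intron homology, signature
report, identity matrix and bootstrapped tree from one configuration."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .align import identity_matrix, progressive_msa
from .hvr import motif_table
from .introns import (check_cds_protein_consistency, cluster_homologous,
                      compute_introns, intron_homology_table, label_groups,
                      project_introns)
from .io import AlignedSet, RasevolError, read_fasta, read_gene_models
from .phylo import bootstrap_support, curate_alignment, write_newick
from .signature import BLOCK1, BLOCK2, conserved_blocks, scan_signature, signature_report


class StageError(RasevolError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    fasta: str | Path
    out_dir: str | Path
    genes: str | Path | None = None
    alignment: str | Path | None = None
    references: str | Path | None = None
    max_mismatch: int = 3
    max_gap_fraction: float = 0.2
    distance_model: str = "kimura"
    bootstrap_replicates: int = 200
    seed: int = 0
    identity_denominator: str = "columns"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage whose inputs are present; return artifact paths.

    Stages: motif annotation (always), identity matrix (always), alignment
    (provided or built), signature report (always), intron homology (needs
    gene models), tree (needs ≥3 sequences).  A stage whose input is
    absent is skipped with a log entry; a stage hard-failure raises
    :class:`StageError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log: list[str] = [f"rasevol {__version__}", f"seed={config.seed}"]

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except RasevolError as exc:
                raise StageError(name, str(exc)) from exc
        return wrap

    records = stage("read-fasta")(lambda: read_fasta(str(config.fasta)))
    log.append(f"read {len(records)} protein records from {config.fasta}")

    # --- motif annotation -------------------------------------------------
    table = stage("annotate-hvr")(lambda: motif_table(records))
    path = out / "motif_table.tsv"
    table.to_csv(path, sep="\t", index=False)
    artifacts["motif_table"] = path
    log.append(f"motif_table.tsv: {len(table)} rows")

    # --- identity matrix --------------------------------------------------
    if config.references:
        references = stage("identity")(lambda: read_fasta(str(config.references)))
    else:
        references = records
        log.append("no reference set given; records used as references")
    matrix = stage("identity")(lambda: identity_matrix(
        records, references, denominator=config.identity_denominator))
    path = out / "identity_matrix.tsv"
    matrix.to_csv(path, sep="\t", index_label="record_id")
    artifacts["identity_matrix"] = path
    log.append(f"identity_matrix.tsv: {matrix.shape[0]}x{matrix.shape[1]}")

    # --- alignment --------------------------------------------------------
    if config.alignment:
        aln = stage("alignment")(lambda: AlignedSet.from_fasta(str(config.alignment)))
        log.append(f"alignment read from {config.alignment}")
    elif len(records) >= 2:
        aln = stage("alignment")(lambda: progressive_msa(records))
        path = out / "alignment.fasta"
        aln.to_fasta(path)
        artifacts["alignment"] = path
        log.append("alignment built with the progressive aligner")
    else:
        aln = None
        log.append("single sequence: alignment stage skipped")

    # --- signature report -------------------------------------------------
    def _signatures():
        hits = {}
        for rec in records:
            rec_hits = []
            for block in (BLOCK1, BLOCK2):
                if len(rec.residues) >= len(block.residues):
                    rec_hits.extend(scan_signature(rec, block, config.max_mismatch))
            hits[rec.id] = rec_hits
        runs = conserved_blocks(aln, min_length=2) if aln is not None \
            and aln.n_rows >= 2 else None
        return signature_report(hits, runs)

    report = stage("signature-scan")(_signatures)
    path = out / "signature_report.tsv"
    report.to_csv(path, sep="\t", index=False)
    artifacts["signature_report"] = path
    log.append(f"signature_report.tsv: {len(report)} rows")

    # --- intron homology --------------------------------------------------
    if config.genes and aln is not None:
        def _introns():
            models = read_gene_models(str(config.genes))
            by_id = {rec.id: rec for rec in records}
            intron_records = []
            for model in models:
                if model.gene_id in by_id:
                    check_cds_protein_consistency(
                        model, len(by_id[model.gene_id].residues))
                intron_records.extend(compute_introns(model))
            projected = project_introns(intron_records, aln)
            groups = label_groups(cluster_homologous(projected))
            return intron_homology_table(projected, groups)

        itable = stage("intron-homology")(_introns)
        path = out / "intron_homology.tsv"
        itable.to_csv(path, sep="\t", index=False)
        artifacts["intron_homology"] = path
        log.append(f"intron_homology.tsv: {len(itable)} rows")
    else:
        log.append("no gene models: intron-homology stage skipped")

    # --- tree -------------------------------------------------------------
    if aln is not None and aln.n_rows >= 3:
        def _tree():
            curated = curate_alignment(aln, config.max_gap_fraction)
            return bootstrap_support(curated, model=config.distance_model,
                                     replicates=config.bootstrap_replicates,
                                     seed=config.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = stage("tree")(_tree)
        path = out / "tree.nwk"
        write_newick(tree, path)
        artifacts["tree"] = path
        log.append(f"tree.nwk: {config.bootstrap_replicates} bootstrap "
                   f"replicates, model={config.distance_model}")
    else:
        log.append("fewer than 3 aligned sequences: tree stage skipped")

    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(log) + "\n")
    artifacts["run_log"] = log_path
    return artifacts
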