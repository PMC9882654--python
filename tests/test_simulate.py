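"""Synthetic family generator: templates, evolution, gene models, truth."""

import numpy as np
import pytest

from rasevol.hvr import profile_hvr
from rasevol.introns import cluster_homologous, compute_introns, project_introns
from rasevol.io import AlignedSet, ProteinRecord, RasevolError
from rasevol.phylo import read_newick
from rasevol.signature import BLOCK1, BLOCK2, conserved_blocks
from rasevol.simulate import (PlannedIntron, archetype, balanced_tree,
                              build_archetypes, evolve_family,
                              make_gene_models, simulate_dataset,
                              vertebrate_intron_plan)


class TestTemplates:
    def test_six_archetypes(self, archetypes):
        assert len(archetypes) == 6
        assert len({t.label for t in archetypes}) == 6

    def test_kras4b_template_has_pbd8_and_phospho(self, archetypes):
        template = archetype("KRAS4B-like")
        rec = ProteinRecord(id="t", residues=template.sequence,
                            clade_label=template.clade)
        profile = profile_hvr(rec)
        assert profile.hit("PBD").net_charge == 8
        assert profile.phospho_acceptor == profile.caax.cys_position - 4

    def test_krasbl_template_is_geranylgeranylated(self):
        template = archetype("KRASBL-like")
        rec = ProteinRecord(id="t", residues=template.sequence,
                            clade_label=template.clade)
        assert profile_hvr(rec).caax.prenyl_type == "geranylgeranyl"

    def test_templates_self_classify(self, archetypes):
        for template in archetypes:
            rec = ProteinRecord(id="t", residues=template.sequence,
                                clade_label=template.clade)
            assert profile_hvr(rec).archetype == template.label

    def test_mask_freezes_signature_blocks_and_caax_cysteine(self, archetypes):
        for template in archetypes:
            mask = template.mask
            for start, end in ((31, 42), (59, 72)):
                assert all(mask[i] == "frozen" for i in range(start - 1, end))
            caax_c = len(template.sequence) - 4
            assert mask[caax_c] == "cysteine-frozen"


class TestEvolveFamily:
    def test_rate_zero_leaves_identical_to_template(self):
        template = archetype("HRAS-like")
        records, _ = evolve_family(template, balanced_tree(8, 0.1),
                                   subs_per_site_per_branch=0.0, seed=1)
        assert len(records) == 8
        assert all(r.residues == template.sequence for r in records)

    def test_same_seed_reproduces_family(self):
        template = archetype("NRAS-like")
        tree = balanced_tree(8, 0.1)
        a, _ = evolve_family(template, tree, 0.5, seed=13)
        b, _ = evolve_family(template, tree, 0.5, seed=13)
        assert [r.residues for r in a] == [r.residues for r in b]
        c, _ = evolve_family(template, tree, 0.5, seed=14)
        assert [r.residues for r in c] != [r.residues for r in a]

    def test_mask_keeps_signature_blocks_invariant(self, kras4b_family):
        records, _ = kras4b_family
        for rec in records:
            assert rec.residues[30:42] == BLOCK1.residues
            assert rec.residues[58:72] == BLOCK2.residues

    def test_sequences_do_diverge_at_free_positions(self, kras4b_family):
        records, _ = kras4b_family
        assert len({r.residues for r in records}) > 1

    def test_unmasked_evolution_erodes_signature(self):
        template = archetype("KRAS4B-like")
        records, _ = evolve_family(template, balanced_tree(8, 0.5),
                                   subs_per_site_per_branch=1.0,
                                   mask_respect=False, seed=3)
        assert any(r.residues[30:42] != BLOCK1.residues for r in records)

    def test_negative_rate_rejected(self):
        with pytest.raises(RasevolError):
            evolve_family(archetype("KRAS4B-like"), balanced_tree(4), -1.0)


class TestNoiselessRecovery:
    """On noiseless families every annotator recovers the generator truth."""

    def test_archetype_recovery_exact(self, archetypes):
        for template in archetypes:
            records, truth = evolve_family(template, balanced_tree(6, 0.1),
                                           subs_per_site_per_branch=0.0, seed=2)
            for rec in records:
                assert profile_hvr(rec).archetype == truth.archetypes[rec.id]

    def test_motif_spans_recovered_exactly(self, archetypes):
        for template in archetypes:
            records, truth = evolve_family(template, balanced_tree(4, 0.1),
                                           subs_per_site_per_branch=0.0, seed=2)
            for rec in records:
                profile = profile_hvr(rec)
                got = {(h.kind, h.start, h.end) for h in profile.hits}
                assert got == set(truth.motif_spans[rec.id])

    def test_masked_archetype_recovery_at_moderate_divergence(self, archetypes):
        for template in archetypes:
            records, truth = evolve_family(template, balanced_tree(8, 0.2),
                                           subs_per_site_per_branch=0.5,
                                           mask_respect=True, seed=21)
            for rec in records:
                assert profile_hvr(rec).archetype == truth.archetypes[rec.id]

    def test_signature_columns_conserved_under_mask(self, kras4b_family):
        records, _ = kras4b_family
        aln = AlignedSet([r.id for r in records], [r.residues for r in records])
        runs = conserved_blocks(aln, min_length=2)
        covered = set()
        for start, end in runs:
            covered.update(range(start, end + 1))
        assert set(range(30, 42)) <= covered
        assert set(range(58, 72)) <= covered


class TestGeneModels:
    def test_vertebrate_plan_reproduces_phases_020(self, kras4b_family):
        records, _ = kras4b_family
        models, truth = make_gene_models(records, vertebrate_intron_plan(188))
        for model in models:
            introns = compute_introns(model)
            assert [i.phase for i in introns] == [0, 2, 0]
            assert [i.cds_offset for i in introns] == [93, 272, 432]
            assert truth[model.gene_id] == [("a", 93, 0), ("b", 272, 2),
                                            ("c", 432, 0)]

    def test_cds_length_is_three_times_protein_plus_stop(self, kras4b_family):
        records, _ = kras4b_family
        models, _ = make_gene_models(records, vertebrate_intron_plan(188))
        by_id = {rec.id: rec for rec in records}
        for model in models:
            assert model.coding_length == 3 * (len(by_id[model.gene_id].residues) + 1)

    def test_intronless_plan_gives_single_exon_models(self, kras4b_family):
        records, _ = kras4b_family
        models, truth = make_gene_models(records[:3], [])
        assert all(len(m.coding_exons) == 1 for m in models)
        assert all(compute_introns(m) == [] for m in models)

    def test_lineage_specific_intron_forms_singleton_group(self, kras4b_family):
        records, _ = kras4b_family
        plan = vertebrate_intron_plan(188) + [
            PlannedIntron("d", 561, lineages=frozenset({records[0].id}))]
        models, truth = make_gene_models(records, plan)
        aln = AlignedSet([r.id for r in records], [r.residues for r in records])
        projected = []
        for model in models:
            projected.extend(project_introns(compute_introns(model), aln))
        groups = cluster_homologous(projected)
        sizes = sorted(len(g.members) for g in groups)
        assert sizes == [1, len(records), len(records), len(records)]

    def test_intron_loss_removes_member(self, kras4b_family):
        records, _ = kras4b_family
        lost_in = records[1].id
        plan = [PlannedIntron("a", 93), PlannedIntron("b", 272,
                                                      lost=frozenset({lost_in}))]
        models, truth = make_gene_models(records[:4], plan)
        by_id = {m.gene_id: m for m in models}
        assert len(compute_introns(by_id[lost_in])) == 1
        assert truth[lost_in] == [("a", 93, 0)]

    def test_plan_beyond_cds_rejected(self, kras4b_family):
        records, _ = kras4b_family
        with pytest.raises(RasevolError, match="beyond"):
            make_gene_models(records[:2], [PlannedIntron("z", 99999)])

    def test_duplicate_offsets_rejected(self, kras4b_family):
        records, _ = kras4b_family
        with pytest.raises(RasevolError, match="duplicate"):
            make_gene_models(records[:2], [PlannedIntron("a", 93),
                                           PlannedIntron("b", 93)])


class TestDatasetEmission:
    def test_artifacts_written_and_parse_back(self, tmp_path):
        out = tmp_path / "sim"
        result = simulate_dataset(out, archetype("KRAS4B-like"),
                                  balanced_tree(6, 0.1), rate=0.1, seed=4)
        for name in ("family.fasta", "genes.tsv", "truth_motifs.tsv",
                     "truth_introns.tsv", "truth_tree.nwk", "params.yaml"):
            assert (out / name).exists(), name
        from rasevol.io import read_fasta, read_gene_models
        records = read_fasta(str(out / "family.fasta"))
        assert {r.id for r in records} == \
            {r.id for r in result["records"]}
        models = read_gene_models(str(out / "genes.tsv"))
        assert len(models) == 6
        tree = read_newick(str(out / "truth_tree.nwk"))
        assert {t.name for t in tree.tips()} == {r.id for r in records}
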