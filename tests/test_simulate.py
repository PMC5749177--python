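import filecmp
import os

import numpy as np
import pytest

from orbweaver import (
    SimulationConfig,
    generative_correlation,
    simulate_caqtl_panel,
    simulate_dataset,
    simulate_pwms,
)
from orbweaver.genome import build_haplotypes, one_hot
from orbweaver.labeling import CELL_TYPES, flags_from_category
from orbweaver.pwm import build_filter_bank, log_transform
from orbweaver.simulate import SimulationError, celltype_motif_map


def _ic(matrix):
    """Mean per-column information content (bits)."""
    p = np.clip(matrix, 1e-12, 1.0)
    return float(np.mean(2 + (p * np.log2(p)).sum(axis=1)))


class TestSimulatePwms:
    def test_strength_one_gives_hard_consensus(self):
        cfg = SimulationConfig(planting_strength=1.0, seed=1)
        for p in simulate_pwms(cfg):
            assert np.all(p.matrix.max(axis=1) == 1.0)

    def test_strength_quarter_gives_uniform_rows(self):
        cfg = SimulationConfig(planting_strength=0.25, seed=1)
        for p in simulate_pwms(cfg):
            np.testing.assert_allclose(p.matrix, 0.25)

    def test_information_content_monotone_in_strength(self):
        ics = [
            np.mean([_ic(p.matrix) for p in simulate_pwms(
                SimulationConfig(planting_strength=s, seed=1))])
            for s in (0.5, 0.7, 0.9)
        ]
        assert ics[0] < ics[1] < ics[2]

    def test_every_celltype_and_shared_group_present(self):
        groups = celltype_motif_map(simulate_pwms(SimulationConfig(seed=1)))
        for t in CELL_TYPES:
            assert len(groups[t]) == 2
        assert len(groups["shared"]) == 1

    def test_narrow_motifs_rejected(self):
        with pytest.raises(SimulationError, match=">= 4"):
            SimulationConfig(motif_width_range=(3, 6))


@pytest.fixture(scope="module")
def sim():
    cfg = SimulationConfig(loci_per_category=40, seed=8)
    pwms = simulate_pwms(cfg)
    return cfg, pwms, simulate_dataset(cfg, pwms)


@pytest.fixture(scope="module")
def panel():
    cfg = SimulationConfig(n_caqtl=30, n_decoys=30, n_individuals=20, seed=8)
    pwms = simulate_pwms(cfg)
    return simulate_caqtl_panel(cfg, pwms)


class TestSimulateDataset:
    def test_per_category_counts_match_config(self, sim):
        cfg, _, ds = sim
        cats = ds.categories
        for o in range(1, 8):
            assert (cats == o).sum() == cfg.loci_per_category

    def test_category_seven_carries_all_celltype_motifs(self, sim):
        _, pwms, ds = sim
        groups = celltype_motif_map(pwms)
        for locus, planted in zip(ds.loci, ds.ground_truth):
            if locus.label.category != 7:
                continue
            tf_ids = {pm.tf_id for pm in planted}
            for t in CELL_TYPES:
                assert {p.tf_id for p in groups[t]} <= tf_ids

    def test_planted_motifs_follow_the_label(self, sim):
        _, pwms, ds = sim
        groups = celltype_motif_map(pwms)
        for locus, planted in zip(ds.loci, ds.ground_truth):
            flags = flags_from_category(locus.label.category)
            tf_ids = {pm.tf_id for pm in planted}
            for t, open_t in zip(CELL_TYPES, flags):
                present = any(p.tf_id in tf_ids for p in groups[t])
                assert present == open_t

    def test_rescanning_recovers_every_planted_motif(self, sim):
        """Every planted site is present verbatim in its window, and the
        forward scan score at the planted offset equals the instance's
        log-odds under the generating filter (the scanner sees the plant)."""
        _, pwms, ds = sim
        bank = build_filter_bank(pwms, strand_policy="forward_only")
        by_id = {p.tf_id: p for p in pwms}
        for locus, planted in zip(ds.loci[:60], ds.ground_truth[:60]):
            seq = locus.window.sequence
            scores = bank.scan(locus.window.matrix)
            for pm in planted:
                pwm = by_id[pm.tf_id]
                assert seq[pm.position : pm.position + pwm.width] == pm.instance
                f = bank.tf_index[pm.tf_id]
                instance_score = sum(
                    log_transform(pwm)[k, "ACGT".index(b)]
                    for k, b in enumerate(pm.instance)
                )
                assert scores[pm.position, f] == pytest.approx(
                    instance_score, abs=1e-6
                )

    def test_written_outputs_are_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(loci_per_category=10, seed=13)
        for d in ("a", "b"):
            pwms = simulate_pwms(cfg)
            simulate_dataset(cfg, pwms).write(str(tmp_path / d))
        for name in ("windows.fa", "labels.tsv", "ground_truth.tsv", "manifest.txt"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)


class TestCaqtlPanel:
    def test_causal_records_have_unit_posteriors_decoys_below_half(self, panel):
        for c in panel.caqtls:
            if c.is_causal:
                assert c.pi_l == c.pi_s == 1.0
            else:
                assert c.pi_s < 0.5

    def test_both_alleles_present_in_every_panel(self, panel):
        for c in panel.caqtls:
            assert 0 < c.hap_alleles.sum() < len(c.hap_alleles)

    def test_snp_ref_matches_window_sequence(self, panel):
        for c in panel.caqtls:
            assert c.ref_seq[c.snp.pos] == c.snp.ref
            assert c.snp.ref != c.snp.alt

    def test_zero_effect_snps_center_on_half(self, panel):
        fracs = [
            c.alt_count / (c.alt_count + c.ref_count)
            for c in panel.caqtls
            if c.effect == 0.0
        ]
        assert len(fracs) >= 20  # all decoys at least
        assert np.mean(fracs) == pytest.approx(0.5, abs=3 * 0.05 / np.sqrt(len(fracs)))

    def test_vcf_round_trip_recovers_haplotype_alleles(self, panel, tmp_path):
        import pyfaidx

        panel.write(str(tmp_path))
        genome = pyfaidx.Fasta(str(tmp_path / "reference.fa"))
        c = panel.caqtls[0]
        from orbweaver.genome import GenomicInterval

        hs = build_haplotypes(
            genome,
            GenomicInterval(c.chrom, 0, 500),
            str(tmp_path / "panel.vcf"),
            c.snp,
        )
        alleles = np.array(
            [1 if h.focal_allele == c.snp.alt else 0 for h in hs.haplotypes]
        )
        np.testing.assert_array_equal(alleles, c.hap_alleles)
        # in-memory construction agrees with the file route
        mem = panel.haplotype_set(0)
        assert [h.sequence for h in mem.haplotypes] == [
            h.sequence for h in hs.haplotypes
        ]

    def test_panel_outputs_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(n_caqtl=8, n_decoys=8, n_individuals=6, seed=4)
        for d in ("a", "b"):
            simulate_caqtl_panel(cfg, simulate_pwms(cfg)).write(str(tmp_path / d))
        for name in ("reference.fa", "panel.vcf", "causal.tsv", "imbalance.tsv",
                     "ground_truth.tsv"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_generative_correlation_matches_one_panel_draw(self):
        """The empirical correlation between planted effects and the panel's
        sampled imbalance sits near the Monte-Carlo generative value."""
        cfg = SimulationConfig(n_caqtl=200, n_decoys=50, n_individuals=10, seed=8)
        panel = simulate_caqtl_panel(cfg, simulate_pwms(cfg))
        r_gen = generative_correlation(panel, n_draws=10_000, seed=1)
        causal = [c for c in panel.caqtls if c.is_causal]
        effects = np.array([c.effect for c in causal])
        fracs = np.array(
            [c.alt_count / (c.alt_count + c.ref_count) for c in causal]
        )
        r_panel = float(np.corrcoef(effects, fracs - 0.5)[0, 1])
        assert r_panel == pytest.approx(r_gen, abs=0.1)

    def test_shallow_depth_warns_not_fails(self, caplog):
        SimulationConfig(depth=5, n_caqtl=2, n_decoys=2, seed=1)
        assert any("unstable" in r.message for r in caplog.records)
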