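import numpy as np
import pytest
from scipy import stats

from orbweaver import (
    CELL_TYPES,
    aggregate_key_tfs,
    deeplift_scores,
    key_tf,
    saturation_mutagenesis,
)
from orbweaver.interpret import (
    ImportanceProfile,
    InterpretError,
    _target_value,
    make_reference,
)


class TestDeepLift:
    def test_reference_input_scores_zero(self, small_net):
        net = small_net["net"]
        ref = make_reference(np.zeros((500, 4)), "background_freq")
        prof = deeplift_scores(net, ref, target=4, reference=ref)
        assert np.all(prof.scores == 0.0)
        assert prof.delta_output == 0.0

    @pytest.mark.parametrize("target", [1, 4, 7, "iPSC", "LCL", "iPSC-CM"])
    def test_summation_to_delta(self, small_net, rng, target):
        net = small_net["net"]
        for _ in range(8):
            X = np.eye(4)[rng.integers(0, 4, 500)]
            prof = deeplift_scores(net, X, target)
            total = prof.scores.sum()
            denom = max(abs(prof.delta_output), 1e-10)
            assert abs(total - prof.delta_output) / denom < 1e-4

    @pytest.mark.parametrize("spec", ["zeros", "shuffled"])
    def test_alternative_references_also_complete(self, small_net, rng, spec):
        net = small_net["net"]
        X = np.eye(4)[rng.integers(0, 4, 500)]
        prof = deeplift_scores(net, X, 7, reference_spec=spec)
        denom = max(abs(prof.delta_output), 1e-10)
        assert abs(prof.scores.sum() - prof.delta_output) / denom < 1e-4

    def test_planted_tf_gets_largest_positive_score(self, small_net):
        """On correctly classified cell-type-specific loci, the planted
        cell-type motif should dominate the attribution."""
        net, ds = small_net["net"], small_net["dataset"]
        idx = [i for i, l in enumerate(ds.loci) if l.label.category in (1, 2, 4)][:120]
        X = np.stack([ds.loci[i].window.matrix for i in idx])
        pred = net.forward_batch(X).argmax(axis=1) + 1
        hits = total = 0
        for j, i in enumerate(idx):
            locus = ds.loci[i]
            if pred[j] != locus.label.category:
                continue
            prof = deeplift_scores(net, locus.window, locus.label.category)
            assignment = key_tf(prof)
            planted = {
                pm.tf_id for pm in ds.ground_truth[i] if "shared" not in pm.tf_id
            }
            total += 1
            hits += assignment.tf_id in planted
        assert total >= 50
        assert hits / total >= 0.7

    def test_invalid_target_rejected(self, small_net):
        with pytest.raises(InterpretError):
            deeplift_scores(small_net["net"], np.zeros((500, 4)), target=9)


def _profile(scores, tf_ids):
    return ImportanceProfile(
        scores=np.asarray(scores, dtype=float),
        tf_ids=tf_ids,
        target=4,
        reference_spec="background_freq",
        delta_output=float(np.asarray(scores).sum()),
    )


class TestKeyTF:
    def test_dominant_tf_wins(self):
        prof = _profile([[0.1, 0.2], [2.0, 1.0], [0.0, 0.3]], ["a", "b", "c"])
        assert key_tf(prof).tf_id == "b"

    def test_exact_tie_breaks_lexicographically(self):
        prof = _profile([[1.0, 0.5], [0.5, 1.0]], ["TFB", "TFA"])
        assert key_tf(prof).tf_id == "TFA"

    def test_all_nonpositive_returns_sentinel(self):
        prof = _profile([[-1.0, 0.0], [-0.5, -0.2]], ["a", "b"])
        assert key_tf(prof).tf_id is None

    def test_matches_brute_force_argmax(self, rng):
        scores = rng.normal(size=(12, 30))
        ids = [f"tf{i:02d}" for i in range(12)]
        prof = _profile(scores, ids)
        agg = np.where(scores > 0, scores, 0).sum(axis=1)
        assert key_tf(prof).tf_id == ids[int(agg.argmax())]

    def test_permutation_invariant_up_to_tie_rule(self, rng):
        scores = rng.normal(size=(6, 20))
        ids = [f"tf{i}" for i in range(6)]
        prof = _profile(scores, ids)
        perm = rng.permutation(6)
        prof_p = _profile(scores[perm], [ids[i] for i in perm])
        assert key_tf(prof).tf_id == key_tf(prof_p).tf_id


class TestAggregateKeyTfs:
    def test_uniform_assignment_gives_fraction_one(self):
        from orbweaver.interpret import KeyTFAssignment

        cats = np.full(10, 4)
        preds = np.full(10, 4)
        assigns = [KeyTFAssignment("X", 1.0)] * 10
        table = aggregate_key_tfs(cats, preds, assigns)
        row = table.iloc[0]
        assert (row.category, row.tf_id, row.fraction) == (4, "X", 1.0)

    def test_misclassified_loci_excluded_and_hand_tally(self):
        from orbweaver.interpret import KeyTFAssignment

        cats = np.array([4] * 10 + [2] * 10)
        preds = np.array([4] * 8 + [7] * 2 + [2] * 10)
        assigns = [KeyTFAssignment("A", 1.0)] * 6 + [
            KeyTFAssignment("B", 1.0)
        ] * 4 + [KeyTFAssignment("C", 1.0)] * 10
        table = aggregate_key_tfs(cats, preds, assigns)
        cat4 = table[table.category == 4].set_index("tf_id")
        # 8 correctly classified in category 4: six A, two B
        assert cat4.loc["A", "fraction"] == pytest.approx(6 / 8)
        assert cat4.loc["B", "fraction"] == pytest.approx(2 / 8)
        assert table[table.category == 2].fraction.sum() == pytest.approx(1.0)

    def test_sentinel_assignments_lower_fraction_sum(self):
        from orbweaver.interpret import KeyTFAssignment

        cats = preds = np.full(4, 1)
        assigns = [KeyTFAssignment("A", 1.0)] * 3 + [KeyTFAssignment(None, 0.0)]
        table = aggregate_key_tfs(cats, preds, assigns)
        assert table.fraction.sum() == pytest.approx(0.75)


class TestMutagenesis:
    def test_reference_base_deltas_exactly_zero(self, small_net):
        locus = small_net["dataset"].loci[3]
        mmap = saturation_mutagenesis(small_net["net"], locus.window, 7)
        ref_base = locus.window.matrix.argmax(axis=1)
        assert np.all(mmap.delta[np.arange(500), ref_base] == 0.0)

    def test_entries_match_single_mutation_forward_pass(self, small_net, rng):
        net = small_net["net"]
        locus = small_net["dataset"].loci[3]
        target = locus.label.category
        mmap = saturation_mutagenesis(net, locus.window, target)
        for _ in range(25):
            p, b = int(rng.integers(500)), int(rng.integers(4))
            m = locus.window.matrix.copy()
            m[p] = np.eye(4)[b]
            v = float(_target_value(net.forward_batch(m[None]), target)[0])
            assert mmap.delta[p, b] == pytest.approx(v - mmap.base_value, abs=1e-9)

    def test_snp_delta_is_map_entry(self, small_net):
        """The predicted allele difference of a SNP is the map entry at the
        alternate base when the window carries the reference."""
        net = small_net["net"]
        locus = small_net["dataset"].loci[8]
        mmap = saturation_mutagenesis(net, locus.window, "iPSC")
        p = 250
        ref = int(locus.window.matrix[p].argmax())
        alt = (ref + 1) % 4
        m = locus.window.matrix.copy()
        m[p] = np.eye(4)[alt]
        v = float(_target_value(net.forward_batch(m[None]), "iPSC")[0])
        assert mmap.delta[p, alt] == pytest.approx(v - mmap.base_value, abs=1e-9)

    def test_planted_positions_carry_higher_attribution_than_background(self, small_net):
        """|delta| inside planted motifs exceeds background |delta| (one-sided
        rank-sum across loci)."""
        net, ds = small_net["net"], small_net["dataset"]
        inside_means, outside_means = [], []
        for locus, planted in zip(ds.loci[:100], ds.ground_truth[:100]):
            mmap = saturation_mutagenesis(net, locus.window, locus.label.category)
            mask = np.zeros(500, dtype=bool)
            for pm in planted:
                width = next(
                    p.width for p in small_net["pwms"] if p.tf_id == pm.tf_id
                )
                mask[pm.position : pm.position + width] = True
            per_pos = np.abs(mmap.delta).sum(axis=1) / 3
            inside_means.append(per_pos[mask].mean())
            outside_means.append(per_pos[~mask].mean())
        res = stats.mannwhitneyu(inside_means, outside_means, alternative="greater")
        assert res.pvalue < 0.01
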