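"""Generators: determinism, recorded truth, marginal structure, validation."""

import numpy as np
import pytest

import edgeproject as ep
from edgeproject.io import EdgeIndex


class TestStaticGenerator:
    def test_determinism(self):
        spec = ep.StaticCohortSpec(n_subjects=50, n_components=8, seed=5,
                                   planted_edges=((1, 0.2),))
        a = ep.gen_static_cohort(spec)
        b = ep.gen_static_cohort(spec)
        assert np.array_equal(a.edge_table.to_numpy(), b.edge_table.to_numpy())
        assert np.array_equal(a.outcome.to_numpy(), b.outcome.to_numpy())
        assert a.covariates.equals(b.covariates)

    def test_different_seeds_differ(self):
        a = ep.gen_static_cohort(ep.StaticCohortSpec(n_subjects=20, n_components=6, seed=1))
        b = ep.gen_static_cohort(ep.StaticCohortSpec(n_subjects=20, n_components=6, seed=2))
        assert not np.array_equal(a.edge_table.to_numpy(), b.edge_table.to_numpy())

    def test_edges_in_range(self, small_cohort):
        vals = small_cohort.edge_table.to_numpy()
        assert (np.abs(vals) <= 1.0).all()

    def test_marginal_base_structure(self, small_cohort):
        """Population edge means match the blocked base structure within 3 SE."""
        spec = small_cohort.truth["spec"]
        idx = EdgeIndex(spec.n_components)
        part = small_cohort.truth["spec"].partition or None
        means = small_cohort.edge_table.mean(axis=0).to_numpy()
        planted = set(small_cohort.truth["planted_edges"])
        # pool within-block vs between-block edges using the generator's default partition
        from edgeproject.synthetic import _block_partition

        part = _block_partition(spec.n_components, min(7, spec.n_components))
        for k in range(len(idx)):
            if k in planted:
                continue
            i, j = idx.pair_of(k)
            expected = spec.base_within if part[i] == part[j] else spec.base_between
            se = (1 - expected**2) / np.sqrt(spec.n_timepoints - 3) / np.sqrt(spec.n_subjects)
            assert abs(means[k] - expected) < max(3 * se, 0.02)

    def test_planted_partial_r_near_target(self, small_cohort):
        """The calibrated effect lands near the requested partial correlation."""
        res = ep.EdgewiseGLM(
            small_cohort.edge_table, small_cohort.outcome, small_cohort.covariates
        ).fit(alpha=1.0)
        for e, gamma in small_cohort.truth["planted_edges"].items():
            assert res.stats.iloc[e]["partial_r"] == pytest.approx(gamma, abs=0.12)

    def test_duplicate_planted_edges_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ep.StaticCohortSpec(planted_edges=((1, 0.1), (1, 0.2)))

    def test_unattainable_effect_rejected(self):
        spec = ep.StaticCohortSpec(n_subjects=10, n_components=6,
                                   planted_edges=((0, 0.9),), behavior_noise_sd=1.0, seed=0)
        with pytest.raises(ValueError, match="unattainable"):
            ep.gen_static_cohort(spec)


class TestDynamicGenerator:
    def test_determinism(self):
        spec = ep.DynamicCohortSpec(n_subjects=10, seed=9)
        a = ep.gen_dynamic_cohort(spec)
        b = ep.gen_dynamic_cohort(spec)
        for ta, tb in zip(a.timecourses, b.timecourses):
            assert np.array_equal(ta.data, tb.data)
        assert np.array_equal(a.symptom.to_numpy(), b.symptom.to_numpy())

    def test_true_ocr_equals_occupancy_of_true_labels(self, dynamic_cohort):
        truth = dynamic_cohort.truth
        labels = truth["true_window_labels"]
        k = truth["spec"].k_states
        recomputed = np.stack([ep.occupancy(v, k) for v in labels])
        assert np.array_equal(recomputed, truth["true_ocr"].to_numpy())

    def test_transition_matrix_stochastic_and_dwell(self, dynamic_cohort):
        P = dynamic_cohort.truth["transition_matrix"]
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.allclose(np.diag(P), 1 - 1 / dynamic_cohort.truth["spec"].mean_dwell)

    def test_invalid_transition_matrix_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            ep.DynamicCohortSpec(k_states=2, occupancy_coupling=(1.0, -1.0),
                                 transition_matrix=np.array([[0.5, 0.4], [0.1, 0.9]]))

    def test_coupling_length_checked(self):
        with pytest.raises(ValueError, match="one entry per state"):
            ep.DynamicCohortSpec(k_states=3, occupancy_coupling=(1.0, -1.0))

    def test_excessive_separation_rejected(self):
        with pytest.raises(ValueError, match="separation"):
            ep.gen_dynamic_cohort(ep.DynamicCohortSpec(n_subjects=2, separation=50.0, seed=0))

    def test_single_state_degenerate_case(self):
        """k_true = 1: clustering at k=2 splits noise into two occupied halves."""
        spec = ep.DynamicCohortSpec(n_subjects=10, k_states=1, occupancy_coupling=(0.0,), seed=3)
        coh = ep.gen_dynamic_cohort(spec)
        assert (coh.truth["true_ocr"].to_numpy() == 1.0).all()
        model = ep.DynamicStateModel(coh.timecourses, list(range(36)))
        res = model.fit(k=2, seed=3)
        occ = res.occupancy.mean()
        assert 0.2 < occ["OCR_1"] < 0.8  # meaningless near-even split, both states used

    def test_symptom_coupled_to_occupancy(self, dynamic_cohort):
        """Construction check: symptom correlates with the planted OCR combination."""
        truth = dynamic_cohort.truth
        b = np.asarray(truth["occupancy_coupling"])
        signal = truth["true_ocr"].to_numpy() @ b
        r = np.corrcoef(signal, dynamic_cohort.symptom.to_numpy())[0, 1]
        assert r > 0.5


class TestPairedCohorts:
    def test_shared_edges_must_be_planted_in_both(self):
        ref = ep.StaticCohortSpec(n_subjects=20, n_components=6, planted_edges=((1, 0.2),), seed=1)
        tgt = ep.StaticCohortSpec(n_subjects=20, n_components=6, covariate_style="target",
                                  planted_edges=((2, 0.2),), seed=2)
        with pytest.raises(ValueError, match="shared_edges"):
            ep.gen_two_cohorts(ref, tgt, shared_edges=[1])

    def test_target_style_enforced(self):
        ref = ep.StaticCohortSpec(n_subjects=20, n_components=6, planted_edges=((1, 0.2),), seed=1)
        tgt = ep.StaticCohortSpec(n_subjects=20, n_components=6, planted_edges=((1, 0.2),), seed=2)
        with pytest.raises(ValueError, match="covariate_style"):
            ep.gen_two_cohorts(ref, tgt)

    def test_transfer_truth_recorded(self):
        ref = ep.StaticCohortSpec(n_subjects=20, n_components=6,
                                  planted_edges=((1, 0.2), (3, 0.2)), seed=1)
        tgt = ep.StaticCohortSpec(n_subjects=20, n_components=6, covariate_style="target",
                                  planted_edges=((1, 0.2), (3, 0.0)), seed=2)
        _, _, truth = ep.gen_two_cohorts(ref, tgt)
        assert truth["shared_edges"] == [1, 3]
        assert truth["transferring_edges"] == [1]
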