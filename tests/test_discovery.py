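"""Discovery: FDR selection, permutation validation, bootstrap sensitivity."""

import numpy as np
import pandas as pd
import pytest

import edgeproject as ep


@pytest.fixture(scope="module")
def fitted(small_cohort):
    model = ep.EdgewiseGLM(small_cohort.edge_table, small_cohort.outcome, small_cohort.covariates)
    return model, model.fit(alpha=0.05)


class TestDiscover:
    def test_planted_edges_recovered(self, small_cohort, fitted):
        _, res = fitted
        planted = set(small_cohort.truth["planted_edges"])
        assert planted <= set(res.discovery.edges)

    def test_alpha_one_returns_all_edges(self, small_cohort):
        model = ep.EdgewiseGLM(small_cohort.edge_table, small_cohort.outcome, small_cohort.covariates)
        res = model.fit(alpha=1.0)
        assert len(res.discovery) == small_cohort.edge_table.shape[1]

    def test_q_at_least_p(self, fitted):
        _, res = fitted
        ok = ~res.stats["skipped"]
        assert (res.stats.loc[ok, "q"] >= res.stats.loc[ok, "p"] - 1e-15).all()

    def test_discovery_ordered_by_p(self, fitted):
        _, res = fitted
        p = res.stats["p"].to_numpy()[res.discovery.edges]
        assert (np.diff(p) >= 0).all()

    def test_discovery_set_round_trip(self, tmp_path, fitted):
        _, res = fitted
        path = tmp_path / "dset.json"
        res.discovery.to_json(path)
        back = ep.DiscoverySet.from_json(path)
        assert back.edges == res.discovery.edges
        assert back.covariate_terms == res.discovery.covariate_terms

    def test_empty_cohort_error(self, small_cohort):
        y = small_cohort.outcome.copy()
        y[:] = np.nan
        with pytest.raises(ValueError, match="zero subjects"):
            ep.EdgewiseGLM(small_cohort.edge_table, y, small_cohort.covariates)


class TestPermutation:
    def test_perfect_association_attains_min_p(self, small_cohort):
        # outcome equal to an edge: no permutation can beat the observed |t|
        edge = small_cohort.edge_table.iloc[:, 5]
        y = pd.Series(edge.to_numpy(), index=edge.index, name="y")
        model = ep.EdgewiseGLM(small_cohort.edge_table, y, small_cohort.covariates)
        res = model.fit(alpha=0.05)
        pp = res.permutation_validate(n_perm=200, seed=1, edges=[5])
        assert pp.iloc[0] == pytest.approx(1.0 / 201.0)

    def test_same_seed_bitwise_identical(self, fitted):
        _, res = fitted
        a = res.permutation_validate(n_perm=100, seed=42)
        b = res.permutation_validate(n_perm=100, seed=42)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_null_empirical_p_uniform(self):
        """For a noise edge the empirical p is ~uniform over seeded replicates."""
        rng = np.random.default_rng(17)
        n = 150
        cov = pd.DataFrame(
            {"age": rng.uniform(45, 85, n), "sex": rng.integers(0, 2, n).astype(float),
             "site": rng.choice(["a", "b"], n)},
            index=[f"S{i}" for i in range(n)],
        )
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            r2 = np.random.default_rng(1000 + rep)
            edges = pd.DataFrame(
                np.clip(r2.standard_normal((n, 3)) * 0.3, -1, 1), index=cov.index,
                columns=["e_1_2", "e_1_3", "e_2_3"],
            )
            y = pd.Series(r2.standard_normal(n), index=cov.index, name="y")
            res = ep.EdgewiseGLM(edges, y, cov).fit(alpha=1.0)
            pp = res.permutation_validate(n_perm=200, seed=rep, edges=[0])
            hits += pp.iloc[0] <= 0.05
        assert abs(hits / n_rep - 0.05) <= 0.05 + 0.03

    def test_seed_mandatory(self, fitted):
        _, res = fitted
        with pytest.raises(ValueError, match="seed"):
            res.permutation_validate(n_perm=10)


class TestBootstrap:
    def test_subsample_sizes(self):
        assert ep.bootstrap_subsample_size(14047, 0.70) == 9833
        assert ep.bootstrap_subsample_size(10, 0.70) == 7

    def test_planted_edge_selected_frequently(self, small_cohort, fitted):
        _, res = fitted
        freq = res.bootstrap_sensitivity(n_boot=60, seed=8)
        for e in small_cohort.truth["planted_edges"]:
            assert freq.iloc[e] >= 0.95

    def test_worker_count_invariance(self, fitted):
        _, res = fitted
        f1 = res.bootstrap_sensitivity(n_boot=20, seed=5, n_jobs=1)
        f2 = res.bootstrap_sensitivity(n_boot=20, seed=5, n_jobs=2)
        assert np.array_equal(f1.to_numpy(), f2.to_numpy())

    def test_subsample_below_rank_error(self, ref_pheno):
        cov, y = ref_pheno
        rng = np.random.default_rng(0)
        edges = pd.DataFrame(
            np.clip(rng.standard_normal((len(y), 3)) * 0.2, -1, 1), index=y.index,
            columns=["e_1_2", "e_1_3", "e_2_3"],
        )
        res = ep.EdgewiseGLM(edges, y, cov).fit()
        with pytest.raises(ValueError, match="subsample"):
            res.bootstrap_sensitivity(n_boot=5, frac=0.02, seed=1)


class TestGroupDiscover:
    def _cohort(self, shift, seed, n_per=250):
        rng = np.random.default_rng(seed)
        n = 2 * n_per
        cov = pd.DataFrame(
            {"age": rng.uniform(45, 85, n), "sex": rng.integers(0, 2, n).astype(float),
             "site": rng.choice(["a", "b"], n)},
            index=[f"S{i}" for i in range(n)],
        )
        g = pd.Series(np.repeat([0.0, 1.0], n_per), index=cov.index, name="group")
        vals = rng.standard_normal((n, 6)) * 0.2
        vals[:, 2] += shift * 0.2 * g.to_numpy()  # mean shift in sd units of the edge
        edges = pd.DataFrame(np.clip(vals, -1, 1), index=cov.index,
                             columns=[f"e_{i}_{j}" for i, j in [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]])
        return edges, g, cov

    def test_null_groups_behave_as_global_null(self):
        counts = []
        for seed in range(10):
            edges, g, cov = self._cohort(0.0, seed)
            dset, _ = ep.group_discover(edges, g, cov, alpha=0.05)
            counts.append(len(dset))
        assert np.mean(counts) <= 0.3

    def test_shifted_edge_recovered(self):
        hits = 0
        for seed in range(10):
            edges, g, cov = self._cohort(1.0, 100 + seed)
            dset, _ = ep.group_discover(edges, g, cov, alpha=0.05)
            hits += 2 in dset.edges
        assert hits == 10

    def test_single_group_error(self):
        edges, g, cov = self._cohort(0.0, 0)
        g[:] = 1.0
        with pytest.raises(ValueError, match="nonempty"):
            ep.group_discover(edges, g, cov)

    def test_non_binary_error(self):
        edges, g, cov = self._cohort(0.0, 0)
        with pytest.raises(ValueError, match="0,1|\\{0,1\\}"):
            ep.group_discover(edges, g + 1.0, cov)
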