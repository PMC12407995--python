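"""Dynamic connectivity: tapers, windows, clustering, occupancy, OCR GLMs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

import edgeproject as ep
from edgeproject.dfnc import kmeans_lloyd


def naive_taper(length, sigma):
    """Direct convolution oracle: explicit double loop, central samples."""
    half = int(np.ceil(3 * sigma))
    g = [np.exp(-(t**2) / (2 * sigma**2)) for t in range(-half, half + 1)]
    rect = [1.0] * length
    full = [0.0] * (length + 2 * half)
    for a, ra in enumerate(rect):
        for b, gb in enumerate(g):
            full[a + b] += ra * gb
    w = np.array(full[half : half + length])
    return w / w.sum()


def naive_weighted_corr(x, y, w):
    """Brute-force weighted-moment correlation (weights sum to 1)."""
    mx = float(np.sum(w * x))
    my = float(np.sum(w * y))
    cxy = float(np.sum(w * (x - mx) * (y - my)))
    vx = float(np.sum(w * (x - mx) ** 2))
    vy = float(np.sum(w * (y - my) ** 2))
    return cxy / np.sqrt(vx * vy)


class TestTaper:
    def test_symmetric_positive_normalized(self):
        w = ep.make_taper(20, 3.0)
        assert np.allclose(w, w[::-1], atol=1e-12)
        assert (w > 0).all() and w.sum() == pytest.approx(1.0)

    def test_sigma_zero_limit_is_uniform(self):
        assert np.allclose(ep.make_taper(20, 1e-6), np.full(20, 1 / 20))

    def test_matches_direct_convolution(self):
        for length, sigma in [(20, 3.0), (15, 2.0), (8, 5.0)]:
            assert np.allclose(ep.make_taper(length, sigma), naive_taper(length, sigma), atol=1e-12)

    def test_center_exceeds_edges(self):
        w = ep.make_taper(20, 3.0)
        assert w[10] > w[0] and 0 < w[0] / w[10] < 1

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            ep.make_taper(20, 0.0)


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "t, length, step, expected",
        [(229, 20, 1, 210), (20, 20, 1, 1), (25, 20, 5, 2)],
    )
    def test_window_counts(self, t, length, step, expected):
        starts = ep.sliding_windows(t, length, step)
        assert len(starts) == expected
        assert starts[0] == 0

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            ep.sliding_windows(10, 20)


class TestWeightedFC:
    def test_uniform_taper_reduces_to_pearson(self, rng):
        data = rng.standard_normal((60, 5))
        tc = ep.TimecourseMatrix("s", data)
        uniform = np.full(20, 1 / 20)
        v = ep.weighted_fc(tc, 10, uniform)
        ref = ep.vectorize(
            ep.pearson_fc(ep.TimecourseMatrix("s", data[10:30])), ep.EdgeIndex(5)
        )
        assert np.allclose(v, ref, atol=1e-12)

    def test_identical_columns_give_one(self, rng):
        col = rng.standard_normal(20)
        tc = ep.TimecourseMatrix("s", np.column_stack([col, col]))
        assert ep.weighted_fc(tc, 0, ep.make_taper(20, 3.0))[0] == pytest.approx(1.0)

    def test_matches_weighted_moment_oracle(self, rng):
        data = rng.standard_normal((20, 4))
        w = ep.make_taper(20, 3.0)
        v = ep.weighted_fc(ep.TimecourseMatrix("s", data), 0, w)
        idx = ep.EdgeIndex(4)
        for k in range(len(idx)):
            i, j = idx.pair_of(k)
            assert v[k] == pytest.approx(naive_weighted_corr(data[:, i], data[:, j], w), abs=1e-12)

    def test_tensor_matches_per_window(self, rng):
        data = rng.standard_normal((40, 4))
        tc = ep.TimecourseMatrix("s", data)
        w = ep.make_taper(20, 3.0)
        tensor = ep.dfnc_tensor(tc, w, step=1)
        for s in [0, 7, 20]:
            assert np.allclose(tensor[s], ep.weighted_fc(tc, s, w), atol=1e-12)

    def test_out_of_bounds(self, rng):
        tc = ep.TimecourseMatrix("s", rng.standard_normal((25, 3)))
        with pytest.raises(ValueError):
            ep.weighted_fc(tc, 10, ep.make_taper(20, 3.0))


class TestKMeans:
    def _blobs(self, rng, k=3, n=200, d=6, sep=10.0):
        centers = rng.standard_normal((k, d)) * sep
        labels = rng.integers(0, k, n)
        return centers[labels] + rng.standard_normal((n, d)), labels

    def test_separated_blobs_ari_one(self, rng):
        X, truth = self._blobs(rng)
        labels, _, _, _ = kmeans_lloyd(X, 3, seed=1)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k1_gives_global_mean_and_tss(self, rng):
        X = rng.standard_normal((50, 4))
        _, centroids, inertia, _ = kmeans_lloyd(X, 1, seed=2)
        assert np.allclose(centroids[0], X.mean(axis=0))
        assert inertia == pytest.approx(float(((X - X.mean(0)) ** 2).sum()))

    def test_same_seed_identical(self, rng):
        X, _ = self._blobs(rng)
        a = kmeans_lloyd(X, 3, seed=7)
        b = kmeans_lloyd(X, 3, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_inertia_trace_monotone(self, rng):
        X = rng.standard_normal((300, 5))  # unstructured: many Lloyd iterations
        _, _, _, trace = kmeans_lloyd(X, 4, n_init=3, seed=3)
        assert (np.diff(trace) <= 1e-9).all()

    def test_agrees_with_sklearn_on_separated_data(self, rng):
        X, _ = self._blobs(rng)
        ours = kmeans_lloyd(X, 3, seed=4)
        sk = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert adjusted_rand_score(sk.labels_, ours[0]) == 1.0
        assert ours[2] == pytest.approx(sk.inertia_, rel=1e-9)

    def test_k_exceeds_rows(self, rng):
        with pytest.raises(ValueError):
            kmeans_lloyd(rng.standard_normal((3, 2)), 5, seed=0)

    def test_seed_mandatory(self, rng):
        with pytest.raises(ValueError, match="seed"):
            kmeans_lloyd(rng.standard_normal((10, 2)), 2)


class TestElbow:
    def test_two_point_masses_select_two(self):
        X = np.repeat([[0.0, 0.0], [10.0, 10.0]], 20, axis=0)
        k, curve = ep.elbow_k(X, k_range=range(2, 6), seed=1)
        assert k == 2
        assert len(curve) == 4

    def test_curve_ratio_nonincreasing(self, rng):
        X = rng.standard_normal((150, 6))
        _, curve = ep.elbow_k(X, k_range=range(2, 8), seed=2)
        r = curve["ratio"].to_numpy()
        assert (np.diff(r) <= 0.05 * r[0]).all()

    def test_degenerate_data_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            ep.elbow_k(np.ones((30, 3)), seed=0)


class TestOccupancy:
    @pytest.mark.parametrize(
        "labels, k, expected",
        [
            ([1, 1, 2, 3], 3, (0.5, 0.25, 0.25)),
            ([2] * 8, 3, (0.0, 1.0, 0.0)),
            ([1] * 105 + [2] * 63 + [3] * 42, 3, (0.5, 0.3, 0.2)),
        ],
    )
    def test_counting(self, labels, k, expected):
        assert ep.occupancy(labels, k) == pytest.approx(expected)

    def test_rows_sum_to_one(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 6))
            v = rng.integers(1, k + 1, size=int(rng.integers(5, 50)))
            assert ep.occupancy(v, k).sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_and_out_of_range(self):
        with pytest.raises(ValueError):
            ep.occupancy([], 3)
        with pytest.raises(ValueError):
            ep.occupancy([0, 1], 3)


class TestOcrGLM:
    def _setup(self, rng, n=120):
        cov = pd.DataFrame(
            {"age": rng.uniform(18, 75, n), "sex": rng.integers(0, 2, n).astype(float),
             "site": rng.choice(["x", "y"], n)},
            index=[f"S{i}" for i in range(n)],
        )
        terms = ("age", "age2", "sex", "agexsex", "site")
        return cov, terms

    def test_k2_betas_antisymmetric(self, rng):
        cov, terms = self._setup(rng)
        o1 = rng.uniform(0.2, 0.8, len(cov))
        ocr = pd.DataFrame({"OCR_1": o1, "OCR_2": 1 - o1}, index=cov.index)
        y = pd.Series(rng.standard_normal(len(cov)), index=cov.index, name="sym")
        res = ep.ocr_glm(ocr, y, cov, terms=terms)
        b = res.set_index("state")["beta"]
        assert b[1] == pytest.approx(-b[2], abs=1e-10)

    def test_null_false_positive_rate(self, rng):
        cov, terms = self._setup(rng)
        fps, total = 0, 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            raw = r.dirichlet([2, 2, 2], len(cov))
            ocr = pd.DataFrame(raw, index=cov.index, columns=["OCR_1", "OCR_2", "OCR_3"])
            y = pd.Series(r.standard_normal(len(cov)), index=cov.index, name="sym")
            res = ep.ocr_glm(ocr, y, cov, terms=terms)
            fps += int(res["significant"].sum())
            total += len(res)
        assert fps / total <= 0.10

    def test_single_state_rejected(self, rng):
        cov, terms = self._setup(rng)
        ocr = pd.DataFrame({"OCR_1": np.ones(len(cov))}, index=cov.index)
        y = pd.Series(rng.standard_normal(len(cov)), index=cov.index)
        with pytest.raises(ValueError, match="compositional"):
            ep.ocr_glm(ocr, y, cov, terms=terms)


class TestDynamicStateModel:
    def test_fit_deterministic(self, dynamic_cohort):
        model = ep.DynamicStateModel(dynamic_cohort.timecourses, list(range(36)))
        a = model.fit(k=3, seed=5)
        b = model.fit(k=3, seed=5)
        assert a.state_vectors.equals(b.state_vectors)
        assert np.array_equal(a.state.centroids, b.state.centroids)

    def test_window_count_and_occupancy_conservation(self, dynamic_cohort):
        model = ep.DynamicStateModel(dynamic_cohort.timecourses, list(range(36)))
        assert model.n_windows == 210
        res = model.fit(k=3, seed=5)
        sums = res.occupancy.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert res.occupancy.shape[1] == 3

    def test_summary_mentions_states(self, dynamic_cohort):
        model = ep.DynamicStateModel(dynamic_cohort.timecourses, list(range(36)))
        res = model.fit(k=3, seed=5)
        assert "k=3" in res.summary()
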