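"""Dynamic functional connectivity: tapered windows, states, occupancy.

Connectivity is recomputed inside successive sliding windows (length 20
TRs, step 1 TR by default) whose samples are weighted by a taper — a
rectangle convolved with a Gaussian (sigma = 3 TRs) — yielding, per
subject, a windows x edges trajectory over a designated edge subset
(typically the union of edges discovered in the reference cohort).  A
229-timepoint scan then gives exactly 210 windows.

Pooled subject-window rows are clustered with seeded Lloyd k-means
(squared-Euclidean objective, best of ``n_init`` initializations); the
cluster number can be fixed or chosen by the elbow method over k = 2..9.
Each subject's window sequence of state assignments (the state vector)
is reduced to occupancy rates: OCR_i = windows in state i / total windows,
summing to 1 across states.  Occupancy rates are finally related to
symptom severity with the same single-regressor GLM used everywhere else
— one model per state's OCR, never all k together, since the OCRs are
compositional and sum to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TARGET_TERMS, EdgeIndex, build_design, drop_missing
from .stats import ResidualizedDesign, batch_edge_glm, bh_fdr

__all__ = [
    "make_taper",
    "sliding_windows",
    "weighted_fc",
    "dfnc_tensor",
    "kmeans_lloyd",
    "cluster_states",
    "elbow_k",
    "occupancy",
    "ocr_glm",
    "DynamicStateModel",
    "DynamicStateResults",
]


def make_taper(length: int = 20, sigma: float = 3.0) -> np.ndarray:
    """Tapered window weights: rectangle of ``length`` TRs convolved with a Gaussian.

    The discrete Gaussian kernel has support +-ceil(3 sigma); the central
    ``length`` samples of the convolution are kept ("same" alignment) and
    normalized to sum 1.  Weights are strictly positive and symmetric about
    the window center; as sigma -> 0 the taper tends to the uniform window.
    """
    if length < 2:
        raise ValueError("window length must be >= 2")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = int(math.ceil(3.0 * sigma))
    x = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    w = np.convolve(np.ones(length), g, mode="full")[half : half + length]
    return w / w.sum()


def sliding_windows(n_timepoints: int, length: int = 20, step: int = 1) -> np.ndarray:
    """0-based start indices of the half-open windows [s, s + length).

    Count is floor((T - length) / step) + 1; T = 229 with the default
    length 20 and step 1 gives 210 windows.
    """
    if length < 2 or step < 1:
        raise ValueError("need length >= 2 and step >= 1")
    if n_timepoints < length:
        raise ValueError(f"T={n_timepoints} is shorter than the window length {length}")
    return np.arange(0, n_timepoints - length + 1, step)


def _weighted_corr(window: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation matrix of one window (weights sum to 1)."""
    mu = weights @ window
    xc = window - mu
    cov = (xc * weights[:, None]).T @ xc
    var = np.diag(cov).copy()
    good = var > 0
    sd = np.sqrt(np.where(good, var, 1.0))
    r = cov / sd[:, None] / sd[None, :]
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    if not good.all():
        r[~good, :] = np.nan
        r[:, ~good] = np.nan
    return r


def weighted_fc(tc, start: int, taper: np.ndarray, edges=None) -> np.ndarray:
    """Taper-weighted Pearson correlations within one window of a subject.

    The taper enters as observation weights in the weighted means and
    covariances, so a uniform taper reduces exactly to the plain Pearson
    estimate on the window slice.  Zero weighted variance marks the
    affected edges NaN.  ``edges`` restricts the output to a flat-index
    subset (full upper triangle if None).
    """
    data = tc.data if hasattr(tc, "data") else np.asarray(tc, dtype=float)
    length = taper.size
    if start < 0 or start + length > data.shape[0]:
        raise ValueError("window out of bounds")
    r = _weighted_corr(data[start : start + length], np.asarray(taper, float))
    idx = EdgeIndex(data.shape[1])
    i, j = idx.pairs
    vec = r[i, j]
    if edges is not None:
        vec = vec[np.asarray(list(edges), dtype=int)]
    return vec


def dfnc_tensor(tc, taper: np.ndarray, step: int = 1, edges=None, fisher_z: bool = False) -> np.ndarray:
    """All windows of one subject at once: a W x E dynamic-connectivity array."""
    data = tc.data if hasattr(tc, "data") else np.asarray(tc, dtype=float)
    length = taper.size
    starts = sliding_windows(data.shape[0], length=length, step=step)
    w = np.asarray(taper, float)
    windows = np.lib.stride_tricks.sliding_window_view(data, length, axis=0)  # (T-L+1, C, L)
    windows = windows[starts].transpose(0, 2, 1)  # (W, L, C)
    mu = np.einsum("l,wlc->wc", w, windows)
    xc = windows - mu[:, None, :]
    cov = np.einsum("l,wli,wlj->wij", w, xc, xc)
    var = np.einsum("wii->wi", cov)
    good = var > 0
    sd = np.sqrt(np.where(good, var, 1.0))
    r = cov / sd[:, :, None] / sd[:, None, :]
    r = np.clip(r, -1.0, 1.0)
    if not good.all():
        bad = ~good
        r[np.broadcast_to(bad[:, :, None], r.shape)] = np.nan
        r[np.broadcast_to(bad[:, None, :], r.shape)] = np.nan
    idx = EdgeIndex(data.shape[1])
    i, j = idx.pairs
    out = r[:, i, j]
    if edges is not None:
        out = out[:, np.asarray(list(edges), dtype=int)]
    if fisher_z:
        out = np.arctanh(np.clip(out, -1 + 1e-15, 1 - 1e-15))
    return out


# ---------------------------------------------------------------------------
# k-means (seeded Lloyd's algorithm)
# ---------------------------------------------------------------------------


def _pairwise_sq(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    d2 = (X**2).sum(1)[:, None] - 2.0 * X @ C.T + (C**2).sum(1)[None, :]
    return np.maximum(d2, 0.0)


def _kmeans_once(X: np.ndarray, k: int, rng, max_iter: int):
    n = X.shape[0]
    # k-means++ seeding
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = _pairwise_sq(X, centroids[:1]).ravel()
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[c] = X[rng.integers(n)]
        else:
            centroids[c] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, _pairwise_sq(X, centroids[c : c + 1]).ravel())
    labels = np.full(n, -1, dtype=np.intp)
    trace = []
    for _ in range(max_iter):
        d2 = _pairwise_sq(X, centroids)
        new_labels = d2.argmin(axis=1)
        mind2 = d2[np.arange(n), new_labels]
        # empty-cluster rule: re-seed from the point farthest from its centroid
        for c in range(k):
            if not (new_labels == c).any():
                far = int(mind2.argmax())
                centroids[c] = X[far]
                new_labels[far] = c
                mind2[far] = -np.inf  # point consumed; never re-picked this iteration
        trace.append(float(np.maximum(mind2, 0.0).sum()))  # consumed points sit on their centroid
        if (new_labels == labels).all():
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = X[labels == c].mean(axis=0)
    return labels, centroids, trace[-1], trace


def kmeans_lloyd(X: np.ndarray, k: int, n_init: int = 10, max_iter: int = 1000, seed=None):
    """Best-of-``n_init`` seeded Lloyd k-means with squared-Euclidean objective.

    Deterministic given ``seed``.  Empty clusters are re-seeded from the
    point currently farthest from its centroid, so every run returns
    exactly k non-empty states.  Returns (labels, centroids, inertia,
    inertia_trace) of the lowest-inertia replicate; the trace is the
    after-assignment objective per Lloyd iteration and is nonincreasing.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (rows x features)")
    if k < 1 or k > X.shape[0]:
        raise ValueError(f"k={k} infeasible for {X.shape[0]} rows")
    if seed is None:
        raise ValueError("a seed is mandatory for clustering")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_init):
        rng = np.random.default_rng(child)
        labels, centroids, inertia, trace = _kmeans_once(X, k, rng, max_iter)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia, trace)
    return best


@dataclass
class StateModel:
    """k-means state solution over pooled subject-window rows."""

    k: int
    centroids: np.ndarray
    labels: np.ndarray  # pooled 1-based assignments
    inertia: float
    inertia_trace: list
    seed: int


def cluster_states(rows: np.ndarray, k: int, n_init: int = 10, max_iter: int = 1000, seed=None) -> StateModel:
    """Cluster pooled dynamic-connectivity rows into k transient states.

    Euclidean distance, Lloyd iterations capped at ``max_iter``, best of
    ``n_init`` seeded replicates.  State labels are 1-based.
    """
    labels, centroids, inertia, trace = kmeans_lloyd(rows, k, n_init=n_init, max_iter=max_iter, seed=seed)
    return StateModel(
        k=k,
        centroids=centroids,
        labels=labels + 1,
        inertia=inertia,
        inertia_trace=trace,
        seed=seed,
    )


def elbow_k(rows: np.ndarray, k_range=range(2, 10), seed=None, n_init: int = 10, max_iter: int = 300):
    """Elbow selection of the cluster number.

    For each candidate k the ratio r(k) = within-cluster dispersion /
    between-cluster dispersion is computed (within = k-means inertia,
    between = total sum of squares minus within).  If r at the smallest k
    is already ~0 the data are perfectly separated at that k and it is
    selected; otherwise the selected k maximizes the discrete curvature
    (second difference) of r over the interior of the range.  Returns
    (k_selected, curve DataFrame with columns k, within, between, ratio).
    """
    rows = np.asarray(rows, dtype=float)
    ks = sorted(int(k) for k in k_range)
    if len(ks) < 2:
        raise ValueError("k_range must contain at least two candidates")
    tss = float(((rows - rows.mean(axis=0)) ** 2).sum())
    if tss <= 0:
        raise ValueError("degenerate data: all rows identical")
    if seed is None:
        raise ValueError("a seed is mandatory for clustering")
    children = np.random.SeedSequence(seed).spawn(len(ks))
    within, ratio = [], []
    for k, child in zip(ks, children):
        _, _, inertia, _ = kmeans_lloyd(rows, k, n_init=n_init, max_iter=max_iter, seed=child)
        between = max(tss - inertia, 0.0)
        within.append(inertia)
        ratio.append(inertia / between if between > 0 else np.inf)
    curve = pd.DataFrame({"k": ks, "within": within, "between": [tss - w for w in within], "ratio": ratio})
    r = np.asarray(ratio)
    if r[0] <= 1e-12:
        k_sel = ks[0]
    else:
        curvature = r[:-2] - 2.0 * r[1:-1] + r[2:]
        k_sel = ks[1 + int(curvature.argmax())]
    return k_sel, curve


def occupancy(state_vector, k: int) -> np.ndarray:
    """Occupancy rates OCR_1..OCR_k of one subject's state vector.

    OCR_i = (windows assigned to state i) / (total windows); labels are
    1-based and the k rates sum to 1.
    """
    v = np.asarray(state_vector, dtype=int)
    if v.size == 0:
        raise ValueError("empty state vector")
    if v.min() < 1 or v.max() > k:
        raise ValueError(f"state labels must lie in [1..{k}]")
    return np.bincount(v - 1, minlength=k) / float(v.size)


def ocr_glm(ocr_table: pd.DataFrame, symptoms, covariates, terms=TARGET_TERMS, alpha: float = 0.05) -> pd.DataFrame:
    """Relate each state's occupancy rate to symptom severity.

    One GLM per (state, symptom): symptom ~ covariates + OCR_i.  The OCRs
    are compositional (they sum to 1), so each is modeled in a separate
    regression — never all k together with an intercept.  BH-FDR is applied
    across the full k x symptoms family.  Needs k >= 2.
    """
    if ocr_table.shape[1] < 2:
        raise ValueError("OCRs are compositional; need k >= 2 states")
    if isinstance(symptoms, pd.Series):
        symptoms = symptoms.to_frame()
    frames = []
    for symptom in symptoms.columns:
        y, cov, _ = drop_missing(symptoms[symptom], covariates, terms)
        X = build_design(cov, terms)
        rd = ResidualizedDesign.from_design(X.to_numpy())
        O = ocr_table.loc[y.index].to_numpy()
        st = batch_edge_glm(O, y.to_numpy(), rd)
        st.index = ocr_table.columns
        st.insert(0, "state", np.arange(1, ocr_table.shape[1] + 1))
        st.insert(0, "symptom", symptom)
        frames.append(st)
    table = pd.concat(frames)
    valid = ~table["skipped"]
    q = np.full(len(table), np.nan)
    q[valid.to_numpy()] = bh_fdr(table.loc[valid, "p"].to_numpy())
    table["q"] = q
    table["significant"] = valid & (table["q"] <= alpha)
    return table


class DynamicStateModel:
    """Dynamic-connectivity state analysis over a cohort of time courses.

    Parameters
    ----------
    timecourses : sequence of TimecourseMatrix
        One per subject; all must share T and C.
    edge_subset : sequence of int
        Flat edge indices to carry through the windowed analysis (e.g. the
        union of discovered edges for a behavioral domain).
    window_length, sigma, step : taper and stride settings (defaults 20, 3, 1).
    fisher_z : apply arctanh to windowed correlations before clustering.
    """

    def __init__(self, timecourses, edge_subset, window_length: int = 20, sigma: float = 3.0, step: int = 1, fisher_z: bool = False):
        self.timecourses = list(timecourses)
        if not self.timecourses:
            raise ValueError("no subjects")
        self.edge_subset = [int(e) for e in edge_subset]
        if not self.edge_subset:
            raise ValueError("empty edge subset")
        self.taper = make_taper(window_length, sigma)
        self.step = step
        self.window_length = window_length
        self.sigma = sigma
        self.fisher_z = fisher_z
        t0 = self.timecourses[0].n_timepoints
        self.starts = sliding_windows(t0, length=window_length, step=step)
        self.subject_ids = [tc.subject_id for tc in self.timecourses]
        tensors = []
        for tc in self.timecourses:
            if tc.n_timepoints != t0:
                raise ValueError("all subjects must share the same number of timepoints")
            tensors.append(dfnc_tensor(tc, self.taper, step=step, edges=self.edge_subset, fisher_z=fisher_z))
        self.tensors = np.asarray(tensors)  # (n_subjects, W, E)

    @property
    def n_windows(self) -> int:
        return self.starts.size

    def fit(self, k=None, k_range=range(2, 10), n_init: int = 10, max_iter: int = 1000, seed=None) -> "DynamicStateResults":
        """Cluster pooled windows into states; ``k=None`` selects k by elbow."""
        if seed is None:
            raise ValueError("a seed is mandatory")
        rows = self.tensors.reshape(-1, self.tensors.shape[2])
        ss = np.random.SeedSequence(seed)
        elbow_seed, cluster_seed = ss.spawn(2)
        curve = None
        if k is None:
            k, curve = elbow_k(rows, k_range=k_range, seed=elbow_seed, n_init=n_init)
        state = cluster_states(rows, int(k), n_init=n_init, max_iter=max_iter, seed=cluster_seed)
        return DynamicStateResults(self, state, elbow_curve=curve, seed=seed)


class DynamicStateResults:
    """Fitted state solution: centroids, state vectors, occupancy, OCR models."""

    def __init__(self, model: DynamicStateModel, state: StateModel, elbow_curve=None, seed=None):
        self.model = model
        self.state = state
        self.elbow_curve = elbow_curve
        self.seed = seed
        n, w = model.tensors.shape[:2]
        self.state_vectors = pd.DataFrame(
            state.labels.reshape(n, w), index=model.subject_ids,
            columns=[f"w{j}" for j in range(w)],
        )
        occ = np.stack([occupancy(v, state.k) for v in self.state_vectors.to_numpy()])
        self.occupancy = pd.DataFrame(
            occ, index=model.subject_ids, columns=[f"OCR_{i}" for i in range(1, state.k + 1)]
        )
        self.occupancy.index.name = "subject_id"

    @property
    def k(self) -> int:
        return self.state.k

    def ocr_association(self, symptoms, covariates, terms=TARGET_TERMS, alpha: float = 0.05) -> pd.DataFrame:
        """GLMs of symptom severity on each state's occupancy rate."""
        return ocr_glm(self.occupancy, symptoms, covariates, terms=terms, alpha=alpha)

    def summary(self) -> str:
        occ_mean = self.occupancy.mean()
        lines = [
            "Dynamic connectivity states",
            "=" * 55,
            f"subjects:       {len(self.model.subject_ids)}",
            f"windows/subj:   {self.model.n_windows} "
            f"(length {self.model.window_length} TR, sigma {self.model.sigma}, step {self.model.step})",
            f"edge subset:    {len(self.model.edge_subset)} edges",
            f"states:         k={self.k}" + ("" if self.elbow_curve is None else " (elbow-selected)"),
            f"inertia:        {self.state.inertia:.6g}",
            "mean occupancy: " + ", ".join(f"{c}={occ_mean[c]:.3f}" for c in self.occupancy.columns),
        ]
        return "\n".join(lines)

    def plot_elbow(self, ax=None):
        """Elbow curve (within/between dispersion ratio vs k)."""
        if self.elbow_curve is None:
            raise ValueError("model was fitted with a fixed k; no elbow curve")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.elbow_curve["k"], self.elbow_curve["ratio"], marker="o")
        ax.axvline(self.k, ls="--", color="gray")
        ax.set_xlabel("k")
        ax.set_ylabel("within / between dispersion")
        return ax

    def plot_occupancy(self, ax=None):
        """Distribution of per-subject occupancy rates by state."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.boxplot([self.occupancy[c] for c in self.occupancy.columns], tick_labels=list(self.occupancy.columns))
        ax.set_ylabel("occupancy rate")
        return ax
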