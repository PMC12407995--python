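"""Synthetic multi-subject cohorts with known ground truth.

Two generative families mirror the statistical structure the analyses
assume, so every pipeline stage is testable without access-restricted data:

* **Static cohorts** — per subject, a latent C x C correlation matrix is
  built from a network-blocked base structure plus a behavior-coupled
  perturbation on a set of planted edges (plus optional covariate effects),
  a T x C Gaussian time series is sampled from it, and the *empirical*
  correlations are emitted.  Discovery therefore runs on realistically
  noisy sampled correlations, not on the latent truth.
* **Dynamic cohorts** — per subject, a hidden Markov chain switches the
  covariance of the time series among k latent states (single-factor
  sign-pattern covariances), and a symptom score is linearly coupled to the
  subject's true state occupancies.

Effect sizes are standardized: a planted static effect of 0.15 means the
population partial correlation between the empirical edge value and the
outcome, given covariates, is 0.15.  The generator calibrates the latent
slope analytically using the large-sample standard deviation of a
T-sample correlation, sd(r) ~ (1 - rho^2) / sqrt(T - 3).

Everything is deterministic given the spec's seed, and each generator
returns a :class:`SyntheticTruth`-style record sufficient to recompute the
cohort and to score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dfnc import make_taper, occupancy, sliding_windows
from .fc import vectorize
from .io import EdgeIndex, NetworkPartition, TimecourseMatrix, edge_columns

__all__ = [
    "StaticCohortSpec",
    "DynamicCohortSpec",
    "StaticCohort",
    "DynamicCohort",
    "gen_static_cohort",
    "gen_dynamic_cohort",
    "gen_two_cohorts",
]

_CHUNK = 256  # subjects per sampling chunk (bounds peak memory)


def _block_partition(n_components: int, n_blocks: int) -> NetworkPartition:
    """Even contiguous block partition used when none is supplied."""
    sizes = np.full(n_blocks, n_components // n_blocks)
    sizes[: n_components % n_blocks] += 1
    labels, cid = {}, 0
    for b, s in enumerate(sizes):
        for _ in range(s):
            labels[cid] = f"N{b + 1}"
            cid += 1
    return NetworkPartition(labels)


@dataclass
class StaticCohortSpec:
    """Conditions for a static (cross-subject) cohort.

    Defaults emulate the reference-cohort regime at desk scale: 53
    components, 229 timepoints, ages 45-85, three collection sites.  The
    target-cohort style (``covariate_style='target'``) switches to ages
    18-75 and adds income, education and trauma-type covariates.
    """

    n_subjects: int = 2000
    n_components: int = 53
    n_timepoints: int = 229
    planted_edges: tuple = ()  # ((flat edge, standardized effect), ...)
    covariate_style: str = "reference"
    base_within: float = 0.30
    base_between: float = 0.10
    behavior_noise_sd: float = 1.0
    edge_age_slope: float = 0.001  # latent correlation change per centered year, planted edges
    seed: int = 0
    partition: NetworkPartition | None = None
    tr_seconds: float = 2.36

    def __post_init__(self):
        edges = [int(e) for e, _ in self.planted_edges]
        if len(set(edges)) != len(edges):
            raise ValueError("planted edges must be distinct")
        if not all(np.isfinite(g) for _, g in self.planted_edges):
            raise ValueError("planted effect sizes must be finite")


@dataclass
class StaticCohort:
    edge_table: pd.DataFrame
    covariates: pd.DataFrame
    outcome: pd.Series
    truth: dict


def _gen_covariates(rng, n: int, style: str) -> pd.DataFrame:
    if style == "reference":
        age = rng.uniform(45.0, 85.0, n)
        site = rng.choice(["siteA", "siteB", "siteC"], size=n, p=[0.40, 0.35, 0.25])
        extra = {}
    elif style == "target":
        age = rng.uniform(18.0, 75.0, n)
        site = rng.choice(["ed1", "ed2", "ed3", "ed4"], size=n, p=[0.30, 0.30, 0.25, 0.15])
        extra = {
            "income": rng.integers(1, 6, n).astype(float),
            "education_years": np.clip(rng.normal(14.0, 2.5, n), 8.0, 22.0),
            "trauma_type": rng.choice(
                ["assault", "fall", "mvc", "other"], size=n, p=[0.15, 0.10, 0.60, 0.15]
            ),
        }
    else:
        raise ValueError(f"unknown covariate_style {style!r}")
    sex = rng.integers(0, 2, n).astype(float)
    cov = pd.DataFrame({"age": age, "sex": sex, "site": site, **extra})
    cov.index = [f"S{i:05d}" for i in range(n)]
    cov.index.name = "subject_id"
    return cov


def _behavior_covariate_effects(cov: pd.DataFrame) -> np.ndarray:
    """Fixed, modest covariate contributions to the behavior score."""
    age_c = cov["age"].to_numpy() - cov["age"].to_numpy().mean()
    y = 0.02 * age_c + 0.20 * cov["sex"].to_numpy()
    site_codes = pd.Categorical(cov["site"]).codes
    y = y + 0.10 * (site_codes - site_codes.mean())
    if "income" in cov.columns:
        y = y - 0.05 * (cov["income"].to_numpy() - 3.0)
    if "education_years" in cov.columns:
        y = y - 0.02 * (cov["education_years"].to_numpy() - 14.0)
    if "trauma_type" in cov.columns:
        tt = pd.Categorical(cov["trauma_type"]).codes
        y = y + 0.10 * (tt - tt.mean())
    return y


def _base_correlation(spec: StaticCohortSpec, partition: NetworkPartition) -> np.ndarray:
    c = spec.n_components
    nets = np.array([partition[i] for i in range(c)])
    same = nets[:, None] == nets[None, :]
    base = np.where(same, spec.base_within, spec.base_between)
    np.fill_diagonal(base, 1.0)
    return base


def _repair_correlation(mat: np.ndarray) -> np.ndarray:
    """Nearest-PD repair: clip eigenvalues, renormalize to unit diagonal."""
    w, v = np.linalg.eigh(mat)
    w = np.maximum(w, 1e-4)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / d[:, None] / d[None, :]
    np.fill_diagonal(fixed, 1.0)
    return fixed


def gen_static_cohort(spec: StaticCohortSpec, outcome_name: str = "behavior") -> StaticCohort:
    """Generate an EdgeTable + covariates + outcome with recorded truth.

    Per subject the latent correlation matrix is the blocked base structure
    plus ``beta_e * u_s`` on each planted edge (u_s the subject's latent
    behavior signal) plus a linear age effect on those edges; a T x C
    Gaussian series is sampled from it and empirical correlations are
    returned.  Matrices pushed out of the positive-definite cone are
    repaired by eigenvalue clipping (logged in the truth record).
    """
    rng = np.random.default_rng(spec.seed)
    n, c, t = spec.n_subjects, spec.n_components, spec.n_timepoints
    idx = EdgeIndex(c)
    partition = spec.partition or _block_partition(c, min(7, c))
    if partition.n_components != c:
        raise ValueError("partition does not match n_components")
    base = _base_correlation(spec, partition)

    cov = _gen_covariates(rng, n, spec.covariate_style)
    u = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    y = _behavior_covariate_effects(cov) + u + spec.behavior_noise_sd * eps
    outcome = pd.Series(y, index=cov.index, name=outcome_name)

    # calibrate latent slopes so the empirical-edge partial correlation hits
    # the requested standardized effect
    slopes = {}
    noise_var = 1.0 + spec.behavior_noise_sd**2
    for e, gamma in spec.planted_edges:
        i, j = idx.pair_of(int(e))
        rho0 = base[i, j]
        sigma_t = (1.0 - rho0**2) / np.sqrt(t - 3.0)
        a2 = gamma**2 * noise_var
        if a2 >= 1.0:
            raise ValueError(f"effect {gamma} unattainable with behavior noise sd {spec.behavior_noise_sd}")
        slopes[int(e)] = float(np.sign(gamma) * sigma_t * np.sqrt(a2 / (1.0 - a2)))

    age_c = cov["age"].to_numpy() - cov["age"].to_numpy().mean()
    edge_vals = np.empty((n, len(idx)))
    n_repaired = 0
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        m = hi - lo
        mats = np.broadcast_to(base, (m, c, c)).copy()
        for e, b in slopes.items():
            i, j = idx.pair_of(e)
            val = base[i, j] + b * u[lo:hi] + spec.edge_age_slope * age_c[lo:hi]
            val = np.clip(val, -0.99, 0.99)
            mats[:, i, j] = val
            mats[:, j, i] = val
        try:
            L = np.linalg.cholesky(mats)
        except np.linalg.LinAlgError:
            for s in range(m):
                try:
                    np.linalg.cholesky(mats[s])
                except np.linalg.LinAlgError:
                    mats[s] = _repair_correlation(mats[s])
                    n_repaired += 1
            L = np.linalg.cholesky(mats)
        z = rng.standard_normal((m, t, c))
        x = np.einsum("stk,sjk->stj", z, L)
        xc = x - x.mean(axis=1, keepdims=True)
        norms = np.sqrt((xc**2).sum(axis=1))
        xn = xc / norms[:, None, :]
        r = np.einsum("sti,stj->sij", xn, xn)
        ii, jj = idx.pairs
        edge_vals[lo:hi] = np.clip(r[:, ii, jj], -1.0, 1.0)

    edge_table = pd.DataFrame(edge_vals, index=cov.index, columns=edge_columns(idx))
    truth = {
        "planted_edges": {int(e): float(g) for e, g in spec.planted_edges},
        "latent_slopes": slopes,
        "latent_signal": u,
        "behavior": y,
        "n_repaired": n_repaired,
        "base_within": spec.base_within,
        "base_between": spec.base_between,
        "seed": spec.seed,
        "spec": spec,
    }
    return StaticCohort(edge_table=edge_table, covariates=cov, outcome=outcome, truth=truth)


# ---------------------------------------------------------------------------
# Dynamic (state-switching) cohorts
# ---------------------------------------------------------------------------


@dataclass
class DynamicCohortSpec:
    """Conditions for a covariance regime-switching cohort.

    Each state is a single-factor correlation pattern: component i carries a
    sign s_i in {-1, +1} and loading a, giving pairwise correlations
    a^2 * s_i * s_j.  State 1 is all-positive; state m > 1 flips the m-th
    contiguous component block, so every pair of states disagrees (by
    2 a^2) on a large fraction of edges.  ``separation`` fixes the per-edge
    contrast between states in units of the windowed-correlation noise sd,
    which the generator computes from the taper; the default 5 puts the
    analysis in the well-separated regime.

    ``occupancy_coupling`` b gives symptom = intercept + covariate effects +
    sum_i b_i * trueOCR_i + noise; the default (0, +10, -10) plants opposing
    clinical valence for states 2 and 3.
    """

    n_subjects: int = 306
    n_components: int = 9
    n_timepoints: int = 229
    k_states: int = 3
    separation: float = 5.0
    mean_dwell: float = 30.0  # TRs
    transition_matrix: np.ndarray | None = None
    symptom_intercept: float = 20.0
    occupancy_coupling: tuple = (0.0, 10.0, -10.0)
    symptom_noise_sd: float = 1.0
    window_length: int = 20
    window_sigma: float = 3.0
    tr_seconds: float = 2.36
    seed: int = 0

    def __post_init__(self):
        if self.k_states < 1:
            raise ValueError("need k_states >= 1")
        if len(self.occupancy_coupling) != self.k_states:
            raise ValueError("occupancy_coupling must have one entry per state")
        if self.transition_matrix is not None:
            P = np.asarray(self.transition_matrix, dtype=float)
            if P.shape != (self.k_states, self.k_states) or (P < 0).any() or not np.allclose(
                P.sum(axis=1), 1.0, atol=1e-10
            ):
                raise ValueError("transition matrix must be row-stochastic k x k")


@dataclass
class DynamicCohort:
    timecourses: list
    covariates: pd.DataFrame
    symptom: pd.Series
    truth: dict


def _state_sign_vectors(c: int, k: int) -> np.ndarray:
    sizes = np.full(k, c // k)
    sizes[: c % k] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    signs = np.ones((k, c))
    for m in range(1, k):
        signs[m, bounds[m] : bounds[m + 1]] = -1.0
    return signs


def _transition_matrix(k: int, mean_dwell: float) -> np.ndarray:
    if k == 1:
        return np.ones((1, 1))
    stay = 1.0 - 1.0 / mean_dwell
    P = np.full((k, k), (1.0 - stay) / (k - 1))
    np.fill_diagonal(P, stay)
    return P


def windowed_noise_sd(window_length: int = 20, sigma: float = 3.0) -> float:
    """Sampling sd of a taper-weighted window correlation near rho = 0.

    Uses the Kish effective sample size of the taper weights,
    n_eff = 1 / sum(w^2), in the large-sample correlation formula.
    """
    w = make_taper(window_length, sigma)
    n_eff = 1.0 / float((w**2).sum())
    return 1.0 / np.sqrt(max(n_eff - 3.0, 1.0))


def gen_dynamic_cohort(spec: DynamicCohortSpec, symptom_name: str = "symptom") -> DynamicCohort:
    """Generate Markov state-switching time courses with OCR-coupled symptoms.

    Truth records, per subject: the TR-resolution state sequence, the
    window-level majority state labels (ties broken toward the lower state
    index), and the true occupancy rates computed from those labels with
    the same :func:`edgeproject.dfnc.occupancy` the analysis uses.
    """
    rng = np.random.default_rng(spec.seed)
    n, c, t, k = spec.n_subjects, spec.n_components, spec.n_timepoints, spec.k_states

    sigma_w = windowed_noise_sd(spec.window_length, spec.window_sigma)
    a2 = spec.separation * sigma_w / 2.0
    if a2 >= 0.95:
        raise ValueError(
            f"separation {spec.separation} needs per-edge contrast {2 * a2:.2f} > attainable range"
        )
    a = np.sqrt(a2)
    signs = _state_sign_vectors(c, k)
    P = (
        np.asarray(spec.transition_matrix, dtype=float)
        if spec.transition_matrix is not None
        else _transition_matrix(k, spec.mean_dwell)
    )

    # Markov state sequences, all subjects advanced together one TR at a time
    states = np.empty((n, t), dtype=np.intp)
    states[:, 0] = rng.integers(0, k, n)
    cum = np.cumsum(P, axis=1)
    for step in range(1, t):
        u = rng.random(n)
        states[:, step] = (u[:, None] > cum[states[:, step - 1]]).sum(axis=1)

    # single-factor sampling: x_t = a * s_state * f_t + sqrt(1-a^2) * eps_t
    f = rng.standard_normal((n, t))
    eps = rng.standard_normal((n, t, c))
    x = a * signs[states] * f[:, :, None] + np.sqrt(1.0 - a2) * eps

    cov = _gen_covariates(rng, n, "target")
    timecourses = [
        TimecourseMatrix(subject_id=sid, data=x[s], tr_seconds=spec.tr_seconds)
        for s, sid in enumerate(cov.index)
    ]

    # window-level majority truth labels via one-hot cumulative counts
    starts = sliding_windows(t, length=spec.window_length, step=1)
    onehot = np.zeros((n, t + 1, k))
    np.put_along_axis(onehot[:, 1:, :], states[:, :, None], 1.0, axis=2)
    cs = np.cumsum(onehot, axis=1)
    counts = cs[:, starts + spec.window_length, :] - cs[:, starts, :]  # (n, W, k)
    true_window_labels = counts.argmax(axis=2) + 1  # ties -> lower state index
    true_ocr = np.stack([occupancy(v, k) for v in true_window_labels])
    ocr_table = pd.DataFrame(true_ocr, index=cov.index, columns=[f"OCR_{i}" for i in range(1, k + 1)])

    b = np.asarray(spec.occupancy_coupling, dtype=float)
    symptom = (
        spec.symptom_intercept
        + _behavior_covariate_effects(cov)
        + true_ocr @ b
        + spec.symptom_noise_sd * rng.standard_normal(n)
    )
    symptom = pd.Series(symptom, index=cov.index, name=symptom_name)

    idx = EdgeIndex(c)
    centroids = np.stack([vectorize(a2 * np.outer(s, s) + (1 - a2) * np.eye(c), idx) for s in signs])
    dists = [
        float(np.linalg.norm(centroids[p] - centroids[q]))
        for p in range(k)
        for q in range(p + 1, k)
    ]
    truth = {
        "state_signs": signs,
        "state_centroids": centroids,
        "loading": float(a),
        "per_edge_contrast": float(2 * a2),
        "windowed_noise_sd": float(sigma_w),
        "min_centroid_distance": min(dists) if dists else 0.0,
        "transition_matrix": P,
        "state_sequences": states + 1,
        "true_window_labels": true_window_labels,
        "true_ocr": ocr_table,
        "occupancy_coupling": tuple(b.tolist()),
        "seed": spec.seed,
        "spec": spec,
    }
    return DynamicCohort(timecourses=timecourses, covariates=cov, symptom=symptom, truth=truth)


def gen_two_cohorts(ref_spec: StaticCohortSpec, target_spec: StaticCohortSpec, shared_edges=None):
    """Paired reference + target static cohorts for the discover-then-project path.

    ``shared_edges`` (default: every edge planted in both specs) must be a
    subset of both planted sets; effects are independently settable per
    cohort.  The combined truth records which reference-planted edges truly
    transfer (nonzero target effect).
    """
    ref_edges = {int(e) for e, _ in ref_spec.planted_edges}
    tgt_edges = {int(e): g for e, g in target_spec.planted_edges}
    if shared_edges is None:
        shared_edges = sorted(ref_edges & set(tgt_edges))
    shared_edges = [int(e) for e in shared_edges]
    if not set(shared_edges) <= ref_edges or not set(shared_edges) <= set(tgt_edges):
        raise ValueError("shared_edges must be planted in both cohorts")
    if target_spec.covariate_style != "target":
        raise ValueError("target cohort must use covariate_style='target'")
    ref = gen_static_cohort(ref_spec)
    target = gen_static_cohort(target_spec, outcome_name="symptom")
    truth = {
        "reference": ref.truth,
        "target": target.truth,
        "shared_edges": shared_edges,
        "transferring_edges": sorted(e for e in shared_edges if tgt_edges.get(e, 0.0) != 0.0),
    }
    return ref, target, truth
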