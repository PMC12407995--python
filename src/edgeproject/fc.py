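"""Static functional network connectivity.

Per subject, connectivity is the Pearson correlation between every pair of
component time courses, giving a symmetric C x C matrix with unit diagonal
that is vectorized to C(C-1)/2 edge features (1,378 for C = 53).  A helper
summarizes which functional networks an edge set concentrates in.

Correlations are used raw by default; pass ``fisher_z=True`` where offered
to apply the arctanh variance-stabilizing transform instead (a common
alternative convention in connectivity pipelines).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import EdgeIndex, NetworkPartition, TimecourseMatrix, edge_columns

__all__ = [
    "pearson_fc",
    "vectorize",
    "edge_table_from_timecourses",
    "network_contribution",
    "edge_sign_labels",
]


def pearson_fc(tc: TimecourseMatrix) -> np.ndarray:
    """Pearson correlation matrix of a subject's component time courses.

    Returns the C x C symmetric matrix with unit diagonal.  Rows/columns of
    constant (zero-variance) components are set to NaN — an explicit
    undefined marker, never silently zero — and are also listed on
    ``tc.degenerate_columns``.
    """
    x = tc.data
    if x.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for a correlation estimate")
    xc = x - x.mean(axis=0)
    norms = np.sqrt((xc**2).sum(axis=0))
    good = norms > 0
    safe = np.where(good, norms, 1.0)
    r = (xc / safe).T @ (xc / safe)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    if not good.all():
        r[~good, :] = np.nan
        r[:, ~good] = np.nan
    return r


def vectorize(fc: np.ndarray, idx: EdgeIndex) -> np.ndarray:
    """Upper-triangle edge vector of a C x C connectivity matrix.

    Entry k is the correlation at ``idx.pair_of(k)``; length C(C-1)/2.
    """
    fc = np.asarray(fc)
    if fc.shape != (idx.n_components, idx.n_components):
        raise ValueError(
            f"matrix shape {fc.shape} does not match EdgeIndex with C={idx.n_components}"
        )
    i, j = idx.pairs
    return fc[i, j]


def edge_table_from_timecourses(
    timecourses, idx: EdgeIndex | None = None, fisher_z: bool = False
) -> pd.DataFrame:
    """Stack per-subject edge vectors into a subjects x edges DataFrame."""
    timecourses = list(timecourses)
    if not timecourses:
        raise ValueError("no subjects")
    c = timecourses[0].n_components
    if idx is None:
        idx = EdgeIndex(c)
    rows = {}
    for tc in timecourses:
        v = vectorize(pearson_fc(tc), idx)
        if fisher_z:
            v = np.arctanh(np.clip(v, -1 + 1e-15, 1 - 1e-15))
        rows[tc.subject_id] = v
    table = pd.DataFrame.from_dict(rows, orient="index", columns=edge_columns(idx))
    table.index.name = "subject_id"
    return table


def network_contribution(
    edges, idx: EdgeIndex, partition: NetworkPartition, mode: str = "endpoints"
) -> pd.Series:
    """Percentage contribution of each functional network to an edge set.

    ``mode='endpoints'`` (default): each edge contributes its two endpoint
    components, and a network's percentage is its share of the 2 x |edges|
    endpoint incidences — percentages sum to 100 across networks.
    ``mode='touching'``: percentage of edges with at least one endpoint in
    the network (can exceed 100 in total).
    """
    edges = sorted(set(int(e) for e in edges))
    if not edges:
        raise ValueError("empty edge set: percentages undefined")
    networks = partition.networks
    counts = {net: 0 for net in networks}
    for e in edges:
        i, j = idx.pair_of(e)
        if mode == "endpoints":
            counts[partition[i]] += 1
            counts[partition[j]] += 1
        elif mode == "touching":
            for net in {partition[i], partition[j]}:
                counts[net] += 1
        else:
            raise ValueError(f"unknown mode {mode!r}")
    denom = 2 * len(edges) if mode == "endpoints" else len(edges)
    out = pd.Series({net: 100.0 * counts[net] / denom for net in networks}, name="percent")
    out.index.name = "network"
    return out


def edge_sign_labels(stats: pd.DataFrame) -> pd.Series:
    """Association-direction label per edge from its GLM coefficient.

    Positive beta -> ``positive-association`` (e.g. connections tracking
    longer reaction times / higher symptom burden), negative beta ->
    ``negative-association``, exactly zero -> ``null``.
    """
    if "beta" not in stats.columns:
        raise ValueError("stats table must contain a 'beta' column")
    sign = np.sign(stats["beta"].to_numpy(dtype=float))
    labels = np.where(sign > 0, "positive-association", np.where(sign < 0, "negative-association", "null"))
    return pd.Series(labels, index=stats.index, name="sign_label")
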