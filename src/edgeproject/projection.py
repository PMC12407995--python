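"""Constrained out-of-sample projection of a discovered edge set.

The second stage of discover-then-project: an edge set found in the
reference cohort is tested — and only that set — against symptom measures
in an independent target cohort with its own covariates (age, sex, age^2,
age x sex, income, years of education, site, trauma type by default).
Restricting the FDR family to the |DiscoverySet| pre-registered edges is
what buys sensitivity: the multiple-testing burden is m tests per symptom
instead of the full edge family.

Per-symptom families are adjusted separately (stress, anxiety and
depression scales each get their own BH correction); a pooled family across
symptoms is available via ``pooled=True``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fc import edge_sign_labels
from .io import TARGET_TERMS, EdgeIndex, build_design, drop_missing
from .stats import ResidualizedDesign, batch_edge_glm, bh_fdr
from .discovery import DiscoverySet

__all__ = ["ConstrainedProjection", "ProjectionResults", "project", "projection_report"]


class ConstrainedProjection:
    """Model: target-cohort symptom ~ target covariates + each discovered edge.

    Parameters
    ----------
    edge_table : DataFrame, subjects x edges
        Target-cohort connectivity table (same edge order as the reference).
    discovery : DiscoverySet
        Reference-derived edge set; defines the FDR family (m = |set|).
    symptoms : DataFrame or Series
        One column per symptom scale (e.g. PCL-5, PROMIS anxiety/depression
        T-scores), indexed by subject_id.
    covariates : DataFrame
        Target-cohort covariates.
    terms : sequence of str
        Covariate terms; defaults to the trauma-cohort specification.
    """

    def __init__(self, edge_table, discovery: DiscoverySet, symptoms, covariates, terms=TARGET_TERMS):
        if len(discovery) == 0:
            raise ValueError("empty DiscoverySet: nothing to project")
        max_edge = max(discovery.edges)
        if max_edge >= edge_table.shape[1]:
            raise ValueError("DiscoverySet refers to edges beyond the target EdgeTable")
        if isinstance(symptoms, pd.Series):
            symptoms = symptoms.to_frame()
        self.edge_table = edge_table
        self.discovery = discovery
        self.symptoms = symptoms
        self.covariates = covariates
        self.terms = tuple(terms)
        self.edge_index = EdgeIndex(discovery.n_components)

    def fit(self, alpha: float = 0.05, pooled: bool = False) -> "ProjectionResults":
        """Fit every (edge, symptom) pair; BH-FDR within each symptom family."""
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        frames = []
        edges = list(self.discovery.edges)
        names = self.edge_table.columns[edges]
        for symptom in self.symptoms.columns:
            y, cov, n_dropped = drop_missing(self.symptoms[symptom], self.covariates, self.terms)
            if len(y) == 0:
                raise ValueError(f"zero subjects remain for symptom {symptom!r}")
            X = build_design(cov, self.terms)
            rd = ResidualizedDesign.from_design(X.to_numpy())
            E = self.edge_table.loc[y.index].to_numpy()[:, edges]
            st = batch_edge_glm(E, y.to_numpy(), rd)
            st.index = names
            st.insert(0, "edge", edges)
            st.insert(0, "symptom", symptom)
            st["n_subjects"] = len(y)
            st["n_dropped"] = n_dropped
            frames.append(st)
        table = pd.concat(frames)
        valid = ~table["skipped"]
        q = np.full(len(table), np.nan)
        if pooled:
            q[valid.to_numpy()] = bh_fdr(table.loc[valid, "p"].to_numpy())
        else:
            for symptom in self.symptoms.columns:
                mask = ((table["symptom"] == symptom) & valid).to_numpy()
                q[mask] = bh_fdr(table.loc[mask, "p"].to_numpy())
        table["q"] = q
        return ProjectionResults(self, table, alpha=alpha, pooled=pooled)


class ProjectionResults:
    """Per (edge, symptom) statistics with the family-restricted FDR adjustment."""

    def __init__(self, model: ConstrainedProjection, table: pd.DataFrame, alpha: float, pooled: bool):
        self.model = model
        self.table = table
        self.alpha = alpha
        self.pooled = pooled
        self.family_size = len(model.discovery)

    def significant(self) -> pd.DataFrame:
        """Rows with q <= alpha, ordered by ascending p (ties keep both)."""
        sig = self.table.loc[(~self.table["skipped"]) & (self.table["q"] <= self.alpha)]
        return sig.sort_values(["symptom", "p", "edge"])

    def report(self, partition=None) -> pd.DataFrame:
        """Tabular report of significant edges per symptom.

        Matches the reporting tuple (beta, SE, partial r, FDR q) with
        endpoint components/networks and an association-direction label.
        An empty significant set yields zero rows with the header intact.
        """
        return projection_report(self, partition)

    def summary(self) -> str:
        d = self.model.discovery
        lines = [
            "Constrained projection",
            "=" * 55,
            f"discovery set:  {len(d)} edges from {d.outcome_name!r} "
            f"(reference n={d.n_subjects}, alpha={d.alpha})",
            f"FDR family:     {'pooled' if self.pooled else 'per symptom'}, m={self.family_size}",
            f"FDR level:      {self.alpha}",
        ]
        sig = self.significant()
        for symptom in self.model.symptoms.columns:
            rows = sig.loc[sig["symptom"] == symptom]
            lines.append(f"{symptom}: {len(rows)} significant edge(s)")
            for name, row in rows.iterrows():
                lines.append(
                    f"  {name:>12s}  beta={row.beta:+.4g}  SE={row.se:.3g}  "
                    f"r={row.partial_r:+.3f}  q={row.q:.3g}"
                )
        return "\n".join(lines)


def project(edge_table_target, edges: DiscoverySet, symptom, covariates, alpha: float = 0.05, terms=TARGET_TERMS):
    """One-shot wrapper: fit the discovered edges against one symptom.

    Returns the full (edge, symptom) statistics table with q adjusted across
    exactly m = |DiscoverySet| tests.
    """
    model = ConstrainedProjection(edge_table_target, edges, symptom, covariates, terms=terms)
    return model.fit(alpha=alpha).table


def projection_report(results: ProjectionResults, partition=None) -> pd.DataFrame:
    """Significant-edge report: endpoints, networks, beta/SE/r/q, sign label."""
    sig = results.significant().copy()
    idx = results.model.edge_index
    ii = np.array([idx.pair_of(e)[0] for e in sig["edge"]], dtype=int)
    jj = np.array([idx.pair_of(e)[1] for e in sig["edge"]], dtype=int)
    sig["component_i"] = ii + 1
    sig["component_j"] = jj + 1
    if partition is not None:
        sig["network_i"] = [partition[i] for i in ii]
        sig["network_j"] = [partition[j] for j in jj]
    if len(sig):
        sig["sign_label"] = edge_sign_labels(sig).to_numpy()
    else:
        sig["sign_label"] = pd.Series(dtype=object)
    keep = ["symptom", "edge", "component_i", "component_j"]
    if partition is not None:
        keep += ["network_i", "network_j"]
    keep += ["beta", "se", "partial_r", "p", "q", "sign_label"]
    return sig[keep]
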