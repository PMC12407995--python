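"""Domain containers and on-disk formats shared by every analysis stage.

The package works with post-ICA component time courses: each subject is a
T x C real matrix (T timepoints, C components), connectivity is summarized
per unordered component pair ("edge"), and phenotypes/covariates live in
ordinary pandas tables keyed by ``subject_id``.

Conventions used throughout:

* Edge order is the row-major upper triangle: (0,1), (0,2), ..., (0,C-1),
  (1,2), ... — i ascending, then j > i.  All modules and all file outputs
  use this order.
* Components are 0-based in memory; file outputs label them 1-based.
* Sex is coded 0/1; categorical covariates (site, trauma type) are
  reference-coded with the alphabetically first level as reference.
* Subjects with missing values in any required model column are dropped
  per-model, with the dropped count reported.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimecourseMatrix",
    "EdgeIndex",
    "NetworkPartition",
    "read_timecourse",
    "read_covariates",
    "read_outcome",
    "read_edge_table",
    "write_edge_table",
    "edge_columns",
    "build_design",
    "load_default_partition",
    "REFERENCE_TERMS",
    "TARGET_TERMS",
]

#: Covariate specification used for the reference (healthy population) cohort.
REFERENCE_TERMS = ("age", "age2", "sex", "agexsex", "site")
#: Covariate specification used for the target (trauma-exposed) cohort.
TARGET_TERMS = (
    "age",
    "age2",
    "sex",
    "agexsex",
    "income",
    "education_years",
    "site",
    "trauma_type",
)


class FormatError(ValueError):
    """Malformed on-disk input (ragged rows, non-numeric cells, ...)."""


@dataclass
class TimecourseMatrix:
    """One subject's component time courses.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    data : ndarray, shape (T, C)
        Real-valued post-ICA time courses; rows are timepoints, columns
        components (arbitrary units).
    tr_seconds : float
        Repetition time in seconds.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float = 1.0
    degenerate_columns: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time course data must be 2-D (timepoints x components)")
        t, c = self.data.shape
        if t < 2 or c < 2:
            raise ValueError(f"need T >= 2 and C >= 2, got T={t}, C={c}")
        if not np.isfinite(self.data).all():
            raise ValueError(f"subject {self.subject_id}: non-finite values in time courses")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        degenerate = tuple(np.flatnonzero(self.data.std(axis=0) == 0.0).tolist())
        self.degenerate_columns = degenerate

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]


class EdgeIndex:
    """Bijective map between component pairs (i, j), i < j, and flat edge ids.

    The flat order is the row-major upper triangle, so for C components there
    are C(C-1)/2 edges; C = 53 gives the familiar 1,378 connectivity features.
    """

    def __init__(self, n_components: int):
        if n_components < 2:
            raise ValueError("need at least 2 components")
        self.n_components = int(n_components)
        iu = np.triu_indices(self.n_components, k=1)
        self._pairs_i = iu[0]
        self._pairs_j = iu[1]
        # lookup (i, j) -> k for i < j
        self._flat = np.full((self.n_components, self.n_components), -1, dtype=np.int64)
        self._flat[iu] = np.arange(iu[0].size)

    def __len__(self) -> int:
        return self._pairs_i.size

    @property
    def pairs(self):
        """(i_array, j_array) of the upper-triangle pairs in flat order."""
        return self._pairs_i, self._pairs_j

    def edge_of(self, i: int, j: int) -> int:
        """Flat index of the edge between components ``i`` and ``j`` (symmetric)."""
        if i == j:
            raise ValueError("self-edges are excluded (i must differ from j)")
        c = self.n_components
        if not (0 <= i < c and 0 <= j < c):
            raise ValueError(f"component out of range [0, {c})")
        a, b = (i, j) if i < j else (j, i)
        return int(self._flat[a, b])

    def pair_of(self, k: int) -> tuple[int, int]:
        """Component pair (i, j) with i < j for flat edge index ``k``."""
        if not 0 <= k < len(self):
            raise ValueError(f"edge index out of range [0, {len(self)})")
        return int(self._pairs_i[k]), int(self._pairs_j[k])


@dataclass
class NetworkPartition:
    """Assignment of every component to exactly one functional network.

    ``labels`` maps 0-based component id to a network label (e.g. one of
    SC, AUD, SM, VIS, CC, DM, CB).
    """

    labels: dict

    def __post_init__(self):
        n = len(self.labels)
        if set(self.labels) != set(range(n)):
            raise ValueError("partition must cover components 0..C-1 exactly once")

    @property
    def n_components(self) -> int:
        return len(self.labels)

    @property
    def networks(self) -> tuple:
        seen = []
        for v in self.labels.values():
            if v not in seen:
                seen.append(v)
        return tuple(seen)

    def __getitem__(self, component: int) -> str:
        return self.labels[component]

    @classmethod
    def from_csv(cls, path) -> "NetworkPartition":
        """Read a two-column CSV (component_id, network); component ids 1-based."""
        df = pd.read_csv(path)
        if not {"component_id", "network"}.issubset(df.columns):
            raise FormatError("partition CSV needs columns component_id, network")
        return cls({int(r.component_id) - 1: str(r.network) for r in df.itertuples()})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component_id": [c + 1 for c in sorted(self.labels)],
                "network": [self.labels[c] for c in sorted(self.labels)],
            }
        )


def load_default_partition() -> NetworkPartition:
    """Packaged 53-component / 7-network partition (synthetic stand-in).

    Network sizes follow the standard 53-component template (SC 5, AUD 2,
    SM 9, VIS 9, CC 17, DM 7, CB 4) with consecutive block assignment;
    anatomical component identities are not encoded.  It is a synthetic
    stand-in for a study-specific component table and is intended for
    simulations, examples and tests.
    """
    ref = importlib.resources.files("edgeproject.data") / "partition53_synthetic.csv"
    with importlib.resources.as_file(ref) as path:
        return NetworkPartition.from_csv(path)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_timecourse(path, tr_seconds: float = 1.0, subject_id: str | None = None) -> TimecourseMatrix:
    """Read one subject's T x C time-course matrix from delimited text.

    Accepts TSV or CSV (delimiter sniffed), with or without a header row.
    Constant (zero-variance) columns load fine but are flagged on
    ``degenerate_columns`` and reported via a warning.
    """
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    delim = "\t" if first.count("\t") >= first.count(",") else ","
    tokens = [t for t in first.strip().split(delim) if t != ""]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = 0 if tokens and not all(_numeric(t) for t in tokens) else None
    try:
        df = pd.read_csv(path, sep=delim, header=header)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed rows ({exc})") from exc
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise FormatError(f"{path}: missing/ragged cell at row {r}, column {c}")
    try:
        data = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for c in range(df.shape[1]):
            coerced = pd.to_numeric(df.iloc[:, c], errors="coerce")
            if coerced.isna().any():
                r = int(coerced.isna().idxmax())
                raise FormatError(
                    f"{path}: non-numeric cell at row {r}, column {c}: {df.iloc[r, c]!r}"
                ) from None
        raise
    if subject_id is None:
        stem = path.rsplit("/", 1)[-1]
        subject_id = stem.rsplit(".", 1)[0]
    tc = TimecourseMatrix(subject_id=subject_id, data=data, tr_seconds=tr_seconds)
    if tc.degenerate_columns:
        warnings.warn(
            f"{path}: constant (degenerate) columns {list(tc.degenerate_columns)}",
            stacklevel=2,
        )
    return tc


def read_covariates(path) -> pd.DataFrame:
    """Read a phenotype/covariate CSV with a mandatory subject_id column.

    Derived columns (age2, agexsex) are never read from disk; they are
    constructed by :func:`build_design`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}: covariate CSV must contain a subject_id column")
    df = df.set_index(df["subject_id"].astype(str)).drop(columns="subject_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicated subject_id {dup!r}")
    return df


def read_outcome(path, column: str) -> pd.Series:
    """Read one outcome column (by name) from a phenotype CSV."""
    df = read_covariates(path)
    if column not in df.columns:
        raise FormatError(f"{path}: no column {column!r}")
    return pd.to_numeric(df[column], errors="raise").rename(column)


def edge_columns(idx: EdgeIndex) -> list:
    """CSV column names e_{i}_{j} for every edge, with 1-based component labels."""
    i, j = idx.pairs
    return [f"e_{a + 1}_{b + 1}" for a, b in zip(i, j)]


def write_edge_table(edge_table: pd.DataFrame, path) -> None:
    """Write a subjects x edges table to CSV (one row per subject)."""
    out = edge_table.copy()
    out.insert(0, "subject_id", out.index)
    out.to_csv(path, index=False)  # pandas default float repr round-trips exactly


def read_edge_table(path) -> pd.DataFrame:
    """Read a subjects x edges CSV written by :func:`write_edge_table`.

    Validates that every correlation lies in [-1, 1] and that the column
    count matches a C(C-1)/2 edge vectorization.
    """
    df = read_covariates(path)
    vals = df.to_numpy(dtype=float)
    if np.nanmax(np.abs(vals)) > 1.0 + 1e-12:
        raise FormatError(f"{path}: edge values outside [-1, 1]")
    m = df.shape[1]
    c = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if c * (c - 1) // 2 != m:
        raise FormatError(f"{path}: {m} columns is not C(C-1)/2 for any integer C")
    return df


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

_DERIVED = {"age2": ("age",), "agexsex": ("age", "sex")}


def build_design(covariates: pd.DataFrame, terms=REFERENCE_TERMS) -> pd.DataFrame:
    """Construct a full-rank design matrix from named covariate terms.

    The intercept column comes first.  ``age2`` and ``agexsex`` are derived
    from ``age``/``sex``; non-numeric (categorical) columns such as site or
    trauma type are reference-coded with the alphabetically first level as
    the reference.  Raises if the expanded design is rank deficient, naming
    the collinear columns.
    """
    cols = {"intercept": pd.Series(1.0, index=covariates.index)}
    for term in terms:
        if term in _DERIVED:
            for base in _DERIVED[term]:
                if base not in covariates.columns:
                    raise ValueError(f"term {term!r} needs base column {base!r}")
            if term == "age2":
                cols["age2"] = covariates["age"].astype(float) ** 2
            else:
                cols["agexsex"] = covariates["age"].astype(float) * covariates["sex"].astype(float)
            continue
        if term not in covariates.columns:
            raise ValueError(f"covariate column {term!r} not present")
        col = covariates[term]
        if pd.api.types.is_numeric_dtype(col):
            cols[term] = col.astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:  # first level alphabetically is reference
                cols[f"{term}[{level}]"] = (col.astype(str) == level).astype(float)
    X = pd.DataFrame(cols)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X.to_numpy(), pivoting=True, mode="economic")
        bad = [X.columns[k] for k in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X


def drop_missing(outcome: pd.Series, covariates: pd.DataFrame, terms) -> tuple:
    """Align outcome and covariates, dropping subjects with missing fields.

    Returns (outcome, covariates, n_dropped).  Mirrors the per-model
    exclusion of subjects with missing clinical information.
    """
    base_cols = []
    for term in terms:
        base_cols.extend(_DERIVED.get(term, (term,)))
    base_cols = [c for c in dict.fromkeys(base_cols) if c in covariates.columns]
    common = outcome.index.intersection(covariates.index)
    out = outcome.loc[common]
    cov = covariates.loc[common]
    keep = out.notna() & cov[base_cols].notna().all(axis=1)
    n_dropped = int((~keep).sum()) + (len(outcome) - len(common))
    return out[keep], cov[keep], n_dropped
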