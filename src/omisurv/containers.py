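"""In-memory containers shared across the pipeline.

A :class:`Cohort` holds per-patient survival outcomes and clinical covariates,
an :class:`OmicMatrix` holds one samples-by-features omic layer, and a
:class:`KernelMatrix` holds the n-by-n similarity matrix (with its
eigendecomposition) that the Bayesian model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

OMIC_KINDS = ("snp", "methylation", "expression", "cnv")

#: canonical outcome column names in a Cohort frame
TIME_COL = "time"
CENSOR_COL = "censor"


class SchemaError(ValueError):
    """Input table does not conform to the expected schema."""


class AlignmentError(ValueError):
    """Sample identifiers of two inputs cannot be aligned."""


@dataclass
class Cohort:
    """Survival outcomes plus clinical covariates, indexed by sample id.

    ``data`` is indexed by unique sample ids and contains the columns
    ``time`` (follow-up in months, strictly positive where present),
    ``censor`` (1 = right censored, 0 = death observed) and any number of
    covariate columns (numeric or categorical). Outcome columns may be NaN
    for cohorts whose outcomes have not been simulated/observed yet.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("Cohort.data must be a pandas DataFrame")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dups[:5]}")
        for col in (TIME_COL, CENSOR_COL):
            if col not in self.data.columns:
                self.data[col] = np.nan
        t = pd.to_numeric(self.data[TIME_COL], errors="coerce")
        bad = self.data.index[(t <= 0) & t.notna()]
        if len(bad):
            raise SchemaError(f"non-positive follow-up time for rows: {bad.tolist()[:5]}")
        c = self.data[CENSOR_COL].dropna()
        if len(c) and not set(np.unique(np.asarray(c, dtype=float))) <= {0.0, 1.0}:
            raise SchemaError("censor indicator must be 0 (event) or 1 (censored)")

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return np.asarray(self.data[TIME_COL], dtype=float)

    @property
    def censor(self) -> np.ndarray:
        return np.asarray(self.data[CENSOR_COL], dtype=float)

    @property
    def event(self) -> np.ndarray:
        """Event indicator (1 = death observed), the complement of ``censor``."""
        return 1.0 - self.censor

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=[TIME_COL, CENSOR_COL])

    def has_outcomes(self) -> bool:
        return bool(self.data[TIME_COL].notna().all() and self.data[CENSOR_COL].notna().all())

    def subset(self, sample_ids) -> "Cohort":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise AlignmentError(f"unknown sample ids: {missing[:5]}")
        return Cohort(self.data.loc[list(sample_ids)].copy())

    def with_outcomes(self, time: np.ndarray, censor: np.ndarray) -> "Cohort":
        out = self.data.copy()
        out[TIME_COL] = np.asarray(time, dtype=float)
        out[CENSOR_COL] = np.asarray(censor, dtype=float)
        return Cohort(out)


def design_matrix(cohort: Cohort, names, drop_first: bool = True):
    """Encode named covariates as a numeric design matrix.

    Numeric columns enter as-is; categorical/object columns are expanded into
    0/1 dummies (dropping the first level). Returns ``(matrix, column_names,
    origin)`` where ``origin`` maps each encoded column back to the covariate
    it came from.
    """
    names = list(names)
    cols, colnames, origin = [], [], []
    for name in names:
        if name not in cohort.data.columns:
            raise SchemaError(f"unknown covariate: {name!r}")
        s = cohort.data[name]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(np.asarray(s, dtype=float)[:, None])
            colnames.append(name)
            origin.append(name)
        else:
            dummies = pd.get_dummies(s, prefix=name, drop_first=drop_first)
            cols.append(np.asarray(dummies, dtype=float))
            colnames.extend(dummies.columns.tolist())
            origin.extend([name] * dummies.shape[1])
    if not cols:
        return np.empty((cohort.n, 0)), [], []
    X = np.hstack(cols)
    if not np.isfinite(X).all():
        raise SchemaError("covariates contain missing/non-finite values")
    return X, colnames, origin


@dataclass
class OmicMatrix:
    """One omic layer: samples x features with optional probe-to-gene map."""

    values: pd.DataFrame
    kind: str
    feature_meta: pd.Series | None = None  # feature id -> gene symbol

    def __post_init__(self) -> None:
        if self.kind not in OMIC_KINDS:
            raise ValueError(f"unknown omic kind {self.kind!r}; expected one of {OMIC_KINDS}")
        if self.values.columns.has_duplicates:
            raise SchemaError(f"duplicate feature ids in {self.kind} matrix")
        if self.values.index.has_duplicates:
            raise SchemaError(f"duplicate sample ids in {self.kind} matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self):
        return self.values.shape

    def to_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def subset(self, sample_ids) -> "OmicMatrix":
        missing = [s for s in sample_ids if s not in self.values.index]
        if missing:
            raise AlignmentError(f"unknown sample ids in {self.kind} matrix: {missing[:5]}")
        return OmicMatrix(self.values.loc[list(sample_ids)].copy(), self.kind, self.feature_meta)


@dataclass
class KernelMatrix:
    """PSD similarity matrix between subjects, with its eigendecomposition.

    ``eigenvalues``/``eigenvectors`` hold only the retained basis: components
    with eigenvalue below ``rank_tol`` times the largest are truncated.
    """

    sample_ids: list
    K: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    rank_tol: float = 1e-8

    @classmethod
    def from_matrix(cls, K: np.ndarray, sample_ids, rank_tol: float = 1e-8) -> "KernelMatrix":
        K = np.asarray(K, dtype=float)
        n = K.shape[0]
        if K.shape != (n, n) or n != len(sample_ids):
            raise ValueError("kernel must be square and match the sample ids")
        asym = np.abs(K - K.T).max() if n else 0.0
        if asym > 1e-10:
            raise ValueError(f"kernel not symmetric (max asymmetry {asym:.2e})")
        vals, vecs = np.linalg.eigh((K + K.T) / 2.0)
        vals, vecs = vals[::-1], vecs[:, ::-1]
        lam_max = max(vals[0], 0.0) if n else 0.0
        keep = vals > rank_tol * lam_max
        return cls(list(sample_ids), K, vals[keep], vecs[:, keep], rank_tol)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def rank(self) -> int:
        return len(self.eigenvalues)

    def subset(self, sample_ids) -> "KernelMatrix":
        idx = pd.Index(self.sample_ids)
        pos = idx.get_indexer(list(sample_ids))
        if (pos < 0).any():
            raise AlignmentError("unknown sample ids for kernel subset")
        return KernelMatrix.from_matrix(self.K[np.ix_(pos, pos)], list(sample_ids), self.rank_tol)

    def cross(self, sample_ids_rows, sample_ids_cols) -> np.ndarray:
        idx = pd.Index(self.sample_ids)
        r = idx.get_indexer(list(sample_ids_rows))
        c = idx.get_indexer(list(sample_ids_cols))
        if (r < 0).any() or (c < 0).any():
            raise AlignmentError("unknown sample ids for kernel cross block")
        return self.K[np.ix_(r, c)]
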