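"""Cross-cell, cross-species analysis of accepted parameter ensembles:
normalized heatmap matrix and PCA species separation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

__all__ = [
    "ParameterMatrix",
    "build_parameter_matrix",
    "PCAResult",
    "run_pca",
    "SeparationReport",
    "cluster_separation",
]


@dataclass
class ParameterMatrix:
    """Rows = parameters (max-normalized, sorted by descending row mean),
    columns = individuals grouped by cell."""

    values: np.ndarray
    parameter_names: list
    columns: list  # (cell_id, individual_rank) per column

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.columns,
                                         names=["cell", "individual"])
        return pd.DataFrame(self.values, index=self.parameter_names,
                            columns=cols)


def build_parameter_matrix(ensembles_per_cell: dict) -> ParameterMatrix:
    """``ensembles_per_cell`` maps cell id -> iterable of individuals (any
    object with a ``parameters`` dict, or a plain dict).  Values are
    normalized to the per-parameter maximum; all-zero rows are excluded with
    a warning.  Normalization is idempotent."""
    columns, rows = [], []
    for cell_id, ensemble in ensembles_per_cell.items():
        individuals = getattr(ensemble, "individuals", ensemble)
        for rank, ind in enumerate(individuals):
            params = ind.parameters if hasattr(ind, "parameters") else ind
            columns.append((cell_id, rank))
            rows.append(params)
    if not rows:
        raise ValueError("no individuals supplied")
    names = sorted(rows[0])
    for params in rows:
        if sorted(params) != names:
            raise ValueError("individuals do not share the parameter "
                             "naming scheme")
    mat = np.array([[p[n] for p in rows] for n in names], dtype=float)
    keep, kept_names = [], []
    for i, name in enumerate(names):
        m = np.max(np.abs(mat[i]))
        if m == 0:
            warnings.warn(f"parameter {name!r} is all-zero; excluded")
            continue
        keep.append(mat[i] / m)
        kept_names.append(name)
    mat = np.vstack(keep)
    order = np.argsort(-mat.mean(axis=1), kind="stable")
    return ParameterMatrix(values=mat[order],
                           parameter_names=[kept_names[i] for i in order],
                           columns=columns)


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    projections: np.ndarray      # centred scores, individuals x components
    loadings: np.ndarray         # components x parameters, orthonormal rows
    parameter_names: list
    scaling: str
    dropped: list = field(default_factory=list)


def run_pca(individuals, parameters=None, scaling: str = "standardize"
            ) -> PCAResult:
    """PCA over a common parameter subset.

    ``individuals``: DataFrame, or iterable of dicts/Individual objects.
    ``scaling``: 'standardize' (per-parameter z-score over the pooled
    individuals) or 'max' (divide by the per-parameter maximum).  Constant
    parameters are dropped with a warning.
    """
    if isinstance(individuals, pd.DataFrame):
        df = individuals.copy()
    else:
        recs = [ind.parameters if hasattr(ind, "parameters") else ind
                for ind in individuals]
        df = pd.DataFrame(recs)
    if parameters is not None:
        missing = set(parameters) - set(df.columns)
        if missing:
            raise ValueError(f"parameters not present: {sorted(missing)}")
        df = df[list(parameters)]
    if len(df) < 2 or df.shape[1] == 0:
        raise ValueError("need >= 2 individuals and a non-empty subset")
    if scaling not in ("standardize", "max"):
        raise ValueError(f"unknown scaling {scaling!r}")
    X = df.to_numpy(dtype=float)
    names = list(df.columns)
    dropped = []
    std = X.std(axis=0, ddof=1)
    keep = std > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"constant parameters dropped: {dropped}")
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    if scaling == "standardize":
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    else:
        X = X / np.max(np.abs(X), axis=0)
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = _SkPCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    ev = pca.explained_variance_
    return PCAResult(
        eigenvalues=ev,
        explained_fraction=pca.explained_variance_ratio_,
        projections=scores,
        loadings=pca.components_,
        parameter_names=names,
        scaling=scaling,
        dropped=dropped,
    )


@dataclass
class SeparationReport:
    component: int
    ranges: dict                 # label -> (lo, hi)
    overlap_fraction: float
    standardized_mean_difference: float
    separated: bool


def cluster_separation(projections, labels, component: int = 0
                       ) -> SeparationReport:
    """Range overlap and standardized mean difference of one projection
    axis between two labeled groups; ``separated`` iff the ranges are
    disjoint."""
    proj = np.asarray(projections, float)
    if proj.ndim == 2:
        proj = proj[:, component]
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("cluster_separation needs exactly two labels")
    a = proj[labels == uniq[0]]
    b = proj[labels == uniq[1]]
    ranges = {uniq[0]: (float(a.min()), float(a.max())),
              uniq[1]: (float(b.min()), float(b.max()))}
    lo = max(a.min(), b.min())
    hi = min(a.max(), b.max())
    span = max(a.max(), b.max()) - min(a.min(), b.min())
    overlap = max(0.0, hi - lo) / span if span > 0 else 1.0
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
    smd = abs(a.mean() - b.mean()) / pooled if pooled > 0 else np.inf
    return SeparationReport(
        component=component, ranges=ranges,
        overlap_fraction=float(overlap),
        standardized_mean_difference=float(smd),
        separated=bool(hi < lo),
    )
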