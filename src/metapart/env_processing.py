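"""Environmental variable transformation, PCA reduction, derived indices.

Field environmental tables mix units (conductivity in uS/cm, precipitation in
mm, cover percentages, depths in m), so variables are transformed to tame
skewness — log10 for right-skewed non-negative quantities, arcsine-square-root
for proportions — and the reduction to three principal components is done on
the correlation matrix (standardized variables), which is the only scale on
which a PCA "of all variables" is meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import skew
from sklearn.decomposition import PCA

__all__ = [
    "EnvironmentTable",
    "PCScores",
    "transform_variables",
    "reduce_environment",
    "shoreline_development",
    "landcover_shannon",
    "auto_assign_transforms",
]

VALID_TRANSFORMS = ("none", "log", "asin_sqrt")
VALID_SETS = ("limnological", "macroclimatic", "landscape", "other")


@dataclass
class EnvironmentTable:
    """Site-by-variable table with per-variable transformation metadata.

    ``metadata`` is indexed by variable name with columns:

    - ``transform``: one of none|log|asin_sqrt
    - ``set``: variable set label (limnological|macroclimatic|landscape|other)
    - ``units``: free text
    - ``percent``: optional bool; asin_sqrt variables on a 0-100 scale are
      divided by 100 before the transform.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.hasnans or self.values.index.duplicated().any():
            raise ValueError("missing or duplicated site_id in environment table")
        missing = [v for v in self.values.columns if v not in self.metadata.index]
        if missing:
            raise ValueError(f"variables without metadata: {missing}")
        bad = [
            v for v in self.values.columns
            if self.metadata.loc[v, "transform"] not in VALID_TRANSFORMS
        ]
        if bad:
            raise ValueError(f"invalid transform flags for: {bad}")

    @property
    def site_id(self) -> list:
        return list(self.values.index)

    def variable_set(self, name: str) -> pd.DataFrame:
        """Sub-table of variables belonging to one set label."""
        keep = self.metadata.index[self.metadata["set"] == name]
        return self.values[[v for v in self.values.columns if v in set(keep)]]


@dataclass
class PCScores:
    """First three principal components of the standardized environment."""

    scores: pd.DataFrame  # site x 3, columns PC1..PC3
    loadings: pd.DataFrame  # variable x 3
    explained: np.ndarray  # per-component variance proportions
    cumulative_explained: float
    dropped: list  # constant variables removed before the PCA


def _percent_flags(meta: pd.DataFrame) -> pd.Series:
    if "percent" in meta.columns:
        return meta["percent"].fillna(False).astype(bool)
    return pd.Series(False, index=meta.index)


def auto_assign_transforms(values: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Assign transform flags from the data distribution.

    Proportion-type variables (all raw values within [0,1], or [0,100] with the
    percent flag) get arcsine-square-root; non-negative variables with sample
    skewness above 1 get log10; everything else is left untransformed.
    """
    meta = metadata.copy()
    percent = _percent_flags(meta)
    for v in values.columns:
        x = values[v].to_numpy(dtype=float)
        upper = 100.0 if percent.get(v, False) else 1.0
        if np.all((x >= 0.0) & (x <= upper)) and percent.get(v, False):
            meta.loc[v, "transform"] = "asin_sqrt"
        elif np.all((x >= 0.0) & (x <= 1.0)) and not np.all(np.isin(x, (0.0, 1.0))):
            meta.loc[v, "transform"] = "asin_sqrt"
        elif np.all(x >= 0.0) and skew(x) > 1.0:
            meta.loc[v, "transform"] = "log"
        else:
            meta.loc[v, "transform"] = "none"
    return meta


def transform_variables(env: EnvironmentTable, auto: bool = False) -> EnvironmentTable:
    """Apply the per-variable transforms recorded in the metadata.

    asin_sqrt: y = arcsin(sqrt(p)), with percent-scale variables divided by
    100 first. log: y = log10(x + c) with c = 1 if the variable contains any
    zero, else 0.
    """
    meta = auto_assign_transforms(env.values, env.metadata) if auto else env.metadata
    percent = _percent_flags(meta)
    out = {}
    for v in env.values.columns:
        x = env.values[v].to_numpy(dtype=float)
        how = meta.loc[v, "transform"]
        if how == "asin_sqrt":
            p = x / 100.0 if percent.get(v, False) else x
            if np.any(p < 0.0) or np.any(p > 1.0):
                raise ValueError(f"asin_sqrt input outside [0, 1] for variable {v!r}")
            out[v] = np.arcsin(np.sqrt(p))
        elif how == "log":
            if np.any(x < 0.0):
                raise ValueError(f"negative input to log for variable {v!r}")
            offset = 1.0 if np.any(x == 0.0) else 0.0
            out[v] = np.log10(x + offset)
        else:
            out[v] = x
    transformed = pd.DataFrame(out, index=env.values.index)
    new_meta = meta.copy()
    new_meta["transform"] = "none"  # transforms are consumed, not reapplied
    return EnvironmentTable(values=transformed, metadata=new_meta)


def reduce_environment(env: EnvironmentTable | pd.DataFrame) -> PCScores:
    """Correlation-matrix PCA; return the first three components.

    Variables are standardized to zero mean and unit variance; constant
    variables are dropped with a warning. Component signs are fixed so the
    largest-magnitude loading of each component is positive, which makes
    downstream forward selection reproducible across LAPACK builds.
    """
    values = env.values if isinstance(env, EnvironmentTable) else env
    if values.shape[0] < 4:
        raise ValueError("need at least 4 sites for a PCA")
    sd = values.std(axis=0, ddof=1)
    dropped = list(values.columns[sd == 0.0])
    if dropped:
        warnings.warn(f"dropping constant variables: {dropped}", stacklevel=2)
        values = values.drop(columns=dropped)
        sd = sd.drop(dropped)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 non-constant variables")
    z = (values - values.mean(axis=0)) / sd
    pca = PCA(n_components=3, svd_solver="full")
    raw_scores = pca.fit_transform(z.to_numpy())
    loadings = pca.components_.T  # variable x 3
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(3)])
    flip[flip == 0] = 1.0
    scores = raw_scores * flip
    loadings = loadings * flip
    explained = pca.explained_variance_ratio_
    return PCScores(
        scores=pd.DataFrame(scores, index=values.index, columns=["PC1", "PC2", "PC3"]),
        loadings=pd.DataFrame(loadings, index=values.columns, columns=["PC1", "PC2", "PC3"]),
        explained=explained,
        cumulative_explained=float(explained.sum()),
        dropped=dropped,
    )


def shoreline_development(perimeter: float, area: float) -> float:
    """Shoreline development index: perimeter over the circumference of the
    equal-area circle, DL = L / (2 sqrt(pi A)). 1 for a perfect circle."""
    if perimeter <= 0.0 or area <= 0.0:
        raise ValueError("perimeter and area must be positive")
    return float(perimeter / (2.0 * np.sqrt(np.pi * area)))


def landcover_shannon(proportions) -> float:
    """Shannon diversity H = -sum p_i ln p_i of land-cover fractions.

    Inputs are renormalized to sum to one; zero classes contribute nothing.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0.0):
        raise ValueError("cover proportions must be non-negative")
    total = p.sum()
    if total == 0.0:
        raise ValueError("all-zero cover vector")
    p = p[p > 0.0] / total
    return float(max(-(p * np.log(p)).sum(), 0.0))
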