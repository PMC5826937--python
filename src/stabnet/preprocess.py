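"""Imputation, normalization, transformation and scaling of the filtered matrix.

Pipeline order: KNN imputation -> constant-sum normalization -> generalized
log transform -> autoscaling, applied to the study-sample matrix before any
statistics or modeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer


@dataclass
class PreprocessedMatrix:
    """Complete (no-missing) samples x features matrix plus provenance.

    ``feature_means`` / ``feature_sds`` are the autoscaling constants
    (per-feature mean and n-1 SD on the glog scale) needed for the inverse
    mapping; ``params`` records k (imputation) and a (glog).
    """

    values: pd.DataFrame
    feature_means: pd.Series
    feature_sds: pd.Series
    params: dict = field(default_factory=dict)

    def provenance(self) -> dict:
        return {
            "params": self.params,
            "feature_means": {k: float(v) for k, v in self.feature_means.items()},
            "feature_sds": {k: float(v) for k, v in self.feature_sds.items()},
        }


def impute_knn(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """K-nearest-neighbour imputation of missing cells.

    Each missing cell is replaced by the mean of that feature's values in
    the k nearest samples, with distances computed as Euclidean over
    co-observed features and rescaled by the number of co-observed features
    (the nan-aware Euclidean metric). Observed cells are untouched.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    all_missing = matrix.isna().all(axis=0)
    if all_missing.any():
        bad = matrix.columns[all_missing].tolist()
        raise ValueError(f"feature(s) missing in every sample: {bad[:5]}")
    if (matrix.notna().sum(axis=1) == 0).any():
        raise ValueError("a sample has no observed values")
    if not matrix.isna().any().any():
        return matrix.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    out = imputer.fit_transform(matrix.to_numpy(dtype=float))
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normalize_constant_sum(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample row by its total intensity so rows sum to 1."""
    sums = matrix.sum(axis=1)
    bad = sums <= 0
    if bad.any():
        raise ValueError(
            f"nonpositive total intensity for sample(s): {matrix.index[bad].tolist()[:5]}"
        )
    return matrix.div(sums, axis=0)


def glog_transform(matrix: pd.DataFrame, a: float = 1.0) -> pd.DataFrame:
    """Generalized log: g(x) = log2((x + sqrt(x^2 + a^2)) / 2).

    Strictly increasing, defined at zero (g(0) = log2(a/2)), and
    asymptotically log2(x) for x >> a.
    """
    if a <= 0:
        raise ValueError("glog parameter a must be > 0")
    x = matrix.to_numpy(dtype=float)
    g = np.log2((x + np.sqrt(x * x + a * a)) / 2.0)
    return pd.DataFrame(g, index=matrix.index, columns=matrix.columns)


def autoscale(matrix: pd.DataFrame, params: dict | None = None) -> PreprocessedMatrix:
    """Center every feature column to mean 0 and scale to unit (n-1) SD.

    Constant columns are centered and left at zero with a warning; the
    centering means and scaling SDs are stored for the inverse mapping.
    """
    if matrix.isna().any().any():
        raise ValueError("autoscale requires a complete matrix")
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    const = sds == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant feature column(s) left at zero after centering",
            stacklevel=2,
        )
    safe_sds = sds.mask(const, 1.0)
    values = (matrix - means) / safe_sds
    return PreprocessedMatrix(
        values=values,
        feature_means=means,
        feature_sds=sds,
        params=dict(params or {}),
    )


def resolve_glog_a(matrix: pd.DataFrame, glog_a: float | str) -> float:
    """Resolve the glog parameter on the scale of the data.

    ``"auto"`` picks a tenth of the median positive entry, so the transform
    is log-like for the bulk of the intensities yet finite at zero. A fixed
    value much larger than the data (e.g. 1 on a constant-sum scale where
    entries are ~1/p) would make g effectively affine, i.e. no
    variance stabilization at all.
    """
    if glog_a == "auto":
        vals = matrix.to_numpy(dtype=float)
        pos = vals[vals > 0]
        if pos.size == 0:
            raise ValueError("no positive entries to scale the glog parameter")
        return float(np.median(pos) / 10.0)
    a = float(glog_a)
    if a <= 0:
        raise ValueError("glog parameter a must be > 0")
    return a


def preprocess(
    matrix: pd.DataFrame, k: int = 10, glog_a: float | str = "auto"
) -> PreprocessedMatrix:
    """impute -> constant-sum -> glog -> autoscale, deterministically."""
    imputed = impute_knn(matrix, k=k)
    normed = normalize_constant_sum(imputed)
    a = resolve_glog_a(normed, glog_a)
    glogged = glog_transform(normed, a=a)
    return autoscale(glogged, params={"knn_k": k, "glog_a": a,
                                      "normalization": "constant_sum"})
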