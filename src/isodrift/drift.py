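"""Repeat-injection drift statistics and hydrophobicity–recovery analysis.

Residual protein in an extract shows up as time-dependent signal drift
across repeat injections of the same resuspended sample. This module
provides the statistics used to detect and quantify that drift:

* a per-feature trend test — natural cubic regression spline (df=4 by
  default) on log10(area+1) against time, F-tested against the
  intercept-only model;
* PCA of the feature table (log10(x+1), mean-center, autoscale by
  default, each step switchable) with the accumulated Euclidean path
  length of consecutive injections in score space as the drift magnitude;
* UpSet-style exclusive intersection counts of per-group significant
  feature sets;
* pooled-QC CV deduplication of compounds measured by several methods;
* Spearman correlation of compound LogP against log2 fold change, used to
  ask how much of a recovery change is explained by hydrophobicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DriftError",
    "FeatureMatrix",
    "TrendResult",
    "PCAResult",
    "DriftSummary",
    "natural_cubic_spline_basis",
    "trend_test",
    "trend_test_matrix",
    "pca_scores",
    "accumulated_path_length",
    "drift_summary",
    "log2_fold_change",
    "logp_recovery_correlation",
    "dedupe_by_qc_cv",
    "significant_set_intersections",
    "intersections_long",
]


class DriftError(ValueError):
    """Invalid drift-analysis input."""


@dataclass
class FeatureMatrix:
    """Features x samples peak-area matrix with metadata.

    ``values`` has features as rows and samples as columns; ``sample_meta``
    is indexed like the columns and may carry ``group``,
    ``injection_order`` and ``time_hr``; ``feature_meta`` is indexed like
    the rows and may carry m/z, RT, LogP, detection method and pooled-QC
    CV columns.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise DriftError("peak areas must be non-negative")
        if self.sample_meta is not None:
            if not self.sample_meta.index.equals(self.values.columns):
                self.sample_meta = self.sample_meta.reindex(self.values.columns)
            if {"group", "injection_order"} <= set(self.sample_meta.columns):
                dup = self.sample_meta.groupby("group")["injection_order"].apply(
                    lambda s: s.duplicated().any()
                )
                if dup.any():
                    raise DriftError("injection order must be unique within each group")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# trend testing


def natural_cubic_spline_basis(x: np.ndarray, df: int = 4) -> np.ndarray:
    """Natural cubic regression spline basis with ``df`` columns (no intercept).

    Boundary knots at min/max of ``x``, ``df - 1`` interior knots at
    equally spaced quantiles. Uses the standard truncated-power
    construction with linearity constraints beyond the boundary knots; the
    F-test downstream depends only on the spanned column space.
    """
    x = np.asarray(x, dtype=float)
    if df < 2:
        raise DriftError("spline df must be >= 2")
    qs = np.linspace(0, 1, df + 1)  # df+1 knots incl. boundaries
    knots = np.quantile(x, qs)
    if np.unique(knots).size != knots.size:
        raise DriftError("degenerate knot sequence (too many tied time points)")
    K = knots.size

    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - knots[K - 1], 0, None) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


@dataclass(frozen=True)
class TrendResult:
    """Spline trend test result for one feature."""

    feature_id: str
    p_value: float
    f_stat: float
    df_model: int
    df_resid: int
    group: str = ""
    constant: bool = False  # flagged when the series carries no variance
    fitted: np.ndarray | None = None


def _spline_f_test(
    Y: np.ndarray, times: np.ndarray, df: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, np.ndarray]:
    """Vectorized F-test of spline model vs intercept for columns of Y."""
    n = times.size
    if n < df + 2:
        raise DriftError(f"need at least df+2={df + 2} time points, got {n}")
    B = natural_cubic_spline_basis(times, df=df)
    X = np.column_stack([np.ones(n), B])
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    rss1 = (resid**2).sum(axis=0)
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    df_model = X.shape[1] - 1
    df_resid = n - X.shape[1]
    constant = rss0 <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / df_model) / (rss1 / df_resid)
    p = np.where(constant, 1.0, stats.f.sf(f, df_model, df_resid))
    # a perfect fit (rss1 == 0) on a non-constant series is maximal evidence
    p = np.where((~constant) & (rss1 <= 1e-300), 0.0, p)
    return f, p, constant, df_resid, X @ coef


def trend_test(
    areas: Sequence[float],
    times: Sequence[float],
    df: int = 4,
    feature_id: str = "",
    group: str = "",
    log_transform: bool = True,
) -> TrendResult:
    """Test one injection series for time-dependent drift.

    Fits a natural cubic spline (``df`` basis columns) to
    log10(area+1) versus time and F-tests it against the intercept-only
    model; two-sided p-value from the F distribution. A constant series is
    reported with p=1 and ``constant=True``.
    """
    y = np.asarray(areas, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise DriftError("areas and times must be equal-length 1-D sequences")
    if log_transform:
        y = np.log10(y + 1.0)
    f, p, constant, df_resid, fitted = _spline_f_test(y[:, None], t, df)
    return TrendResult(
        feature_id=feature_id,
        p_value=float(p[0]),
        f_stat=float(f[0]) if np.isfinite(f[0]) else float("inf"),
        df_model=df,
        df_resid=df_resid,
        group=group,
        constant=bool(constant[0]),
        fitted=fitted[:, 0],
    )


def trend_test_matrix(
    wide: pd.DataFrame,
    times: Sequence[float],
    df: int = 4,
    group: str = "",
    alpha: float = 0.05,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Trend-test every row of a features x injections table at once.

    Returns a tidy frame with raw p-values, a Benjamini–Hochberg FDR
    column, and the raw-p significance call at ``alpha``.
    """
    t = np.asarray(times, dtype=float)
    Y = wide.to_numpy(dtype=float).T  # injections x features
    if Y.shape[0] != t.size:
        raise DriftError("times length must match the number of columns")
    if log_transform:
        Y = np.log10(Y + 1.0)
    f, p, constant, df_resid, _ = _spline_f_test(Y, t, df)
    order = np.argsort(p)
    m = p.size
    bh = np.empty(m)
    ranked = p[order] * m / (np.arange(m) + 1)
    bh[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    return pd.DataFrame(
        {
            "feature_id": wide.index,
            "group": group,
            "f_stat": f,
            "p_value": p,
            "fdr_bh": np.clip(bh, 0, 1),
            "significant": p < alpha,
            "constant": constant,
        }
    ).set_index("feature_id")


# ---------------------------------------------------------------------------
# PCA and path length


@dataclass
class PCAResult:
    """SVD-based PCA of a feature table."""

    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components
    explained_variance_ratio: np.ndarray
    sample_ids: list
    feature_ids: list
    dropped_features: list = field(default_factory=list)


def pca_scores(
    matrix: FeatureMatrix | pd.DataFrame,
    log_transform: bool = True,
    center: bool = True,
    scale: bool = True,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of a features x samples table (MetaboAnalyst-style defaults).

    Preprocessing is log10(x+1), per-feature mean-centering and unit-
    variance autoscaling, each independently switchable. Zero-variance
    features are dropped with a warning. Scores are sample coordinates
    (U·S from the SVD of the samples x features matrix); explained-variance
    fractions sum to <= 1.
    """
    values = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    if values.shape[1] < 2 or values.shape[0] < 2:
        raise DriftError("PCA needs at least 2 features and 2 samples")
    X = values.to_numpy(dtype=float).T  # samples x features
    if log_transform:
        if (X < 0).any():
            raise DriftError("log transform requires non-negative areas")
        X = np.log10(X + 1.0)
    var = X.var(axis=0, ddof=1)
    keep = var > 0
    dropped = [fid for fid, k in zip(values.index, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance features", stacklevel=2)
        X = X[:, keep]
        var = var[keep]
    if X.shape[1] < 1:
        raise DriftError("no features with variance remain")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n = X.shape[0]
    total_var = (X**2).sum() / (n - 1) if center else np.trace(X.T @ X) / (n - 1)
    evr = (S**2 / (n - 1)) / total_var
    k = S.size if n_components is None else min(n_components, S.size)
    return PCAResult(
        scores=U[:, :k] * S[:k],
        loadings=Vt[:k].T,
        explained_variance_ratio=evr[:k],
        sample_ids=list(values.columns),
        feature_ids=[fid for fid, kk in zip(values.index, keep) if kk],
        dropped_features=dropped,
    )


def accumulated_path_length(scores: np.ndarray, dims: int = 2) -> float:
    """Accumulated Euclidean distance along consecutive injections.

    ``scores`` must be ordered by injection; the path is measured in the
    first ``dims`` principal components. A single injection gives 0 with a
    warning.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
    if s.shape[0] < 2:
        warnings.warn("fewer than 2 injections: path length is 0", stacklevel=2)
        return 0.0
    if dims > s.shape[1]:
        raise DriftError(f"dims={dims} exceeds available components ({s.shape[1]})")
    seg = np.diff(s[:, :dims], axis=0)
    return float(np.sqrt((seg**2).sum(axis=1)).sum())


@dataclass
class DriftSummary:
    """Per-group PCA drift quantification on a joint score space."""

    pca: PCAResult
    path_lengths: dict
    dims: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": list(self.path_lengths), "path_length": list(self.path_lengths.values())}
        ).set_index("group")


def drift_summary(matrix: FeatureMatrix, dims: int = 2, **pca_kwargs) -> DriftSummary:
    """Joint PCA of all samples plus per-group accumulated path lengths.

    Requires ``sample_meta`` with ``group`` and ``injection_order``
    columns; within each group, scores are ordered by injection before the
    path is accumulated.
    """
    if matrix.sample_meta is None or not {
        "group",
        "injection_order",
    } <= set(matrix.sample_meta.columns):
        raise DriftError("sample_meta with 'group' and 'injection_order' is required")
    pca = pca_scores(matrix, **pca_kwargs)
    meta = matrix.sample_meta.loc[pca.sample_ids]
    lengths = {}
    for grp, sub in meta.groupby("group", sort=False):
        order = np.argsort(sub["injection_order"].to_numpy())
        rows = [pca.sample_ids.index(sid) for sid in sub.index[order]]
        lengths[grp] = accumulated_path_length(pca.scores[rows], dims=dims)
    return DriftSummary(pca=pca, path_lengths=lengths, dims=dims)


# ---------------------------------------------------------------------------
# recovery vs hydrophobicity


def log2_fold_change(
    condition_areas: Sequence[float],
    control_areas: Sequence[float],
    pseudocount: float = 0.0,
) -> float:
    """log2 of the ratio of replicate means (condition over control).

    The ratio of means (not mean of ratios) is used; a pseudocount guards
    against zero means when requested.
    """
    c = float(np.mean(np.asarray(condition_areas, dtype=float))) + pseudocount
    r = float(np.mean(np.asarray(control_areas, dtype=float))) + pseudocount
    if c <= 0 or r <= 0:
        raise DriftError("non-positive mean area; use a pseudocount")
    return float(np.log2(c / r))


def logp_recovery_correlation(table: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation of LogP against Log2FC.

    ``table`` needs ``logp`` and ``log2fc`` columns over >= 4 compounds.
    Average-rank tie handling; two-sided p-value via the t approximation.
    """
    for col in ("logp", "log2fc"):
        if col not in table.columns:
            raise DriftError(f"missing column {col!r}")
    x = table["logp"].to_numpy(dtype=float)
    y = table["log2fc"].to_numpy(dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DriftError("LogP and Log2FC must be finite (apply pseudo-count handling first)")
    if x.size < 4:
        raise DriftError("need at least 4 compounds")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DriftError("correlation undefined: a column is entirely tied")
    r_s, p = stats.spearmanr(x, y)
    return float(r_s), float(p)


# ---------------------------------------------------------------------------
# deduplication and set intersections


def dedupe_by_qc_cv(
    features: pd.DataFrame,
    compound_col: str = "compound",
    method_col: str = "method",
    cv_col: str = "qc_cv",
) -> pd.DataFrame:
    """Keep, per compound, the detection method with the lowest pooled-QC CV.

    Ties are broken by lexicographic method name. Every row must carry a
    CV; missing values are a validation error. Never increases the row
    count and returns at most one row per compound.
    """
    for col in (compound_col, method_col, cv_col):
        if col not in features.columns:
            raise DriftError(f"missing column {col!r}")
    if features[cv_col].isna().any():
        raise DriftError("every (compound, method) pair must have a QC CV")
    ordered = features.sort_values([compound_col, cv_col, method_col], kind="mergesort")
    out = ordered.drop_duplicates(subset=compound_col, keep="first")
    return out.sort_index()


def significant_set_intersections(sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Exclusive (UpSet-style) intersection counts of named feature sets.

    Each element of the union is assigned to exactly one region — the
    frozenset of set names containing it — and regions are tallied.
    Only non-empty regions appear in the result.
    """
    counts: dict[frozenset, int] = {}
    universe = set().union(*sets.values()) if sets else set()
    for el in universe:
        region = frozenset(name for name, s in sets.items() if el in s)
        counts[region] = counts.get(region, 0) + 1
    return counts


def intersections_long(counts: Mapping[frozenset, int]) -> pd.DataFrame:
    """UpSet-compatible long form: one row per region, '&'-joined names."""
    rows = [
        {"region": "&".join(sorted(region)), "degree": len(region), "count": n}
        for region, n in counts.items()
    ]
    return (
        pd.DataFrame(rows, columns=["region", "degree", "count"])
        .sort_values(["degree", "region"])
        .reset_index(drop=True)
    )
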