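"""Per-metabolite differential analysis for the simulated-colon study design.

Untargeted MS intensities (samples x metabolites, missing values allowed) are
half-minimum imputed and log2 transformed, then each metabolite is tested for
a treatment effect in an additive linear model controlling for bioreplicate
and colon region, with Benjamini-Hochberg correction across metabolites.
One-way ANOVA with Tukey's HSD serves the pairwise region comparisons, and
sub-pathway summaries apply the same treatment test to mean member profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetaboliteTable",
    "preprocess",
    "treatment_lm",
    "fit_treatment_model",
    "bh_adjust",
    "anova_tukey",
    "summarize_by_subpathway",
    "differential_analysis",
    "TreatmentDifferentialAnalysis",
]

METADATA_COLUMNS = ("region", "bioreplicate", "treatment", "day")
REGIONS = ("AC", "TC", "DC")
BIOREPLICATES = ("BR1", "BR2", "BR3")
TREATMENTS = ("control", "LGG")


@dataclass
class MetaboliteTable:
    """Metabolite intensities with per-sample metadata.

    intensities : samples x metabolites; NaN marks values below detection.
    metadata    : indexed like intensities, columns region / bioreplicate /
                  treatment / day.
    annotations : optional, indexed by metabolite, columns name,
                  super_pathway, sub_pathway, identified.
    log2_transformed : whether :func:`preprocess` has already run.
    """

    intensities: pd.DataFrame
    metadata: pd.DataFrame
    annotations: pd.DataFrame | None = None
    log2_transformed: bool = False

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.metadata.index):
            raise ValueError("intensities and metadata must share the same sample index")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata lacks required column(s): {missing}")
        if self.metadata[list(METADATA_COLUMNS)].isna().any().any():
            raise ValueError("metadata must be complete for every sample")

    @property
    def samples(self) -> pd.Index:
        return self.intensities.index

    @property
    def metabolites(self) -> pd.Index:
        return self.intensities.columns

    def to_tsv(self, path) -> None:
        """Write a single TSV: sample_id + metadata columns, then intensities."""
        out = pd.concat([self.metadata[list(METADATA_COLUMNS)], self.intensities], axis=1)
        out.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, annotations: pd.DataFrame | None = None) -> "MetaboliteTable":
        frame = pd.read_csv(path, sep="\t", index_col="sample_id")
        meta = frame[list(METADATA_COLUMNS)]
        intensities = frame.drop(columns=list(METADATA_COLUMNS))
        return cls(intensities=intensities, metadata=meta, annotations=annotations)


def preprocess(
    table: MetaboliteTable, max_missing_fraction: float = 0.8
) -> MetaboliteTable:
    """Half-minimum impute, drop mostly-missing metabolites, log2 transform.

    Missing values are replaced by half the smallest observed intensity of
    that metabolite (the standard left-censoring rule for untargeted MS);
    metabolites missing in more than ``max_missing_fraction`` of samples, or
    never observed at all, are dropped with a warning.  Idempotent: a table
    already flagged as log2-transformed is returned unchanged.
    """
    if table.log2_transformed:
        return table
    x = table.intensities
    missing_frac = x.isna().mean(axis=0)
    drop = missing_frac[missing_frac > max_missing_fraction].index
    if len(drop):
        warnings.warn(
            f"dropping {len(drop)} metabolite(s) missing in "
            f">{max_missing_fraction:.0%} of samples: {list(drop[:10])}"
            + ("..." if len(drop) > 10 else ""),
            stacklevel=2,
        )
    x = x.drop(columns=drop)
    if (x <= 0).any().any():
        raise ValueError("intensities must be positive on the linear scale")
    half_min = x.min(axis=0) / 2.0
    x = x.fillna(half_min)
    ann = table.annotations
    if ann is not None:
        ann = ann.loc[ann.index.intersection(x.columns)]
    return MetaboliteTable(
        intensities=np.log2(x),
        metadata=table.metadata,
        annotations=ann,
        log2_transformed=True,
    )


def _design_matrix(metadata: pd.DataFrame, include_day: bool = False) -> pd.DataFrame:
    """Additive treatment + bioreplicate + region design with intercept.

    Treatment is coded LGG=1 vs control=0 so the treatment coefficient is the
    log2 LGG-vs-control difference; the coding of the nuisance factors does
    not affect that test.
    """
    cols = {"intercept": np.ones(len(metadata))}
    cols["treatment"] = (metadata["treatment"].astype(str) == "LGG").astype(float)
    for level in sorted(metadata["bioreplicate"].astype(str).unique())[1:]:
        cols[f"br_{level}"] = (metadata["bioreplicate"].astype(str) == level).astype(float)
    for level in sorted(metadata["region"].astype(str).unique())[1:]:
        cols[f"region_{level}"] = (metadata["region"].astype(str) == level).astype(float)
    if include_day:
        day = metadata["day"].astype(float)
        cols["day"] = day - day.mean()
    return pd.DataFrame(cols, index=metadata.index)


def treatment_lm(
    y: pd.DataFrame, metadata: pd.DataFrame, include_day: bool = False
) -> pd.DataFrame:
    """Vectorised OLS of each column of ``y`` on the treatment design.

    Returns one row per metabolite with columns ``coefficient`` (log2 units),
    ``se``, ``p_value`` (two-sided t test of the treatment coefficient) and a
    ``zero_variance`` flag.  Columns with no variance get coefficient 0 and
    p = 1.  All columns share the design matrix, so a single least-squares
    solve covers the whole table.

    Raises
    ------
    ValueError
        If the design matrix is rank deficient (e.g. treatment confounded
        with a nuisance factor) or has no residual degrees of freedom.
    """
    levels = metadata["treatment"].astype(str).unique()
    if len(levels) < 2:
        raise ValueError("both treatment levels must be present")
    X = _design_matrix(metadata, include_day=include_day).values
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design: treatment is confounded with covariates")
    dof = n - p
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    Y = y.values.astype(float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # p x m
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    j = 1  # treatment column
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[j, j], 0.0))
    coef = beta[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, coef / np.where(se > 0, se, 1.0), np.inf * np.sign(coef))
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    zero_var = Y.std(axis=0) == 0
    coef = np.where(zero_var, 0.0, coef)
    pval = np.where(zero_var, 1.0, pval)
    pval = np.where(np.isnan(pval), 1.0, pval)
    return pd.DataFrame(
        {
            "coefficient": coef,
            "se": np.where(zero_var, 0.0, se),
            "p_value": pval,
            "zero_variance": zero_var,
        },
        index=y.columns,
    )


def fit_treatment_model(
    y: pd.Series, metadata: pd.DataFrame, include_day: bool = False
) -> tuple[float, float]:
    """Treatment coefficient and two-sided p-value for one metabolite."""
    res = treatment_lm(y.to_frame(name=y.name or "y"), metadata, include_day=include_day)
    row = res.iloc[0]
    return float(row["coefficient"]), float(row["p_value"])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; rejection at alpha iff q <= alpha."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def anova_tukey(y, group_factor, alpha: float = 0.05):
    """One-way ANOVA with Tukey HSD post-hoc comparisons.

    Parameters
    ----------
    y : array-like of observations.
    group_factor : array-like of group labels, same length.
    alpha : family-wise error rate for the ``reject`` column.

    Returns
    -------
    (F, p, table) where ``table`` has one row per unordered group pair with
    the mean difference, Tukey-adjusted p (studentized range distribution)
    and rejection flag.

    Raises
    ------
    ValueError
        With fewer than 2 groups or any single-observation group (whose
        variance contribution is undefined), naming the group.
    """
    y = np.asarray(y, dtype=float)
    labels = np.asarray(group_factor)
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = []
    for g in groups:
        arr = y[labels == g]
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        arrays.append(arr)
    if np.ptp(np.concatenate(arrays)) == 0:
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*arrays)
        if np.isnan(F):
            F, p = 0.0, 1.0
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p_adj = float(hsd.pvalue[i, j])
            rows.append(
                {
                    "group_1": groups[i],
                    "group_2": groups[j],
                    "mean_difference": float(arrays[j].mean() - arrays[i].mean()),
                    "p_adj": p_adj,
                    "reject": p_adj <= alpha,
                }
            )
    return float(F), float(p), pd.DataFrame(rows)


def differential_analysis(
    table: MetaboliteTable,
    alpha: float = 0.05,
    include_day: bool = False,
) -> pd.DataFrame:
    """Per-metabolite treatment test with BH correction and per-region flags.

    The table is preprocessed if needed.  The main test is the additive model
    ``log2 intensity ~ treatment + bioreplicate + region``; per-region flags
    re-fit the treatment test within each colon region (controlling for
    bioreplicate only) with BH correction within the region.
    """
    table = preprocess(table)
    res = treatment_lm(table.intensities, table.metadata, include_day=include_day)
    res["q_value"] = bh_adjust(res["p_value"].values)
    res["significant"] = res["q_value"] <= alpha
    res["direction"] = np.sign(res["coefficient"]).astype(int)
    for region in sorted(table.metadata["region"].astype(str).unique()):
        mask = table.metadata["region"].astype(str) == region
        sub_meta = table.metadata.loc[mask]
        flag_col = f"significant_{region}"
        if sub_meta["treatment"].astype(str).nunique() < 2:
            res[flag_col] = False
            continue
        X = table.intensities.loc[mask]
        cols = {"intercept": np.ones(mask.sum())}
        cols["treatment"] = (sub_meta["treatment"].astype(str) == "LGG").astype(float)
        for level in sorted(sub_meta["bioreplicate"].astype(str).unique())[1:]:
            cols[f"br_{level}"] = (sub_meta["bioreplicate"].astype(str) == level).astype(float)
        sub = _region_lm(X.values, pd.DataFrame(cols, index=sub_meta.index).values)
        res[flag_col] = bh_adjust(sub) <= alpha
    res.index.name = "metabolite"
    return res


def _region_lm(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Two-sided p-values of the treatment column (index 1) for each column of Y."""
    n, p = X.shape
    dof = n - p
    if dof <= 0 or np.linalg.matrix_rank(X) < p:
        return np.ones(Y.shape[1])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta[1] / np.where(se > 0, se, 1.0), 0.0)
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    return np.where(np.isnan(pval), 1.0, pval)


def summarize_by_subpathway(
    table: MetaboliteTable,
    annotations: pd.DataFrame | None = None,
    alpha: float = 0.05,
    include_day: bool = False,
) -> pd.DataFrame:
    """Treatment test on sub-pathway mean profiles, BH across sub-pathways.

    Each sub-pathway's profile is the mean log2 intensity of its member
    metabolites per sample; metabolites without a sub-pathway annotation are
    grouped under ``"unannotated"`` rather than dropped.
    """
    table = preprocess(table)
    ann = annotations if annotations is not None else table.annotations
    if ann is None:
        raise ValueError("sub-pathway summary requires annotations")
    sub = ann.reindex(table.metabolites)["sub_pathway"].fillna("unannotated").astype(str)
    profiles = table.intensities.T.groupby(sub).mean().T
    res = treatment_lm(profiles, table.metadata, include_day=include_day)
    res["q_value"] = bh_adjust(res["p_value"].values)
    res["significant"] = res["q_value"] <= alpha
    res["n_members"] = sub.value_counts().reindex(res.index).astype(int)
    res.index.name = "sub_pathway"
    return res


class TreatmentDifferentialAnalysis(BaseEstimator):
    """Estimator wrapper for the per-metabolite treatment analysis.

    Parameters
    ----------
    alpha : BH-adjusted significance level.
    include_day : include (centered) sampling day as a covariate.

    Attributes
    ----------
    results_ : per-metabolite DataFrame (coefficient, p, q, flags).
    subpathway_results_ : per-sub-pathway DataFrame, when annotations exist.
    n_significant_ : number of metabolites with q <= alpha.
    """

    def __init__(self, alpha: float = 0.05, include_day: bool = False):
        self.alpha = alpha
        self.include_day = include_day

    def fit(self, X: MetaboliteTable, y=None) -> "TreatmentDifferentialAnalysis":
        if not isinstance(X, MetaboliteTable):
            raise TypeError("X must be a MetaboliteTable")
        self.results_ = differential_analysis(
            X, alpha=self.alpha, include_day=self.include_day
        )
        if X.annotations is not None:
            self.subpathway_results_ = summarize_by_subpathway(
                X, alpha=self.alpha, include_day=self.include_day
            )
        else:
            self.subpathway_results_ = None
        self.n_significant_ = int(self.results_["significant"].sum())
        return self
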