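"""Peak-to-trough ratio (PTR) inference from multi-sample contig coverage.

Relative distances of virtual contigs from the replication origin are
inferred by PCA of the per-sample-centered coverage matrix (contigs as
observations): for an actively replicating population, log2 coverage decays
linearly with distance from oriC, so contig scores on the first principal
component order the contigs along the replichore.  A linear mixed-effects
model with per-sample fixed slopes on distance and crossed random intercepts
for sample and contig yields the effect sizes b_s, and each sample's PTR is
``2**(-b_s)`` — the model's origin/terminus coverage ratio with distances
scaled to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .coverage import FilterThresholds, assemble_matrix, split_virtual_contigs, windowed_coverage

__all__ = [
    "DistanceEstimate",
    "PTREstimator",
    "infer_distances",
    "fit_lmm",
    "construct_ptr",
    "estimate_ptr",
]


@dataclass
class DistanceEstimate:
    """Inferred relative contig distances from oriC, rescaled to [0, 1]."""

    relative_distance: pd.Series
    pc1_variance_fraction: float
    orientation_flipped: bool
    degenerate: bool = False


def infer_distances(
    matrix: pd.DataFrame, degenerate_threshold: float = 0.5
) -> DistanceEstimate:
    """PCA-based relative distances of contigs from the replication origin.

    The samples x contigs matrix is centered per sample; contig scores on
    the first principal component are min-max rescaled to [0, 1].
    Orientation is fixed so the across-sample median of per-sample OLS
    slopes of coverage on distance is negative (the origin is the
    high-coverage end).  When PC1 explains less than
    ``degenerate_threshold`` of the variance the ordering is noise and the
    estimate is flagged degenerate.
    """
    if matrix.isna().any().any():
        raise ValueError("coverage matrix must be complete (no masked cells)")
    if matrix.shape[0] < 3 or matrix.shape[1] < 4:
        raise ValueError("need >= 3 samples and >= 4 contigs")
    A = matrix.values.astype(float)
    Z = (A - A.mean(axis=1, keepdims=True)).T  # contigs x samples, column-centered
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    total = float((S**2).sum())
    scale = max(np.abs(A).max(), 1.0)
    if np.sqrt(total) <= 1e-9 * scale:
        # perfectly flat matrix: no gradient to order contigs
        d = pd.Series(np.zeros(matrix.shape[1]), index=matrix.columns)
        return DistanceEstimate(d, 0.0, False, degenerate=True)
    frac = float(S[0] ** 2 / total)
    scores = U[:, 0] * S[0]
    span = scores.max() - scores.min()
    d = (scores - scores.min()) / span if span > 0 else np.zeros_like(scores)

    # orientation: per-sample OLS slope of y on d, median must be negative
    dc = d - d.mean()
    denom = float(dc @ dc)
    flipped = False
    if denom > 0:
        slopes = (A - A.mean(axis=1, keepdims=True)) @ dc / denom
        if np.median(slopes) > 0:
            d = 1.0 - d
            flipped = True
    distances = pd.Series(d, index=matrix.columns, name="relative_distance")
    return DistanceEstimate(
        distances, frac, flipped, degenerate=frac < degenerate_threshold
    )


def _ols_per_sample(matrix: pd.DataFrame, x: np.ndarray) -> tuple[pd.Series, pd.Series]:
    """Per-sample OLS of log2 coverage on distance; returns slopes and SEs."""
    slopes, ses = {}, {}
    xc = x - x.mean()
    sxx = float(xc @ xc)
    n = len(x)
    for sample, row in matrix.iterrows():
        y = row.values.astype(float)
        b = float(xc @ (y - y.mean()) / sxx)
        resid = (y - y.mean()) - b * xc
        dof = max(n - 2, 1)
        s2 = float(resid @ resid) / dof
        slopes[sample] = b
        ses[sample] = float(np.sqrt(s2 / sxx))
    return pd.Series(slopes), pd.Series(ses)


def fit_lmm(
    matrix: pd.DataFrame, distances: DistanceEstimate, reml: bool = True
) -> tuple[pd.Series, pd.Series, dict]:
    """Per-sample distance slopes from the mixed model, with fallback.

    The model has a global intercept, fixed per-sample slopes on relative
    distance, and crossed random intercepts for sample and contig (variance
    components), fitted by REML.  Singular or non-convergent fits (e.g.
    noiseless data with zero residual variance) fall back to per-sample OLS
    of coverage on distance; the route taken is recorded in the returned
    diagnostics dict.
    """
    if distances.degenerate:
        warnings.warn(
            "distance estimate is degenerate; slopes reflect noise", stacklevel=2
        )
    x = distances.relative_distance.reindex(matrix.columns).values
    samples = list(matrix.index)

    # per-sample centering removes sequencing-depth offsets exactly, so a
    # library-size shift cannot leak into the slopes through the shrinkage
    # of the random sample intercepts
    matrix = matrix.sub(matrix.mean(axis=1), axis=0)
    long = matrix.stack().rename("y").reset_index()
    long.columns = ["sample", "contig", "y"]
    long["x"] = distances.relative_distance.reindex(long["contig"]).values
    long["group"] = 1

    diagnostics: dict = {"method": "lmm"}
    try:
        import statsmodels.formula.api as smf
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            res = None
            for method in ("powell", "lbfgs"):
                model = smf.mixedlm(
                    "y ~ C(sample):x",
                    long,
                    groups="group",
                    re_formula="0",
                    vc_formula={
                        "sample": "0 + C(sample)",
                        "contig": "0 + C(contig)",
                    },
                )
                res = model.fit(reml=reml, method=method, maxiter=2000)
                if getattr(res, "converged", False):
                    break
        slope_names = {s: f"C(sample)[{s}]:x" for s in samples}
        slopes = pd.Series({s: res.params[nm] for s, nm in slope_names.items()})
        ses = pd.Series({s: res.bse[nm] for s, nm in slope_names.items()})
        ok = (
            bool(getattr(res, "converged", True))
            and np.all(np.isfinite(slopes.values))
            and np.all(np.isfinite(ses.values))
            and res.scale > 1e-10
        )
        if not ok:
            raise RuntimeError("singular or non-convergent mixed model")
        diagnostics["residual_variance"] = float(res.scale)
        diagnostics["converged"] = True
        return slopes, ses, diagnostics
    except Exception as exc:  # noqa: BLE001 - any fit failure routes to OLS
        diagnostics["method"] = "ols_fallback"
        diagnostics["reason"] = str(exc)
        slopes, ses = _ols_per_sample(matrix, x)
        return slopes, ses, diagnostics


def construct_ptr(
    slopes: pd.Series,
    ses: pd.Series,
    distances: DistanceEstimate,
) -> pd.DataFrame:
    """PTR per sample from the slope effect sizes: ``ptr = 2**(-b)``.

    With distances spanning [0, 1] and orientation fixed so replication
    gives negative slopes, 2**(-b) is the model's origin/terminus coverage
    ratio.  The 95% interval maps the slope's normal interval through the
    same transform.  Samples with ptr <= 1, or any sample under a degenerate
    distance estimate, are flagged non-replicating.
    """
    b = slopes.values.astype(float)
    se = ses.reindex(slopes.index).values.astype(float)
    ptr = np.exp2(-b)
    ci_low = np.exp2(-(b + 1.959963984540054 * se))
    ci_high = np.exp2(-(b - 1.959963984540054 * se))
    flags = (ptr <= 1.0) | distances.degenerate
    return pd.DataFrame(
        {
            "sample_id": slopes.index,
            "slope": b,
            "ptr": ptr,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "pc1_variance_fraction": distances.pc1_variance_fraction,
            "flag_nonreplicating": flags,
        }
    ).set_index("sample_id")


class PTREstimator(BaseEstimator):
    """Estimate per-sample PTRs from a complete coverage matrix.

    Parameters
    ----------
    degenerate_threshold : minimum PC1 variance fraction below which the
        contig ordering is treated as noise and samples are flagged
        non-replicating.
    use_lmm : fit the mixed model (with OLS fallback); if False go straight
        to per-sample OLS.

    Attributes
    ----------
    distances_ : DistanceEstimate used for the fit.
    slopes_, slope_ses_ : per-sample effect sizes and standard errors.
    results_ : DataFrame with slope, ptr, ci_low, ci_high, flags.
    diagnostics_ : dict describing the fitting route.
    """

    def __init__(self, degenerate_threshold: float = 0.5, use_lmm: bool = True):
        self.degenerate_threshold = degenerate_threshold
        self.use_lmm = use_lmm

    def fit(self, X: pd.DataFrame, y=None, distances: DistanceEstimate | None = None):
        X = pd.DataFrame(X)
        if distances is None:
            distances = infer_distances(X, self.degenerate_threshold)
        self.distances_ = distances
        if self.use_lmm and not distances.degenerate:
            slopes, ses, diag = fit_lmm(X, distances)
        else:
            slopes, ses = _ols_per_sample(
                X, distances.relative_distance.reindex(X.columns).values
            )
            diag = {"method": "ols"}
        self.slopes_, self.slope_ses_, self.diagnostics_ = slopes, ses, diag
        self.results_ = construct_ptr(slopes, ses, distances)
        return self

    def predict(self, X=None) -> pd.Series:
        """Per-sample PTR point estimates from the fitted model."""
        return self.results_["ptr"]


def _diagnostics_table(
    matrix: pd.DataFrame, distances: DistanceEstimate, level: float = 0.99
) -> pd.DataFrame:
    """Per-sample regression lines of log2 coverage on inferred distance.

    Emits observed points, the per-sample OLS fit and a confidence band for
    the mean response (t-based, default 99%), mirroring the usual
    replication-gradient diagnostic plot.
    """
    x = distances.relative_distance.reindex(matrix.columns).values
    xc = x - x.mean()
    sxx = float(xc @ xc)
    n = len(x)
    tcrit = stats.t.ppf(0.5 + level / 2, max(n - 2, 1))
    rows = []
    for sample, row in matrix.iterrows():
        y = row.values.astype(float)
        b = float(xc @ (y - y.mean()) / sxx)
        a = float(y.mean() - b * x.mean())
        fitted = a + b * x
        resid = y - fitted
        s2 = float(resid @ resid) / max(n - 2, 1)
        half = tcrit * np.sqrt(s2 * (1.0 / n + xc**2 / sxx))
        for contig, xi, yi, fi, hi in zip(matrix.columns, x, y, fitted, half):
            rows.append(
                {
                    "sample_id": sample,
                    "contig": contig,
                    "relative_distance": xi,
                    "log2_coverage": yi,
                    "fitted": fi,
                    "ci_low": fi - hi,
                    "ci_high": fi + hi,
                }
            )
    return pd.DataFrame(rows)


def estimate_ptr(
    sam_paths,
    genome_fasta,
    n_contigs: int = 20,
    thresholds: FilterThresholds | None = None,
    window_size: int | None = None,
    window_step: int | None = None,
    degenerate_threshold: float = 0.5,
    out: str | Path | None = None,
    diagnostics_out: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end PTR estimation from SAM files and the reference FASTA.

    Composes coverage profiling (filtering, windowing, masking), distance
    inference, the mixed model and the PTR construction.  Returns the
    per-sample results table and the regression diagnostic table; optionally
    writes both as TSV.
    """
    from Bio import SeqIO

    sam_paths = [Path(p) for p in sam_paths]
    if len(sam_paths) < 3:
        raise ValueError("PTR estimation needs >= 3 SAM files")
    record = next(SeqIO.parse(str(genome_fasta), "fasta"))
    genome_length = len(record.seq)
    contigs = split_virtual_contigs(genome_length, n_contigs)
    rows = {}
    for path in sorted(sam_paths):
        try:
            row = windowed_coverage(
                path, contigs, thresholds, window_size, window_step
            )
        except ValueError as exc:
            raise ValueError(f"coverage stage failed for {path}: {exc}") from exc
        rows[row.name] = row
    try:
        matrix = assemble_matrix(rows)
    except ValueError as exc:
        raise ValueError(f"matrix assembly failed: {exc}") from exc
    est = PTREstimator(degenerate_threshold=degenerate_threshold).fit(matrix)
    diag = _diagnostics_table(matrix, est.distances_)
    if out is not None:
        est.results_.to_csv(out, sep="\t")
    if diagnostics_out is not None:
        diag.to_csv(diagnostics_out, sep="\t", index=False)
    return est.results_, diag
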