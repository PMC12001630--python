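"""Two-group negative-binomial differential expression.

A self-contained NB Wald stage for the heat-stress (morning vs night) style
two-group contrast:

1. median-of-ratios size factors (geometric-mean reference per gene, median
   ratio per sample, factors rescaled to geometric mean 1);
2. per-gene dispersion by method of moments on normalised counts within
   groups, shrunk toward a fitted mean–dispersion trend;
3. per-gene NB GLM with log link and size-factor offsets, fitted by IRLS
   vectorised across genes; the group-indicator coefficient is the natural-log
   fold change, tested with a Wald z statistic;
4. Benjamini–Hochberg FDR adjustment; a gene is differentially expressed at
   ``adjusted_p < alpha`` (default 0.05) with no fold-change cutoff.

This stage deliberately omits outlier (Cook's) filtering, independent
filtering and LFC shrinkage; it is a transparent, testable NB Wald test, not
a DESeq2 clone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import DesignError, ParameterError
from .counts import CountMatrix

__all__ = [
    "DEResult",
    "size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "adjust_and_call",
    "run_de",
    "deg_set",
]

_LN2 = float(np.log(2.0))
#: Dispersion floor (effectively Poisson).
MIN_DISPERSION = 1e-8


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2_fold_change: float
    p_value: float
    adjusted_p: float
    direction: Literal["up", "down", "ns"]


def size_factors(
    matrix: CountMatrix, fallback_positive_only: bool = True
) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean over samples; each sample's
    factor is the median over genes of count/reference.  Only genes with a
    positive count in every sample enter by default; if none exists (sparse
    low-depth data), the positive-counts-only variant takes the median over
    genes with a positive geometric mean, using each sample's positive
    entries.  Disable the fallback to get a hard error instead.
    """
    counts = matrix.counts.astype(float)
    all_positive = (counts > 0).all(axis=1)
    if all_positive.any():
        sub = counts[all_positive]
        log_ref = np.mean(np.log(sub), axis=1)
        ratios = np.log(sub) - log_ref[:, None]
        log_factors = np.median(ratios, axis=0)
    elif fallback_positive_only:
        with np.errstate(divide="ignore"):
            log_counts = np.where(counts > 0, np.log(counts), np.nan)
        log_ref = np.nanmean(log_counts, axis=1)
        usable = np.isfinite(log_ref)
        if not usable.any():
            raise DesignError("matrix is all zero; size factors undefined")
        ratios = log_counts[usable] - log_ref[usable, None]
        log_factors = np.nanmedian(ratios, axis=0)
        if np.isnan(log_factors).any():
            raise DesignError(
                "a sample has no positive counts; size factors undefined"
            )
    else:
        raise DesignError(
            "no gene has positive counts in all samples and fallback disabled"
        )
    log_factors = log_factors - log_factors.mean()  # geometric mean 1
    return np.exp(log_factors)


def _group_masks(labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise DesignError(f"expected exactly two groups, got {groups}")
    mask_a = labels == groups[0]
    mask_b = labels == groups[1]
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise DesignError("each group needs >= 2 samples")
    return mask_a, mask_b, groups


def estimate_dispersions(
    matrix: CountMatrix,
    factors: np.ndarray,
    labels: Sequence[str],
    shrink_weight: float = 0.6,
) -> np.ndarray:
    """Per-gene NB dispersion (variance = mu + alpha mu^2) estimates.

    Method of moments within each group on size-factor-normalised counts,
    pooled across groups by residual degrees of freedom, floored at
    ``MIN_DISPERSION`` and shrunk toward a mean–dispersion trend
    ``alpha(mu) = a0 + a1/mu`` fitted over genes (the classic parametric
    trend for RNA-seq dispersions).  ``shrink_weight`` in [0, 1] is the
    weight on the trend; it moderates the noisy per-gene moment estimates at
    small sample sizes.
    """
    if not (0.0 <= shrink_weight <= 1.0):
        raise ParameterError("shrink_weight must be in [0, 1]")
    mask_a, mask_b, _ = _group_masks(labels)
    norm = matrix.counts / np.asarray(factors, dtype=float)[None, :]

    raw = np.zeros(matrix.n_genes)
    means = np.zeros(matrix.n_genes)
    num = np.zeros(matrix.n_genes)
    den = 0.0
    for mask in (mask_a, mask_b):
        sub = norm[:, mask]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        means += m * mask.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / np.square(m)
        a = np.where(np.isfinite(a), a, 0.0)
        dof = mask.sum() - 1
        num += a * dof
        den += dof
    raw = np.clip(num / den, MIN_DISPERSION, None)
    means = means / (mask_a.sum() + mask_b.sum())

    trend = _dispersion_trend(means, raw)
    shrunk = (1.0 - shrink_weight) * raw + shrink_weight * trend
    return np.clip(shrunk, MIN_DISPERSION, None)


def _dispersion_trend(means: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu over moderately expressed genes.

    Falls back to the median raw dispersion when too few genes are usable.
    """
    usable = (means > 1.0) & (raw > MIN_DISPERSION * 10)
    if usable.sum() < 10:
        return np.full_like(raw, np.median(raw[means > 0]) if (means > 0).any()
                            else MIN_DISPERSION)
    X = np.column_stack([np.ones(usable.sum()), 1.0 / means[usable]])
    target = raw[usable]
    # one robustness pass: trim the most extreme residuals
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    resid = np.abs(target - X @ coef)
    keep = resid <= np.quantile(resid, 0.9)
    if keep.sum() >= 10:
        coef, *_ = np.linalg.lstsq(X[keep], target[keep], rcond=None)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.clip(means, 1e-8, None)
    return np.clip(trend, MIN_DISPERSION, None)


def nb_wald_test(
    matrix: CountMatrix,
    factors: np.ndarray,
    dispersions: np.ndarray,
    labels: Sequence[str],
    max_iter: int = 50,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Per-gene NB GLM Wald test of the two-group contrast.

    The model for gene g, sample j is ``y_gj ~ NB(mu_gj, alpha_g)`` with
    ``log mu_gj = log s_j + b0_g + b1_g * 1[j in group B]``; groups are taken
    in sorted label order, so ``b1`` is the log fold change of the second
    group over the first.  Fitting is IRLS with NB2 working weights
    ``mu/(1 + alpha mu)``, vectorised across genes (the design has only two
    columns, so the weighted normal equations are solved in closed form).

    Returns a DataFrame with columns gene_id, base_mean, log2_fold_change,
    se, stat, p_value, status.  All-zero genes are reported with status
    ``"untested"`` and missing p; non-converged genes with status
    ``"failed"``.  Two-sided p-values come from the standard normal.
    """
    mask_a, mask_b, groups = _group_masks(labels)
    factors = np.asarray(factors, dtype=float)
    alpha = np.asarray(dispersions, dtype=float)
    y = matrix.counts.astype(float)
    n_genes, n_samples = y.shape
    if factors.shape != (n_samples,):
        raise DesignError("factors length must match sample count")
    if alpha.shape != (n_genes,):
        raise DesignError("dispersions length must match gene count")

    offset = np.log(factors)[None, :]
    group = mask_b.astype(float)[None, :]

    nonzero = y.sum(axis=1) > 0
    # Initialise from group means of normalised counts (pseudocount for
    # group-wise zeros).
    norm = y / factors[None, :]
    mean_a = norm[:, mask_a].mean(axis=1)
    mean_b = norm[:, mask_b].mean(axis=1)
    eps = 0.5 / n_samples
    b0 = np.log(np.clip(mean_a, eps, None))
    b1 = np.log(np.clip(mean_b, eps, None)) - b0

    active = nonzero.copy()
    converged = np.zeros(n_genes, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = offset + b0[:, None] + b1[:, None] * group
        eta = np.clip(eta, -50, 50)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset) + (y - mu) / mu
        # Weighted least squares for design [1, g], per gene.
        s00 = w.sum(axis=1)
        s01 = (w * group).sum(axis=1)
        s11 = (w * group * group).sum(axis=1)
        t0 = (w * z).sum(axis=1)
        t1 = (w * z * group).sum(axis=1)
        det = s00 * s11 - s01 * s01
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        new_b0 = (s11 * t0 - s01 * t1) / det
        new_b1 = (s00 * t1 - s01 * t0) / det
        bad = ~np.isfinite(new_b0) | ~np.isfinite(new_b1)
        new_b0 = np.where(bad, b0, new_b0)
        new_b1 = np.where(bad, b1, new_b1)
        step = np.maximum(np.abs(new_b0 - b0), np.abs(new_b1 - b1))
        update = active & ~bad
        b0 = np.where(update, new_b0, b0)
        b1 = np.where(update, new_b1, b1)
        done = active & (step < tol)
        converged |= done
        active &= ~done & ~bad

    # Wald standard error of b1 from the final weighted information matrix.
    eta = np.clip(offset + b0[:, None] + b1[:, None] * group, -50, 50)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    s00 = w.sum(axis=1)
    s01 = (w * group).sum(axis=1)
    s11 = (w * group * group).sum(axis=1)
    det = s00 * s11 - s01 * s01
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = s00 / det
    se = np.sqrt(np.where(var_b1 > 0, var_b1, np.nan))
    stat = b1 / se
    p = 2.0 * stats.norm.sf(np.abs(stat))

    status = np.where(nonzero, np.where(converged, "ok", "failed"), "untested")
    tested = status == "ok"
    p = np.where(tested, p, np.nan)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "base_mean": norm.mean(axis=1),
            "log2_fold_change": b1 / _LN2,
            "se": se / _LN2,
            "stat": stat,
            "p_value": p,
            "status": status,
            "contrast": f"{groups[1]}_vs_{groups[0]}",
        }
    )


def adjust_and_call(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini–Hochberg adjustment and DEG calling at ``adjusted_p < alpha``.

    Genes with missing p (untested or failed) are excluded from the BH family
    and reported with direction ``"ns"`` and missing adjusted p.
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError("alpha must be in (0, 1)")
    out = results.copy()
    tested = out["p_value"].notna().to_numpy()
    adjusted = np.full(len(out), np.nan)
    if tested.any():
        adjusted[tested] = multipletests(
            out.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    out["adjusted_p"] = adjusted
    significant = tested & (adjusted < alpha)
    lfc = out["log2_fold_change"].to_numpy()
    out["direction"] = np.where(
        significant, np.where(lfc > 0, "up", "down"), "ns"
    )
    return out


def run_de(
    matrix: CountMatrix,
    labels: Sequence[str],
    alpha: float = 0.05,
    shrink_weight: float = 0.6,
) -> pd.DataFrame:
    """Full DE stage: size factors, dispersions, Wald test, BH calling."""
    factors = size_factors(matrix)
    disp = estimate_dispersions(matrix, factors, labels, shrink_weight)
    results = nb_wald_test(matrix, factors, disp, labels)
    return adjust_and_call(results, alpha=alpha)


def deg_set(called: pd.DataFrame) -> set[str]:
    """Gene IDs called differentially expressed (direction up or down)."""
    mask = called["direction"].isin(["up", "down"])
    return set(called.loc[mask, "gene_id"])
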