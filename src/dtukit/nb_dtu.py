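"""Per-transcript negative-binomial test of differential usage.

Each transcript is analyzed one-vs-rest: its counts are paired with the
summed counts of the other transcripts of its gene, and both series are
modeled as negative binomial (variance ``mu + alpha * mu^2``) in a GLM with
design ``~ sample + feature + condition:feature`` against the reduced
``~ sample + feature``.  The sample main effects absorb total gene
expression, the feature effect absorbs the baseline usage proportion, and
the single interaction coefficient captures a condition-specific change in
the proportion of this transcript relative to the rest of the gene.  The
likelihood-ratio statistic is referred to chi-squared with one degree of
freedom.

Dispersion is estimated per transcript by Cox-Reid adjusted profile
likelihood, a parametric trend ``alpha(mu) = a1/mu + a0`` is fitted across
transcripts, and the final value shrinks the per-transcript estimate toward
the trend (maximum a posteriori under a log-normal prior), leaving clear
outliers above the trend unshrunk.

Transcript p-values are aggregated per gene with the Sidak-adjusted minimum,
``p_gene = 1 - (1 - min_t p_t)^K``, and BH-corrected across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import chi2

from .dm_dtu import adjust_bh

__all__ = [
    "AugmentedCounts",
    "NBResults",
    "build_augmented_counts",
    "estimate_size_factors",
    "estimate_dispersions",
    "test_interaction_lrt",
    "per_gene_qvalue",
    "fit_nb",
]

_DISP_FLOOR = 1e-8
_DISP_CEIL = 10.0
_PRIOR_VAR_FLOOR = 0.25


@dataclass
class AugmentedCounts:
    """One-vs-rest count pairs: for each transcript, (this, others) x samples."""

    gene_ids: np.ndarray
    feature_ids: np.ndarray
    this_counts: np.ndarray   # [transcripts x samples]
    others_counts: np.ndarray  # [transcripts x samples]
    samples: pd.DataFrame

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass
class NBResults:
    """Transcript-level NB interaction test results and per-gene q-values."""

    transcript: pd.DataFrame  # featureID, groupID, lr, df, pvalue
    gene: pd.DataFrame        # gene, pvalue, qval
    size_factors: np.ndarray
    dispersions: np.ndarray


def build_augmented_counts(ds) -> AugmentedCounts:
    """Round counts to integers and build (this, others) pairs per transcript."""
    counts = np.rint(ds.counts)
    totals = np.zeros_like(counts)
    for _, rows in ds.gene_groups():
        totals[rows] = counts[rows].sum(axis=0)
    return AugmentedCounts(
        gene_ids=np.asarray(ds.gene_ids),
        feature_ids=np.asarray(ds.transcript_ids),
        this_counts=counts,
        others_counts=totals - counts,
        samples=ds.samples,
    )


def estimate_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Rows with a zero in any sample are excluded from the reference geometric
    means; at least one all-positive row is required.
    """
    counts = np.asarray(counts, dtype=float)
    positive = np.all(counts > 0, axis=1)
    if not positive.any():
        raise ValueError("size-factor estimation needs at least one all-positive row")
    logc = np.log(counts[positive])
    ref = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - ref, axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def _design_matrices(n_samples: int, condition: np.ndarray):
    """Full and reduced designs for one augmented (this, others) pair.

    Rows are ordered (this, sample 1..n) then (others, sample 1..n).
    Columns: intercept, sample dummies 2..n, feature indicator (this), and
    for the full design the condition2:this interaction.
    """
    n = n_samples
    levels = list(dict.fromkeys(condition))
    if len(levels) != 2:
        raise ValueError("the NB interaction test supports exactly two condition groups")
    cond2 = (np.asarray(condition) == levels[1]).astype(float)
    sample_dummies = np.zeros((n, n - 1))
    for i in range(1, n):
        sample_dummies[i, i - 1] = 1.0
    block = np.column_stack([np.ones(n), sample_dummies])
    X_common = np.vstack([block, block])
    feature = np.concatenate([np.ones(n), np.zeros(n)])
    interaction = np.concatenate([cond2, np.zeros(n)])
    X_reduced = np.column_stack([X_common, feature])
    X_full = np.column_stack([X_reduced, interaction])
    return X_full, X_reduced


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB log-likelihood (mean/dispersion parameterization, full constant)."""
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-10)
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + y * np.log(alpha * mu / (1 + alpha * mu))
            - r * np.log1p(alpha * mu)
        )
    )


def _fit_glm(y, X, offset, alpha):
    fam = sm.families.NegativeBinomial(alpha=max(alpha, _DISP_FLOOR))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=fam, offset=offset)
        return model.fit(maxiter=100, tol=1e-8)


def _cr_adjusted_profile(y, X, offset, mu):
    """Return f(alpha) = CR-adjusted NB profile log-likelihood with mu fixed."""

    def f(alpha):
        w = mu / (1.0 + alpha * mu)
        xtwx = X.T @ (X * w[:, None])
        sign, logdet = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return -np.inf
        return _nb_loglik(y, mu, alpha) - 0.5 * logdet

    return f


def _mle_dispersion(y, X, offset) -> tuple[float, float]:
    """Cox-Reid adjusted dispersion MLE; returns (alpha_hat, mean_count)."""
    try:
        fit0 = _fit_glm(y, X, offset, alpha=0.1)
        mu = np.asarray(fit0.mu)
    except Exception:
        mu = np.maximum(np.full_like(y, y.mean(), dtype=float), 0.1)
    alpha = 0.1
    for _ in range(2):
        f = _cr_adjusted_profile(y, X, offset, mu)
        res = optimize.minimize_scalar(
            lambda la: -f(np.exp(la)),
            bounds=(np.log(_DISP_FLOOR), np.log(_DISP_CEIL)),
            method="bounded", options={"xatol": 1e-4},
        )
        alpha = float(np.exp(res.x))
        try:
            fit = _fit_glm(y, X, offset, alpha)
            mu = np.asarray(fit.mu)
        except Exception:
            break
    return alpha, float(np.mean(mu))


def _fit_trend(means: np.ndarray, disps: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a1/mu + a0 by iteratively reweighted least squares.

    Weights follow a gamma-family GLM (1/fitted^2); transcripts with
    dispersion at the optimization floor are excluded from the fit.
    """
    valid = means > 0
    if valid.sum() < 3 or (disps[valid] > 10 * _DISP_FLOOR).sum() < 3:
        return 0.0, float(np.median(disps))
    x_all = np.column_stack([np.ones(valid.sum()), 1.0 / means[valid]])
    # floor-level estimates enter as zero: "no overdispersion" is data too
    y_all = np.where(disps[valid] > 10 * _DISP_FLOOR, disps[valid], 0.0)
    coef = np.array([max(np.median(y_all), 1e-6), 0.0])
    prev_use = None
    for _ in range(10):
        # exclude points far above the current trend before refitting, so a
        # single dispersion outlier cannot drag the whole curve
        fitted_all = np.maximum(x_all @ coef, 1e-10)
        use = y_all < 15 * fitted_all
        if use.sum() < 3:
            use = np.ones(len(y_all), dtype=bool)
        x, y = x_all[use], y_all[use]
        fitted = np.maximum(x @ coef, 1e-10)
        w = 1.0 / fitted**2
        wx = x * w[:, None]
        coef_new, *_ = np.linalg.lstsq(wx.T @ x, wx.T @ y, rcond=None)
        coef_new = np.maximum(coef_new, [1e-8, 0.0])
        converged = np.allclose(coef_new, coef, rtol=1e-6) and (
            prev_use is not None and np.array_equal(use, prev_use)
        )
        coef, prev_use = coef_new, use
        if converged:
            break
    a0, a1 = float(coef[0]), float(coef[1])
    return a1, a0


def estimate_dispersions(aug: AugmentedCounts, size_factors: np.ndarray) -> np.ndarray:
    """Final per-transcript dispersions: MLE, trend, then MAP shrinkage.

    The prior variance of log dispersion around the trend is estimated from
    the spread of the log residuals (MAD-based, floored at 0.25).  Estimates
    more than two prior SDs above the trend are treated as outliers and kept
    at their MLE.
    """
    condition = aug.samples["condition"].to_numpy()
    n = len(aug.samples)
    X_full, _ = _design_matrices(n, condition)
    offset = np.log(np.concatenate([size_factors, size_factors]))
    m = aug.n_features
    mle = np.empty(m)
    means = np.empty(m)
    for t in range(m):
        y = np.concatenate([aug.this_counts[t], aug.others_counts[t]])
        mle[t], means[t] = _mle_dispersion(y, X_full, offset)

    a1, a0 = _fit_trend(means, mle)
    trend = np.maximum(a1 / np.maximum(means, 1e-10) + a0, _DISP_FLOOR)

    ok = mle > 10 * _DISP_FLOOR
    if ok.sum() >= 3:
        resid = np.log(mle[ok]) - np.log(trend[ok])
        mad = np.median(np.abs(resid - np.median(resid)))
        prior_var = max(_PRIOR_VAR_FLOOR, (1.4826 * mad) ** 2)
    else:
        prior_var = _PRIOR_VAR_FLOOR

    final = np.empty(m)
    for t in range(m):
        if np.log(mle[t]) > np.log(trend[t]) + 2.0 * np.sqrt(prior_var):
            final[t] = mle[t]  # outlier above the trend: no shrinkage
            continue
        y = np.concatenate([aug.this_counts[t], aug.others_counts[t]])
        try:
            fit = _fit_glm(y, X_full, offset, max(mle[t], _DISP_FLOOR))
            mu = np.asarray(fit.mu)
        except Exception:
            mu = np.maximum(np.full_like(y, y.mean(), dtype=float), 0.1)
        f = _cr_adjusted_profile(y, X_full, offset, mu)
        lt = np.log(trend[t])

        def neg_post(la):
            return -(f(np.exp(la)) - (la - lt) ** 2 / (2.0 * prior_var))

        res = optimize.minimize_scalar(
            neg_post, bounds=(np.log(_DISP_FLOOR), np.log(_DISP_CEIL)),
            method="bounded", options={"xatol": 1e-4},
        )
        final[t] = float(np.exp(res.x))
    return np.maximum(final, _DISP_FLOOR)


def test_interaction_lrt(
    aug: AugmentedCounts, size_factors: np.ndarray, dispersions: np.ndarray
) -> pd.DataFrame:
    """LRT of the condition:feature interaction per transcript (df = 1).

    Non-converged fits yield a missing p-value; sanitize downstream.
    """
    condition = aug.samples["condition"].to_numpy()
    n = len(aug.samples)
    X_full, X_reduced = _design_matrices(n, condition)
    offset = np.log(np.concatenate([size_factors, size_factors]))
    rows = []
    for t in range(aug.n_features):
        y = np.concatenate([aug.this_counts[t], aug.others_counts[t]])
        alpha = float(dispersions[t])
        try:
            full = _fit_glm(y, X_full, offset, alpha)
            red = _fit_glm(y, X_reduced, offset, alpha)
            lr = max(0.0, 2.0 * (full.llf - red.llf))
            p = float(chi2.sf(lr, 1)) if np.isfinite(lr) else np.nan
        except Exception:
            lr, p = np.nan, np.nan
        rows.append((aug.feature_ids[t], aug.gene_ids[t], lr, 1, p))
    return pd.DataFrame(rows, columns=["featureID", "groupID", "lr", "df", "pvalue"])


def per_gene_qvalue(transcript_p: np.ndarray, gene_ids: np.ndarray) -> pd.DataFrame:
    """Sidak-aggregated per-gene p-values with BH correction across genes.

    ``p_gene = 1 - (1 - min_t p_t)^K`` over the gene's K tested transcripts;
    missing transcript p-values are ignored in the minimum (a gene with all
    p missing gets p_gene = 1).
    """
    df = pd.DataFrame({"gene": gene_ids, "p": np.asarray(transcript_p, dtype=float)})
    rows = []
    for gene, sub in df.groupby("gene", sort=False):
        pvals = sub["p"].dropna().to_numpy()
        K = len(sub)
        if pvals.size == 0:
            rows.append((gene, 1.0))
            continue
        pmin = float(np.clip(pvals.min(), 0.0, 1.0))
        rows.append((gene, float(1.0 - (1.0 - pmin) ** K)))
    out = pd.DataFrame(rows, columns=["gene", "pvalue"])
    out["qval"] = adjust_bh(out["pvalue"].to_numpy())
    return out


def fit_nb(ds) -> NBResults:
    """Run the full NB one-vs-rest analysis on a filtered dataset."""
    aug = build_augmented_counts(ds)
    sf = estimate_size_factors(np.rint(ds.counts))
    disp = estimate_dispersions(aug, sf)
    tx = test_interaction_lrt(aug, sf, disp)
    gene = per_gene_qvalue(tx["pvalue"].to_numpy(), tx["groupID"].to_numpy())
    return NBResults(transcript=tx, gene=gene, size_factors=sf, dispersions=disp)
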