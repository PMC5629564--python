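"""Differential-expression testing under the signal+background model.

Two tests are provided, routed per gene by the pooled count size:

* ``exact_test`` — a moderated Fisher-style exact test.  With pooled group
  counts x and y, every split (a, b) of the total n = x + y is assigned the
  null probability p(a, b) = P_A(a) * P_B(b), where P_A and P_B are the
  Delaporte laws of the group sums under an equal-signal-mean null; the
  p-value is the probability mass of all splits no more likely than the
  observed one, normalized by the total mass on the line a + b = n.
* ``beta_approx_test`` — a fast beta-distribution approximation for genes
  with large counts: the observed proportion x/z is scored against a beta
  density whose shape parameters derive from the pooled per-sample mean.
  The printed expression is a density and can exceed 1; it is clamped into
  (0, 1].

``run_de`` wires normalization, per-group estimation, routing and BH
adjustment into a per-gene result table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .estimation import size_factors
from .model import DelaporteParams, delaporte_logpmf_vector, delaporte_pmf_vector

logger = logging.getLogger(__name__)

__all__ = [
    "exact_test",
    "beta_approx_test",
    "null_pooled_params",
    "run_de",
    "bh_adjust",
    "filter_results",
]

_EPS = 1e-8
# relative slack for the "no more likely than observed" comparison, so exact
# floating ties (symmetric splits) are always included
_TIE_REL = 1e-8


def exact_test(
    x: int, y: int, paramsA: DelaporteParams, paramsB: DelaporteParams
) -> float:
    """Moderated exact test p-value for pooled counts (x, y).

    ``paramsA``/``paramsB`` are the null-rescaled Delaporte parameters of the
    *pooled group sums* (see :func:`null_pooled_params`).  Enumerates all
    a + b = x + y; returns 1.0 when x + y == 0 by convention.
    """
    x, y = int(x), int(y)
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    n = x + y
    if n == 0:
        return 1.0
    pa = delaporte_pmf_vector(n, paramsA)
    pb = delaporte_pmf_vector(n, paramsB)
    probs = pa * pb[::-1]  # probs[a] = P_A(a) * P_B(n - a)
    denom = probs.sum()
    obs = probs[x]
    if denom <= 0.0 or obs <= 0.0:
        return _exact_test_logspace(x, n, paramsA, paramsB)
    p = probs[probs <= obs * (1.0 + _TIE_REL)].sum() / denom
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def _exact_test_logspace(
    x: int, n: int, paramsA: DelaporteParams, paramsB: DelaporteParams
) -> float:
    la = delaporte_logpmf_vector(n, paramsA)
    lb = delaporte_logpmf_vector(n, paramsB)
    lp = la + lb[::-1]
    obs = lp[x]
    if not np.isfinite(obs):
        return 1.0
    keep = lp <= obs + np.log1p(_TIE_REL)
    num = special.logsumexp(lp[keep])
    den = special.logsumexp(lp)
    return float(min(np.exp(num - den), 1.0))


def beta_approx_test(x: int, y: int, n1: int, n2: int) -> float:
    """Beta-approximation p-value for large pooled counts (x, y).

    z = x + y, mu = z/(n1+n2); beta shapes a = n1*mu/(1 + n1/mu) and
    b = n2*mu/(1 + n2/mu); the evaluation point is (x+0.5)/z below the beta
    median, (x-0.5)/z above it; p = 2 * k^(a-1) (1-k)^(b-1) / B(a, b),
    clamped into (0, 1].  If the observation straddles the median, p = 1.
    """
    p = _beta_approx_vec(np.array([x]), np.array([y]), n1, n2)
    return float(p[0])


def _beta_approx_vec(x: np.ndarray, y: np.ndarray, n1: int, n2: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    if n1 < 1 or n2 < 1:
        raise ValueError("n1, n2 must be >= 1")
    z = x + y
    out = np.ones_like(z, dtype=float)
    ok = z > 0
    if not ok.any():
        return out
    zo, xo = z[ok], x[ok]
    mu = zo / (n1 + n2)
    a = n1 * mu / (1.0 + n1 / mu)
    b = n2 * mu / (1.0 + n2 / mu)
    med = special.betaincinv(a, b, 0.5)
    k_lo = (xo + 0.5) / zo
    k_hi = (xo - 0.5) / zo
    k = np.where(k_lo < med, k_lo, np.where(k_hi > med, k_hi, np.nan))
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = (
            np.log(2.0)
            + (a - 1.0) * np.log(k)
            + (b - 1.0) * np.log1p(-k)
            - special.betaln(a, b)
        )
    p = np.exp(logp)
    p = np.where(np.isnan(k), 1.0, p)  # straddle: observation at the center
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    res = out.copy()
    res[ok] = p
    return res


def null_pooled_params(
    mu0: float, beta: float, lam: float, n_samples: int
) -> DelaporteParams:
    """Delaporte law of a group's pooled count under the equal-mean null.

    The sum of ``n_samples`` iid Delaporte draws with per-sample signal mean
    ``mu0``, gamma scale ``beta`` (the group's own dispersion) and background
    mean ``lam`` is Delaporte with NB shape scaled by ``n_samples`` and
    Poisson mean ``n_samples * lam``.
    """
    beta = max(beta, _EPS)
    mu0 = max(mu0, _EPS)
    return DelaporteParams(
        alpha=n_samples * mu0 / beta, beta=beta, lam=max(n_samples * lam, 0.0)
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def _group_moments(mat: np.ndarray, bg: np.ndarray):
    mu = mat.mean(axis=1)
    var = mat.var(axis=1, ddof=1)
    lam = bg.mean(axis=1)
    mu_s = np.maximum(mu - lam, _EPS)
    v_s = np.maximum(var - lam, mu_s * (1.0 + _EPS))
    beta = v_s / mu_s - 1.0
    return mu, mu_s, beta, lam


def run_de(
    X: pd.DataFrame,
    B: pd.DataFrame,
    groups,
    est_method: str = "np",
    big_count: int = 900,
    dispersion_share: str = "maximum",
) -> pd.DataFrame:
    """Per-gene differential-expression test between two groups.

    Parameters
    ----------
    X, B
        Congruent gene x sample matrices of observed exonic and background
        counts (same genes, same samples).
    groups
        Two-level sample labels, one per column.
    est_method
        ``"np"`` (moment matching, default) or ``"mle"`` (per-gene BFGS fit;
        slower, intended for larger sample sizes).
    big_count
        Pooled-count threshold routing a gene from the exact test to the
        beta approximation.
    dispersion_share
        How the signal dispersion entering the null is formed in the
        non-parametric route: ``"maximum"`` (default; the larger of the
        per-gene moment estimate and the across-gene mean-dispersion trend,
        conservative), ``"fit-only"`` (the trend alone), or ``"gene-est"``
        (raw per-gene moments; anti-conservative at small m).

    Returns
    -------
    DataFrame indexed by gene with columns mean_A, mean_B, log2FC, pval,
    padj, test.  Genes with zero total count get p = padj = 1 and are
    excluded from the BH denominator.
    """
    if not X.index.equals(B.index) or not X.columns.equals(B.columns):
        raise ValueError("X and B must share genes and samples")
    groups = np.asarray(groups)
    if groups.size != X.shape[1]:
        raise ValueError("one group label per sample required")
    levels = pd.unique(groups)
    if levels.size != 2:
        raise ValueError(f"exactly two group levels required, got {levels.size}")
    if est_method not in ("np", "mle"):
        raise ValueError("est_method must be 'np' or 'mle'")
    gA = groups == levels[0]
    gB = groups == levels[1]
    n1, n2 = int(gA.sum()), int(gB.sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs >= 2 samples for estimation")
    if est_method == "np" and min(n1, n2) > 10:
        logger.info(
            "both groups have > 10 samples; est_method='mle' is worth considering"
        )

    sf = size_factors(X.to_numpy())
    xn = X.to_numpy(dtype=float) / sf
    bn = B.to_numpy(dtype=float) / sf

    muA, muSA, betaA, lamA = _group_moments(xn[:, gA], bn[:, gA])
    muB, muSB, betaB, lamB = _group_moments(xn[:, gB], bn[:, gB])
    mu0 = (n1 * muSA + n2 * muSB) / (n1 + n2)

    if est_method == "np" and dispersion_share != "gene-est":
        # share dispersion across genes: per-gene moment dispersions are far
        # too noisy at small m; fit phi(mu) = a0 + a1/mu to bin medians
        from .estimation import fit_dispersion_trend

        expressed = mu0 > 1.0
        phi_raw = np.maximum((betaA / np.maximum(muSA, _EPS) + betaB / np.maximum(muSB, _EPS)) / 2.0, _EPS)
        _, _, phi_fit = fit_dispersion_trend(mu0[expressed], phi_raw[expressed])
        phi_use = np.full_like(phi_raw, _EPS)
        if dispersion_share == "maximum":
            phi_use[expressed] = np.maximum(phi_raw[expressed], phi_fit)
        elif dispersion_share == "fit-only":
            phi_use[expressed] = phi_fit
        else:
            raise ValueError(
                "dispersion_share must be 'maximum', 'fit-only' or 'gene-est'"
            )
        betaA = betaB = np.maximum(phi_use * mu0, _EPS)

    if est_method == "mle":
        from .estimation import GeneObservation, estimate_mle

        for i in range(xn.shape[0]):
            if xn[i].sum() == 0:
                continue
            for mask, muS, beta, lam in ((gA, muSA, betaA, lamA), (gB, muSB, betaB, lamB)):
                res = estimate_mle(
                    GeneObservation(np.rint(xn[i, mask]), np.rint(bn[i, mask]))
                )
                muS[i] = res.params.alpha * res.params.beta
                beta[i] = res.params.beta
                lam[i] = res.params.lam

    x = np.rint(xn[:, gA].sum(axis=1)).astype(np.int64)
    y = np.rint(xn[:, gB].sum(axis=1)).astype(np.int64)
    tot = x + y
    # recompute after the MLE route may have updated the group signal means
    mu0 = (n1 * muSA + n2 * muSB) / (n1 + n2)

    pval = np.ones(len(X), dtype=float)
    test = np.full(len(X), "none", dtype=object)
    beta_mask = tot > big_count
    exact_mask = (tot > 0) & ~beta_mask

    if beta_mask.any():
        pval[beta_mask] = _beta_approx_vec(x[beta_mask], y[beta_mask], n1, n2)
        test[beta_mask] = "beta"
    for i in np.flatnonzero(exact_mask):
        pA = null_pooled_params(mu0[i], betaA[i], lamA[i], n1)
        pB = null_pooled_params(mu0[i], betaB[i], lamB[i], n2)
        pval[i] = exact_test(x[i], y[i], pA, pB)
    test[exact_mask] = "exact"

    padj = np.ones(len(X), dtype=float)
    tested = tot > 0
    if tested.any():
        padj[tested] = bh_adjust(pval[tested])

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(muB / muA)
    return pd.DataFrame(
        {
            "mean_A": muA,
            "mean_B": muB,
            "log2FC": log2fc,
            "pval": pval,
            "padj": padj,
            "test": test,
        },
        index=X.index.rename("gene_id"),
    )


def filter_results(
    results: pd.DataFrame,
    fc_min: float = 1.5,
    expr_quantile: float = 0.5,
    padj_max: float = 0.1,
) -> pd.DataFrame:
    """Keep genes with |fold change| >= fc_min (either direction), mean
    expression above the given quantile of all genes' means, and
    padj < padj_max."""
    if results.empty:
        raise ValueError("results must be non-empty")
    base = (results["mean_A"] + results["mean_B"]) / 2.0
    if expr_quantile > 0:
        expr_ok = (base > base.quantile(expr_quantile)).to_numpy()
    else:
        expr_ok = np.ones(len(results), dtype=bool)
    with np.errstate(invalid="ignore"):
        fc_ok = np.power(2.0, np.abs(results["log2FC"].to_numpy())) >= fc_min
    fc_ok = fc_ok | np.isinf(results["log2FC"].to_numpy())
    keep = fc_ok & expr_ok & (results["padj"] < padj_max).to_numpy()
    return results.loc[keep]
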