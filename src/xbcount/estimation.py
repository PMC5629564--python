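"""Per-gene parameter estimation and depth normalization.

Two estimation routes for the Delaporte parameters (alpha, beta, lam):

* ``estimate_nonparametric`` — the default moment-matching scheme: the
  Poisson background mean is estimated from the measured background counts,
  and the NB signal moments are recovered by subtracting the Poisson
  contribution from the mean and variance of the depth-normalized observed
  counts.  No iteration; works from m >= 2 replicates.
* ``estimate_mle`` — joint maximum likelihood under the full convolution
  likelihood (Delaporte for X times Poisson for B), optimized over
  (log alpha, log beta, log lam) with BFGS and numerical gradients.
  Preferred when the number of replicates is large (> 10).

Depth normalization uses median-of-ratios size factors rescaled to
geometric mean 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .model import DelaporteParams, delaporte_logpmf_vector

__all__ = [
    "GeneObservation",
    "NormalizationError",
    "size_factors",
    "estimate_lambda",
    "estimate_nonparametric",
    "estimate_mle",
    "fit_dispersion_trend",
    "MLEResult",
    "read_counts",
    "write_counts",
]

_EPS = 1e-8


class NormalizationError(ValueError):
    pass


@dataclass
class GeneObservation:
    """One gene's observed exonic counts ``x`` and background counts ``b``
    across the same m samples."""

    x: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.x.shape != self.b.shape or self.x.ndim != 1 or self.x.size < 1:
            raise ValueError("x and b must be 1-d arrays of equal length >= 1")
        if (self.x < 0).any() or (self.b < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def m(self) -> int:
        return self.x.size


def size_factors(counts: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample j, the factor is the median over genes (restricted to
    genes positive in every sample) of ``count_ij / geomean_i``.  Raises
    :class:`NormalizationError` when no gene is positive in all samples.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2:
        raise ValueError("counts must be 2-d (genes x samples)")
    if mat.shape[1] == 1:
        return np.ones(1)
    pos = (mat > 0).all(axis=1)
    if not pos.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; consider a "
            "pseudo-reference (e.g. add a pseudocount) before normalizing"
        )
    logs = np.log(mat[pos])
    log_geomean = logs.mean(axis=1, keepdims=True)
    log_sf = np.median(logs - log_geomean, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return np.exp(log_sf)


def estimate_lambda(obs: GeneObservation, sf: np.ndarray | None = None) -> float:
    """Poisson background mean: mean of size-factor-normalized background counts."""
    sf = np.ones(obs.m) if sf is None else np.asarray(sf, dtype=float)
    return float(np.mean(obs.b / sf))


def estimate_nonparametric(
    obs: GeneObservation, sf: np.ndarray | None = None
) -> DelaporteParams:
    """Moment-matching estimate of (alpha, beta, lam).

    With normalized counts x~_j = x_j / sf_j:

    * lam-hat   = mean(b~)
    * mu_S-hat  = max(mean(x~) - lam-hat, eps)
    * v_S-hat   = max(var(x~) - lam-hat, mu_S-hat * (1 + eps))   (ddof=1)
    * beta-hat  = v_S/mu_S - 1,  alpha-hat = mu_S / beta-hat

    The variance floor keeps beta strictly positive; an under-dispersed gene
    collapses to a near-Poisson signal (beta ~ eps * mu_S).
    """
    if obs.m < 2:
        raise ValueError("non-parametric estimation needs m >= 2 replicates")
    sf = np.ones(obs.m) if sf is None else np.asarray(sf, dtype=float)
    xn = obs.x / sf
    lam = estimate_lambda(obs, sf)
    mu_s = max(float(xn.mean()) - lam, _EPS)
    v_s = max(float(xn.var(ddof=1)) - lam, mu_s * (1.0 + _EPS))
    beta = v_s / mu_s - 1.0
    alpha = mu_s / beta
    return DelaporteParams(alpha=alpha, beta=beta, lam=lam)


def fit_dispersion_trend(
    mu: np.ndarray, phi: np.ndarray, n_bins: int = 20, floor: float = 1e-8
):
    """Robust across-gene dispersion-vs-mean trend: phi(mu) = a0 + a1/mu.

    Per-gene dispersion estimates from few replicates are individually
    useless but informative in aggregate; genes are binned by log mean and
    the trend is least-squares fitted to the bin medians, which resists the
    heavy right tail of raw moment dispersions.  Returns ``(a0, a1,
    phi_fitted)``; with too few usable genes the raw values are returned
    unfitted.
    """
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    ok = np.isfinite(mu) & np.isfinite(phi) & (mu > 0)
    if ok.sum() < 3 * n_bins:
        return np.nan, np.nan, np.maximum(phi, floor)
    lm = np.log10(mu[ok])
    edges = np.quantile(lm, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.digitize(lm, edges) - 1, 0, n_bins - 1)
    med_phi = np.array([np.median(phi[ok][idx == i]) for i in range(n_bins)])
    med_mu = np.array([np.median(mu[ok][idx == i]) for i in range(n_bins)])
    design = np.vstack([np.ones(n_bins), 1.0 / med_mu]).T
    (a0, a1), *_ = np.linalg.lstsq(design, med_phi, rcond=None)
    fitted = np.maximum(a0 + a1 / np.maximum(mu, floor), floor)
    return float(a0), float(a1), fitted


@dataclass
class MLEResult:
    params: DelaporteParams
    loglik: float
    converged: bool
    n_iter: int = 0


def _neg_loglik(theta: np.ndarray, x: np.ndarray, b: np.ndarray) -> float:
    alpha, beta, lam = np.exp(theta)
    lam = max(lam, 1e-12)
    p = DelaporteParams(alpha=alpha, beta=beta, lam=lam)
    n = int(x.max())
    logpmf = delaporte_logpmf_vector(n, p)
    ll_x = logpmf[x.astype(int)].sum()
    ll_b = float(np.sum(b * np.log(lam) - lam - gammaln(b + 1)))
    return -(ll_x + ll_b)


def estimate_mle(
    obs: GeneObservation,
    init: DelaporteParams | None = None,
    sf: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> MLEResult:
    """Joint MLE of (alpha, beta, lam) under the convolution likelihood.

    Optimizes over log parameters (positivity for free) by BFGS with
    numerical gradients, starting from ``init`` or the moment estimate.
    Counts are normalized by ``sf`` and rounded to integers first.  Never
    raises on non-convergence: the best point found is returned with
    ``converged=False``.
    """
    if obs.m < 2:
        raise ValueError("MLE needs m >= 2 replicates")
    sf = np.ones(obs.m) if sf is None else np.asarray(sf, dtype=float)
    x = np.rint(obs.x / sf)
    b = np.rint(obs.b / sf)
    if init is None:
        init = estimate_nonparametric(GeneObservation(x, b))
    theta0 = np.log([init.alpha, init.beta, max(init.lam, 1e-6)])
    ll0 = -_neg_loglik(theta0, x, b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(
            _neg_loglik,
            theta0,
            args=(x, b),
            method="BFGS",
            options={"maxiter": max_iter, "gtol": tol},
        )
    alpha, beta, lam = np.exp(res.x)
    best = DelaporteParams(alpha=alpha, beta=beta, lam=max(lam, 0.0))
    ll = -res.fun
    if not np.isfinite(ll) or ll < ll0 - tol:
        # optimizer wandered; keep the better of init and result
        return MLEResult(params=init, loglik=ll0, converged=False, n_iter=res.nit)
    return MLEResult(params=best, loglik=ll, converged=bool(res.success), n_iter=res.nit)


# ---------------------------------------------------------------------------
# delimited-text count matrix I/O


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample count matrix from TSV/CSV (first column gene IDs,
    header row of sample IDs, integer cells)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty count matrix")
    if not df.index.is_unique:
        raise ValueError(f"{path}: duplicate gene IDs")
    mat = df.apply(pd.to_numeric)
    if (mat.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return mat.astype(np.int64)


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")
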