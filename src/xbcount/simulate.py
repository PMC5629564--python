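"""Synthetic two-group RNA-seq experiments with controlled background noise.

The generator mirrors a standard bulk RNA-seq benchmark design: per-gene NB
signal parameters are sampled from a pool emulating estimates from a real
dataset (log-normal means, a dispersion-vs-mean trend with jitter, a small
Poisson background proportional to the mean, with low-expression genes and
the top-decile dispersions discarded); a fraction of genes receives a fold
change in condition 2; background noise is Poisson at baseline, with a
fixed number M of genes stressed by an inflated-noise law whose mean is
itself Poisson(lam + NF) and which adds Normal dispersion sigma.

Defaults are the benchmark study conditions: 5000 genes, 10% DE at
1.5-fold, 3 samples per group, M = 100 inflated genes, sigma = 3, and a
noise factor NF in {0, 7, 20} for low/intermediate/high background noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "make_parameter_pool",
    "simulate_signal",
    "simulate_background",
    "simulate_experiment",
    "truth_frames",
]


@dataclass(frozen=True)
class SimConfig:
    """One simulation scenario."""

    n_genes: int = 5000
    prop_de: float = 0.10
    fold_change: float = 1.5
    n_per_group: int = 3
    M: int = 100
    sigma: float = 3.0
    NF: float = 0.0
    n_reps: int = 100
    seed: int = 0
    # 'hybrid-all': every gene's background follows the hybrid law
    #   round(Normal(mu, sigma)), mu ~ Poisson(lam + NF)  (M/100 = scale 1);
    # 'inflated-subset': baseline Poisson(lam) everywhere, only M random
    #   genes receive the hybrid law.
    noise_model: str = "hybrid-all"
    # parameter-pool generator knobs (stand-in for real-data estimates)
    pool_log10_mean: float = 2.0
    pool_log10_sd: float = 0.8
    pool_mean_range: tuple[float, float] = (10.0, 1e5)
    pool_disp_base: float = 0.1
    pool_disp_slope: float = 4.0
    pool_disp_jitter_sd: float = 0.3
    pool_bg_frac: tuple[float, float] = (0.01, 0.05)

    def __post_init__(self) -> None:
        if not (0 < self.prop_de < 1):
            raise ValueError("prop_de must be in (0, 1)")
        if not (self.fold_change >= 1):
            # fold_change == 1 is the null limit (DE labels without effect)
            raise ValueError("fold_change must be >= 1")
        if self.NF < 0:
            raise ValueError("NF must be >= 0")
        if self.M > self.n_genes:
            raise ValueError("M must not exceed n_genes")
        if self.n_per_group < 1 or self.n_genes < 1 or self.n_reps < 1:
            raise ValueError("counts must be positive")
        if self.noise_model not in ("hybrid-all", "inflated-subset"):
            raise ValueError("noise_model must be 'hybrid-all' or 'inflated-subset'")


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    de: np.ndarray  # bool, per gene
    mu1: np.ndarray  # true signal mean, condition 1
    mu2: np.ndarray  # true signal mean, condition 2
    dispersion: np.ndarray  # NB dispersion phi (var = mu + phi mu^2)
    lam: np.ndarray  # Poisson background mean
    inflated: np.ndarray  # bool, gene got the stressed noise law
    S: np.ndarray  # true signal counts
    B_true: np.ndarray  # noise actually added to X
    B_obs: np.ndarray  # independently measured background
    X: np.ndarray  # observed counts, S + B_true
    groups: np.ndarray  # sample labels

    @property
    def signal_mean(self) -> np.ndarray:
        """Per-gene true signal mean averaged over conditions (strata basis)."""
        return (self.mu1 + self.mu2) / 2.0

    @property
    def r(self) -> np.ndarray:
        """NB size of the condition-1 signal."""
        return 1.0 / self.dispersion

    @property
    def p(self) -> np.ndarray:
        """NB success probability of the condition-1 signal."""
        return 1.0 / (1.0 + self.dispersion * self.mu1)


def make_parameter_pool(
    n: int, seed: int | np.random.Generator, config: SimConfig | None = None
) -> pd.DataFrame:
    """Per-gene (mean, dispersion, lam) pool emulating real-data estimates.

    Means are log-normal (log10 mean 2.0, log10 sd 0.8) truncated to
    [10, 1e5]; dispersions follow the trend ``0.1 + 4/mean`` with log-normal
    jitter (sd 0.3 on the log scale); the background mean is 1-5% of the
    signal mean.  Genes in the top 10% of dispersion (of the pre-filter
    draw) and genes with mean < 10 are discarded and re-drawn.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = cfg.pool_mean_range

    def draw(k: int):
        mean = 10.0 ** rng.normal(cfg.pool_log10_mean, cfg.pool_log10_sd, size=k)
        while True:  # truncate by redraw
            bad = (mean < lo) | (mean > hi)
            if not bad.any():
                break
            mean[bad] = 10.0 ** rng.normal(cfg.pool_log10_mean, cfg.pool_log10_sd, size=bad.sum())
        disp = (cfg.pool_disp_base + cfg.pool_disp_slope / mean) * np.exp(
            rng.normal(0.0, cfg.pool_disp_jitter_sd, size=k)
        )
        lam = rng.uniform(*cfg.pool_bg_frac, size=k) * mean
        return mean, disp, lam

    # over-draw, establish the pre-filter dispersion decile, keep the rest
    k0 = max(int(np.ceil(n / 0.9)) + 10, 20)
    mean, disp, lam = draw(k0)
    q90 = np.quantile(disp, 0.9)
    keep = disp < q90
    while keep.sum() < n:
        m2, d2, l2 = draw(k0)
        mean = np.concatenate([mean, m2])
        disp = np.concatenate([disp, d2])
        lam = np.concatenate([lam, l2])
        keep = disp < q90
    idx = np.flatnonzero(keep)[:n]
    return pd.DataFrame(
        {"mean": mean[idx], "dispersion": disp[idx], "lam": lam[idx]}
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray, size) -> np.ndarray:
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size=size)


def simulate_signal(
    pool: pd.DataFrame, config: SimConfig, rng: np.random.Generator
):
    """Draw the true-signal matrix S and DE labels.

    Genes are sampled from the pool with replacement; ``round(n_genes *
    prop_de)`` genes get the fold change in condition 2 (half up, half
    down).  Returns (S, de, mu1, mu2, dispersion, lam).
    """
    n = config.n_genes
    idx = rng.integers(0, len(pool), size=n)
    mu1 = pool["mean"].to_numpy()[idx]
    phi = pool["dispersion"].to_numpy()[idx]
    lam = pool["lam"].to_numpy()[idx]
    n_de = int(round(n * config.prop_de))
    de_idx = rng.choice(n, size=n_de, replace=False)
    de = np.zeros(n, dtype=bool)
    de[de_idx] = True
    direction = np.ones(n)
    up = de_idx[: n_de // 2]
    down = de_idx[n_de // 2 :]
    direction[up] = config.fold_change
    direction[down] = 1.0 / config.fold_change
    mu2 = mu1 * direction
    m = config.n_per_group
    S1 = _nb_draw(rng, mu1[:, None], phi[:, None], (n, m))
    S2 = _nb_draw(rng, mu2[:, None], phi[:, None], (n, m))
    S = np.concatenate([S1, S2], axis=1)
    return S, de, mu1, mu2, phi, lam


def _noise_draw(
    rng: np.random.Generator,
    lam: np.ndarray,
    inflated: np.ndarray,
    n_samples: int,
    NF: float,
    sigma: float,
) -> np.ndarray:
    """One draw of the background-noise matrix (genes x samples)."""
    n = lam.size
    B = rng.poisson(lam[:, None], size=(n, n_samples))
    if inflated.any():
        k = int(inflated.sum())
        mu = rng.poisson(lam[inflated, None] + NF, size=(k, n_samples))
        noise = np.rint(rng.normal(mu.astype(float), sigma))
        B[inflated] = np.clip(noise, 0, None).astype(np.int64)
    return B.astype(np.int64)


def simulate_background(
    config: SimConfig, lam: np.ndarray, rng: np.random.Generator
):
    """Background noise matrices (B_true added to X; B_obs measured).

    Under the default ``noise_model="hybrid-all"`` every gene's noise
    follows the hybrid law: per sample, mu ~ Poisson(lam + NF), noise =
    round(Normal(mu, sigma)) clipped at 0 — the noise factor NF raises the
    background level of the whole experiment and sigma its dispersion.
    Under ``"inflated-subset"`` only M randomly chosen genes receive that
    law while the rest keep baseline Poisson(lam) noise.  B_obs is an
    independent draw from the same per-gene law (the separately measured
    background).
    """
    n = lam.size
    if config.noise_model == "hybrid-all":
        inflated = np.ones(n, dtype=bool)
    else:
        inflated = np.zeros(n, dtype=bool)
        inflated[rng.choice(n, size=config.M, replace=False)] = True
    m = 2 * config.n_per_group
    B_true = _noise_draw(rng, lam, inflated, m, config.NF, config.sigma)
    B_obs = _noise_draw(rng, lam, inflated, m, config.NF, config.sigma)
    return B_true, B_obs, inflated


def simulate_experiment(
    config: SimConfig, rep: int = 0, pool: pd.DataFrame | None = None
) -> SimTruth:
    """Compose signal + background into one full experiment.

    Deterministic given (config.seed, rep); the rep index perturbs the seed
    reproducibly.  The parameter pool is drawn from the same seed unless one
    is supplied.
    """
    rng = np.random.default_rng([config.seed, rep])
    if pool is None:
        pool = make_parameter_pool(config.n_genes, np.random.default_rng(config.seed))
    S, de, mu1, mu2, phi, lam = simulate_signal(pool, config, rng)
    B_true, B_obs, inflated = simulate_background(config, lam, rng)
    X = S + B_true
    m = config.n_per_group
    groups = np.array(["A"] * m + ["B"] * m)
    return SimTruth(
        de=de,
        mu1=mu1,
        mu2=mu2,
        dispersion=phi,
        lam=lam,
        inflated=inflated,
        S=S,
        B_true=B_true,
        B_obs=B_obs,
        X=X,
        groups=groups,
    )


def truth_frames(truth: SimTruth) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(X, B_obs, truth-table) as DataFrames ready for the DE pipeline / disk."""
    genes = pd.Index([f"gene_{i}" for i in range(truth.X.shape[0])], name="gene_id")
    samples = [f"{g}{j}" for j, g in enumerate(truth.groups)]
    X = pd.DataFrame(truth.X, index=genes, columns=samples)
    B = pd.DataFrame(truth.B_obs, index=genes, columns=samples)
    tt = pd.DataFrame(
        {
            "de": truth.de,
            "mu1": truth.mu1,
            "mu2": truth.mu2,
            "dispersion": truth.dispersion,
            "lam": truth.lam,
            "inflated": truth.inflated,
        },
        index=genes,
    )
    return X, B, tt
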