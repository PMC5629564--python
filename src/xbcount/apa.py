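"""Differential alternative-polyadenylation (APA) usage testing.

A gene with two poly(A) sites produces a short isoform (the PRE region)
and a long isoform carrying an extra 3'UTR extension (the POST region).
The length-normalized short/long expression ratio is

    m/M = (l_post * r_pre) / (l_pre * r_post) - 1

where l_pre / l_post are the PRE length and the extra POST length, and
r_pre / r_post the reads falling in each region.  Shortening of the 3'UTR
under treatment shows up as an increased m/M; the effect size is the
"roar" ratio m/M(treatment) / m/M(control).  Significance comes from
two-sided Fisher exact tests of the PRE/POST 2x2 table for every
cross-group sample pair, combined with Fisher's method.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .detest import bh_adjust

__all__ = [
    "ApaGeneGeometry",
    "ApaCounts",
    "UNDEFINED",
    "mM_ratio",
    "roar_ratio",
    "apa_fisher",
    "combine_fisher",
    "run_apa",
    "filter_apa",
]

#: sentinel for ratios that cannot be formed (zero denominator); genes carrying
#: it are reported but excluded from multiple-testing correction
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ApaGeneGeometry:
    """PRE/POST region geometry of one gene."""

    gene_id: str
    l_pre: int
    l_post: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.l_pre <= 0 or self.l_post <= 0:
            raise ValueError("l_pre and l_post must be positive lengths")


@dataclass(frozen=True)
class ApaCounts:
    """Reads in the short-isoform region (PRE) and in the long-isoform
    extension only (POST), for one gene in one sample."""

    r_pre: int
    r_post: int

    def __post_init__(self) -> None:
        if self.r_pre < 0 or self.r_post < 0:
            raise ValueError("counts must be non-negative")


def mM_ratio(geom: ApaGeneGeometry, counts: ApaCounts) -> float:
    """Length-normalized short/long expression ratio (m/M).

    Returns NaN (the untestable sentinel) when r_post == 0.
    """
    if counts.r_post == 0:
        return UNDEFINED
    return (geom.l_post * counts.r_pre) / (geom.l_pre * counts.r_post) - 1.0


def roar_ratio(mM_treatment: float, mM_control: float) -> float:
    """Ratio of m/M between treatment and control ("ratio of ratios")."""
    if np.isnan(mM_treatment) or np.isnan(mM_control) or mM_control == 0:
        return UNDEFINED
    return mM_treatment / mM_control


def apa_fisher(c1: ApaCounts, c2: ApaCounts) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[pre1, post1], [pre2, post2]]."""
    table = [[c1.r_pre, c1.r_post], [c2.r_pre, c2.r_post]]
    if sum(table[0]) + sum(table[1]) == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def combine_fisher(pvals) -> float:
    """Fisher's method: -2 sum(ln p) ~ chi-square with 2k df; upper tail.

    Zero p-values are clamped to the smallest positive normal float before
    the log (a literal zero would make the statistic infinite).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    p = np.maximum(p, np.finfo(float).tiny)
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, df=2 * p.size))


def run_apa(
    counts_by_sample: dict[str, dict[str, ApaCounts]],
    geometry: dict[str, ApaGeneGeometry] | list[ApaGeneGeometry],
    groups: dict[str, str],
) -> pd.DataFrame:
    """Differential APA usage test across two groups of samples.

    Parameters
    ----------
    counts_by_sample
        sample id -> (gene id -> :class:`ApaCounts`).
    geometry
        gene id -> :class:`ApaGeneGeometry` (or a list thereof).
    groups
        sample id -> group label; exactly two levels.

    Per gene: per-sample m/M, group m/M from group-pooled counts, the roar
    ratio (first level = treatment, second = control), one Fisher exact p
    per cross-group sample pair, the Fisher's-method combination, and BH
    adjustment across testable genes.
    """
    if isinstance(geometry, list):
        geometry = {g.gene_id: g for g in geometry}
    labels = pd.unique(np.asarray(list(groups.values())))
    if labels.size != 2:
        raise ValueError(f"exactly two group levels required, got {labels.size}")
    samples_t = [s for s in counts_by_sample if groups[s] == labels[0]]
    samples_c = [s for s in counts_by_sample if groups[s] == labels[1]]
    if not samples_t or not samples_c:
        raise ValueError("each group needs at least one sample")

    rows = []
    for gid, geom in geometry.items():
        per = {s: counts_by_sample[s].get(gid, ApaCounts(0, 0)) for s in counts_by_sample}
        pooled_t = ApaCounts(
            sum(per[s].r_pre for s in samples_t), sum(per[s].r_post for s in samples_t)
        )
        pooled_c = ApaCounts(
            sum(per[s].r_pre for s in samples_c), sum(per[s].r_post for s in samples_c)
        )
        mM_t = mM_ratio(geom, pooled_t)
        mM_c = mM_ratio(geom, pooled_c)
        roar = roar_ratio(mM_t, mM_c)
        pair_p = [
            apa_fisher(per[st], per[sc]) for st, sc in product(samples_t, samples_c)
        ]
        combined = combine_fisher(pair_p)
        mean_expr = np.mean(
            [per[s].r_pre + per[s].r_post for s in counts_by_sample]
        )
        rows.append(
            {
                "gene_id": gid,
                "mM_treatment": mM_t,
                "mM_control": mM_c,
                "roar": roar,
                "mean_expr": mean_expr,
                "pval_combined": combined,
                "pair_pvals": pair_p,
            }
        )
    out = pd.DataFrame(rows).set_index("gene_id")
    out["padj"] = np.nan
    testable = ~out["roar"].isna()
    if testable.any():
        out.loc[testable, "padj"] = bh_adjust(out.loc[testable, "pval_combined"])
    return out


def filter_apa(
    results: pd.DataFrame,
    roar_min: float = 1.5,
    expr_quantile: float = 0.5,
    padj_max: float = 0.1,
) -> pd.DataFrame:
    """Keep genes with roar >= roar_min or <= 1/roar_min (two-sided), mean
    PRE+POST expression above the given quantile, and padj < padj_max."""
    if results.empty:
        raise ValueError("results must be non-empty")
    roar = results["roar"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        if roar_min > 0:
            roar_ok = ((roar >= roar_min) | (roar <= 1.0 / roar_min)) & ~np.isnan(roar)
        else:
            roar_ok = np.ones(len(results), dtype=bool)
    base = results["mean_expr"]
    if expr_quantile > 0:
        expr_ok = (base > base.quantile(expr_quantile)).to_numpy()
    else:
        expr_ok = np.ones(len(results), dtype=bool)
    keep = roar_ok & expr_ok & (results["padj"] < padj_max).to_numpy()
    return results.loc[keep]
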