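"""Two-population negative-binomial differential expression.

The test models counts as NB with mean ``s_j * q_g`` (sample size factor
times gene abundance) and variance ``mu + alpha * mu^2``. Size factors
use the median-of-ratios estimator. Dispersion is estimated per gene by
method of moments on normalized counts within groups, then averaged
across genes into a single shared value: with only two replicates per
group a per-gene estimate is far too noisy to plug into a test statistic,
while the cross-gene average is accurate whenever dispersion does not
vary wildly between genes. Significance comes from an exact conditional
NB test on the group count sums (the same construction as the classical
DESeq exact test): conditioned on the total, the probability of a split
at least as extreme as the observed one is summed. This keeps the null
distribution honest far into the tail, where a Wald normal approximation
at n = 2 per group does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

P_FLOOR = 1e-300  # avoid log10(0) in ranking output


@dataclass
class DEConfig:
    """Thresholds and numerical knobs for the NB test.

    p_threshold / fdr_threshold implement the joint significance gate
    (p < 1e-7 and BH q < 0.001) used for every enrichment call.
    """

    p_threshold: float = 1e-7
    fdr_threshold: float = 1e-3
    dispersion_floor: float = 1e-3
    pseudocount_for_fold: float = 0.5
    min_mean_for_dispersion: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_threshold", "fdr_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.dispersion_floor <= 0:
            raise ValueError("dispersion_floor must be positive")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    For each gene expressed in every sample, the ratio of its count to
    its across-sample geometric mean is taken; a sample's factor is the
    median of those ratios.
    """
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has a positive count in every sample; "
            "filter empty genes or check the table orientation"
        )
    sub = counts.loc[positive].astype(float)
    log_geo = np.log(sub).mean(axis=1)
    ratios = np.log(sub).sub(log_geo, axis=0)
    factors = np.exp(ratios.median(axis=0))
    factors = factors / np.exp(np.log(factors).mean())  # geometric mean 1
    return factors


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(pvalues, method="fdr_bh")[1]


def estimate_shared_dispersion(
    norm: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    sf: pd.Series,
    cfg: DEConfig,
) -> float:
    """Across-gene mean of per-gene method-of-moments dispersions.

    Within-group sample variances are pooled, the Poisson component
    ``q * mean(1/s)`` subtracted, and the remainder divided by ``q^2``.
    Genes with normalized mean below ``cfg.min_mean_for_dispersion``
    contribute mostly noise and are excluded from the average.
    """
    q = norm.mean(axis=1)
    vA = norm[group_a].var(axis=1, ddof=1)
    vB = norm[group_b].var(axis=1, ddof=1)
    v = (vA + vB) / 2.0
    inv_s = float(np.mean(1.0 / sf[group_a + group_b]))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - q * inv_s) / q**2
    raw = raw[q >= cfg.min_mean_for_dispersion].replace([np.inf, -np.inf], np.nan).dropna()
    if raw.empty:
        log.warning("no genes usable for dispersion estimation; using floor")
        return cfg.dispersion_floor
    return float(max(raw.mean(), cfg.dispersion_floor))


def exact_nb_pvalue(
    k_a: int,
    k_b: int,
    s_a: float,
    s_b: float,
    s2_a: float,
    s2_b: float,
    alpha: float,
) -> float:
    """Exact conditional NB test on the two group count sums.

    ``s_*`` are sums of size factors per group and ``s2_*`` sums of their
    squares (the sum of NB counts with common dispersion ``alpha`` and
    means ``s_j q`` has mean ``S q`` and variance ``S q + alpha q^2 sum
    s_j^2``). Conditioning on ``k_a + k_b``, the p-value sums the joint
    probabilities of all splits no more likely than the observed one.
    """
    total = k_a + k_b
    if total == 0:
        return 1.0
    q = total / (s_a + s_b)
    mu_a, mu_b = s_a * q, s_b * q
    a_eff_a = alpha * s2_a / s_a**2
    a_eff_b = alpha * s2_b / s_b**2
    ks = np.arange(total + 1)

    def pmf(x: np.ndarray, mu: float, a: float) -> np.ndarray:
        if a < 1e-10:
            return stats.poisson.pmf(x, mu)
        r = 1.0 / a
        return stats.nbinom.pmf(x, r, r / (r + mu))

    joint = pmf(ks, mu_a, a_eff_a) * pmf(total - ks, mu_b, a_eff_b)
    denom = joint.sum()
    if denom <= 0:
        return 1.0
    observed = joint[k_a]
    p = joint[joint <= observed * (1 + 1e-8)].sum() / denom
    return float(min(1.0, p))


def nb_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    cfg: DEConfig | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Per-gene differential expression between two sample groups.

    Returns a table with gene_id, base_mean, log2_fold (A over B on
    normalized means, with pseudocount), p_value, q_value and call in
    ``{label_a}_enriched / {label_b}_enriched / ns``. Genes with zero
    counts everywhere are excluded from testing and reported as ``ns``
    with NaN p.
    """
    cfg = cfg or DEConfig()
    for name, grp in (("group_a", group_a), ("group_b", group_b)):
        if len(grp) < 2:
            raise ValueError(f"{name} needs >= 2 replicates for a dispersion estimate")
        missing = [s for s in grp if s not in counts.columns]
        if missing:
            raise KeyError(f"{name} samples not in count table: {missing}")
    samples = list(group_a) + list(group_b)
    sf = size_factors(counts[samples])
    norm = counts[samples].div(sf, axis=1)
    alpha = estimate_shared_dispersion(norm, list(group_a), list(group_b), sf, cfg)
    log.info("shared NB dispersion estimate: %.4g", alpha)

    c = cfg.pseudocount_for_fold
    mean_a = norm[group_a].mean(axis=1)
    mean_b = norm[group_b].mean(axis=1)
    base_mean = norm.mean(axis=1)
    log2_fold = np.log2((mean_a + c) / (mean_b + c))

    s_a = float(sf[group_a].sum())
    s_b = float(sf[group_b].sum())
    s2_a = float((sf[group_a] ** 2).sum())
    s2_b = float((sf[group_b] ** 2).sum())

    k_a = counts[group_a].sum(axis=1).astype(int)
    k_b = counts[group_b].sum(axis=1).astype(int)
    tested = (k_a + k_b) > 0

    pvals = np.full(len(counts), np.nan)
    for i, gene in enumerate(counts.index):
        if tested.iloc[i]:
            pvals[i] = exact_nb_pvalue(
                int(k_a.iloc[i]), int(k_b.iloc[i]), s_a, s_b, s2_a, s2_b, alpha
            )
    qvals = np.full(len(counts), np.nan)
    if tested.any():
        qvals[tested.values] = bh_adjust(pvals[tested.values])

    res = pd.DataFrame(
        {
            "gene_id": counts.index,
            "base_mean": base_mean.values,
            "log2_fold": log2_fold.values,
            "p_value": pvals,
            "q_value": qvals,
        }
    )
    significant = (res["p_value"] < cfg.p_threshold) & (res["q_value"] < cfg.fdr_threshold)
    res["call"] = "ns"
    res.loc[significant & (res["log2_fold"] > 0), "call"] = f"{label_a}_enriched"
    res.loc[significant & (res["log2_fold"] < 0), "call"] = f"{label_b}_enriched"
    return res.reset_index(drop=True)


def glucose_response(
    counts_control: pd.DataFrame,
    counts_glucose: pd.DataFrame,
    cfg: DEConfig | None = None,
    lnc_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Rank transcripts by glucose regulation (high vs. low glucose).

    Both tables must cover the same transcript universe (coding genes
    plus lncRNAs). Output is the NB test of glucose over control, sorted
    by signed significance ``sign(log2_fold) * -log10(p)`` so the most
    up-regulated transcripts come first and the most down-regulated last.
    ``lnc_ids`` flags the lncRNA rows.
    """
    if set(counts_control.index) != set(counts_glucose.index):
        raise ValueError("control and glucose tables must share the same transcript universe")
    merged = counts_glucose.add_suffix("_glc").join(
        counts_control.add_suffix("_ctl"), how="inner"
    )
    res = nb_test(
        merged,
        group_a=[c for c in merged.columns if c.endswith("_glc")],
        group_b=[c for c in merged.columns if c.endswith("_ctl")],
        cfg=cfg,
        label_a="up",
        label_b="down",
    )
    res = res.rename(columns={"call": "direction"})
    res["direction"] = res["direction"].map(
        {"up_enriched": "up", "down_enriched": "down", "ns": "ns"}
    )
    res["is_lnc"] = res["gene_id"].isin(lnc_ids or set())
    p = np.clip(res["p_value"].fillna(1.0), P_FLOOR, 1.0)
    res["signed_score"] = np.sign(res["log2_fold"]) * (-np.log10(p))
    return res.sort_values(
        ["signed_score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
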