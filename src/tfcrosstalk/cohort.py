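"""Signature definition, metagene composite scoring of a paired
tumour/normal cohort, paired testing, copy-number stratification and
score correlation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class Signature:
    """A named gene list with the binding class / contrast that defined it."""

    name: str
    genes: frozenset
    provenance: str = ""


def define_signatures(gene_sets: dict[str, set[str]]) -> dict[str, Signature]:
    """HIF / AHR / common activation signatures from the target gene sets.

    The HIF signature is HIF-bound-only and hypoxia-up; the AHR signature
    AHR-bound-only and ITE-up; genes bound and up-regulated by both
    factors form the separate common signature and are excluded from the
    single-factor signatures.
    """
    common = set(gene_sets.get("common_targets", set()))
    hif = set(gene_sets.get("HIF_targets", set())) - common
    ahr = set(gene_sets.get("AHR_targets", set())) - common
    overlap = hif & ahr
    hif -= overlap
    ahr -= overlap
    sigs = {
        "HIF": Signature("HIF", frozenset(hif), "HIF-bound-only & hypoxia-up"),
        "AHR": Signature("AHR", frozenset(ahr), "AHR-bound-only & ITE-up"),
        "common": Signature("common", frozenset(common), "co-bound & up under both stimuli"),
    }
    assert not (sigs["HIF"].genes & sigs["AHR"].genes)
    assert not (sigs["HIF"].genes & sigs["common"].genes)
    assert not (sigs["AHR"].genes & sigs["common"].genes)
    return sigs


def composite_score(
    expression: pd.DataFrame,
    signature: Signature,
    min_coverage: float = 0.5,
    aggregation: str = "mean",
) -> pd.Series:
    """Per-sample composite activation score for a signature.

    Expression (linear scale, genes x samples) is log2(x+1)-transformed,
    each gene z-standardised across all cohort samples, and the
    signature genes averaged per sample.
    """
    present = [g for g in signature.genes if g in expression.index]
    coverage = len(present) / max(len(signature.genes), 1)
    if coverage < min_coverage:
        raise ValueError(
            f"signature {signature.name!r}: only {coverage:.0%} of genes present "
            f"(minimum {min_coverage:.0%})"
        )
    if coverage < 1.0:
        logger.info("signature %s coverage %.1f%%", signature.name, 100 * coverage)
    logx = np.log2(expression.loc[present].to_numpy(dtype=float) + 1.0)
    mu = logx.mean(axis=1, keepdims=True)
    sd = logx.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (logx - mu) / sd
    if aggregation == "mean":
        scores = z.mean(axis=0)
    elif aggregation == "median":
        scores = np.median(z, axis=0)
    else:
        raise ValueError("aggregation must be 'mean' or 'median'")
    return pd.Series(scores, index=expression.columns, name=f"{signature.name}_score")


def paired_wilcoxon(
    tumour: np.ndarray | pd.Series, normal: np.ndarray | pd.Series
) -> dict:
    """Wilcoxon signed-rank test on paired scores (two-sided).

    V is the sum of ranks of positive differences (tumour - normal).
    Zero differences are dropped; the exact null is used for n <= 25 and
    the normal approximation with continuity correction above.
    """
    t = np.asarray(tumour, dtype=float)
    n = np.asarray(normal, dtype=float)
    if t.shape != n.shape:
        raise ValueError("tumour and normal score vectors must align pairwise")
    diff = t - n
    diff = diff[diff != 0]
    if len(diff) == 0:
        logger.info("all paired differences are zero; p = 1 by convention")
        return {"V": 0.0, "pvalue": 1.0, "n_pairs": 0, "method": "degenerate"}
    ranks = stats.rankdata(np.abs(diff))
    v = float(ranks[diff > 0].sum())
    method = "exact" if len(diff) <= 25 else "approx"
    res = stats.wilcoxon(diff, alternative="two-sided", method=method, correction=(method == "approx"))
    return {"V": v, "pvalue": float(res.pvalue), "n_pairs": int(len(diff)), "method": method}


def jonckheere_terpstra(
    values: np.ndarray, groups: np.ndarray, ordered_levels: list, n_perm: int = 2_000, seed: int = 0
) -> dict:
    """Jonckheere–Terpstra test for an ordered trend across groups.

    JT = sum over ordered group pairs (i < j) of the Mann-Whitney count
    #{a < b} + 0.5 #{a == b}; two-sided p from a seeded permutation of
    group labels.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == lev] for lev in ordered_levels]
    if sum(len(s) > 0 for s in samples) < 2:
        raise ValueError("trend test needs >= 2 non-empty ordered groups")

    def jt(samples_list):
        total = 0.0
        for i in range(len(samples_list)):
            for j in range(i + 1, len(samples_list)):
                a, b = samples_list[i], samples_list[j]
                if len(a) == 0 or len(b) == 0:
                    continue
                diff = b[None, :] - a[:, None]
                total += (diff > 0).sum() + 0.5 * (diff == 0).sum()
        return total

    observed = jt(samples)
    sizes = [len(s) for s in samples]
    mean_null = sum(
        sizes[i] * sizes[j] for i in range(len(sizes)) for j in range(i + 1, len(sizes))
    ) / 2.0
    rng = np.random.default_rng(seed)
    pool = values.copy()
    exceed = 0
    for _ in range(n_perm):
        rng.shuffle(pool)
        parts, start = [], 0
        for sz in sizes:
            parts.append(pool[start : start + sz])
            start += sz
        if abs(jt(parts) - mean_null) >= abs(observed - mean_null):
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return {"JT": float(observed), "pvalue": float(p), "n_perm": n_perm}


def cn_stratified(
    scores: pd.Series, cn_groups: pd.Series, ordered_levels: list | None = None,
    n_perm: int = 2_000, seed: int = 0,
) -> dict:
    """Composite scores stratified by ordered copy-number loss groups.

    Reports per-group medians, the Jonckheere–Terpstra trend p
    (permutation, seeded) and pairwise Mann-Whitney p-values as a
    secondary output.
    """
    cn = cn_groups.loc[scores.index]
    levels = ordered_levels or sorted(cn.unique(), reverse=True)
    if len(levels) < 2:
        raise ValueError("trend undefined with a single copy-number group")
    trend = jonckheere_terpstra(scores.to_numpy(), cn.to_numpy(), levels, n_perm, seed)
    medians = {lev: float(scores[cn == lev].median()) for lev in levels}
    pairwise = {}
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = scores[cn == levels[i]], scores[cn == levels[j]]
            if len(a) and len(b):
                _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                pairwise[(levels[i], levels[j])] = float(p)
    return {"medians": medians, "trend": trend, "pairwise_p": pairwise, "levels": levels}


def score_correlation(
    hif_scores: pd.Series, ahr_scores: pd.Series, method: str = "spearman"
) -> dict:
    """Correlation between HIF and AHR composite scores per sample."""
    joined = pd.concat([hif_scores, ahr_scores], axis=1, join="inner")
    x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return {"rho": float(rho), "pvalue": float(p), "n": int(len(joined)), "method": method}
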