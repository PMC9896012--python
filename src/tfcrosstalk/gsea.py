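"""Gene-level differential expression, binding-class gene sets, the
signed pre-ranking statistic, weighted pre-ranked GSEA with a gene-set
permutation null, and the dual-target additivity analysis.

The ranking statistic combines the log2 fold change phi and the p-value
Pv of each gene. Two readings are offered: the default sign-aware product
pi = phi * (-log10 Pv), which ranks significantly down-regulated genes at
the bottom, and a literal difference pi = phi - log10 Pv behind the
``mode`` switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffbind import estimate_dispersion, nb_wald
from .peaks import BindingSite

P_FLOOR = 1e-300


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference.

    Only genes with all-positive counts contribute to the median.
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    logx = np.log(x[positive])
    ref = logx.mean(axis=1)
    factors = np.exp(np.median(logx - ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns)


def gene_de(
    counts: pd.DataFrame,
    group1_cols: list[str],
    group2_cols: list[str],
    epsilon: float = 0.5,
) -> pd.DataFrame:
    """NB Wald differential expression for condition2 vs condition1.

    Counts are scaled by median-of-ratios size factors; dispersion is the
    shrunk method-of-moments estimate pooled over both groups.
    """
    sub = counts[group1_cols + group2_cols]
    sf = size_factors(sub)
    norm = sub / sf
    resid = pd.concat(
        [
            norm[group1_cols].sub(norm[group1_cols].mean(axis=1), axis=0),
            norm[group2_cols].sub(norm[group2_cols].mean(axis=1), axis=0),
        ],
        axis=1,
    )
    # dispersion from within-group variation around each group's own mean
    pooled_mean = norm.mean(axis=1).to_numpy()
    dof = len(group1_cols) + len(group2_cols) - 2
    s2 = (resid.to_numpy() ** 2).sum(axis=1) / max(dof, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(pooled_mean > 0, np.maximum(0.0, (s2 - pooled_mean) / pooled_mean**2), 0.0)
    centre = float(stats.trim_mean(alpha_raw, 0.1)) if len(alpha_raw) else 0.0
    alpha = 0.5 * alpha_raw + 0.5 * centre
    return nb_wald(norm[group1_cols], norm[group2_cols], alpha, epsilon, feature_ids=counts.index)


def build_gene_sets(
    sites: list[BindingSite],
    de_ite: pd.DataFrame,
    de_hypoxia: pd.DataFrame,
    alpha: float = 0.05,
) -> dict[str, set[str]]:
    """Binding-class gene sets and stimulus-specific target sets.

    Each site is already linked to its nearest-TSS gene. A gene is
    AHR-bound-only when none of its linked sites involves HIF (and at
    least one involves AHR), HIF-bound-only symmetrically, and co-bound
    when it has both an AHR and a HIF linkage (possibly via one shared
    site). "Up-regulated" means log2fc > 0 and q < alpha in the given
    contrast; common targets are co-bound and up-regulated under both
    stimuli.
    """
    ahr_genes: set[str] = set()
    hif_genes: set[str] = set()
    for site in sites:
        gene = site.nearest_gene
        if gene is None:
            continue
        factors = set(site.site_class.split("&")) if site.site_class else set()
        if "AHR" in factors:
            ahr_genes.add(gene)
        if factors & {"HIF1", "HIF2"}:
            hif_genes.add(gene)

    def up(de: pd.DataFrame) -> set[str]:
        sel = (de["log2fc"] > 0) & (de["qvalue"] < alpha)
        return set(de.index[sel])

    up_ite, up_hyp = up(de_ite), up(de_hypoxia)
    sets = {
        "AHR_bound_only": ahr_genes - hif_genes,
        "HIF_bound_only": hif_genes - ahr_genes,
        "co_bound": ahr_genes & hif_genes,
        "AHR_targets": (ahr_genes - hif_genes) & up_ite,
        "HIF_targets": (hif_genes - ahr_genes) & up_hyp,
        "common_targets": (ahr_genes & hif_genes) & up_ite & up_hyp,
    }
    for name, members in sets.items():
        if not members:
            warnings.warn(f"gene set {name!r} is empty", stacklevel=2)
    return sets


def rank_genes(de: pd.DataFrame, mode: str = "product") -> pd.Series:
    """Pre-ranking score per gene, sorted descending (ties by gene ID).

    mode='product': pi = phi * (-log10 Pv); mode='literal':
    pi = phi - log10 Pv. Pv is floored at 1e-300.
    """
    if mode not in ("product", "literal"):
        raise ValueError("mode must be 'product' or 'literal'")
    phi = de["log2fc"].to_numpy(dtype=float)
    pv = np.maximum(de["pvalue"].to_numpy(dtype=float), P_FLOOR)
    if mode == "product":
        pi = phi * (-np.log10(pv))
    else:
        pi = phi - np.log10(pv)
    ser = pd.Series(pi, index=de.index, name="pi")
    return ser.sort_index(kind="mergesort").sort_values(ascending=False, kind="mergesort")


@dataclass
class GseaResult:
    gene_set: str
    es: float
    pvalue: float
    n_perm: int
    set_size: int
    seed: int


def _es_from_hits(
    weights_cum: np.ndarray, weights_hit: np.ndarray, idx: np.ndarray, n: int, k: int
) -> np.ndarray:
    """Signed maximum deviation of the running sum, evaluated only at hit
    boundaries (the statistic is piecewise linear between hits).

    All inputs are (P, k) arrays for P permutations with sorted hit
    indices ``idx``.
    """
    total = weights_cum[:, -1:]
    miss_step = 1.0 / (n - k)
    j = np.arange(1, k + 1)[None, :]
    d_after = weights_cum / total - (idx + 1 - j) * miss_step
    d_before = (weights_cum - weights_hit) / total - (idx - (j - 1)) * miss_step
    candidates = np.concatenate([d_before, d_after], axis=1)
    best = np.take_along_axis(
        candidates, np.argmax(np.abs(candidates), axis=1)[:, None], axis=1
    )[:, 0]
    return best


def gsea_preranked(
    ranking: pd.Series,
    gene_set: set[str] | list[str],
    weight: float = 1.0,
    n_perm: int = 10_000,
    seed: int = 0,
) -> GseaResult:
    """Weighted pre-ranked GSEA enrichment score with a gene-set
    permutation null.

    Hits advance the running sum by |pi|^w / sum_hits |pi|^w, misses
    retreat by 1/(N - N_hit); ES is the signed maximum deviation. The
    null is n_perm random same-size gene sets drawn without replacement
    from the ranked universe; p = (1 + #{|ES_null| >= |ES|, same sign}) /
    (#same-sign + 1).
    """
    genes = list(ranking.index)
    n = len(genes)
    members = set(gene_set)
    if not members:
        raise ValueError("empty gene set")
    if len(members) > n:
        raise ValueError("gene set larger than the ranked universe")
    unknown = members - set(genes)
    if unknown:
        raise ValueError(f"gene set members absent from ranking: {sorted(unknown)[:5]}")
    k = len(members)
    if k == n:
        raise ValueError("gene set equals the whole universe; ES undefined")
    wv = np.abs(ranking.to_numpy(dtype=float)) ** weight
    wv = np.maximum(wv, 1e-12)  # all-zero scores would break the hit normalisation
    pos = {g: i for i, g in enumerate(genes)}
    obs_idx = np.sort(np.array([pos[g] for g in members]))[None, :]
    obs_w = wv[obs_idx]
    es = float(_es_from_hits(np.cumsum(obs_w, axis=1), obs_w, obs_idx, n, k)[0])

    rng = np.random.default_rng(seed)
    batch = 2_000
    null_es = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        # sorted k-subsets via partial argsort of uniform keys
        keys = rng.random((b, n))
        idx = np.sort(np.argpartition(keys, k - 1, axis=1)[:, :k], axis=1)
        w_hit = wv[idx]
        null_es[done : done + b] = _es_from_hits(np.cumsum(w_hit, axis=1), w_hit, idx, n, k)
        done += b
    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    exceed = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
    p = (1 + exceed) / (n_same + 1)
    return GseaResult("", es, float(p), n_perm, k, seed)


def additivity(
    de_hypoxia: pd.DataFrame,
    de_ite: pd.DataFrame,
    de_both: pd.DataFrame,
    genes: set[str] | list[str],
) -> tuple[pd.DataFrame, dict]:
    """Per-gene fold changes under each stimulus and their combination,
    with the additive prediction phi_hyp + phi_ite and a sign test of
    whether the combined response exceeds the stronger single stimulus."""
    genes = [g for g in genes if g in de_both.index]
    table = pd.DataFrame(
        {
            "phi_hypoxia": de_hypoxia.loc[genes, "log2fc"],
            "phi_ite": de_ite.loc[genes, "log2fc"],
            "phi_both": de_both.loc[genes, "log2fc"],
        }
    )
    table["phi_additive"] = table["phi_hypoxia"] + table["phi_ite"]
    exceeds = (table["phi_both"] > table[["phi_hypoxia", "phi_ite"]].max(axis=1)).sum()
    n = len(table)
    sign_p = float(stats.binomtest(int(exceeds), n, 0.5).pvalue) if n else np.nan
    summary = {
        "median_hypoxia": float(table["phi_hypoxia"].median()) if n else np.nan,
        "median_ite": float(table["phi_ite"].median()) if n else np.nan,
        "median_both": float(table["phi_both"].median()) if n else np.nan,
        "median_additive": float(table["phi_additive"].median()) if n else np.nan,
        "n_exceeding_single": int(exceeds),
        "n_genes": n,
        "sign_test_p": sign_p,
    }
    return table, summary
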