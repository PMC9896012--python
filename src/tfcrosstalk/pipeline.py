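"""End-to-end orchestration: simulation -> peaks -> quantification ->
differential binding -> motifs -> gene-set enrichment -> cohort scoring.

Each stage draws its randomness from a child seed derived from the single
run seed, so stage outputs are reproducible independently of stage order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort as cohort_mod
from . import diffbind, gsea, motifs, peaks, quant
from .intervals import GenomicInterval
from .io import RunConfig, write_bed, write_fasta, write_table
from .simulate import CLASS_FACTORS, simulate_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "peaks", "quant", "diff", "motifs", "gsea", "cohort")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (independent of stage order)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


@dataclass
class RunManifest:
    timestamp: str
    seed: int
    config_hash: str
    checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _site_counts_table(ds) -> pd.DataFrame:
    return ds.chip_counts


def run_all(
    config: RunConfig,
    outdir: str | Path,
    genome_length: int = 600_000,
    gamma: float = 0.5,
    class_counts: dict[str, int] | None = None,
    n_pairs: int = 72,
    gsea_nperm: int | None = None,
    write_tracks: bool = False,
) -> dict:
    """Run every stage on a synthetic dataset and write per-stage tables.

    Returns a results dictionary with the headline quantities of each
    stage; all tables are also written under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_resolved.yaml")
    results: dict = {"seed": config.seed}
    t0 = time.time()

    # ---- simulate -------------------------------------------------------
    ds = simulate_dataset(
        seed=stage_seed(config.seed, "simulate"),
        genome_length=genome_length,
        gamma=gamma,
        class_counts=class_counts,
        bin_width=10,
    )
    write_fasta(ds.genome, outdir / "genome.fa")
    site_bed = [
        GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]), r["strand"], name=sid,
                        extra={"rest": [r["site_class"]]})
        for sid, r in ds.model.sites.iterrows()
    ]
    write_bed(site_bed, outdir / "planted_sites.bed")
    write_table(ds.chip_counts, outdir / "chip_site_counts.tsv", index_label="site")
    write_table(ds.gene_counts, outdir / "gene_counts.tsv", index_label="gene")
    logger.info("simulate: %d sites, %d genes", len(ds.model.sites), len(ds.gene_table))

    # ---- peaks ----------------------------------------------------------
    pk_rng = np.random.default_rng(stage_seed(config.seed, "peaks"))
    conditions = list(config.conditions)
    active = {
        "AHR": [c for c in conditions if "ITE" in c or "FICZ" in c],
        "HIF1": [c for c in conditions if c.startswith("hypoxia")],
        "HIF2": [c for c in conditions if c.startswith("hypoxia")],
        "ARNT": conditions,
    }
    called: dict[tuple[str, str, int], list[peaks.Peak]] = {}
    for factor in ("AHR", "HIF1", "HIF2", "ARNT"):
        for cond in active[factor]:
            for rep in (1, 2):
                track = ds.chip_tracks[(factor, cond, rep)]
                pa = peaks.call_peaks_enrichment(
                    track, ds.input_track, min_fold=config.caller_min_fold,
                    min_len=config.caller_min_len, alpha=config.caller_alpha,
                    merge_dist=config.caller_merge_dist,
                )
                pb = peaks.call_peaks_shape(
                    track, bandwidth=config.shape_bandwidth, prominence=config.shape_prominence
                )
                both = peaks.consensus(pa, pb)
                both = peaks.exclude_blacklist(both, [])
                # empirical background: random non-site regions of median peak width
                widths = [len(p.interval) for p in both] or [400]
                width = int(np.median(widths))
                n_bg = min(config.n_background_regions, 20_000)
                chrom = next(iter(track.data))
                glen = track.chrom_length(chrom)
                bg_starts = pk_rng.integers(0, glen - width, size=n_bg)
                site_mids = ds.model.sites["start"].to_numpy()
                far = np.abs(bg_starts[:, None] - site_mids[None, :]).min(axis=1) > 1_000
                bg_starts = bg_starts[far]
                bg_counts = np.array(
                    [track.area(chrom, int(s), int(s) + width) for s in bg_starts]
                )
                thr = peaks.background_threshold(bg_counts, config.background_q)
                called[(factor, cond, rep)] = peaks.filter_peaks(both, thr)

    canonical: dict[str, list[peaks.BindingSite]] = {}
    for factor in ("AHR", "HIF1", "HIF2"):
        per_cond_sites: list[peaks.BindingSite] = []
        for cond in active[factor]:
            sites_c = peaks.canonical_sites(
                called[(factor, cond, 1)], called[(factor, cond, 2)],
                called[("ARNT", cond, 1)], called[("ARNT", cond, 2)], factor=factor,
            )
            for s in sites_c:
                s.conditions[cond] = True
            per_cond_sites.extend(sites_c)
        # union across conditions: merge by overlap, keep first summit
        merged, _ = peaks.classify_venn({factor: per_cond_sites})
        for m in merged:
            m.site_class = factor
            if factor not in m.summits:
                m.summits[factor] = (m.interval.start + m.interval.end) // 2
        canonical[factor] = merged
    merged_sites, venn = peaks.classify_venn(canonical)
    results["n_canonical"] = {f: len(canonical[f]) for f in canonical}
    results["venn_union"] = venn.union()
    results["venn_multi"] = venn.multi_factor()
    results["venn_overlap_pct"] = venn.overlap_percentage()
    venn.as_table().to_csv(outdir / "venn_counts.tsv", sep="\t", index=False)

    tss = pd.DataFrame(
        {
            "gene": ds.gene_table.index,
            "chrom": ds.gene_table["chrom"],
            "pos": ds.gene_table["tss"],
            "strand": ds.gene_table["strand"],
        }
    ).reset_index(drop=True)
    peaks.annotate_tss(merged_sites, tss)
    for factor in canonical:
        peaks.annotate_tss(canonical[factor], tss)
    logger.info("peaks: %s canonical, union %d", results["n_canonical"], venn.union())

    # ---- quant ----------------------------------------------------------
    # depth scaling from the trimmed mean of genome-wide bin counts: the
    # genome is background-dominated, so this tracks sequencing depth
    # without absorbing genuine global binding changes into the factors
    sample_cols = ds.chip_counts.columns
    depth = {}
    for c in sample_cols:
        track = ds.chip_tracks[_parse_col(c)]
        vals = np.concatenate([v for v in track.data.values()])
        depth[c] = float(stats.trim_mean(vals, 0.01))
    depth_ser = pd.Series(depth)
    depth_ser /= depth_ser.mean()
    scaled = ds.chip_counts / depth_ser

    # MA normalisation is applied where its assumption (equal expected
    # occupancy over common features) holds: between replicates of the
    # same factor x condition, anchored on replicate 1
    normed_cols = {}
    ma_params: dict[str, tuple[float, float]] = {}
    log2_mat = np.log2(scaled + config.pseudocount)
    for factor in ("AHR", "HIF1", "HIF2", "ARNT"):
        for cond in active[factor]:
            pair = [f"{factor}_{cond}_rep{r}" for r in (1, 2)]
            sub, params = quant.ma_normalise(log2_mat[pair], reference=pair[0])
            ma_params.update(params)
            for c in pair:
                normed_cols[c] = sub[c]
    normed = pd.DataFrame(normed_cols)
    write_table(normed, outdir / "chip_site_signal_ma.tsv", index_label="site")
    results["ma_params_mean_v"] = float(np.mean([v for (_, v) in ma_params.values()]))

    shared_ah1 = [s for s in merged_sites if s.site_class == "AHR&HIF1"]
    sd = quant.summit_distance(shared_ah1, shared_ah1, factor_a="AHR", factor_b="HIF1")
    results["summit_median_AHR_HIF1"] = sd["median"]
    shared_ah2 = [s for s in merged_sites if s.site_class == "AHR&HIF2"]
    sd2 = quant.summit_distance(shared_ah2, shared_ah2, factor_a="AHR", factor_b="HIF2")
    results["summit_median_AHR_HIF2"] = sd2["median"]

    r2, order = quant.correlate_and_cluster(normed)
    r2.to_csv(outdir / "sample_correlation_r2.tsv", sep="\t")
    results["cluster_order"] = order

    # ---- differential binding ------------------------------------------
    def cols(factor, cond):
        return [f"{factor}_{cond}_rep{r}" for r in (1, 2)]

    lin = scaled  # depth-scaled counts; cross-condition contrasts stay on this scale
    site_class = ds.model.sites["site_class"]
    contrasts = {
        "AHR_hypoxia_effect": ("AHR", "normoxia_ITE", "hypoxia_ITE"),
        "HIF1_ite_effect": ("HIF1", "hypoxia_DMSO", "hypoxia_ITE"),
        "HIF2_ite_effect": ("HIF2", "hypoxia_DMSO", "hypoxia_ITE"),
    }
    diff_results = {}
    for name, (factor, c1, c2) in contrasts.items():
        g1, g2 = lin[cols(factor, c1)], lin[cols(factor, c2)]
        # within-group dispersion only; pooling across groups would absorb
        # the condition effect into the variance
        alpha_vec = 0.5 * (diffbind.estimate_dispersion(g1) + diffbind.estimate_dispersion(g2))
        res = diffbind.nb_wald(g1, g2, alpha_vec, config.pseudocount)
        write_table(res, outdir / f"diff_{name}.tsv", index_label="site")
        diff_results[name] = res

    res_ahr = diff_results["AHR_hypoxia_effect"]
    indiv = res_ahr.loc[site_class == "AHR", "log2fc"].to_numpy()
    shared1 = res_ahr.loc[site_class == "AHR&HIF1", "log2fc"].to_numpy()
    strat = diffbind.stratified_comparison(shared1, indiv)
    results["stratified_AHR"] = strat
    logger.info("diff: shared median %.3f vs individual %.3f",
                strat["median_shared"], strat["median_individual"])

    # ---- motifs ---------------------------------------------------------
    mot_rng = np.random.default_rng(stage_seed(config.seed, "motifs"))
    by_class = {}
    chrom = next(iter(ds.genome))
    glen = len(ds.genome[chrom])
    bg_starts = mot_rng.integers(config.motif_flank, glen - config.motif_flank, size=200)
    site_mids = ds.model.sites["start"].to_numpy()
    bg_starts = bg_starts[np.abs(bg_starts[:, None] - site_mids[None, :]).min(axis=1) > 1_000]
    background = {
        f"bg_{i}": ds.genome[chrom][s - config.motif_flank : s + config.motif_flank]
        for i, s in enumerate(bg_starts)
    }
    for cls_name, keep in (("AHR_sites", ("AHR",)), ("HIF_sites", ("HIF1", "HIF2"))):
        sel = [
            s for s in merged_sites
            if set(s.site_class.split("&")) & set(keep) and not (
                cls_name == "AHR_sites" and set(s.site_class.split("&")) & {"HIF1", "HIF2"}
            )
        ]
        seqs = motifs.extract_site_sequences(ds.genome, sel, flank=config.motif_flank)
        enr = motifs.variant_enrichment(seqs, background)
        enr.to_csv(outdir / f"motif_enrichment_{cls_name}.tsv", sep="\t")
        by_class[cls_name] = enr
    results["top_variant_AHR"] = by_class["AHR_sites"]["fold"].idxmax()
    results["top_variant_HIF"] = by_class["HIF_sites"]["fold"].idxmax()

    # ---- GSEA -----------------------------------------------------------
    nperm = gsea_nperm if gsea_nperm is not None else config.gsea_nperm

    def rna_cols(cond):
        return [c for c in ds.gene_counts.columns if c.startswith(cond + "_rep")]

    de_hyp = gsea.gene_de(ds.gene_counts, rna_cols("normoxia_DMSO"), rna_cols("hypoxia_DMSO"))
    de_ite = gsea.gene_de(ds.gene_counts, rna_cols("normoxia_DMSO"), rna_cols("normoxia_ITE"))
    de_both = gsea.gene_de(ds.gene_counts, rna_cols("normoxia_DMSO"), rna_cols("hypoxia_ITE"))
    de_ahr_hyp = gsea.gene_de(ds.gene_counts, rna_cols("normoxia_ITE"), rna_cols("hypoxia_ITE"))
    for nm, de in (("hypoxia", de_hyp), ("ite", de_ite), ("both", de_both)):
        write_table(de, outdir / f"gene_de_{nm}.tsv", index_label="gene")
    gene_sets = gsea.build_gene_sets(merged_sites, de_ite, de_hyp, alpha=config.bh_alpha)
    results["gene_set_sizes"] = {k: len(v) for k, v in gene_sets.items()}

    gsea_out = {}
    rank_ite = gsea.rank_genes(de_ite, config.ranking_mode)
    rank_hyp_in_ite = gsea.rank_genes(de_ahr_hyp, config.ranking_mode)
    rank_hyp = gsea.rank_genes(de_hyp, config.ranking_mode)
    gsea_seed = stage_seed(config.seed, "gsea")
    jobs = {
        "AHR_targets_in_ite": (rank_ite, gene_sets["AHR_bound_only"]),
        "AHR_targets_in_hypoxia_vs_ite": (rank_hyp_in_ite, gene_sets["AHR_bound_only"]),
        "HIF_targets_in_hypoxia": (rank_hyp, gene_sets["HIF_bound_only"]),
        "co_bound_in_hypoxia": (rank_hyp, gene_sets["co_bound"]),
        "co_bound_in_ite": (rank_ite, gene_sets["co_bound"]),
    }
    for name, (ranking, members) in jobs.items():
        members = set(members) & set(ranking.index)
        if not members or len(members) >= len(ranking):
            continue
        res = gsea.gsea_preranked(ranking, members, config.gsea_weight, nperm, gsea_seed)
        res.gene_set = name
        gsea_out[name] = {"es": res.es, "p": res.pvalue, "k": res.set_size}
    results["gsea"] = gsea_out
    pd.DataFrame(gsea_out).T.to_csv(outdir / "gsea_results.tsv", sep="\t")

    add_table, add_summary = gsea.additivity(de_hyp, de_ite, de_both, gene_sets["common_targets"])
    add_table.to_csv(outdir / "additivity.tsv", sep="\t")
    results["additivity"] = add_summary

    # ---- cohort ---------------------------------------------------------
    from .simulate import simulate_cohort

    sigs = cohort_mod.define_signatures(gene_sets)
    sig_lists = {k: sorted(v.genes) for k, v in sigs.items() if v.genes}
    if "HIF" in sig_lists and "AHR" in sig_lists:
        expr, meta = simulate_cohort(
            n_pairs, sig_lists, seed=stage_seed(config.seed, "cohort")
        )
        cohort_res = {}
        scores = {}
        for name in ("HIF", "AHR", "common"):
            if name not in sig_lists:
                continue
            sc = cohort_mod.composite_score(expr, sigs[name], aggregation=config.score_aggregation)
            scores[name] = sc
            tum = sc[meta["tissue"] == "tumour"]
            nor = sc[meta["tissue"] == "normal"]
            # align pairs by patient
            tum = tum.rename(lambda s: s.rsplit("_", 1)[0])
            nor = nor.rename(lambda s: s.rsplit("_", 1)[0])
            both_idx = tum.index.intersection(nor.index)
            pw = cohort_mod.paired_wilcoxon(tum[both_idx], nor[both_idx])
            cohort_res[name] = {
                "median_tumour": float(tum.median()),
                "median_normal": float(nor.median()),
                "wilcoxon": pw,
            }
            tum_samples = meta.index[meta["tissue"] == "tumour"]
            cn = cohort_mod.cn_stratified(
                sc[tum_samples], meta.loc[tum_samples, "cn_group"],
                ordered_levels=[0, -1, -2], seed=stage_seed(config.seed, "cohort") + 1,
            )
            cohort_res[name]["cn_trend_p"] = cn["trend"]["pvalue"]
            cohort_res[name]["cn_medians"] = cn["medians"]
        tum_samples = meta.index[meta["tissue"] == "tumour"]
        corr = cohort_mod.score_correlation(
            scores["HIF"][tum_samples], scores["AHR"][tum_samples],
            method=config.correlation_method,
        )
        cohort_res["hif_ahr_correlation"] = corr
        results["cohort"] = cohort_res
        pd.DataFrame(scores).to_csv(outdir / "cohort_scores.tsv", sep="\t")

    # ---- manifest -------------------------------------------------------
    manifest = RunManifest(
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        seed=config.seed,
        config_hash=_checksum(outdir / "config_resolved.yaml"),
    )
    for f in sorted(outdir.glob("*.tsv")) + [outdir / "planted_sites.bed"]:
        manifest.checksums[f.name] = _checksum(f)
    manifest.to_json(outdir / "manifest.json")
    results["elapsed_s"] = round(time.time() - t0, 1)
    logger.info("run complete in %.1f s", results["elapsed_s"])
    return results


def _parse_col(col: str) -> tuple[str, str, int]:
    factor, rest = col.split("_", 1)
    cond, rep = rest.rsplit("_rep", 1)
    return factor, cond, int(rep)
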