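"""Dual-caller peak detection, consensus, background filtering, canonical
sites, Venn classification and TSS annotation.

Two deliberately different callers are provided: an enrichment-over-control
caller (fold change + Poisson tail test per bin) and a shape caller
(smoothed local maxima with a prominence criterion). A peak is accepted
only when found by both ("consensus"), then filtered against the empirical
percentile of counts in random background regions, and finally required to
replicate (>= 1 bp overlap between independent replicates). A canonical
site for a factor is a replicated factor peak that also overlaps a
replicated peak of the shared partner (ARNT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .intervals import GenomicInterval, merge_intervals, overlaps_any
from .io import CoverageTrack


@dataclass
class Peak:
    """A called peak; ``summit`` is an absolute genomic position inside the span."""

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    total_count: float = 0.0

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie within the peak interval")
        if self.total_count < 0:
            raise ValueError("total_count must be >= 0")


@dataclass
class BindingSite:
    """A consensus canonical site with its factor class and annotations."""

    interval: GenomicInterval
    site_class: str = ""
    summits: dict = field(default_factory=dict)  # factor -> absolute summit
    tss_distance: float | None = None
    nearest_gene: str | None = None
    conditions: dict = field(default_factory=dict)  # condition -> present flag


def _plateau_summit(values: np.ndarray, lo_bin: int, bin_width: int) -> int:
    """Summit = floor of the midpoint of the leftmost maximal-value run."""
    vmax = values.max()
    at_max = np.flatnonzero(values == vmax)
    run_start = at_max[0]
    run_end = run_start
    for idx in at_max[1:]:
        if idx == run_end + 1:
            run_end = idx
        else:
            break
    mid_bin = (run_start + run_end) // 2
    return (lo_bin + mid_bin) * bin_width + bin_width // 2


def call_peaks_enrichment(
    sample: CoverageTrack,
    control: CoverageTrack,
    min_fold: float = 4.0,
    min_len: int = 100,
    alpha: float = 1e-3,
    merge_dist: int = 100,
    pseudocount: float = 0.5,
) -> list[Peak]:
    """Caller A: bins enriched over the library-size-scaled control.

    A bin qualifies when scaled fold change >= min_fold AND the Poisson
    upper-tail p-value (expected = scaled control) < alpha. Qualifying runs
    are merged within ``merge_dist`` bp and kept if >= min_len bp long.
    """
    if set(sample.data) != set(control.data):
        raise ValueError("sample and control tracks cover different chromosomes")
    if sample.bin_width != control.bin_width:
        raise ValueError("sample and control bin widths differ")
    bw = sample.bin_width
    peaks: list[Peak] = []
    ratio = sample.library_size / control.library_size
    for chrom in sorted(sample.data):
        s = sample.data[chrom]
        c = control.data[chrom] * ratio  # expected counts at sample depth
        fold = (s + pseudocount) / (c + pseudocount)
        pval = stats.poisson.sf(s - 1, np.maximum(c, pseudocount))
        ok = (fold >= min_fold) & (pval < alpha)
        if not ok.any():
            continue
        idx = np.flatnonzero(ok)
        gap = max(1, merge_dist // bw)
        breaks = np.flatnonzero(np.diff(idx) > gap)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [len(idx) - 1]))
        for rs, re_ in zip(run_starts, run_ends):
            lo, hi = idx[rs], idx[re_] + 1
            start, end = lo * bw, hi * bw
            if end - start < min_len:
                continue
            vals = s[lo:hi]
            summit = _plateau_summit(vals, lo, bw)
            score = float(-np.log10(np.maximum(pval[lo:hi].min(), 1e-300)))
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), min(summit, end - 1), score, float(vals.sum()))
            )
    return peaks


def call_peaks_shape(
    sample: CoverageTrack,
    bandwidth: float = 50.0,
    prominence: float = 5.0,
    rel_height: float = 0.75,
) -> list[Peak]:
    """Caller B: smoothed local maxima whose prominence over flanking
    minima exceeds the threshold; peak bounds from the width at
    ``rel_height`` of the prominence."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    bw = sample.bin_width
    sigma = max(bandwidth / bw, 1e-6)
    peaks: list[Peak] = []
    for chrom in sorted(sample.data):
        raw = sample.data[chrom]
        smooth = gaussian_filter1d(raw, sigma=sigma, mode="nearest")
        locs, props = _signal.find_peaks(smooth, prominence=prominence)
        if len(locs) == 0:
            continue
        widths = _signal.peak_widths(smooth, locs, rel_height=rel_height)
        for k, loc in enumerate(locs):
            lo = int(np.floor(widths[2][k]))
            hi = int(np.ceil(widths[3][k])) + 1
            start, end = lo * bw, min(hi * bw, len(raw) * bw)
            vals = raw[lo:hi]
            summit = _plateau_summit(vals, lo, bw)
            peaks.append(
                Peak(
                    GenomicInterval(chrom, start, end),
                    min(summit, end - 1),
                    float(props["prominences"][k]),
                    float(vals.sum()),
                )
            )
    return peaks


# ---------------------------------------------------------------- set logic


def consensus(peaks_a: list[Peak], peaks_b: list[Peak]) -> list[Peak]:
    """Peaks from A that overlap >= 1 bp with some peak in B (A coordinates)."""
    mask = overlaps_any([p.interval for p in peaks_a], [p.interval for p in peaks_b])
    return [p for p, keep in zip(peaks_a, mask) if keep]


def exclude_blacklist(peaks: list[Peak], blacklist: list[GenomicInterval]) -> list[Peak]:
    """Remove peaks overlapping any blacklist interval by >= 1 bp."""
    if not blacklist:
        return list(peaks)
    mask = overlaps_any([p.interval for p in peaks], blacklist)
    return [p for p, hit in zip(peaks, mask) if not hit]


def background_threshold(counts: np.ndarray, q: float = 0.9999) -> float:
    """Empirical q-quantile (type 7, linear interpolation) of background counts."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty background region set")
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    recommended = 1.0 / (1.0 - q)
    if counts.size < recommended:
        warnings.warn(
            f"only {counts.size} background regions for q={q}; "
            f">= {recommended:.0f} recommended",
            stacklevel=2,
        )
    return float(np.quantile(counts, q, method="linear"))


def filter_peaks(peaks: list[Peak], threshold: float) -> list[Peak]:
    """Keep peaks whose total count strictly exceeds the threshold."""
    return [p for p in peaks if p.total_count > threshold]


def reproducible(rep1: list[Peak], rep2: list[Peak]) -> list[Peak]:
    """Peaks from replicate 1 that overlap >= 1 bp a replicate-2 peak."""
    return consensus(rep1, rep2)


def canonical_sites(
    factor_rep1: list[Peak],
    factor_rep2: list[Peak],
    arnt_rep1: list[Peak],
    arnt_rep2: list[Peak],
    factor: str = "",
) -> list[BindingSite]:
    """Replicated factor peaks that also overlap a replicated ARNT peak.

    Site coordinates come from the factor peak (replicate 1).
    """
    fac = reproducible(factor_rep1, factor_rep2)
    arnt = reproducible(arnt_rep1, arnt_rep2)
    kept = consensus(fac, arnt)
    return [
        BindingSite(interval=p.interval, site_class=factor, summits={factor: p.summit} if factor else {})
        for p in kept
    ]


# ---------------------------------------------------------------- Venn


@dataclass
class VennCounts:
    """Venn region counts over the merged site universe; provides the
    inclusion–exclusion arithmetic used for reporting."""

    region_counts: dict[frozenset, int] = field(default_factory=dict)

    def total(self, factor: str) -> int:
        return sum(n for combo, n in self.region_counts.items() if factor in combo)

    def union(self) -> int:
        return sum(self.region_counts.values())

    def multi_factor(self) -> int:
        return sum(n for combo, n in self.region_counts.items() if len(combo) > 1)

    def overlap_percentage(self, factor: str | None = None) -> int:
        """Percent (rounded to nearest integer) of sites that are
        multi-factor: overall when factor is None, else among that
        factor's sites."""
        if factor is None:
            denom, num = self.union(), self.multi_factor()
        else:
            denom = self.total(factor)
            num = sum(
                n for combo, n in self.region_counts.items() if factor in combo and len(combo) > 1
            )
        return int(round(100.0 * num / denom)) if denom else 0

    def as_table(self) -> pd.DataFrame:
        rows = [
            {"factors": "&".join(sorted(combo)), "n_sites": n}
            for combo, n in sorted(self.region_counts.items(), key=lambda kv: ("&".join(sorted(kv[0]))))
        ]
        return pd.DataFrame(rows)


def pairwise_union(n_a: int, n_b: int, n_ab: int) -> int:
    """|A ∪ B| from component counts by inclusion–exclusion."""
    return n_a + n_b - n_ab


def classify_venn(sites_by_factor: dict[str, list[BindingSite]]) -> tuple[list[BindingSite], VennCounts]:
    """Merge all sites (>= 1 bp overlap) into a cluster universe and label
    each cluster with the set of factors present.

    Returns the merged site list (one BindingSite per cluster, class =
    '&'-joined sorted factor names) and the Venn counts, which satisfy
    inclusion–exclusion exactly by construction.
    """
    universe = merge_intervals(
        [s.interval for sites in sites_by_factor.values() for s in sites]
    )
    counts: dict[frozenset, int] = {}
    merged: list[BindingSite] = []
    factor_masks = {}
    for factor, sites in sites_by_factor.items():
        factor_masks[factor] = overlaps_any(universe, [s.interval for s in sites])
    # carry factor summits onto clusters for downstream summit statistics
    summit_lookup: dict[str, list[tuple[GenomicInterval, int]]] = {
        factor: [(s.interval, s.summits.get(factor, -1)) for s in sites]
        for factor, sites in sites_by_factor.items()
    }
    for i, block in enumerate(universe):
        present = frozenset(f for f in sites_by_factor if factor_masks[f][i])
        if not present:
            continue
        counts[present] = counts.get(present, 0) + 1
        summits = {}
        for factor in present:
            for iv, sm in summit_lookup[factor]:
                if sm >= 0 and iv.overlaps(block):
                    summits[factor] = sm
                    break
        merged.append(
            BindingSite(interval=block, site_class="&".join(sorted(present)), summits=summits)
        )
    return merged, VennCounts(counts)


# ---------------------------------------------------------------- TSS


def annotate_tss(sites: list[BindingSite], tss: pd.DataFrame) -> list[BindingSite]:
    """Attach the signed distance from each site's summit (or span
    midpoint) to the nearest TSS.

    ``tss`` columns: gene, chrom, pos, strand. Sign is negative when the
    summit lies upstream of the TSS in the gene's reading direction. Ties
    on |distance| break toward the first TSS in (pos, gene) sort order.
    """
    required = {"gene", "chrom", "pos", "strand"}
    if not required <= set(tss.columns):
        raise ValueError(f"TSS table must have columns {sorted(required)}")
    tss_sorted = tss.sort_values(["chrom", "pos", "gene"], kind="mergesort")
    by_chrom = {
        chrom: grp.reset_index(drop=True) for chrom, grp in tss_sorted.groupby("chrom")
    }
    for site in sites:
        chrom = site.interval.chrom
        if chrom not in by_chrom:
            site.tss_distance = None
            continue
        summit = next(iter(site.summits.values()), None)
        if summit is None:
            summit = (site.interval.start + site.interval.end) // 2
        grp = by_chrom[chrom]
        pos = grp["pos"].to_numpy()
        j = int(np.searchsorted(pos, summit))
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(grp):
                d = abs(int(pos[k]) - summit)
                if best is None or d < best[0]:
                    best = (d, k)
        # absorb runs of equal |distance|: first in sorted order wins
        d_best, k_best = best
        for k in range(max(0, j - 1), min(len(grp), j + 1)):
            if abs(int(pos[k]) - summit) == d_best and k < k_best:
                k_best = k
        row = grp.iloc[k_best]
        signed = summit - int(row["pos"]) if row["strand"] == "+" else int(row["pos"]) - summit
        site.tss_distance = float(signed)
        site.nearest_gene = str(row["gene"])
    return sites


def tss_distance_histogram(
    distances: np.ndarray, n_bins: int = 20, max_abs: float = 1e6
) -> pd.DataFrame:
    """Counts of |distance| in log-spaced bins, split by sign."""
    d = np.asarray([x for x in distances if x is not None and np.isfinite(x)])
    edges = np.geomspace(10.0, max_abs, n_bins + 1)
    edges = np.concatenate(([0.0], edges))
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (np.abs(d) >= lo) & (np.abs(d) < hi)
        rows.append(
            {
                "abs_lo": lo,
                "abs_hi": hi,
                "upstream": int(((d < 0) & sel).sum()),
                "downstream": int(((d >= 0) & sel).sum()),
            }
        )
    return pd.DataFrame(rows)
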