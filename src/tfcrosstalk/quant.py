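"""Region counting, RPKM, MA normalisation, summit-distance statistics
and sample-correlation clustering."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .intervals import GenomicInterval
from .io import CoverageTrack
from .peaks import BindingSite

logger = logging.getLogger(__name__)

STATES = ("raw", "rpkm", "ma-normalised")


@dataclass
class CountMatrix:
    """Features x samples counts with library sizes and normalisation state.

    The state flag only moves forward (raw -> rpkm / ma-normalised)."""

    counts: pd.DataFrame
    library_sizes: pd.Series
    state: str = "raw"
    bin_width: int | None = None
    shift: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")
        missing = set(self.counts.columns) - set(self.library_sizes.index)
        if missing:
            raise ValueError(f"missing library sizes for samples: {sorted(missing)}")


def count_in_regions(
    track: CoverageTrack,
    regions: list[GenomicInterval] | list[BindingSite],
    fragment_width: int = 200,
    shift: int = 150,
) -> np.ndarray:
    """Fragment counts per region: area under the coverage track within
    the region divided by the fragment width.

    This is the coverage-level surrogate for midpoint counting; ``shift``
    (the read-start offset used with read-level input) is carried for
    provenance only.
    """
    out = np.zeros(len(regions))
    for i, r in enumerate(regions):
        iv = r.interval if isinstance(r, BindingSite) else r
        if iv.chrom not in track.data:
            continue
        out[i] = track.area(iv.chrom, iv.start, iv.end) / fragment_width
    return out


def rpkm(counts: np.ndarray | pd.DataFrame, lengths: np.ndarray, library_size: float | np.ndarray):
    """Reads per kilobase of region per million mapped reads."""
    lengths = np.asarray(lengths, dtype=float)
    return counts / (lengths[:, None] if np.ndim(counts) == 2 else lengths) / 1e-3 / (
        np.asarray(library_size, dtype=float) / 1e6
    )


def ma_normalise(
    log2_mat: pd.DataFrame,
    common_mask: np.ndarray | None = None,
    reference: str | None = None,
    min_common: int = 10,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Linear MA normalisation of log2 signal to a reference sample.

    For each sample j an OLS line x_ref = u + v * x_j is fitted over the
    common features and x_j is mapped through it, which zeroes both the
    mean of M = x_ref - x_j' and the trend of M against A over those
    features. Falls back to a median-offset alignment when fewer than
    ``min_common`` common features are available.
    """
    reference = reference or log2_mat.columns[0]
    if reference not in log2_mat.columns:
        raise ValueError(f"reference sample {reference!r} not in matrix")
    mask = np.ones(len(log2_mat), dtype=bool) if common_mask is None else np.asarray(common_mask, bool)
    xr = log2_mat.loc[mask, reference].to_numpy()
    out = log2_mat.copy()
    params: dict[str, tuple[float, float]] = {}
    for col in log2_mat.columns:
        if col == reference:
            params[col] = (0.0, 1.0)
            continue
        xj = log2_mat.loc[mask, col].to_numpy()
        if mask.sum() < min_common:
            logger.warning(
                "only %d common features; falling back to median-offset alignment", mask.sum()
            )
            u, v = float(np.median(xr) - np.median(xj)), 1.0
        else:
            if np.var(xj) == 0:
                raise ValueError(f"degenerate fit: zero variance in sample {col!r}")
            v, u = np.polyfit(xj, xr, 1)
        out[col] = u + v * log2_mat[col]
        params[col] = (float(u), float(v))
    return out, params


def summit_distance(
    sites_a: list[BindingSite],
    sites_b: list[BindingSite],
    factor_a: str | None = None,
    factor_b: str | None = None,
    control_distances: np.ndarray | None = None,
) -> dict:
    """|summit_A - summit_B| for every pair of sites overlapping >= 1 bp.

    One distance per overlapping (A, B) pair, which makes the statistic
    symmetric in its arguments. Returns distances, their median, and
    (optionally) a two-sided Mann-Whitney comparison against a control
    distance distribution.
    """

    def _summit(site: BindingSite, factor: str | None) -> int | None:
        if factor is not None:
            s = site.summits.get(factor)
            return int(s) if s is not None else None
        return int(next(iter(site.summits.values()))) if site.summits else None

    b_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for sb in sites_b:
        s = _summit(sb, factor_b)
        if s is not None:
            b_by_chrom.setdefault(sb.interval.chrom, []).append((sb.interval.start, sb.interval.end, s))
    dists = []
    for sa in sites_a:
        s_a = _summit(sa, factor_a)
        if s_a is None:
            continue
        dists.extend(
            abs(s_a - s_b)
            for (bs, be, s_b) in b_by_chrom.get(sa.interval.chrom, [])
            if bs < sa.interval.end and sa.interval.start < be
        )
    dists = np.asarray(dists, dtype=float)
    result = {"distances": dists, "median": float(np.median(dists)) if len(dists) else np.nan}
    if control_distances is not None and len(dists) and len(control_distances):
        stat, p = stats.mannwhitneyu(dists, control_distances, alternative="two-sided")
        result["mannwhitney_u"], result["mannwhitney_p"] = float(stat), float(p)
    return result


def correlate_and_cluster(signal: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson r^2 between samples (columns) and average-linkage
    hierarchical clustering on 1 - r^2; leaf order is deterministic
    (columns are pre-sorted by label before linkage)."""
    mat = signal[sorted(signal.columns)]
    r = np.corrcoef(mat.to_numpy().T)
    r2 = pd.DataFrame(r**2, index=mat.columns, columns=mat.columns)
    dist = 1.0 - r2.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [mat.columns[i] for i in hierarchy.leaves_list(link)]
    return r2, order
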