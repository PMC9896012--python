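"""Readers/writers for BED, bedGraph, FASTA and TSV tables, plus run config.

Every downstream module consumes the in-memory types defined here; no
analysis operation reads a file directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

# ---------------------------------------------------------------- BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse a BED3/BED6+ file into GenomicInterval records, order preserved.

    Extra columns beyond the sixth are retained in ``extra['rest']``.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = GenomicInterval(fields[0], start, end, strand, name, score)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if len(fields) > 6:
                iv.extra["rest"] = fields[6:]
            intervals.append(iv)
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            has6 = iv.name is not None or iv.score is not None or iv.strand != "." or iv.extra.get("rest")
            if has6:
                cols += [
                    iv.name if iv.name is not None else ".",
                    format(iv.score, "g") if iv.score is not None else ".",
                    iv.strand,
                ]
                cols += list(iv.extra.get("rest", []))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------- coverage


@dataclass
class CoverageTrack:
    """Per-chromosome read-depth arrays at a fixed bin width.

    Values are non-negative reals (counts or count densities per bin);
    ``library_size`` is the total mapped-fragment count for the sample.
    """

    data: dict[str, np.ndarray]
    bin_width: int = 1
    library_size: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative coverage on {chrom}")
            self.data[chrom] = arr

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom]) * self.bin_width

    def values_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Bin values covering [start, end); partial edge bins are included."""
        lo = start // self.bin_width
        hi = -(-end // self.bin_width)
        return self.data[chrom][lo:hi]

    def area(self, chrom: str, start: int, end: int) -> float:
        """Total signal over [start, end): bin totals, pro-rated for
        partial edge bins (per-base depth when bin_width is 1)."""
        arr = self.data[chrom]
        bw = self.bin_width
        lo, hi = start // bw, min(-(-end // bw), len(arr))
        if lo >= hi:
            return 0.0
        total = 0.0
        for b in (lo, hi - 1) if hi - 1 > lo else (lo,):
            b_start, b_end = b * bw, (b + 1) * bw
            frac = (min(end, b_end) - max(start, b_start)) / bw
            total += arr[b] * frac
        if hi - lo > 2:
            total += float(arr[lo + 1 : hi - 1].sum())
        return total


def read_bedgraph(
    path: str | Path, chrom_lengths: Mapping[str, int] | None = None, library_size: float | None = None
) -> CoverageTrack:
    """Read a bedGraph into a per-base CoverageTrack.

    Records must be sorted and non-overlapping within each chromosome;
    unspecified positions are zero.
    """
    records: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if value < 0:
                raise ValueError(f"{path}: line {lineno}: negative value")
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            recs = records.setdefault(chrom, [])
            if recs and start < recs[-1][1]:
                raise ValueError(f"{path}: line {lineno}: overlapping or unsorted records")
            recs.append((start, end, value))
    lengths = dict(chrom_lengths or {})
    for chrom, recs in records.items():
        lengths.setdefault(chrom, recs[-1][1])
    data = {}
    for chrom, length in lengths.items():
        arr = np.zeros(length)
        for start, end, value in records.get(chrom, []):
            arr[start:end] = value
        data[chrom] = arr
    total = sum(float(a.sum()) for a in data.values())
    return CoverageTrack(data, bin_width=1, library_size=library_size or max(total, 1.0))


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Run-length-encode a track back to bedGraph (zero runs omitted)."""
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    fh.write(f"{chrom}\t{s * bw}\t{e * bw}\t{arr[s]:g}\n")


# ---------------------------------------------------------------- tables


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with feature IDs in the first column, sample IDs in the header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature IDs: {dups[:5]}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = df.index[(df[col].isna() | bad)][0]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- config


@dataclass
class RunConfig:
    """Resolved run configuration; every tunable threshold has a default here.

    ``background_q`` is the empirical-percentile level of the quantitative
    peak filter (counts above the q-quantile of random background regions
    are retained). GSEA settings follow the weighted pre-ranked scheme.
    """

    seed: int = 0
    conditions: tuple[str, ...] = (
        "normoxia_DMSO",
        "normoxia_ITE",
        "normoxia_FICZ",
        "hypoxia_DMSO",
        "hypoxia_ITE",
        "hypoxia_FICZ",
    )
    factors: tuple[str, ...] = ("AHR", "HIF1", "HIF2", "ARNT")
    background_q: float = 0.9999
    n_background_regions: int = 100_000
    caller_min_fold: float = 4.0
    caller_alpha: float = 1e-3
    caller_min_len: int = 100
    caller_merge_dist: int = 100
    shape_bandwidth: float = 50.0
    shape_prominence: float = 5.0
    pseudocount: float = 0.5
    gsea_weight: float = 1.0
    gsea_nperm: int = 10_000
    bh_alpha: float = 0.05
    ranking_mode: str = "product"  # or "literal"
    score_aggregation: str = "mean"  # or "median"
    correlation_method: str = "spearman"  # or "pearson"
    motif_flank: int = 100
    fragment_width: int = 200
    bin_size: int = 1000
    shift_size: int = 150

    def __post_init__(self) -> None:
        if not (0.0 < self.background_q < 1.0):
            raise ValueError("background_q must lie in (0, 1)")
        if self.gsea_nperm < 1:
            raise ValueError("gsea_nperm must be >= 1")
        if self.ranking_mode not in ("product", "literal"):
            raise ValueError("ranking_mode must be 'product' or 'literal'")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("conditions", "factors"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["conditions"] = list(doc["conditions"])
        doc["factors"] = list(doc["factors"])
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
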