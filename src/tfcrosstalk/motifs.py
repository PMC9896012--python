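"""Core-motif scanning for the NCGTG consensus and variant-preference
statistics (hypoxia response element ACGTG vs xenobiotic response element
GCGTG)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VARIANTS = ("A", "C", "G", "T")
FOLD_CAP = 1e6


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class MotifHit:
    """One NCGTG occurrence within a site sequence.

    ``offset`` is the 0-based start of the matched pentamer on the given
    sequence; ``variant`` is the N base as read on the motif strand.
    """

    site_id: str
    offset: int
    strand: str
    variant: str


def scan_ncgtg(sequences: dict[str, str]) -> list[MotifHit]:
    """All NCGTG occurrences on both strands of each site sequence.

    Overlapping hits are all reported. A minus-strand motif appears as
    CACGN in the given sequence; its variant is the complement of the
    final base.
    """
    hits: list[MotifHit] = []
    for site_id, seq in sequences.items():
        s = seq.upper()
        for i in range(len(s) - 4):
            penta = s[i : i + 5]
            if penta[1:] == "CGTG" and penta[0] in VARIANTS:
                hits.append(MotifHit(site_id, i, "+", penta[0]))
            if penta[:4] == "CACG" and penta[4] in VARIANTS:
                hits.append(MotifHit(site_id, i, "-", penta[4].translate(COMPLEMENT)))
    return hits


def extract_site_sequences(
    genome: dict[str, str], sites, flank: int = 100
) -> dict[str, str]:
    """Sequence +/- flank bp around each site's summit (or midpoint)."""
    out = {}
    for i, site in enumerate(sites):
        iv = site.interval
        centre = next(iter(site.summits.values()), None)
        if centre is None:
            centre = (iv.start + iv.end) // 2
        chrom_seq = genome[iv.chrom]
        lo, hi = max(0, centre - flank), min(len(chrom_seq), centre + flank)
        sid = getattr(site, "site_id", None) or f"site_{i:05d}_{iv.chrom}:{iv.start}"
        out[sid] = chrom_seq[lo:hi]
    return out


def variant_enrichment(
    foreground: dict[str, str], background: dict[str, str]
) -> pd.DataFrame:
    """Per-variant fold enrichment and Fisher exact p.

    A site counts as positive for variant N when it contains >= 1 NCGTG
    hit with that N (either strand). Fold = fg frequency / bg frequency;
    an infinite fold (bg frequency 0) is capped and flagged.
    """
    fg_hits, bg_hits = scan_ncgtg(foreground), scan_ncgtg(background)
    rows = []
    n_fg, n_bg = len(foreground), len(background)
    for v in VARIANTS:
        fg_pos = len({h.site_id for h in fg_hits if h.variant == v})
        bg_pos = len({h.site_id for h in bg_hits if h.variant == v})
        table = [[fg_pos, n_fg - fg_pos], [bg_pos, n_bg - bg_pos]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        fg_freq = fg_pos / n_fg if n_fg else 0.0
        bg_freq = bg_pos / n_bg if n_bg else 0.0
        capped = bg_freq == 0.0 and fg_freq > 0.0
        fold = FOLD_CAP if capped else (fg_freq / bg_freq if bg_freq > 0 else np.nan)
        rows.append(
            {
                "variant": v,
                "motif": v + "CGTG",
                "fg_sites": fg_pos,
                "bg_sites": bg_pos,
                "fg_freq": fg_freq,
                "bg_freq": bg_freq,
                "fold": fold,
                "fold_capped": capped,
                "fisher_p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("variant")
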