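"""Synthetic data with the statistical structure of a two-factor
competition experiment.

The generator emulates ChIP-seq of three DNA-binding bHLH-PAS activators
(AHR, HIF-1α, HIF-2α) that all require the same limiting dimerization
partner (ARNT / HIF-1β). Competition is modelled at the dimer-fraction
level: in condition c each factor X is active at level a_X(c) >= 0 and the
fraction of X bound into productive dimers saturates as

    f_X(c) = a_X(c) / (K + sum_Y a_Y(c))

so activating any one factor necessarily lowers the dimer fraction of the
others (trans-antagonism through the shared pool). Chromatin occupancy of
X at site s with intrinsic strength S_s is

    occ_{X,s}(c) = S_s * f_X(c) * m_{X,s} * (1 + gamma * f_P(s)(c))

where m_{X,s} is 1 iff X has a motif planted at s, and f_P(s) is the dimer
fraction of the partner factor when s is a shared (co-bound) site; gamma
>= 0 is the cis-cooperation coefficient that lets two factors bound at the
same site reinforce each other.

Six stimulus conditions mirror a {normoxia, hypoxia} x {vehicle, ITE,
FICZ} design, with FICZ driving slightly weaker AHR activity than ITE.
Planted motifs are the hypoxia response element ACGTG for HIF and the
xenobiotic response element GCGTG for AHR; shared sites carry both motifs
separated by a configurable offset (default 40 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io import CoverageTrack

HIF_MOTIF = "ACGTG"
AHR_MOTIF = "GCGTG"

SITE_CLASSES = ("AHR", "HIF1", "HIF2", "AHR&HIF1", "AHR&HIF2", "HIF1&HIF2")

#: which factors carry a motif at a site of each class
CLASS_FACTORS = {
    "AHR": ("AHR",),
    "HIF1": ("HIF1",),
    "HIF2": ("HIF2",),
    "AHR&HIF1": ("AHR", "HIF1"),
    "AHR&HIF2": ("AHR", "HIF2"),
    "HIF1&HIF2": ("HIF1", "HIF2"),
}

DEFAULT_ACTIVITIES = {
    #              AHR   HIF1  HIF2
    "normoxia_DMSO": (0.02, 0.03, 0.03),
    "normoxia_ITE": (1.00, 0.03, 0.03),
    "normoxia_FICZ": (0.80, 0.03, 0.03),
    "hypoxia_DMSO": (0.02, 1.00, 0.70),
    "hypoxia_ITE": (1.00, 1.00, 0.70),
    "hypoxia_FICZ": (0.80, 1.00, 0.70),
}

DEFAULT_CLASS_COUNTS = {
    "AHR": 50,
    "HIF1": 40,
    "HIF2": 20,
    "AHR&HIF1": 15,
    "AHR&HIF2": 10,
    "HIF1&HIF2": 15,
}


@dataclass
class OccupancyModel:
    """Competitive-dimerization occupancy model.

    activities maps condition -> {factor: a_X}; K is the half-saturation
    constant of the shared-partner pool (the pool size B is absorbed into
    the site strengths), gamma the cis-cooperation coefficient, and
    ``sites`` the planted-site table (chrom, start, end, site_class,
    strength, motif positions/strand, offset).
    """

    activities: dict[str, dict[str, float]]
    K: float = 1.0
    gamma: float = 0.0
    B: float = 1.0
    sites: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.K <= 0 or self.B <= 0:
            raise ValueError("K and B must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        for cond, acts in self.activities.items():
            for fac, a in acts.items():
                if a < 0:
                    raise ValueError(f"a_{fac}({cond}) must be >= 0")

    @property
    def conditions(self) -> list[str]:
        return list(self.activities)

    def dimer_fractions(self, condition: str) -> dict[str, float]:
        if condition not in self.activities:
            raise KeyError(f"unknown condition {condition!r}")
        acts = self.activities[condition]
        denom = self.K + sum(acts.values())
        return {fac: a / denom for fac, a in acts.items()}


def default_model(
    rng: np.random.Generator,
    genome_length: int = 2_000_000,
    class_counts: dict[str, int] | None = None,
    site_width: int = 400,
    min_spacing: int = 2_000,
    motif_offset: int = 40,
    gamma: float = 0.0,
    K: float = 1.0,
    chrom: str = "chrS",
) -> OccupancyModel:
    """Build a model with the default six-condition design and a random
    site layout on a single synthetic chromosome (sites >= 2 kb apart)."""
    counts = dict(class_counts or DEFAULT_CLASS_COUNTS)
    n_sites = sum(counts.values())
    span = site_width + min_spacing
    usable = genome_length - 2 * min_spacing
    if n_sites * span > usable:
        raise ValueError("genome too small for requested site count and spacing")
    # evenly spaced slots with random jitter keeps sites collision-free
    slots = np.linspace(min_spacing, genome_length - min_spacing - site_width, n_sites)
    jitter = rng.uniform(-min_spacing / 4, min_spacing / 4, n_sites)
    starts = np.sort((slots + jitter).astype(int))
    classes = [cls for cls, n in counts.items() for _ in range(n)]
    rng.shuffle(classes)
    rows = []
    for i, (start, cls) in enumerate(zip(starts, classes)):
        centre = start + site_width // 2
        strand = "+" if rng.random() < 0.5 else "-"
        factors = CLASS_FACTORS[cls]
        if len(factors) == 1:
            motif_pos = {factors[0]: centre}
        else:
            motif_pos = {
                factors[0]: centre - motif_offset // 2,
                factors[1]: centre + motif_offset - motif_offset // 2,
            }
        rows.append(
            {
                "site_id": f"site_{i:04d}",
                "chrom": chrom,
                "start": int(start),
                "end": int(start + site_width),
                "site_class": cls,
                "strength": float(rng.uniform(0.8, 1.2)),
                "strand": strand,
                "motif_offset": motif_offset if len(factors) > 1 else 0,
                **{f"motif_{f}": motif_pos.get(f, -1) for f in ("AHR", "HIF1", "HIF2")},
            }
        )
    sites = pd.DataFrame(rows).set_index("site_id")
    activities = {
        cond: dict(zip(("AHR", "HIF1", "HIF2"), vals)) for cond, vals in DEFAULT_ACTIVITIES.items()
    }
    return OccupancyModel(activities=activities, K=K, gamma=gamma, sites=sites)


def simulate_occupancy(model: OccupancyModel, condition: str) -> pd.DataFrame:
    """Deterministic per-site, per-factor occupancy under one condition.

    Columns AHR/HIF1/HIF2 give occ_{X,s}; ARNT is their sum (every
    productive dimer contains the shared partner).
    """
    f = model.dimer_fractions(condition)
    sites = model.sites
    occ = pd.DataFrame(0.0, index=sites.index, columns=["AHR", "HIF1", "HIF2"])
    partner_of = {}
    for cls, factors in CLASS_FACTORS.items():
        if len(factors) == 2:
            partner_of[(cls, factors[0])] = factors[1]
            partner_of[(cls, factors[1])] = factors[0]
    for factor in ("AHR", "HIF1", "HIF2"):
        has_motif = sites["site_class"].map(lambda c: factor in CLASS_FACTORS[c])
        boost = sites["site_class"].map(
            lambda c: 1.0 + model.gamma * f.get(partner_of.get((c, factor), ""), 0.0)
        )
        occ[factor] = sites["strength"] * f[factor] * has_motif.astype(float) * boost
    occ["ARNT"] = occ[["AHR", "HIF1", "HIF2"]].sum(axis=1)
    return occ


# ---------------------------------------------------------------- ChIP noise


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with Var = mean + alpha * mean^2; alpha = 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def simulate_region_counts(
    model: OccupancyModel,
    condition: str,
    factor: str,
    n_replicates: int = 2,
    rng: np.random.Generator | None = None,
    scale: float = 1000.0,
    background: float = 5.0,
    dispersion: float = 0.05,
) -> pd.DataFrame:
    """Observed per-site counts for one factor's ChIP in one condition.

    Expected count lambda_s = background + scale * occ_s; replicates are
    independent NB draws around the same expectation.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = rng or np.random.default_rng(0)
    occ = simulate_occupancy(model, condition)[factor].to_numpy()
    lam = background + scale * occ
    data = {
        f"{factor}_{condition}_rep{r + 1}": _nb_draw(rng, lam, dispersion)
        for r in range(n_replicates)
    }
    return pd.DataFrame(data, index=model.sites.index)


def simulate_chip(
    model: OccupancyModel,
    condition: str,
    factor: str,
    genome_length: int,
    n_replicates: int = 2,
    seed: int = 0,
    scale: float = 1000.0,
    background: float = 5.0,
    dispersion: float = 0.05,
    fragment_width: int = 200,
    bin_width: int = 10,
    chrom: str = "chrS",
) -> tuple[list[CoverageTrack], pd.DataFrame]:
    """Coverage tracks (one per replicate) plus the per-site count table.

    Site signal is shaped as a triangular kernel of the fragment width
    centred on each planted motif (shared sites therefore show two kernels
    separated by the motif offset); per-bin counts get NB noise. The same
    seed reproduces identical output.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    occ = simulate_occupancy(model, condition)[factor]
    n_bins = -(-genome_length // bin_width)
    lam = np.full(n_bins, background * bin_width / fragment_width, dtype=float)

    half = fragment_width  # kernel half-width: fragments span the motif
    positions = (np.arange(n_bins) + 0.5) * bin_width
    factors_here = ("AHR", "HIF1", "HIF2") if factor == "ARNT" else (factor,)
    occ_all = simulate_occupancy(model, condition)
    for sid, row in model.sites.iterrows():
        for fac in factors_here:
            pos = row.get(f"motif_{fac}", -1)
            o = occ_all.loc[sid, fac]
            if pos < 0 or o <= 0:
                continue
            lo = max(0, int((pos - half) // bin_width))
            hi = min(n_bins, int((pos + half) // bin_width) + 1)
            tri = np.clip(1.0 - np.abs(positions[lo:hi] - pos) / half, 0.0, None)
            # area of the kernel equals scale*occ counts spread over bins
            lam[lo:hi] += scale * o * tri / max(tri.sum(), 1e-12)
    tracks = []
    counts = {}
    for r in range(n_replicates):
        vals = _nb_draw(rng, lam, dispersion).astype(float)
        track = CoverageTrack({chrom: vals}, bin_width=bin_width, library_size=float(vals.sum()))
        tracks.append(track)
        # per-site observed counts = bin totals within the site span
        site_counts = [
            float(vals[row["start"] // bin_width : -(-row["end"] // bin_width)].sum())
            for _, row in model.sites.iterrows()
        ]
        counts[f"{factor}_{condition}_rep{r + 1}"] = site_counts
    return tracks, pd.DataFrame(counts, index=model.sites.index)


# ---------------------------------------------------------------- genome


def simulate_genome(
    model: OccupancyModel, genome_length: int = 2_000_000, seed: int = 0, chrom: str = "chrS"
) -> dict[str, str]:
    """i.i.d. uniform ACGT background with motifs planted at site positions.

    AHR sites get GCGTG, HIF sites ACGTG, on the site's declared strand.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=genome_length)
    comp = str.maketrans("ACGT", "TGCA")
    for _, row in model.sites.iterrows():
        for fac, motif in (("AHR", AHR_MOTIF), ("HIF1", HIF_MOTIF), ("HIF2", HIF_MOTIF)):
            pos = row.get(f"motif_{fac}", -1)
            if pos < 0:
                continue
            planted = motif if row["strand"] == "+" else motif.translate(comp)[::-1]
            start = int(pos) - len(motif) // 2
            seq[start : start + len(motif)] = list(planted)
    return {chrom: "".join(seq)}


# ---------------------------------------------------------------- RNA


def make_gene_table(
    model: OccupancyModel,
    rng: np.random.Generator,
    n_null_genes: int = 150,
    genome_length: int = 2_000_000,
    chrom: str = "chrS",
    beta: float = 2.0,
) -> pd.DataFrame:
    """One responsive gene per site (TSS within 1 kb of the site) plus
    unlinked null genes; beta_g is the log2 occupancy->expression slope."""
    rows = []
    for i, (sid, row) in enumerate(model.sites.iterrows()):
        offset = int(rng.integers(200, 1000)) * (1 if rng.random() < 0.5 else -1)
        tss = int(np.clip(row["start"] + (row["end"] - row["start"]) // 2 + offset, 0, genome_length - 1))
        rows.append(
            {
                "gene_id": f"gene_{sid}",
                "chrom": chrom,
                "tss": tss,
                "strand": "+" if rng.random() < 0.5 else "-",
                "linked_site": sid,
                "beta": beta,
                "base_mean": float(rng.uniform(50, 500)),
            }
        )
    # null genes fall midway between sites, far from any planted site
    site_mids = model.sites["start"].to_numpy()
    for j in range(n_null_genes):
        pos = int(rng.integers(0, genome_length))
        if np.abs(site_mids - pos).min() < 5_000:
            pos = (pos + 10_000) % genome_length
        rows.append(
            {
                "gene_id": f"gene_null_{j:04d}",
                "chrom": chrom,
                "tss": pos,
                "strand": "+" if rng.random() < 0.5 else "-",
                "linked_site": "",
                "beta": 0.0,
                "base_mean": float(rng.uniform(50, 500)),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def simulate_rna(
    gene_table: pd.DataFrame,
    model: OccupancyModel,
    conditions: list[str],
    n_replicates: int = 6,
    dispersion: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-level NB counts per condition.

    Gene mean mu_g(c) = base_g * 2**(beta_g * occ_link(g, c) / occ_max),
    where occ_link is the total occupancy (all factors) at the gene's
    linked site and occ_max the maximum such total over all sites and the
    supplied conditions.
    """
    rng = np.random.default_rng(seed)
    occ_by_cond = {c: simulate_occupancy(model, c) for c in conditions}
    totals = {c: occ_by_cond[c][["AHR", "HIF1", "HIF2"]].sum(axis=1) for c in conditions}
    occ_max = max(float(t.max()) for t in totals.values()) or 1.0
    data = {}
    for cond in conditions:
        link = gene_table["linked_site"]
        occ_link = np.where(
            link.eq("").to_numpy(),
            0.0,
            totals[cond].reindex(link.replace("", pd.NA)).fillna(0.0).to_numpy(),
        )
        mu = gene_table["base_mean"].to_numpy() * 2.0 ** (
            gene_table["beta"].to_numpy() * occ_link / occ_max
        )
        for r in range(n_replicates):
            data[f"{cond}_rep{r + 1}"] = _nb_draw(rng, mu, dispersion)
    return pd.DataFrame(data, index=gene_table.index)


# ---------------------------------------------------------------- cohort


def simulate_cohort(
    n_pairs: int,
    signatures: dict[str, list[str]],
    delta_hif: float = 0.5,
    delta_ahr: float = -0.5,
    cn_dose: dict[int, float] | None = None,
    cn_probs: dict[int, float] | None = None,
    sigma: float = 1.0,
    n_other_genes: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired normal/tumour expression cohort with copy-number strata.

    Tumour samples shift HIF-signature genes by +delta_hif and AHR genes
    by delta_ahr (negative) on the log2 scale, scaled by the tumour's
    copy-number dose multiplier and a shared per-patient activation factor
    (the shared factor makes HIF-up and AHR-down co-occur within a
    patient, as loss of VHL would cause). Common-signature genes receive
    delta_hif + delta_ahr. Returns (expression linear-scale genes x
    samples, metadata).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    cn_dose = cn_dose or {0: 1.0, -1: 1.5, -2: 2.0}
    cn_probs = cn_probs or {0: 0.3, -1: 0.5, -2: 0.2}
    genes: list[str] = []
    delta_map: dict[str, float] = {}
    for name, glist in signatures.items():
        for g in glist:
            genes.append(g)
            if name == "HIF":
                delta_map[g] = delta_hif
            elif name == "AHR":
                delta_map[g] = delta_ahr
            elif name == "common":
                delta_map[g] = delta_hif + delta_ahr
            else:
                delta_map[g] = 0.0
    genes += [f"bg_gene_{i:04d}" for i in range(n_other_genes)]
    genes = list(dict.fromkeys(genes))
    base = rng.normal(8.0, 1.0, size=len(genes))
    cn_levels = list(cn_dose)
    probs = np.array([cn_probs[c] for c in cn_levels], dtype=float)
    probs = probs / probs.sum()
    meta_rows, cols = [], {}
    deltas = np.array([delta_map.get(g, 0.0) for g in genes])
    for p in range(n_pairs):
        patient = f"P{p + 1:03d}"
        cn = int(rng.choice(cn_levels, p=probs))
        activation = rng.normal(1.0, 0.3)
        for tissue in ("normal", "tumour"):
            sample = f"{patient}_{tissue}"
            log_expr = base + rng.normal(0.0, sigma, size=len(genes))
            if tissue == "tumour":
                log_expr = log_expr + deltas * cn_dose[cn] * activation
            cols[sample] = np.maximum(2.0**log_expr - 1.0, 0.0)
            meta_rows.append(
                {
                    "sample": sample,
                    "patient": patient,
                    "tissue": tissue,
                    "cn_group": cn if tissue == "tumour" else 0,
                }
            )
    expr = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return expr, meta


# ---------------------------------------------------------------- dataset


@dataclass
class SimulatedDataset:
    """Everything a full pipeline run consumes, generated from one seed."""

    model: OccupancyModel
    genome: dict[str, str]
    gene_table: pd.DataFrame
    chip_tracks: dict[tuple[str, str, int], CoverageTrack]  # (factor, condition, rep)
    chip_counts: pd.DataFrame  # sites x (factor_condition_rep)
    input_track: CoverageTrack
    gene_counts: pd.DataFrame
    cohort_expr: pd.DataFrame | None = None
    cohort_meta: pd.DataFrame | None = None


def simulate_dataset(
    seed: int = 0,
    genome_length: int = 2_000_000,
    gamma: float = 0.5,
    class_counts: dict[str, int] | None = None,
    conditions: list[str] | None = None,
    n_chip_replicates: int = 2,
    n_rna_replicates: int = 6,
    scale: float = 1000.0,
    background: float = 5.0,
    dispersion: float = 0.05,
    bin_width: int = 10,
    with_cohort: bool = False,
) -> SimulatedDataset:
    """Generate the full six-condition, four-factor dataset."""
    root = np.random.SeedSequence(seed)
    keys = root.spawn(6)
    rng_model = np.random.default_rng(keys[0])
    model = default_model(rng_model, genome_length=genome_length, gamma=gamma, class_counts=class_counts)
    conditions = conditions or model.conditions
    genome = simulate_genome(model, genome_length, seed=int(keys[1].generate_state(1)[0] % 2**31))
    gene_table = make_gene_table(model, np.random.default_rng(keys[2]), genome_length=genome_length)
    tracks: dict[tuple[str, str, int], CoverageTrack] = {}
    count_frames = []
    chip_seed_root = keys[3]
    sub = {
        (factor, cond): s
        for (factor, cond), s in zip(
            [(f, c) for f in ("AHR", "HIF1", "HIF2", "ARNT") for c in conditions],
            chip_seed_root.spawn(4 * len(conditions)),
        )
    }
    for (factor, cond), ss in sub.items():
        tr, cnt = simulate_chip(
            model,
            cond,
            factor,
            genome_length,
            n_replicates=n_chip_replicates,
            seed=int(ss.generate_state(1)[0] % 2**31),
            scale=scale,
            background=background,
            dispersion=dispersion,
            bin_width=bin_width,
        )
        for r, t in enumerate(tr):
            tracks[(factor, cond, r + 1)] = t
        count_frames.append(cnt)
    chip_counts = pd.concat(count_frames, axis=1)
    # input control: flat background, no site signal
    rng_in = np.random.default_rng(keys[4])
    n_bins = -(-genome_length // bin_width)
    in_vals = _nb_draw(rng_in, np.full(n_bins, background * bin_width / 200.0), dispersion).astype(float)
    input_track = CoverageTrack({"chrS": in_vals}, bin_width=bin_width, library_size=float(in_vals.sum()))
    gene_counts = simulate_rna(
        gene_table, model, conditions, n_replicates=n_rna_replicates,
        dispersion=dispersion, seed=int(keys[5].generate_state(1)[0] % 2**31),
    )
    ds = SimulatedDataset(
        model=model,
        genome=genome,
        gene_table=gene_table,
        chip_tracks=tracks,
        chip_counts=chip_counts,
        input_track=input_track,
        gene_counts=gene_counts,
    )
    if with_cohort:
        sigs = {
            "HIF": [f"gene_{s}" for s in model.sites.index[model.sites["site_class"].isin(["HIF1", "HIF2", "HIF1&HIF2"])]],
            "AHR": [f"gene_{s}" for s in model.sites.index[model.sites["site_class"] == "AHR"]],
            "common": [f"gene_{s}" for s in model.sites.index[model.sites["site_class"].isin(["AHR&HIF1", "AHR&HIF2"])]],
        }
        ds.cohort_expr, ds.cohort_meta = simulate_cohort(72, sigs, seed=seed + 1)
    return ds
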