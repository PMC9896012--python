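# Methods

## Occupancy model

The generator treats chromatin binding of AHR, HIF-1α and HIF-2α as
limited by a shared dimerization partner (ARNT/HIF-1β). Factor X has an
activity a_X(c) ≥ 0 in condition c (arbitrary units; activity summarises
ligand binding, protein stabilisation and nuclear abundance). The
fraction of X present as productive DNA-binding dimer follows a
Michaelis-like saturation of the shared pool:

    f_X(c) = a_X(c) / (K + Σ_Y a_Y(c)),

so the f_X lie in [0, 1], sum to < 1, and each is strictly decreasing in
every other factor's activity — the trans-antagonism is built in rather
than emergent. The partner pool size is absorbed into the per-site
strengths, so K (default 1.0) is the only competition constant.
Occupancy of X at site s is

    occ_{X,s}(c) = S_s · f_X(c) · m_{X,s} · (1 + γ · f_P(s)(c)),

with site strength S_s ~ U(0.8, 1.2), motif indicator m_{X,s} ∈ {0, 1},
and, at sites carrying motifs for two factors, a cis-cooperation boost
proportional to the partner's dimer fraction with coefficient γ ≥ 0
(default 0.5 for end-to-end runs; 0 turns the effect off exactly). ARNT
occupancy is the sum over factor occupancies, since every productive
dimer contains ARNT. This is a deliberately minimal phenomenological
model: it is not a thermodynamic simulation, and it reproduces the
qualitative structure (reciprocal repression, cis mitigation, dual
targets) with recoverable parameters, which is what the tests need.

### Default design

Six conditions mirror a {normoxia, hypoxia} × {vehicle(DMSO), ITE, FICZ}
design: a_AHR = 1.0 (ITE), 0.8 (FICZ, slightly weaker), 0.02 (vehicle);
a_HIF1 = 1.0 and a_HIF2 = 0.7 under hypoxia, 0.03 under normoxia (a
small residual activity, as HIF is never fully off). No quantitative
dimerization affinities are available for these factors, so the relative
activities are free parameters of the generator, fixed once at these
values.

Sites: 150 planted on one synthetic 2 Mb chromosome (600 kb in the
default end-to-end run, scaled with the site count), ≥ 2 kb apart, 400 bp
wide, in six classes — AHR-only (50), HIF1-only (40), HIF2-only (20),
AHR∩HIF1 (15), AHR∩HIF2 (10), HIF1∩HIF2 (15); the end-to-end run uses
the same proportions at 63 sites. Shared sites carry both motifs
separated by 40 bp (the order of the observed summit separation between
co-bound factors), single sites one motif at the centre. Background
sequence is i.i.d. uniform ACGT; planted motifs are GCGTG (AHR) and
ACGTG (HIF) on a random recorded strand.

### Noise model

Per-site expected ChIP count is λ_s = background + scale · occ_s
(background 5, scale 1000, giving roughly 40–80× peak enrichment at
active sites — comfortably above the callers' thresholds, as a
well-enriched ChIP should be). Observed counts are negative binomial
with Var = λ + αλ² (α = 0.05; α = 0 degenerates to Poisson). Coverage
tracks shape λ as a triangular kernel of the fragment width (200 bp)
centred on each planted motif, binned at 10 bp, with independent NB
noise per bin and replicate. RNA-seq: gene mean μ_g(c) = base_g ·
2^(β_g · occ_link(g,c)/occ_max) with base_g ~ U(50, 500), β_g = 2 for
the one gene linked to each site (TSS within 1 kb) and 0 for 150
unlinked null genes; six replicates per condition, NB noise. Cohort:
72 patient pairs; tumour samples shift each HIF-signature gene by
+δ_HIF = +0.5 log₂ units and each AHR-signature gene by δ_AHR = −0.5,
both multiplied by a copy-number dose factor (VHL CN 0/−1/−2 →
1.0/1.5/2.0, sampled 0.3/0.5/0.2) and a shared per-patient activation
factor ~ N(1, 0.3); the shared factor is what makes HIF-up and AHR-down
co-occur within a patient and hence drives the negative score
correlation. Per-gene noise σ = 1 on the log₂ scale.

### What the generator does not emulate

Read-level artefacts (mappability, GC bias, duplicates), chromatin
accessibility structure, copy-number effects on ChIP signal, correlated
gene-gene expression beyond the planted signatures, and tumour purity.
Passing tests therefore demonstrate that the analysis recovers the
statistical structure it assumes, not that it is robust to every
real-data artefact.

## Analysis pipeline

**Peak calling.** Two deliberately different callers: (A) enrichment
over a library-size-scaled control — bins with fold change ≥ 4 and
Poisson upper-tail p < 10⁻³, runs merged within 100 bp, length ≥ 100 bp,
summit at the maximum (plateaus: floor of the midpoint of the leftmost
maximal run); (B) shape — Gaussian-smoothed (bandwidth 50 bp) local
maxima with prominence above threshold, bounds from the width at 75% of
the prominence. A peak is kept only if called by both (≥ 1 bp overlap,
caller-A coordinates; which caller contributes coordinates is an
arbitrary but documented choice). Surviving peaks must exceed the
empirical 99.99th percentile (type-7 linear interpolation, recorded in
config) of total counts in random background regions — in synthetic
mode, up to 20,000 non-site regions of median peak width sampled with
the run seed, applied per condition — and must overlap (≥ 1 bp) between
the two replicates. A canonical site for a factor is a replicated factor
peak that also overlaps a replicated ARNT peak. Per-condition site sets
are unioned by overlap before Venn classification.

**Venn classification.** All canonical sites are merged (≥ 1 bp) into a
cluster universe and each cluster labelled with the set of factors
present; counts over this universe satisfy inclusion–exclusion exactly,
and the reporting helpers expose union, multi-factor counts and rounded
overlap percentages, which is also the path used for published-count
arithmetic.

**TSS annotation.** Signed summit-to-TSS distance; negative = upstream
in the gene's reading direction; ties broken toward the first TSS in
(position, gene) sort order.

**Quantification and normalisation.** Region counts are the area under
the coverage track divided by the fragment width (the coverage-level
surrogate for midpoint counting; the read-shift parameter is carried as
metadata). RPKM and MA normalisation are independent normalisation
paths. MA normalisation fits x_ref = u + v·x_j by OLS over common
features in log₂ space and maps x_j through the line, which zeroes the
mean and trend of M against A; below 10 common features it falls back to
a median-offset alignment with a logged warning. In the end-to-end run
MA normalisation is applied where its assumption (equal expected signal
over common features) holds — between replicates of the same factor ×
condition — while cross-condition contrasts use counts scaled by the 1%
trimmed mean of genome-wide bin counts, which tracks sequencing depth
without absorbing genuine global binding changes; normalising conditions
onto each other over peaks would subtract the trans-competition effect
that the analysis is designed to measure.

**Differential binding.** Per-feature method-of-moments NB dispersion on
scaled counts, α̂ = max(0, (s² − m)/m²), shrunk 50/50 toward the
10%-trimmed mean across features; two-group Wald test with
φ = log₂((m₂+ε)/(m₁+ε)), ε = 0.5, delta-method SE from
Var(m_i) = (m_i + αm_i²)/n_i, BH-adjusted q-values. The shared-vs-
individual strata are compared with a two-sided Mann–Whitney U (the
per-site tests are Wald; the strata contrast is a rank test by design).

**Motifs.** All NCGTG occurrences on both strands within ±100 bp of the
summit; per-variant presence/absence Fisher exact tests against
background sequences; infinite folds are capped and flagged.

**GSEA.** The ranking statistic combines log₂ fold change φ and p-value:
the default is the sign-aware product π = φ·(−log₁₀ Pv) (raw Pv, floored
at 10⁻³⁰⁰); the literal difference π = φ − log₁₀ Pv is available behind
a config switch but ranks strongly down-regulated significant genes
positively, which contradicts the use of the ranking to detect
depletion, hence it is not the default. Weighted running sum (weight 1):
hits add |π|^w normalised by the in-set total, misses subtract 1/(N−N_H);
ES is the signed maximum deviation, evaluated only at hit boundaries
(the statistic is piecewise linear between hits). The null is gene-set
permutation — random same-size sets without replacement, seeded —
with p = (1 + #{|ES₀| ≥ |ES|, same sign})/(#same-sign + 1); 10,000
permutations by default (2,000 in the bundled end-to-end run to keep it
fast at equivalent precision for the effect sizes involved).

**Cohort scoring.** Signatures: HIF = HIF-bound-only ∧ hypoxia-up,
AHR = AHR-bound-only ∧ ITE-up, common = co-bound ∧ up under both; the
single-factor signatures exclude the common genes and are disjoint by
construction (asserted). Composite score = per-sample mean of per-gene
z-standardised log₂(x+1) over all cohort samples (standardising over all
samples, and the unweighted mean, are the simplest schemes consistent
with "normalise, then combine"; a median aggregation is switchable);
signatures with < 50% gene coverage raise an error. Paired
tumour/normal comparison: Wilcoxon signed-rank (V = sum of positive
ranks; exact null for n ≤ 25, normal approximation with continuity
correction above; all-zero differences give p = 1 by convention,
logged). Copy-number strata are unpaired ordered groups, so a
Jonckheere–Terpstra trend test (seeded permutation p, pairwise
Mann–Whitney as secondary output) replaces the paired test there — a
deliberate substitution, since a paired test is undefined across strata.
Score correlation is Spearman by default (rank-robust; Pearson
switchable).

## Numerical and design choices

- Coordinates are 0-based half-open throughout; 1-based appears only in
  formatting. Chromosome names are taken verbatim.
- Overlap always means ≥ 1 bp on the same chromosome; all overlap
  operations are validated against an all-pairs oracle in the tests.
- Summit ties resolve to the floor of the midpoint of the leftmost
  maximal run (deterministic, symmetric for symmetric peaks).
- The summit-distance statistic reports one distance per overlapping
  site pair, making it symmetric in its two arguments.
- Per-stage seeds derive from the run seed via SHA-256 of
  "seed:stage", so stages are reproducible independently of execution
  order; every stochastic operation takes an explicit seed and the run
  manifest records config hash and output checksums.
- Degenerate inputs: empty background region sets, empty GSEA sets,
  sets equal to the universe, zero-variance MA fits, single
  copy-number groups and empty strata all raise explicit errors; empty
  gene sets in set construction warn rather than fail.
- Problem sizes in the bundled runs (150-site genome, 600 kb end-to-end
  chromosome, 20 seeds/simulations for recovery statistics, 2,000–10,000
  permutations) were chosen as the smallest sizes at which the planted
  effects are comfortably identifiable; all are parameters.

## Known limitations

The callers are intentionally simple surrogates for MACS/T-PIC-class
tools and are tuned for sharp transcription-factor peaks, not broad
marks; no IDR, no GC/mappability correction, no spike-in normalisation;
the differential model is a two-group contrast, not a GLM with blocking;
GSEA reports per-set permutation p only (no cross-set FDR or
leading-edge analysis); cohort scoring does not model tumour purity or
survival.
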