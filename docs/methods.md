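# Methods

`xenoplasma` re-implements, as a tested pipeline, the analysis of cell-free RNA
(cfRNA) from longitudinal low-volume plasma draws in a humanized
patient-derived-xenograft (PDTX) lymphoma mouse model. Real cohorts of this
kind are sequenced once and deposited; to make every stage testable without
downloads, the package pairs each analysis step with a synthetic cohort
generator whose ground truth (per-read species of origin, per-sample tumor
volume and cfRNA masses, cell-type mixture weights) is recorded and recovered
by the downstream statistics.

## Study design emulated by the generator

Arms combine humanization (HIS: a human immune system engrafted from cord-blood
stem cells), xenografting (a diffuse large B-cell lymphoma PDTX), and treatment
(PBS, R-CHOP, or huCD20-Fc-AFN-CHOP). Default: seven arms × 7 mice, with plasma
draws at pre-humanization (HIS only, day −14), pre-PDTX (day 0), pre-treatment
(day 14), post-treatment (day 28) and sacrifice (day 42), 80 µL plasma per
draw.

**Tumor growth.** Gompertz, V(t) = K·exp(ln(V0/K)·e^(−a·t)), with V0 = 20 mm³,
K = 2000 mm³, a = 0.06/day and lognormal per-mouse rate dispersion (σ = 0.15).
The growth law itself is a modeling choice — xenograft growth is heterogeneous
but no parametric law is implied by the data the pipeline consumes; Gompertz is
bounded and standard for xenografts. Humanized, untreated mice clear the graft
with probability 0.3 (Bernoulli, "immune control"); treated mice switch to
exponential decay at 0.12/day after day 14 unless flagged resistant
(probability 0.1). Caliper volume uses V = L·W²/2 with a fixed L/W = 1.5 aspect
ratio so recorded lengths/widths invert exactly to the simulated volume; a
mouse is sacrificed at the first day V > 1500 mm³ (the humane endpoint), and
draws scheduled after that day are dropped (the final draw moves to the
sacrifice day).

**cfRNA masses.** Per sample, murine background is 600 pg/mL; human cfRNA is
`humanization_baseline` (3.5 pg/mL) for humanized mice plus
`tumor_mass_coeff`·V(t) with 0.012 pg·mL⁻¹·mm⁻³. The two coefficients were
chosen so that an untreated xenograft near sacrifice shows human cfRNA of
roughly 15–20 pg/mL at a human read fraction of a few percent — the
concentration regime a low-volume plasma biopsy of this model actually
occupies. Spikes are added at known mass: an ERCC spike (default stock
5200 pg/µL, 1/200,000 dilution, 2 µL → 0.052 pg) and a Sequin mix
(2600 pg/µL, 1/260,000, 2 µL); stock concentrations are config inputs.

**Counts.** Reads are allocated to sources (murine background, human
endogenous, each spike) proportional to mass. Per-gene counts are
gamma–Poisson: each gene's weight is its profile value times a
Gamma(1/φ, φ) draw (φ = 0.3), giving negative-binomial marginals — the noise
model the downstream Wald test assumes — while weights are renormalized within
species so that per-sample species mass shares are exact and species-total
read counts stay Poisson-concentrated (this is what makes 5%-level
concentration recovery possible at 10⁴ spike reads). Library sizes are
lognormal (mean 120k reads, CV 0.3 by default; library depth is a free design
parameter of the generator, not a quantity the consumed tables dictate). The
human profile mixes an immune component (basis-matrix columns weighted by the
sample's true cell-type fractions) and a tumor component (lognormal profile
over tumor genes with the eight signature genes enriched 40-fold, plus a 30%
plasma-cell-marker component, the tumor being a B-cell malignancy). Treated
humanized mice have circulating B cells depleted to 15% of baseline after
treatment start.

**Cross-species artifacts.** 50 paired 200-bp hotspot windows per genome are
drawn once per seed inside gene bodies. A read overlapping its genome's window
is re-mapped, with probability 0.3, into the partner genome's paired window —
*uniquely* mapped (NH = 1), so unique-read selection cannot catch it; this is
precisely the artifact the empirical masking stage must remove. Independently,
5% of reads are multi-mappers (NH ∈ 2–8) removed by NH = 1 selection.
Coordinates are 0-based half-open throughout (BED convention).

## Species-of-origin splitting

1. `select_unique` keeps NH = 1 records.
2. `derive_mask` scans pure-species control samples (default 3 mouse + 3 human,
   500k reads each) and adds the interval of every cross-mapped control read to
   the mask of the genome it mapped to, merging overlaps. A single cross-mapped
   control read suffices to mask a region — maximally conservative, since no
   evidence threshold is dictated by the data. Padding defaults to 0 and strand
   is ignored (records carry none); both are exposed in config.
3. `apply_mask` removes records overlapping the mask by ≥1 bp on their mapped
   genome (idempotent).
4. `count_by_gene` counts union-mode: a read increments a gene iff it overlaps
   exactly one annotated gene on its mapped genome; ambiguous reads are
   discarded. Interval joins go through pyranges.

On default settings the mask removes ≥90% of misassigned reads while losing
≤1% of correctly assigned reads (measured against the generator's per-read
truth); the residual loss is reads genuinely inside hotspot windows.

## Quantification

Absolute concentration anchors on a spike of known mass m: concentration =
m · (endogenous reads / spike reads) / plasma volume, computed separately for
human and murine reads against the same anchor spike (ERCC-00130 by default).
Zero spike reads raise an explicit flagged error rather than silently zeroing.
Species fraction, detected-gene counts (min_count = 1 by default; "detected"
has no canonical definition, so the threshold is exposed), CPM normalization
(no log; optional per-species universe) and Spearman correlation complete the
per-sample metrics. Note that the signature score (below) uses CPM over the
*whole endogenous* library: per-species CPM would rescale away exactly the
tumor-burden signal the score is meant to capture.

## Differential abundance

* **Size factors** — median-of-ratios; if no gene is nonzero in every sample, a
  poscounts-style fallback takes geometric means over positive entries only.
* **Dispersion** — per-gene method-of-moments on normalized counts
  (α̂ = (Var − m·mean(1/s))/m²), replaced by a fitted α(m) = a0 + a1/m trend
  ("trend", default) or a common trimmed mean ("common"). The trend is fitted
  by least squares on the raw estimates; this is a deliberately simplified
  stand-in for full empirical-Bayes shrinkage and is accurate when dispersion
  is shared, as in the generator.
* **Wald test** — per-gene NB GLM with log link and size-factor offsets,
  fitted by IRLS vectorized across genes (the 2×2 normal equations are solved
  in closed form per gene). Wald p-values on the group coefficient;
  Benjamini–Hochberg within each species family (abundance tables are reported
  per species); genes with mean normalized count < 1 are excluded from testing
  and from the BH family (independent filtering). Exact invariance to joint
  rescaling of a sample's counts and size factor does not hold for NB
  likelihoods; agreement is to tolerance.
* **Impulse model** — single-pulse mean
  μ(t) = (1/h1)·[h0 + (h1−h0)σ(β(t−t1))]·[h2 + (h1−h2)σ(β(t−t2))], NB
  likelihood with fixed dispersion, L-BFGS-B over (log h0, log h1, log h2, t1,
  Δ=t2−t1 ≥ 0, log β) from 8 deterministic data-driven starts (per-timepoint
  mean profiles set the amplitude levels; peak/valley positions set t1).
  Likelihood-ratio test against the constant NB model, χ²(5); with
  h0 = h1 = h2 the impulse reduces exactly to the constant model, so flat genes
  get p ≈ 1. BH across genes.
* **Pre-ranked enrichment** — running sum over the log2FC-descending ranking
  (ties broken by gene id for determinism): |score|^p increments at set
  members (p = 1 default), uniform 1/(N−N_hits) decrements elsewhere; ES is the
  extremum. Null: gene-label permutations (1000 default; sample permutation is
  impossible at these group sizes); NES = ES / mean |same-sign null ES|;
  p carries the +1 correction. A set covering the entire ranking is degenerate
  (there are no misses); the decrement is then spread uniformly so the running
  sum still closes at zero and the ES collapses toward 0.
* **PCA** — genes centered across samples, SVD; sample coordinates, per-gene
  loadings (the largest-magnitude loading of each component is made positive)
  and variance-explained fractions.

## Signature classification

The 8-gene signature (PHF14, PELP1, RPL7L1, HPRT1, RELN, RNU1-75P, RNU5A-8P,
RNVU1-19) is scored as the arithmetic mean of the genes' CPM values (no log;
a log2(CPM+1) flag exists). Genes absent from a matrix are imputed 0 with a
warning — expected in shallow plasma samples. A one-feature logistic model is
fitted by ML on a stratified 70/30 split (fixed seed); perfect separation is
not an error — the training class score ranges are checked directly, the
coefficient is capped at |β| = 30 (on standardized scores) and the model
flagged. ROC/AUC use the Mann–Whitney construction with ties counted ½.
The classification target is tumor-bearing PBS versus *successfully* treated
late-draw samples; the simulation truth is used to exclude immune-controlled
PBS mice (nothing to detect) and treatment-resistant mice (nothing cleared).

## Repertoire overlap

Detection sets are genes of one species with ≥ min_count reads. Jaccard
overlap significance uses a permutation null drawing uniform subsets of the
observed sizes from the detected-gene universe (the union of genes detected in
≥1 sample of the group — conditioning on detectability rather than the whole
annotation). Given the set sizes, the null intersection is exactly
hypergeometric and the Jaccard index a deterministic function of it, so nulls
are sampled via the hypergeometric distribution — distributionally identical to
explicit subset draws and far cheaper; p = (1 + #{null ≥ observed})/(n_perm+1).
The p-value distribution under the null is uniform up to the discreteness of
the intersection support, so calibration checks use sets large enough for a
rich support. Shared-gene summaries report exact UpSet-style region counts and
"detected in ≥k mice" tallies; detected-vs-undetected tissue abundance is
compared by the two-sample Kolmogorov–Smirnov test (asymptotic p).

## Deconvolution

Linear ν-SVR of the CPM-scaled (never log-transformed) sample vector on a
basis matrix (marker genes × cell types, CPM columns). The sample is rescaled
to CPM internally, making fractions invariant to positive rescaling of the
input. For each ν in {0.05, 0.1, 0.15, 0.25, 0.5, 0.75}, coefficients are
clipped at zero and renormalized to sum 1; the reported ν maximizes the
Pearson r between the clipped-coefficient reconstruction and the observation.
Fractions are renormalized over all basis columns (a per-immune-type view can
be derived from the returned vector). The bundled basis is synthetic —
12 cell types × 500 genes, block-sparse markers (25 per type, 60-fold
enriched over a lognormal background), with IGHM/SSR3/CD74 named as
plasma-cell markers — generated programmatically with a fixed seed; a real
atlas-derived basis can be supplied as a TSV.

## Pipeline, determinism and problem sizes

`pipeline.run_all` executes simulate → mask → split → quantify → differential
abundance → impulse → enrichment → signature → overlap → deconvolution,
writing every table as TSV plus a `manifest.json` of all parameters; stage
dependencies are validated up front and a stage failure aborts naming the
stage, retaining completed outputs. All randomness flows from one seed through
`numpy.random.SeedSequence` spawns (design randomness is drawn before count
randomness, so expected masses are comparable across configurations at a fixed
seed); two runs under one config are byte-identical.

The demo configuration (2 mice/arm, 50k-read libraries, 300k-read controls)
and the test/acceptance problem sizes (e.g. 7-mice arms at 120k reads,
12-million-read libraries only where deep spike counts are the point, 20-seed
calibration batches) are the package's chosen working scales; they exercise
every code path at cohort sizes matching the emulated design while keeping a
full run in minutes on a single CPU.

## What the synthetic cohorts do and do not show

The generator reproduces the design's structure — additive humanization and
tumor contributions to human cfRNA, NB count noise, hotspot-concentrated
cross-mapping with unique-mapper misassignment, multimapping, spike anchoring,
B-cell depletion and plasma-cell expansion under treatment/growth. It does not
model fragment-level sequence effects (no FASTQ, quality, GC or length bias),
spliced or strand-aware alignment, inter-gene correlation beyond the mixture
structure, secretion/degradation kinetics, or real cross-species homology
(hotspots are exchangeable windows, not homologous loci). Passing tests
therefore demonstrate that the statistics recover the truths the generator
encodes at realistic noise levels — not that any biological claim about real
plasma holds; on real data the masking step inherits whatever coverage the
pure-species controls achieve, and concentrations inherit spike pipetting
accuracy, neither of which has an analogue here.

## Known limitations

* The dispersion trend is a two-parameter fit without per-gene shrinkage
  weights; with strongly gene-dependent dispersion it is coarser than full
  empirical Bayes.
* The impulse LRT uses a fixed χ²(5) reference; with boundary solutions
  (Δ = 0) it is conservative.
* `nusvr_deconvolve` selects ν by reconstruction correlation only; with many
  collinear basis columns the per-type errors grow even when reconstruction is
  good.
* The real-alignment adapter consumes name-sorted records with NH tags; it
  does not handle spliced alignments or strand.
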