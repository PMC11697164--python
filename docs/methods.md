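# Methods

This note documents the models implemented in `darksip`, the defaults chosen
where the underlying science leaves a choice open, what the synthetic-data
generators do and do not emulate, and the package's known limitations.

## Single-cell stable-isotope probing

A nanoSIMS measurement yields, per cell, the secondary-ion ratios
¹²C¹⁵N⁻/¹²C¹⁴N⁻ and ¹³C¹²C⁻/¹²C₂⁻. Standard isotope algebra converts these to
atom fractions: the CN⁻ ion carries one N atom, so `x = R/(1+R)`; the C₂⁻
dimer carries two C atoms, giving `R = 2x/(1−x)` and hence `x = R/(2+R)`.
Both maps are monotone bijections from [0, ∞) to [0, 1), and the inverses are
used by the simulator.

**Enrichment calling.** A cell counts as a consumer of the labeled substrate
when its ratio strictly exceeds the mean plus two sample standard deviations
(n−1 denominator) of the 0-h control cells from the same site and substrate.
Under a Gaussian null this flags ≈ 2.28 % of unlabeled cells (one-sided 2-SD
tail); the test suite verifies this calibration on 5×10⁴ simulated null cells.

**Ka and rates.** The isotope-based growth coefficient uses the linear
mass-balance form

    Ka = (x_cell − x0) / ((x_sub − x0) · t),      [d⁻¹]

the fraction of a cell's initial element pool replaced by substrate-derived
atoms per day. An exponential-growth variant differs only at enrichments far
above those seen in dark-ocean incubations, so the linear form is used
throughout. `x_sub`, the atom fraction of the amended pool, is the
element-atom-weighted mean of the label purity and the ambient pool at natural
abundance; molecule concentrations are converted to element atoms first (urea
carries two N). Negative excess — measurement noise below baseline — clamps Ka
to 0 with a warning and the cell stays in denominator counts. The per-cell
rate is `Ka × cell N (or C) content / 24` in fg cell⁻¹ h⁻¹. The per-cell
elemental content is **not** inferable from the ion data; it is a config
parameter whose default (10 fg N/cell) is an order-of-magnitude placeholder
for small marine prokaryotes and should be set per study.

**Depth summaries and region integration.** Per site/depth/substrate we report
the percent of analyzed cells enriched and the mean Ka and rate over enriched
cells only (missing when none). Depths map to epi- (0–200 m), meso-
(200–1000 m) and bathypelagic (1000–4500 m) by half-open intervals; each
region's total assimilation is the arithmetic mean of its depths' volumetric
rates (cell density × enriched fraction × mean rate) times the region volume,
which is user-supplied configuration.

**Substrate comparison.** Rates of urea- versus ammonium-fed cells are
compared with the unpaired two-sided Wilcoxon rank-sum (Mann-Whitney U) test,
exact for small tie-free samples: cells in separate incubations cannot be
paired, so a signed-rank form is undefined here.

## Nitrification rates

δ¹⁵N-NOx (‰ vs air-N₂, R_std = 0.0036765) converts to atom fraction via
`R = (δ/1000 + 1)·R_std`, `x = R/(1+R)`. Excess ¹⁵N-NOx is
`(x_t − x_0) × [NOx] × 1000` in nmol ¹⁵N L⁻¹ with `x_0` taken from the 0-h
samples. The rate is the OLS slope of excess against time, pooled across
replicates, divided by the substrate's ¹⁵N atom fraction to convert tracer
production into total N oxidation — standard tracer practice; omitting the
division would understate rates by the pool-dilution factor (~2× for an
evenly diluted amendment). Detection requires a positive slope with one-sided
p < 0.05; a negative fitted slope is reported as rate 0, undetected.
Per-replicate fits feed a two-sided Welch t-test between substrates.
Incubations whose mean NOx falls below a configurable floor (default 0.5 µM)
are excluded at the pipeline layer, since δ¹⁵N cannot be measured reliably in
near-zero pools. Isotope dilution of the substrate pool over the incubation is
not modeled.

## Marker-gene prevalence

Gene abundance is RPKM (`reads / (length/1000) / (library/10⁶)`), summed
across contigs per sample per gene. Dividing a gene's RPKM by that of the
single-copy housekeeping gene *recA* gives genome equivalents; dividing the
*ureC*/*recA* ratio further by the mean *ureC* copies per carrier genome
(default 1.1, from an assembled-genome set) estimates the fraction of cells
carrying *ureC*. Values above 1 are flagged, not clipped — they signal
copy-number or mapping artifacts. *amoA* is left uncorrected; nitrate-pathway
genes share the same machinery with no gene-specific logic.

Contig taxonomy is a per-rank majority vote over the contig's gene-level
calls: walking root→leaf, a taxon is retained when carried by strictly more
than 50 % of the contig's classified genes (and consistent with the retained
prefix); the walk stops at the first rank without such a majority, so an even
split retains only the ranks above it. This is deterministic and
order-invariant. The *ureC* community composition weights each passing contig
(breadth ≥ 0.5, length ≥ 3000 bp; both filters applied to numerator and
denominator alike) by its sequencing coverage.

Depth trends in per-sample ratios are tested with one-way ANOVA across depth
regions followed by Tukey's HSD; regions with fewer than two samples are
excluded with a warning.

## Carbon budget

Nitrification fuels chemoautotrophy at a fixed yield of 0.09 mol DIC fixed
per mol N oxidized; with carbon at 12.011 g/mol, 1 nmol N L⁻¹ d⁻¹ converts to
1.081 µg C m⁻³ d⁻¹. Ammonia- and urea-based rates are summed per depth before
conversion, and rates that fail detection enter as 0, not missing. The
volumetric profile is integrated trapezoidally over the dark column (default
100 m to the site-dependent bottom), holding the shallowest/deepest measured
value constant out to each bound — the simplest defensible scheme for sparse
profiles (a layer-mean × thickness alternative differs by at most the
curvature of the true profile between sampled depths). The gravitational POC
flux at the base of the euphotic zone is net primary production times the
export efficiency `e-eff = 0.23·e^(−0.08·SST)`, and the headline number is
fixation as a percent of that flux, rounded to an integer percent only at the
reporting layer.

## Synthetic data

The generators invert the analysis models so planted parameters are
recoverable, and they are deterministic under a fixed seed (byte-identical
TSVs).

- **ROI tables.** 0-h cells draw their ratio from a Gaussian around the
  natural-abundance baseline with a stated CV (default 5 %, on the ratio
  scale — the simplest noise model consistent with the 2-SD rule). At the
  labeled timepoint an exact `frac_active` subset draws Ka from a lognormal
  (skewed single-cell rates are the norm; the within-population spread is a
  free parameter because it is not constrained a priori) and sits at the
  ratio implied by Ka, the incubation time and the substrate label fraction,
  capped at full substrate labeling; inactive cells stay at baseline. Urea
  incubations also carry a ¹³C channel labeled with the same Ka; ammonium
  incubations keep natural ¹³C.
- **Incubation series.** Excess ¹⁵N-NOx grows linearly at
  `true_rate × substrate_label_fraction`; δ values are back-computed and get
  additive Gaussian noise (default 0.2 ‰, typical isotope-ratio MS precision),
  independent across replicates and timepoints. Defaults: 0/24/72 h,
  duplicate incubations, 30 µM NOx, label fraction 0.5 (mid-range pool
  dilution).
- **Gene coverage.** Genome relative abundances are lognormal (σ = 0.7, a
  moderate rank-abundance skew); every genome carries one *recA*, an exact
  `frac_ureC` subset carries *ureC* with Bernoulli-rounded copies averaging
  `ureC_copy_mean`, and reads are multinomial over gene copies weighted by
  abundance × length × copies. Each carrier contributes one contig with
  planted gene-level taxonomy (occasionally one discordant call), coverage
  proportional to abundance, and drawn breadth/length including a minority
  that fail the composition filters.
- **Depth profile.** Cell density declines exponentially from 5×10⁸ cells/L
  at the surface to a 2×10⁷ cells/L bathypelagic floor (800 m e-folding),
  emulating typical open-ocean prokaryote counts.

What the generators do **not** emulate: raw ion images and ROI segmentation
noise structure, instrument drift and QSA effects, isotope dilution of the
substrate pool over time, assembly/binning artifacts, chimeric contigs, and
any covariance between activity and genome abundance. Passing recovery tests
therefore demonstrates the correctness of the estimators under the stated
noise models, not robustness to every artifact of real cruise data.

## Verification problem sizes

The test suite checks, among ~150 tests: null calibration of the enrichment
caller on 5×10⁴ simulated unlabeled cells (flagging rate 2.28 % ± 0.7);
recovery of a planted 50 % active fraction within 5 points and of the mean Ka
among enriched cells within 10 % at 1000 cells per timepoint; unbiasedness of
the nitrification estimator (mean of 1000 seeded series at 16 nmol N L⁻¹ d⁻¹
within 2 %) and null detection frequency 0.05 ± 0.02; recovery of a planted
*ureC* carrier fraction of 0.39 within ±0.03 from a 10⁶-read library over
2000 genomes; and 10⁻⁹-level agreement of RPKM, Welch t, exact small-n
rank-sum p and trapezoidal integration with independent brute-force oracles.

## Limitations

- The linear Ka form and the per-cell content placeholder mean absolute
  assimilation rates are only as good as the configured fg-per-cell value.
- Region volumes for integrated assimilation are user configuration, not
  derived.
- The tracer-dilution division by the substrate label fraction is applied
  always; studies reporting raw ¹⁵N-NOx production will differ by that factor.
- Consensus-taxonomy tie behavior (stop at the last majority rank) is one
  defensible convention among several.
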