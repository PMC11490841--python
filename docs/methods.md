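# Methods

## Scope and model

`oncoflux` implements the quantitative stages of a cell-line metabolism
study: extracellular-flux bioenergetics, natural-abundance correction of
¹³C labelling data, and the downstream normalisation/statistics applied to
proteome tables and growth curves. Synthetic-data generators stand in for
the instrument outputs so every stage is testable against known ground
truth.

## Extracellular-flux bioenergetics

A mitochondrial stress test records oxygen consumption (OCR, pmol O₂/min)
and extracellular acidification (ECAR, mpH/min) per well over measurement
cycles, with sequential injections of oligomycin (ATP-synthase inhibitor),
FCCP (uncoupler), antimycin A + rotenone (electron-transport inhibitors)
and monensin (ionophore eliciting maximal glycolysis). The pipeline:

1. **Normalisation.** Raw OCR/ECAR are divided by per-well crystal-violet
   OD595, a proxy for adherent cell number. Multiplying a well's raw rates
   and its OD595 by the same factor leaves all downstream outputs
   unchanged (scale equivariance).
2. **Phase aggregation.** Injection events define half-open cycle windows.
   Defaults: basal = mean of pre-injection cycles; oligomycin and
   antimycin/rotenone = minimum cycle; FCCP and monensin = maximum cycle.
   Extremum aggregators are robust to the transient right after an
   injection but are biased order statistics under noise, so the
   plateau-recovery experiments use mean aggregation for every phase; both
   choices are configurable and recorded in output metadata.
3. **Respiratory parameters.** Non-mitochondrial OCR = post-antimycin/
   rotenone rate; mitochondrial OCR = basal − non-mito; coupled = basal −
   oligomycin; leak = oligomycin − non-mito, so mito = coupled + leak
   exactly. Maximal respiratory capacity (MRC) is the raw post-FCCP OCR (a
   switch subtracts non-mito OCR); spare respiratory capacity = MRC −
   basal. Negative derived rates are clamped to zero and the well flagged,
   with the unclamped value kept in `*_raw` diagnostics; wells with more
   than half their derived rates clamped are excluded from group means
   (configurable).
4. **ATP production rates.** Total proton production is ECAR divided by
   the medium buffering power. The respiratory share is
   `10^(pH−pK₁)/(1+10^(pH−pK₁)) × (H⁺/O₂) × OCR_mito`, using the
   carbonic-acid first pKa at assay temperature; the remainder (clamped at
   zero) is glycolytic. Then

       J_ATP-glycolysis = PPR_glyc × (ATP/lactate) + OCR_mito × 2 × P/O_glyc
       J_ATP-OxPhos     = OCR_coupled × 2 × P/O_oxphos + OCR_mito × 2 × P/O_TCA

   Basal terms use basal-phase ECAR/OCR; the maximal state takes ECAR from
   the monensin phase and OCR from the FCCP phase (monensin exists only to
   elicit maximal glycolysis). The glycolytic index is the basal
   glycolytic share of total ATP production in percent; it is 100 when OCR
   is identically zero with positive ECAR, and undefined (flagged) for a
   dead well.

### Coefficients

Defaults describe glucose oxidation in a bicarbonate-free assay medium:
buffering power 0.1 mpH/pmol H⁺ (medium-specific — strict mode demands an
explicit value), pH 7.4, pK₁ 6.093 at 37 °C, 1 H⁺/O₂, 1 ATP/lactate,
P/O_glyc 0.167 (2 ATP per glucose over 12 O), P/O_oxphos 2.486, P/O_TCA
0.121. All live in config and are echoed into every run manifest, so a run
is fully reproducible and substrate assumptions are auditable.

## Natural-abundance correction of MIDs

GC/MS fragments of TBDMS-derivatized metabolites contain derivatization C,
H and Si in addition to the metabolite backbone, so natural heavy isotopes
(especially ²⁹Si/³⁰Si) contribute mass shifts that must be removed before
interpreting ¹³C label. For a fragment with N labellable backbone carbons,
column j of the correction matrix is the theoretical mass-shift
distribution given exactly j labelled carbons: the convolution of a
binomial over the j labelled positions (tracer isotopic purity, default
0.99), the natural ¹³C distribution of the remaining carbons, and the
natural distributions of all other atoms. Rows cover shifts 0…N+4 by
default; mass pushed past the retained range is recorded per column as
truncated mass rather than renormalised away.

Correction solves `A x ≈ m` by non-negative least squares and renormalises
x to sum 1 — non-negativity is required for a valid MID and handles
measurements whose unconstrained solution would dip negative under noise.
The NNLS residual and the matrix condition number are attached as
diagnostics, with a warning above a configurable condition bound.
Fractional enrichment is `1 − x₀`; isotopologue ratios (e.g. m+5
glutamate / m+5 glutamine) flag a zero denominator rather than erroring.
Relative metabolite abundance is total ion intensity over the
internal-standard (myristic acid-d₂₇) intensity, divided by cell count
when available. Heatmap summaries use log₂ of each value over its
metabolite's arithmetic mean ("ratio to mean" read literally; switchable).

The fragment registry ships typical TBDMS M-57 fragment formulas for the
assayed TCA intermediates and amino acids; entries are editable and
documented as literature-typical rather than instrument-verified, since
fragment choice varies by SIM method.

## Proteome and growth statistics

Protein abundances are normalised per sample to equal totals, log₂
transformed, and contrasted with per-protein Welch t-tests (Satterthwaite
degrees of freedom); p-values are Benjamini–Hochberg adjusted across all
tested proteins. A protein is significant only if q < 0.05 **and**
−log₁₀ p > 1.3 **and** |log₂ fold change| > 0.48 — the raw-p and FDR
filters are partially redundant but enforced conjunctively as a matter of
fidelity to the protocol this reproduces. Fold changes are differences of
group means on the log₂ scale. Growth series are expressed relative to
their first timepoint; apoptosis reporter counts are divided by relative
confluence per timepoint, with non-computable timepoints flagged NaN.

## Synthetic data

* **Flux plates.** Per-group plateau rates per phase (defaults contrast a
  glycolytic with an oxidative phenotype); per-well log-normal cell-number
  factors (sd 0.10) couple raw rates and OD595 so normalisation tests are
  meaningful; additive Gaussian measurement noise (default sd 3 raw-rate
  units against an OD base of 0.5, i.e. σ = 6 on the normalised scale);
  3 cycles per phase. With zero noise, normalised phase aggregates equal
  the design plateaus exactly.
* **Labelling.** Measured intensities are `abundance × (A @ x)` for
  ground-truth MIDs x — the same forward model the corrector inverts —
  under multiplicative log-normal noise (default log-sd 0.05, i.e. ~5%),
  with an internal-standard channel. Default truth MIDs encode
  glutamine-anaplerosis-like m+4/m+5 patterns; they are specified
  directly, not simulated from a flux network.
* **Proteomes and growth.** Log-normal abundances (baseline log₂ level ~
  N(20, 2), replicate noise 0.25 log₂ units, three samples per group)
  with spiked log₂ effects; logistic confluence curves (10% → 95%
  capacity) with Gaussian observation noise.

What the simulations do **not** emulate: injection transients and drift
within phases, heteroscedastic or correlated well noise, chromatographic
peak-integration error, missing values and batch structure in proteomes.
Passing recovery tests therefore demonstrates correctness of the
computations under idealised noise, not robustness to every failure mode
of real instruments.

## Numerical choices and limitations

* Accounting identities (mito = coupled + leak; total ATP = glycolytic +
  oxidative) hold exactly by construction, including after clamping.
* Clamping at zero (respiratory rates, glycolytic proton production)
  prioritises plate-level robustness over raising errors on noisy wells;
  every clamp is flagged.
* NNLS correction is deterministic; correction matrices for the shipped
  registry have modest condition numbers (≲ 10).
* Welch p-values at n = 3 per group deviate from the uniform null by a
  Kolmogorov–Smirnov distance of about 0.03 — a property of the
  Satterthwaite approximation itself, visible with thousands of tests.
  Calibration checks size uniformity tests accordingly (≈300 tests per
  table) while false-discovery control is verified at 2000 proteins.
* Monte-Carlo problem sizes (100–200 seeds, 12 wells/group, 2000-protein
  nulls) were chosen to give the coverage statements useful resolution
  while keeping the whole suite fast to iterate on.
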