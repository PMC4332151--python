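# Methods

## Scope and modelling strategy

`photoclock` couples a compact circadian-clock circuit to the two
best-characterised photoperiodic output pathways of *Arabidopsis*: the
CDF1/FKF1/GI → CO → *FT* flowering pathway and the PIF4/PIF5 → target-gene
elongation pathway.  The network topology — which regulator acts on which
promoter or protein, and with which sign — follows the published molecular
evidence; the rate laws and all kinetic constants were authored and calibrated
here.  Every parameter therefore carries the provenance tag `fitted`
(calibrated against published qualitative and semi-quantitative behaviours:
peak phases, mutant effects, temperature fold-changes) or `default`
(structural switches).  Concentrations are in arbitrary relative units, as are
the published expression data the model is compared to; all comparisons are
made on peak-normalised series.

## State and rate laws

The state has 40 species (see `photoclock.registry.SPECIES`): 19 clock
species, 8 flowering species, and 13 elongation species.  All transcription
terms are products of saturating Hill activation/repression functions (default
Hill coefficient 2); degradation is first order, with light- or
dark-multiplied rates where turnover is known to be conditional.  Production
terms are non-negative and every loss term is proportional to its own species,
so the positive orthant is forward-invariant by construction (verified by a
property test under random ±20 % parameter perturbation).

Clock circuit.  CCA1 and LHY are pooled into one gene (they act redundantly
in every context used here).  The pool's transcription is repressed by the
PRR9+PRR7+PRR5+TOC1 protein pool and acutely boosted by light at dawn; PRR9
transcription is CCA1/LHY-activated, EC-repressed and light-gated (a small
dark basal rate), which anchors the morning wave to dawn; PRR7 and PRR5 are
driven sequentially by the preceding PRR protein; TOC1 and the evening-complex
genes (*ELF3*, *ELF4*, *LUX*) are CCA1/LHY- and EC-repressed evening genes.
PRR5/PRR7/TOC1 and GI proteins have dark-enhanced turnover (absorbing
the ZTL/COP1 machinery, which is not modelled as explicit species).  The EC
pool assembles from the product of the three component proteins, moderated by
GI, and decays at 0.38 h⁻¹.

EC readout for the PIF promoters.  The repressive EC activity seen by
*PIF4*/*PIF5* is the instantaneous ELF3·ELF4·LUX assembly signal (scaled to
EC-equivalent units), which leads the accumulated EC pool by ≈2 h — a causal
implementation of the observed phase advance of EC action at these promoters,
integrable as a plain ODE.  The lead is set by the EC pool's decay rate
(first-order lag ≈ arctan(ω/d)/ω ≈ 2 h at d = 0.38 h⁻¹) and is asserted as
2 ± 0.5 h by a test.  Setting `ec_readout_assembly = 0` switches the readout
back to the EC pool itself.

Flowering pathway.  *FKF1* transcription mirrors *GI*; CDF1 protein is
degraded by the blue-light-dependent GI–FKF1 complex and by a mass-action
GI-dependent, FKF1-independent route (`k_cdf1_gi·GI_p·CDF1_p`; the simplest
form consistent with the evidence that *gi* retains higher and flatter CDF1
than *fkf1*).  CO protein is strongly dark-degraded (9× the light rate) and
stabilised by FKF1 in light; *FT* transcription is CDF1-repressed and driven
by a Hill function of CO protein plus a PIF term gated by a saturating
function of CO protein — so PIF affects *FT* only when the light-dependent CO
activator is present, and night-time PIF changes leave *FT* untouched.

Elongation pathway.  Active phyB follows fast photoactivation
(2 h⁻¹ in light) and slow dark reversion (0.9 h⁻¹), degrading the pooled PIF
protein (weights 0.6/0.4 on *PIF4*/*PIF5* mRNA); the "Interactor" pool
(DELLAs/PAR1/HFR1/HY5 as one class) is synthesised proportional to light and
decays at 0.6 h⁻¹, dividing PIF activity competitively
(`PIF_act = PIF_p/(1+INT_p/k)`).  Each PIF-induced target (*ATHB2*, *IAA29*,
two cluster transcripts) has five target-specific parameters (basal rate,
maximal rate, half-saturation, Hill coefficient, decay); four PIF-repressed
cluster transcripts use the repressive form.

## Environment and temperature

Light is a smoothed square wave (logistic ramps, twilight half-width 0.05 h by
default, configurable towards a near-step) so the right-hand side stays
continuous for the stiff solver.  Temperature is purely parametric: the warm
scenarios multiply the EC half-repression constant on the *PIF4* promoter
(×5 at 28 °C, ×4 at 27 °C — "mild" modulation calibrated during model
construction so the published outcomes emerge: a 2–3 h earlier pre-dawn *PIF4*
rise and 3–4× dawn ATHB2 at 28 °C) and, at 27 °C only, add a uniform *FT*
activation of 0.18 h⁻¹ (calibrated to the published 2–3× *FT* increase;
represents warmth-released constitutive repressors such as SVP/FLM, leaving
22 °C behaviour bit-identical).  Whether *PIF5* shares the EC-affinity scaling
is a scenario flag (default: *PIF4* only).

## Simulation and entrainment

LSODA with rtol 1e-8 / atol 1e-10 (halving the tolerances changes sampled
outputs by <1e-4 relative, a tested property).  Entrainment starts from the
documented state (every species at 0.1) and iterates 24-h cycles until the
dawn state repeats to relative 1e-6; wild type converges in 5–10 cycles in
every photoperiod 4L–20L, and the default cap is 40 cycles so strongly
damped mutants still converge.  Non-convergence (e.g. arrhythmic clock
mutants) is flagged on the result, never raised: downstream statistics then
use the final cycle, matching how such genotypes are reported.  All
trajectory statistics (peaks, AUCs, fold-changes) are computed on the last
entrained cycle.

## Calibration anchors

The defaults reproduce, simultaneously: CCA1/LHY mRNA peak within ±1 h of
dawn; *GI*/*FKF1* peaks ZT9–10 in 10L; EC activity peaking in the early
night; *FT* peak at ZT16 in 16L:8D; CO transcript means ordered
WT > *fkf1* > *gi*; elevated *CDF1* and flattened *FKF1* in *prr9;7*;
night-derepressed *PIF4* in *elf3*; a 3–6 h *CO*/*FT* phase advance in
*cca1;lhy* short days; near-constant CDF1 protein in `CDF1-ox;gi` versus a
residual rhythm in `CDF1-ox;fkf1`; short-day bimodal PIF-target profiles
(dawn peak plus a post-dusk peak near ZT14) that collapse to unimodal in long
days; daytime PIF protein at roughly half the short-day cycle peak; and
monotone FT_AREA (increasing) / ATHB2_AREA (decreasing) across photoperiods.
These anchors were calibrated jointly by hand and small grid searches during
model construction; the acceptance script measures them, it does not set them.

## Phenotype maps

days = floor + range/(1+(FT_AREA/K)^h) and
length = floor + range·A^h/(K^h+A^h): the simplest monotone saturating
families honouring the required directions, with (range, K) fitted to two
anchor pairs per phenotype (exact interpolation) and floor/h fixed by config.
The shipped anchors are representative Col-0 values (58/21 days at 8L/16L;
6.8/2.4 mm), marked synthetic in their filenames; real studies should
recalibrate with `calibrate_map`.  Phenotypes are clamped to [floor, ceiling].

## Clustering

Profiles are z-scored per condition (genes near-constant in any condition are
dropped with a log record), concatenated, and compared by Pearson
correlation.  Affinity propagation is implemented directly (damping 0.9,
median off-diagonal preference, lowest-index tie-break, no noise injection)
so results are bit-deterministic and non-convergence returns the last labels;
scikit-learn's implementation is used as an independent cross-check in the
tests.  "Large and coherent" clusters default to ≥20 genes and mean
within-cluster similarity ≥0.6 — parameters, not constants.  Overlap
enrichment is the hypergeometric upper tail (scipy), validated against
exhaustive enumeration for universes ≤25.

## Fitting

Seeded multi-start (default 20 starts, log-uniform within bounds, first start
at the incumbent) around bounded local least squares (scipy TRF on log-scale
parameters).  The flagship problem — the five target-specific parameters of a
PIF-driven transcript — exploits the network structure: targets feed nothing
back, so their ODE (linear in the transcript) is solved exactly against a
frozen PIF-activity trajectory, including the periodic initial condition in
closed form.  A slow full-model residual exists for other cases.  The final
cost never exceeds the cost at the starting parameters.

## Synthetic data

qPCR-style timeseries: entrained model sampled on a harvest grid, replicate
scatter as multiplicative lognormal noise (always-positive values; σ = 0
reproduces truth exactly), then peak-normalised.  Cluster matrices: three
planted motifs per condition (the model's PIF-induced cluster shape, its
antiphase, a 6-h shift) across six conditions (SD, LD, 12L wild type and
*lux*, LHYox, *phyB*), additive Gaussian noise on the z-score scale, so the
expected within-cluster correlation has the closed form 1/(1+σ²); remaining
genes are unstructured noise with truth label −1.  Phenotype pairs: a known
map evaluated on an area grid plus lognormal noise.  Every generator returns
a truth record sufficient for its downstream recovery test, and all
randomness flows through explicit `numpy.random.default_rng(seed)` streams.

## What the synthetic data do and do not show

The generators emulate the statistical shape of the real inputs (relative
scale, replicate scatter, condition-specific profiles, planted coherence) but
not microarray probe effects, cross-hybridisation, normalisation artefacts,
or genuine biological heterogeneity between PIF targets.  Passing the
clustering and recovery tests therefore demonstrates that the pipeline is
correct and well-conditioned at realistic noise, not that the published
cluster memberships would be reproduced from the original microarrays (which
are not redistributed here).

## Numerical choices and degenerate inputs

Peak phase uses 3-point quadratic refinement with earliest-sample tie-breaks
and raises on constant series; phase differences are circular, mapped to
(−12, +12].  Bimodality counts interior maxima with prominence ≥0.1 of the
range on a circularly tiled cycle, robust to solver ripple.  AUC is
trapezoidal.  Solver undershoot below zero (at the atol scale) is clipped.
0L and 24L photoperiods are legal inputs and produce flagged (possibly
non-entrained) rows in scans rather than errors.

## Known limitations

The clock is tuned for entrained light:dark conditions: it is strongly
damped rather than a robust self-sustained oscillator, so free-run (LL/DD)
period and phase are outside the model's validity (and out of scope).  The
*prr9;7* lesion collapses the whole PRR wave (PRR7→PRR5 are chained), making
that mutant's clock near-arrhythmic — its tested behaviours (elevated *CDF1*,
flattened *FKF1*, low *CO*/*FT*) still hold, but its residual rhythmicity is
underestimated.  The calibrated daytime-PIF fraction (~59 % of the short-day
peak) and the warm-scenario PIF4 rise advance (~3.3 h) sit at the generous
end of the published ~50 % and 2–3 h.  Photoreceptor dynamics beyond a single
phyB pool, spectral light quality, and continuous temperature response
curves are not modelled.
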