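# Methods

## Microcosm kinetic model

The simulator tracks dissolved NH4⁺, NO2⁻ and NO3⁻ (mM-N) in the 30 mL
liquid phase of a stirred 5 g sediment microcosm. Each guild g ∈ {AOA, AOB,
comammox (CMX), NOB} has a maximal rate r_g (mM-N·day⁻¹) softened by a
Michaelis–Menten factor S/(K_g + S) of its substrate:

    d[NH4]/dt = doses − v_AOA − v_AOB − v_CMX
    d[NO2]/dt = v_AOA + v_AOB + λ·v_CMX − v_NOB
    d[NO3]/dt = (1 − λ)·v_CMX + v_NOB − v_DNRA

where λ is the comammox nitrite-leak fraction (default 0.1: comammox
releases a small share of the nitrite it produces instead of oxidizing it
through to nitrate) and v_DNRA (default 0) is a nitrate sink for
dissimilatory nitrate reduction. With the default K = 0.005 mM (well below
the ~0.1–0.3 mM ammonium maintained by daily 0.1 mM dosing) the rates are
effectively zero-order, so oxidized N accumulates linearly in time — the
regime the OLS rate fits assume. There is no biomass growth, urease step, pH
or CO2 chemistry: the model is a rate assay, not an ecosystem model.

Inhibitors are treated as complete and instantaneous: chlorate
(treatment II) zeroes CMX and NOB, chlorate + 1-octyne (treatment III)
additionally zeroes AOB, and the nitrate-only control (treatment IV)
replaces ammonium doses with nitrate and idles all ammonia oxidizers.
Partial inhibition dose–response is deliberately out of scope.

Salinity enters as a per-guild rate multiplier plus an adaptation lag during
which a guild's rate ramps linearly from zero (min(1, t/lag)). Defaults at
3% salinity: CMX ×0.14, AOB ×0.48, AOA ×10.2, NOB ×0.25, with a 12 h lag for
ammonia oxidizers and 36 h for NOB. The multipliers reproduce the observed
activity pattern (comammox nearly silenced, AOB halved, AOA favoured under
salt); the longer NOB lag makes nitrite accumulate transiently and then
decline as nitrite oxidation recovers, the behaviour seen in saline
incubations. The lag is stored per salinity and per guild rather than as a
single scalar because the adaptation is a saline-only phenomenon and differs
between the ammonia- and nitrite-oxidizing steps. Freshwater guild rates
default to comammox 4.4, AOB 3.6, AOA 0.1 mg N·day⁻¹·kg⁻¹ (converted by the
factor 84 = 14 × 0.030 / 0.005 into mM-N·day⁻¹), i.e. the magnitudes the
assay design is meant to resolve.

Integration is classical fixed-step RK4 at 0.005 day (within the 0.01-day
step bound), with dose and sample times hit exactly by shortening the last
step before each event. Fluxes other than DNRA are transfers between pools,
so total dissolved N is conserved to machine precision; RK4 keeps the
deviation from a 10×-finer integration near 1e-12 mM, far inside the 1e-4 mM
agreement the tests require (simple Euler at the same step could not
guarantee that near substrate depletion). Measurement noise is additive
Gaussian (default SD 0.002 mM, the scale of ion-chromatography replicate
scatter at these concentrations) applied only at sampling, then clamped at
zero; all randomness derives from (config seed, replicate seed).

## Rate fitting and partition

Each replicate's PAR is the OLS slope of NO2⁻ + NO3⁻ versus time
(scipy.stats.linregress), fitting the sum rather than nitrate alone so the
estimate is invariant to how far nitrite is oxidized — which differs across
treatments as NOB are variously inhibited. Points before `exclude_before`
(default 0 h; 12 h for saline fits) are dropped. Slopes convert to
mg N·day⁻¹·kg wet soil⁻¹; wet mass is used because the assay reports per kg
of sediment as weighed.

A treatment's PAR is the mean of its replicate slopes. Its SD is
max(between-replicate SD, pooled within-fit slope SE): with triplicates the
between-replicate SD has only 2 degrees of freedom and underestimates the
true scatter roughly a quarter of the time, so the pooled regression SE
(15 df at 7 time points × 3 replicates) acts as a floor. Guild PARs are the
treatment differences given in the README; their SDs propagate as
root-sum-of-squares, which assumes independent treatment errors (separate
vials). Negative derived PARs are possible under noise and are reported with
a warning, never clipped, so the partition identity
PAR_AOA + PAR_AOB + PAR_CMX = PAR_I stays exact and the uncertainty honest.
Percent contributions are each guild's PAR over the treatment-I PAR, rounded
to integers.

The treatment-IV control passes when the fitted NO3⁻ slope is no more
negative than −0.005 mM·day⁻¹ (default tolerance), i.e. nitrate losses to
DNRA/denitrification are negligible relative to the rates being partitioned.

## Gradient model and labeling calls

Fraction k of the linear gradient has center density
ρ_k = 1.7925 − 0.0085·k g/mL (k = 1 heaviest, matching top-displacement
collection); the intercept and step reproduce the bench anchors 1.716 g/mL
at fraction 9 and 1.7075 g/mL at fraction 10, and both are configuration,
not constants. A taxon bands at ρ = 1.660 + 0.098·GC + 0.036·a (a = excess
¹³C atom fraction) — standard SIP calibration values, likewise exposed as
module constants. Copies in a fraction are the band's Gaussian mass
(default SD 0.006 g/mL) over the fraction's density bin times lognormal
noise (default CV 0.1, unit mean). Bands within the gradient range retain
≥ 99% of their copies; bands outside it are truncated with a warning.

Labeling of a target is called from a paired ¹²C/¹³C gradient when the
weighted mean density rises by ≥ 0.004 g/mL (≈ 11% atom excess) **or** the
peak fraction moves ≥ 1 fraction toward the heavy end. The visual
peak-shift judgement commonly used for SIP profiles is thereby made
explicit and configurable; the two defaults were fixed from the model's own
scales (0.036 g/mL full-label shift, 0.0085 g/mL fraction width) before any
stochastic evaluation. Profiles are normalized per target, so calls are
invariant to uniform copy scaling; files may arrive heaviest- or
lightest-first — the reader restores the heavy = low-index order.

Default synthetic bands place unlabeled AOA, AOB and comammox peaks at
fractions 12, 11 and 10 (GC 0.311, 0.398, 0.485) and shift them under
¹³CO2 by 2/2/1 fractions in freshwater and 2/1/0 in saline gradients —
comammox unlabeled under salt. The implied atom excess per one-fraction
shift is 0.0085/0.036 ≈ 0.24; real 13-day incubations do not report their
achieved labeling, so these values are chosen only to reproduce the
observed one-fraction peak shifts, and passing tests show the statistics
recover what the generator encodes, not what any particular sediment would
yield. The generator also omits real-gradient features — compositional
coupling between taxa sharing a sequencing library, density smile, carryover
between fractions — so classification accuracies measured here are upper
bounds.

## qPCR

Standard curves are OLS fits of Cq on log10 copies over ≥ 3 dilutions
spanning ≥ 3 orders of magnitude; efficiency is 10^(−1/slope) − 1.
Efficiency outside 0.83–0.94 or r² ≤ 0.99 raises a warning and clears the
QC flag rather than failing: those bands describe the assays this design
achieved, not mathematical validity (a perfect-doubling curve is flagged,
correctly, as outside that band). Unknowns back-calculate as
10^((Cq − intercept)/slope) copies/µL, scaled by elution volume (default
30 µL) ÷ template fraction per reaction (default 1/30 — a declared
placeholder, since the loading is rarely reported) ÷ extracted soil mass
(default 0.16 g). Cq values implying copies outside the calibrated range
raise an extrapolation warning. Group comparison is limited to means and
fold changes; multiple-range testing is out of scope.

## Problem sizes and numerical choices

Default assays are 72 h with 7 samplings (0–72 h every 12 h) in triplicate;
the recovery experiment uses 50 seeded runs, the labeling-accuracy check
100 seeded gradient pairs, the control Monte Carlo 200 vials — sizes at
which the full test suite completes in a few seconds while the binomial
checks (≥ 90%, ≥ 95% success) have negligible evaluation noise. Ties in
peak fractions resolve to the first (heaviest) maximum. Degenerate inputs
(fewer than two fit points, zero time variance, all-zero profiles,
non-positive totals) raise typed errors rather than returning NaN. CSV
artifacts carry `#`-prefixed provenance headers (package version, seed,
config hash) and identical configurations produce byte-identical outputs.

## Known limitations

The kinetic model omits growth, so it cannot reproduce the accelerating
rates of a blooming population; inhibition is binary; salinity multipliers
are condition-level constants rather than mechanistic osmotic responses;
the density model ignores GC heterogeneity within a target group; and the
qPCR error model is lognormal in copies / Gaussian in Cq with no
inhibition or primer-mismatch effects. These are acceptable for validating
the statistics — they bound what the synthetic benchmarks say about field
samples.
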