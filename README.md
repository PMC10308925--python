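# nitripartition

Guild-resolved nitrification activity for sediment microcosms: who is
oxidizing the ammonia — ammonia-oxidizing archaea (AOA), ammonia-oxidizing
bacteria (AOB), or complete ammonia oxidizers (comammox *Nitrospira*)?

The package implements the computational side of a differential-inhibitor /
DNA-SIP / qPCR study design used to partition potential ammonium-oxidation
rates (PARs) in intertidal-sediment microcosms under freshwater and saline
conditions, together with a mechanistic synthetic-data generator so that the
entire analysis is testable without laboratory data. It is aimed at
environmental microbiologists running nitrification assays and at method
developers who need a transparent, seedable test bed for SIP and rate-
partition statistics.

## The method

**Inhibitor partition.** Four treatments are incubated in parallel:
I (no inhibitor), II (1 mM chlorate — chlorite produced by nitrite
oxidoreductase poisons comammox and strict nitrite oxidizers),
III (chlorate + 4 µM 1-octyne, which additionally inactivates AOB), and
IV (nitrate only, a DNRA/denitrification control). The PAR of a treatment is
the OLS slope of oxidized N (NO2⁻ + NO3⁻) versus time, converted to
mg N·day⁻¹·kg wet soil⁻¹ (× 14 mg/mmol × 0.030 L ÷ 0.005 kg for the default
30 mL / 5 g geometry). Then

    PAR_comammox = PAR_I  − PAR_II
    PAR_AOB      = PAR_II − PAR_III
    PAR_AOA      = PAR_III

with root-sum-of-squares uncertainty propagation, so the guild rates sum to
the uninhibited total exactly. Saline incubations exclude the 0–12 h
adaptation window from the fits.

**DNA-SIP.** Taxon DNA bands as a Gaussian in a linear CsCl buoyant-density
gradient (fraction 1 heaviest); density follows
ρ = 1.660 + 0.098·GC + 0.036·a, where a is the excess ¹³C atom fraction.
A target is called labeled when its ¹³C profile moves toward the heavy end:
weighted-mean-density shift ≥ 0.004 g/mL, or a peak shift ≥ 1 fraction.

**qPCR.** Standard curves Cq = m·log10(copies) + b give amplification
efficiency E = 10^(−1/m) − 1; unknowns are back-calculated through the curve
and scaled to copies per gram of soil, with QC warnings outside the
efficiency band 83–94% or r² ≤ 0.99.

## Worked example

Run the analysis scripts from the repository root:

```sh
python analysis/01_simulate.py        # synthetic microcosms + gradients
python analysis/02_partition_rates.py # PAR fits and guild partition
python analysis/03_sip_labeling.py    # labeling calls per target
python analysis/04_qpcr_abundance.py  # standard curves and fold change
```

`02_partition_rates.py` prints, for the default simulated experiment:

```
salinity 0.06%: comammox 4.19 (54%), AOB 3.53 (45%), AOA 0.06 (1%) mg N/day/kg; DNRA control ok: True
salinity 3.0%: comammox 0.57 (18%), AOB 1.69 (52%), AOA 0.99 (30%) mg N/day/kg; DNRA control ok: True
```

i.e. comammox dominates ammonia oxidation in freshwater (54% of a total
7.8 mg N·day⁻¹·kg⁻¹) but is largely shut down at 3% salinity, where AOB take
over — and the nitrate control confirms that DNRA losses are negligible, so
the slopes really measure ammonia oxidation. `03_sip_labeling.py` reaches
the matching conclusion from the gradient side: comammox *amoA* shifts one
fraction heavier (to the 1.716 g/mL fraction) only in freshwater, while AOA
and AOB label under both conditions. `04_qpcr_abundance.py` fits standard
curves (efficiencies ≈ 90–92%, r² > 0.999) and reports a ≈ 3.6-fold
comammox abundance increase in the freshwater microcosm.

The same stages are available as a CLI
(`nitripartition simulate|partition|sip|qpcr|run --config run.yaml`), each a
thin wrapper over the library functions.

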