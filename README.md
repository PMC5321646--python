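# petkin

Kinetic quantification of dynamic PET time–activity curves, built around a
reproducible synthetic benchmark for benzodiazepine-receptor tracers in the
rat brain.

## Scientific problem

A dynamic PET scan measures a time–activity curve (TAC) per region: the
frame-averaged sum of tracer in tissue and in the blood fraction of the
voxel. For a reversible tracer such as [11C]flumazenil, tissue kinetics are
described by compartment models driven by the metabolite-corrected arterial
plasma curve:

* **1T** — one tissue compartment, rates `K1, k2`;
* **2T** — adds a specific-binding compartment, rates `K1, k2, k3, k4`;
* **3T** — adds a non-specific compartment in parallel (`k5, k6`), used here
  as the generative truth.

The macro parameters of interest are the total distribution volume
`V_T = (K1/k2)(1 + k3/k4 + k5/k6)`, the binding potential
`BP_ND = k3/k4`, and the reference-normalised `DVR − 1 = V_T/V_T,ref − 1`.
When no arterial input is available, reference-tissue models (SRTM, FRTM,
and a variant with a two-tissue reference, SRTM-2C) estimate `BP_ND` from a
reference region — which for this tracer is itself not binding-free (the
pons), so reference estimates are biased low.

The package provides:

* exact (piecewise-linear × exponential) simulation of 1T/2T/3T TACs on a
  realistic 21-frame, 60-min schedule, with a blood-volume term and a
  seeded noise model;
* sklearn-style estimators for plasma-input fits (`OneTissueModel`,
  `TwoTissueModel`), spectral analysis (`SpectralAnalysis`), and
  reference-tissue fits (`SRTM`, `FRTM`, `SRTM2C`), each with thin
  functional wrappers;
* AIC-based model preference, Bland–Altman agreement and Holm-corrected
  testing utilities;
* a pipeline + CLI that regenerates the benchmark macro-parameter table and
  the full simulation experiment from a single seed.

## Worked example

```python
from petkin import (MicroParams, default_frame_schedule, fit_compartment_model,
                    fit_srtm, macro_from_micro, model_tac, synthetic_input)

schedule = default_frame_schedule()          # 21 frames, 60 min
plasma, blood = synthetic_input(seed=0)      # parent plasma + whole blood

# a high-binding region: three-tissue kinetics, k3 = 2.60 min^-1
truth = MicroParams(K1=0.8, k2=2.25, k3=2.60, k4=0.17, k5=0.15, k6=0.08,
                    vB=0.05)
tac = model_tac(truth, plasma, blood, schedule)

one = fit_compartment_model(tac, plasma, blood, schedule, "1T")
two = fit_compartment_model(tac, plasma, blood, schedule, "2T")
print(f"true V_T                  {macro_from_micro(truth).VT:.3f}")
print(f"1T fit: V_T {one.macro.VT:.3f}   AIC {one.aic:.1f}")
print(f"2T fit: V_T {two.macro.VT:.3f}   AIC {two.aic:.1f}")

# BP_ND against a pseudo-reference region that itself binds (k3 = 0.20)
reference = model_tac(MicroParams(K1=0.8, k2=2.25, k3=0.20, k4=0.17,
                                  k5=0.15, k6=0.08, vB=0.05),
                      plasma, blood, schedule)
srtm = fit_srtm(tac, reference, schedule)
print(f"SRTM BP_ND {srtm.BPND:.3f}")
```

Output:

```text
true V_T                  6.460
1T fit: V_T 6.296   AIC -82.3
2T fit: V_T 6.419   AIC -201.4
SRTM BP_ND 3.193
```

The 2T model wins decisively on AIC and recovers `V_T` to 0.6% even though
the data are three-tissue; SRTM against the binding pseudo-reference lands
at 3.19 versus the theoretical `DVR − 1` of 3.48 — the characteristic
downward bias of reference models for this tracer.

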