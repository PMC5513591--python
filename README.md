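# lactoflow

Milk production is hard to measure in small rodents: the traditional
weight-suckle-weight (WSW) approach — weigh the litter, let it suckle for an
hour, weigh it again — asks a 10 mg scale to resolve gram-scale gains against
grams of unmeasured urine, feces and evaporative loss. `lactoflow`
implements the alternative: a deuterated-water (D₂O) **water-turnover
method**, in which a single intravenous tracer bolus to the dam yields her
total body water, her water turnover, and — through a two-compartment model
linking dam and litter — the milk flow to the pups, in g/h, with a
per-animal uncertainty. It is intended for lactation physiologists and
nutrition researchers who need to detect diet- or drug-induced changes in
milk yield with very few animals (e.g. screening candidate galactologues).

## Model

The dam and her litter are each one well-mixed body-water pool, both at
(near-)steady state over the sampling window. A bolus of *D* grams of D₂O
(5 g/kg, purity-corrected) labels the dam's pool TBW_d at *t* = 0. With
first-order rate constants *K*₀₁ (dam → environment), *K*₂₁ (dam → litter,
the milk route) and *K*₀₂ (litter → environment), the tracer masses obey

```
dm₁/dt = −(K₀₁ + K₂₁)·m₁
dm₂/dt = K₂₁·m₁ − K₀₂·m₂,          m₁(0) = D, m₂(0) = 0
```

so the enrichment above the 155 ppm natural-abundance baseline is

```
C₁(t) = (D/TBW_d)·e^(−λ₁ t),                                  λ₁ = K₀₁ + K₂₁
C₂(t) = D·K₂₁·(e^(−λ₁ t) − e^(−K₀₂ t)) / (TBW_l·(K₀₂ − λ₁))
```

The analysis is two-stage: (1) TBW_d = D / C₁(0), with C₁(0) the intercept
of a log-linear regression of plasma enrichment on time (isotope dilution);
(2) the three rate constants are fitted to the joint plasma + pooled-urine
series by iteratively reweighted least squares under a constant-CV (~1 %,
FTIR) error model, with TBW_d fixed from stage 1 and TBW_l fixed at
0.76 × litter mass. Milk flow is **R₂₁ = K₂₁ × TBW_d** (g/h). Groups are
compared with an exact (fully enumerated) Mann-Whitney test for the
kinetic endpoints and Welch's t test for the daily WSW endpoint.

## Worked example

Simulate a full study (control NP n=4 vs low-protein LP n=5 dams, 8 pups
per litter, the reference dosing and sampling design) and run both
experiments:

```python
from lactoflow import generate_study, run_experiment1, run_experiment2

bundle = generate_study(seed=42)        # tracer + dose + WSW tables, with ground truth
rep1 = run_experiment1(bundle)          # dilution TBW, compartmental fits, group tests
for g in ("NP", "LP"):
    s = rep1.summaries[g]
    print(g, "TBW median %.1f g" % s["tbw_mass_g"]["median"],
          "| milk flow median %.2f [%.2f; %.2f] g/h" % (
              s["milk_flow_g_per_h"]["median"],
              s["milk_flow_g_per_h"]["min"], s["milk_flow_g_per_h"]["max"]))
t = rep1.tests["milk_flow_g_per_h"]
print("Mann-Whitney milk flow: U=%.1f p=%.4f" % (t["statistic"], t["p_two_sided"]))
```

prints

```
NP TBW median 258.8 g | milk flow median 3.39 [3.12; 3.48] g/h
LP TBW median 214.1 g | milk flow median 2.07 [1.95; 2.12] g/h
Mann-Whitney milk flow: U=20.0 p=0.0159
```

The low-protein diet reduces the median milk flow by ~39 % in this
realization; U = 20 is complete separation of the per-dam flows at n = 4
vs 5, whose exact two-sided level is 2/126 = 0.0159. The WSW comparator
(`run_experiment2(bundle)`) returns the per-day group means ± SD and Welch
p-values — note its far wider spread at the same true flows:

```
 pnd  NP_mean  NP_sd  LP_mean  LP_sd  p_two_sided
  11    3.443  0.922    2.096  1.263        0.107
  12    3.030  0.477    1.840  1.624        0.182
  13    2.980  2.324    2.590  2.413        0.813
  14    2.360  1.278    2.424  0.686        0.932
```

The same workflow is available from a shell:

```sh
lactoflow simulate --seed 42 --out-dir study
lactoflow fit study --out-dir exp1
lactoflow wsw study --out-dir exp2
lactoflow compare exp1/experiment1_report.json exp2/experiment2_report.json
```

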