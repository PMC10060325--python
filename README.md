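# mitothermics

Analysis pipeline for mitochondrial bioenergetics and whole-body metabolic
phenotyping in two-group (control vs chronically stressed) mouse studies.
It takes the four raw data kinds such a study produces — extracellular-flux
(Seahorse-style) OCR plate traces from isolated muscle mitochondria,
metabolic-cage gas-exchange traces, label-free proteome abundance tables,
and Nd1/Lpl qPCR Ct values — and turns them into respiration states,
thermodynamic coupling and efficiency of oxidative phosphorylation,
circadian substrate-oxidation summaries, pathway statistics and mtDNA copy
number, with the study's test-selection rules applied throughout.  A
synthetic-data generator emulates all four input kinds so the whole
pipeline runs and is tested without any animal data.

## The model at the core

Oxidative phosphorylation is treated as a linear two-flow energy converter
(Stucki's formalism): substrate oxidation (input flow) drives ADP
phosphorylation (output flow) with degree of coupling *q* ∈ [0, 1].  From
the plate assay, oligomycin-inhibited respiration (state 4o) measures the
pure leak flow and ADP-stimulated respiration (state 3) the loaded flow,
giving

```
q     = √(1 − state4o / state3)
η_opt = q² / (1 + √(1 − q²))²
```

where η_opt is the converter's efficiency at the optimal-efficiency force
ratio x_opt = −q/(1+√(1−q²)).  Four degrees of coupling are singled out as
thermodynamic set points — the *q* at which operation at optimal efficiency
also maximizes net output flow (q_f = 0.786), output power (q_p = 0.910),
economic flow (q_f^ec = 0.953) or economic power (q_p^ec = 0.972).  They
are derived at run time by maximizing F_n(q) = qⁿ·s/(1+s)ⁿ (s = √(1−q²),
n = 1…4), never hard-coded, and every sample's *q* is classified into the
band the set points delimit.  The respiratory control ratio
RCR = state3/state4o uses a batch offset rule (a single constant raising
all negative state-4o readings above zero) so that raw plate exports remain
usable; *q* is computed from the same adjusted readings, preserving
q = √(1 − 1/RCR).

Around this core: RER = VCO₂/VO₂, energy expenditure EE = VO₂/BW^0.75, and
Péronnet–Massicotte substrate oxidation rates (CHO = 4.585·VCO₂ −
3.2255·VO₂, FAO = 1.6946·VO₂ − 1.7012·VCO₂, L/min → g/min) summarized over
exactly two circadian cycles; volcano-style differential abundance
(t-test on log2 intensities, 1.5-fold gate), EASE-style conservative
Fisher enrichment with Benjamini–Hochberg correction, estimation-plot
pathway z-scores; mtDNA/nDNA ratio 2^(ΔCt); and a normality-gated test
chooser (Shapiro–Wilk → Student t / Mann–Whitney / ANOVA+Tukey).

## Worked example

```python
import mitothermics as mt

# 1. thermodynamic set points (derived numerically, not hard-coded)
sp = mt.stucki_setpoints()
print(f"set points: q_f={sp.q_f:.3f} q_p={sp.q_p:.3f} "
      f"q_f_ec={sp.q_f_ec:.3f} q_p_ec={sp.q_p_ec:.3f}")

# 2. synthetic complex-II coupling assay -> states -> coupling table
cfg = mt.GeneratorConfig(seed=1)
plate, truth = mt.gen_flux_plate(cfg, "coupling-CII")
states = mt.normalize_states(mt.extract_states(plate), plate)
coup = mt.thermodynamic_coupling(
    states.table["state3"], states.table["state4o"], samples=states.table.index
)
summary = coup.table.join(states.table["group"], on="sample").groupby("group")[
    ["rcr", "q", "eta_opt"]].mean().round(3)
print(summary)

# 3. group comparison of optimal efficiency with the normality-gated test
eta = coup.table.set_index("sample")["eta_opt"]
res = mt.compare_groups(
    {g: eta[states.table["group"] == g].to_numpy() for g in ("Ctrl", "Cvs")}
)
print(f"{res.test_name}: p = {res.p:.4g}")
```

prints

```
set points: q_f=0.786 q_p=0.910 q_f_ec=0.953 q_p_ec=0.972
          rcr      q  eta_opt
group
Ctrl    3.723  0.855    0.317
Cvs    20.020  0.975    0.635
t-test: p = 4.34e-18
```

The stressed cohort's complex-II coupling (mean q = 0.975) sits above the
economic-power set point while the control cohort sits between q_f and
q_p — the coupling shift the pipeline is built to detect — and the gated
comparison of optimal efficiency picks the parametric branch and finds the
difference highly significant.

The same analyses run from the shell:

```
mitothermics simulate --seed 3 --out sim/           # all four input kinds
mitothermics flux --plate sim/plate_coupling-CII.csv --protocol coupling-CII --out states.csv
mitothermics thermo --states states.csv --out coupling.csv
mitothermics cage --trace sim/cage.csv --out phases.csv
mitothermics run --seed 5 --out results/            # full pipeline + summary.json
```

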