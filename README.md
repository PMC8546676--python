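# perihg

Mercury methylation/demethylation kinetics and methylator-community
profiling for periphyton biofilms.

Periphyton — the attached biofilm of phototrophs and heterotrophs on
submerged substrates — can methylate inorganic mercury (IHg) into the
biomagnifiable neurotoxin monomethylmercury (MMHg). Field studies measure
this with enriched-isotope tracers: spiking water with ²⁰⁰Hg(II) and
MM¹⁹⁸Hg and measuring the product MM²⁰⁰Hg and the surviving MM¹⁹⁸Hg after
incubation, while metagenomes and 16S amplicons identify who carries the
*hgcA* methylation gene. `perihg` implements the downstream analysis of
such a study as a tested, reusable Python package, exercisable end to end
on synthetic data with known ground truth.

## The model

Tracer kinetics follow the two-compartment first-order system

    d[MMHg]/dt = k_m [Hg(II)] − k_d [MMHg]

with methylation and demethylation rate constants k_m, k_d (day⁻¹). Spiked
tracers start as pure pools ([MM²⁰⁰Hg]₀ = [¹⁹⁸Hg(II)]₀ = 0), so a single
time-point measurement inverts the simplified forward maps:

    k_m = −ln(1 − [MM²⁰⁰Hg]_t / [²⁰⁰Hg(II)]₀) / t
    k_d = −ln([MM¹⁹⁸Hg]_t / [MM¹⁹⁸Hg]₀) / t

Product measurements at or below the detection limit are non-detects and
are excluded from site means. Around the kinetics sit the other stages:

* **budget** — speciation arithmetic: IHg = THg − MMHg, %MMHg of THg,
  AFDW/DW organic-matter fractions, spike-to-ambient fold ratios;
* **hgca** — HgcA screening of predicted proteins: bit score ≥ 100 makes a
  candidate, ≥ 164 with one of the six conserved cap-helix motifs
  (NVWCAAGK, NVWCASGK, NVWCAGGK, NIWCAAGK, NIWCAGGK, NVWCSAGK) a
  *complete* identification; abundance is coverage-weighted; merA/merB
  (EC 1.16.1.1 / 4.99.1.2) are counted from annotations;
* **taxonomy** — consensus between threshold-filtered similarity best hits
  (E ≤ 1e−20, identity ≥ 40%, query coverage ≥ 80%) and clade placement on
  a reference tree, with an agreement percentage;
* **community** — 16S ASV profiling: relative abundance by rank, <2%
  lumping, Bray–Curtis, PCoA, one-way PERMANOVA (999 permutations);
* **synthetic** — generators for every input, with ground truth.

## Worked example

Simulate a three-site triplicate tracer experiment and fit it:

```python
import numpy as np
from perihg.synthetic import TracerSpec, gen_tracer_experiment
from perihg.kinetics import TracerKineticsModel

table, truth = gen_tracer_experiment(
    TracerSpec(mode="simplified"), np.random.default_rng(1)
)
print(TracerKineticsModel.from_dataframe(table).fit().summary())
```

```
Tracer kinetics fit
===================

site_id rate  mean_per_day  se_per_day  n_detected  n_total
natural   km       0.00273    5.21e-05           3        3
flooded   km       0.00287    7.52e-05           3        3
wetland   km       0.00565     0.00013           3        3
natural   kd           1.4      0.0327           3        3
flooded   kd          2.08     0.00451           3        3
wetland   kd           1.8      0.0139           3        3

km: one-way ANOVA F = 320, p = 7.98e-07
  Tukey HSD natural vs flooded: p = 0.537
  Tukey HSD natural vs wetland: p = 1.26e-06
  Tukey HSD flooded vs wetland: p = 1.71e-06
...
```

The site means recover the generator's true rate constants (wetland
k_m = 5.9 × 10⁻³ day⁻¹, k_d ≈ 1.8 day⁻¹) within the 10% measurement
noise; the ANOVA separates the sites whose true rates differ.

The same stages run from the shell:

```sh
perihg simulate --seed 1 --outdir sim/
perihg rates --input sim/tracer/tracer.tsv --outdir out/rates
perihg budget --outdir out/budget          # packaged speciation table
perihg run --seed 1 --outdir out/full      # everything, one report
```

`perihg budget` prints, among others, `"percent_mmhg": 23.2` for wetland
water (MMHg 0.23 / THg 0.99 ng L⁻¹), `18.0` for flooded periphyton, and
spike folds `2.94` (THg) and `26.7` (MMHg) — the 4 ng L⁻¹ isotope spike
relative to mean ambient concentrations.

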