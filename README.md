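# ecoevo

Analysis toolkit for eco-evolutionary experiments in which co-occurring
bacterial species adapt to a novel environment by serial transfer — alone
(monoculture) or together (polyculture) — and the consequences are read
out through growth assays, spent-medium interaction assays, metabolic
footprints of the medium, and community respiration. It is written for
experimental microbial ecologists and evolution researchers who have plate
OD time series, integrated NMR peak tables, transfer logs, and colorimetric
respiration readings, and who want a tested, reproducible path from those
tables to the field's standard statistics.

## What it computes

* **Growth**: blank-corrected OD600 → calibrated cell densities via a
  shared-slope, per-species-intercept regression of log₁₀(colonies/ml) on
  OD600 → *V*<sub>MAX</sub>, the OLS slope of log₂ density over the first
  48 h (doublings/day), plus carrying capacity at 96 h and permutation
  contrasts between evolutionary treatments.
* **Interactions**: directed networks where edge donor→recipient is
  *V*<sub>MAX</sub> on donor-used medium minus *V*<sub>MAX</sub> on fresh
  medium — negative for niche overlap, positive for facilitation — with
  permutation significance and bootstrap intervals; CSV/DOT/GraphML output.
* **Metabolic footprints**: per-compound net production/consumption
  profiles (spent − fresh medium, integrals relative to an internal
  standard), contaminant removal, merging of correlated resonances
  (r > 0.95), covariance-based (unscaled) PCA, and Monte Carlo permutation
  tests of two statistics: the mean ancestral→evolved footprint distance
  per species (*evolution*) and the change in mean between-species
  distance (*divergence*, i.e. character displacement). Profiles are
  shuffled among treatment labels within species, B = 10,000, two-tailed.
* **Cross-feeding**: δ₀,₁ (first species' change to the medium) and δ₁,₂
  (second species' further change), compared evolved-vs-ancestral per
  produced compound; Pearson correlation of production change against
  consumption change per treatment, and the OLS interaction model
  `y ~ x * treatment`.
* **Demography**: generations per transfer g = log₂(N(t)/(N(t−1)/d)) and
  effective population sizes Ne = N₀·g from transfer logs.
* **Respiration**: cresol-red indicator readings → normalised absorbance →
  %CO₂ via A + B/(1 + D·Ai) → µg CO₂ ml⁻¹ h⁻¹, with community contrasts.
* **Synthetic experiments**: a ground-truth community generator
  (consumption/production matrices, logistic growth, measurement noise)
  that emulates all five input tables, so every stage is testable without
  any external data. See `docs/methods.md` for the model and defaults.

## Worked example

`examples/03_metabolic_footprints.py` simulates a four-species community
(seed 11), cleans the peak table, and tests evolution and divergence of
resource use:

```
peak axis after cleaning: 10 compounds; merged resonance groups: ['glucose+glucose_b']
variance explained by PC1/PC2: 50% / 22%
evolution_distance (monoculture): observed +0.337, two-tailed p = 0.0002
divergence_distance (monoculture): observed -0.287, two-tailed p = 0.0002
evolution_distance (polyculture): observed +1.379, two-tailed p = 0.0002
divergence_distance (polyculture): observed +1.122, two-tailed p = 0.0002
```

Reading: the two methanol/acetonitrile contaminant peaks were dropped and
two resonances of glucose merged; species that evolved in polyculture
moved ~4× further from their ancestors in footprint space than monoculture
lineages and spread *apart* (positive divergence contrast — character
displacement), while monoculture lineages converged slightly. The other
examples print the matching growth-rate trade-off, the ancestral
all-negative vs polyculture partly-positive interaction networks, the
negative production–consumption coupling (cross-feeding), ~65 generations
per 15 transfers, and the higher CO₂ output of communities reassembled
from co-evolved isolates.

A full pipeline run over all stages, from a config file or the built-in
demo:

```bash
ecoevo demo --seed 0 --out demo_out/        # synthetic end-to-end run
ecoevo run --config my_run.yaml --out out/  # same stages on your CSVs
```

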