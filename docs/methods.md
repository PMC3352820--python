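# Methods

`ecoevo` analyses a serial-transfer evolution experiment in which several
naturally co-occurring heterotrophic bacteria adapt to a plant-extract
medium ("tea") either alone (monoculture) or together (polyculture), and in
which the consequences of that adaptation are read out through growth
assays on fresh and spent medium, metabolic footprints of the medium,
serial-transfer demography, and community respiration. This note documents
the models, estimators, defaults, and the design decisions that were
genuinely open.

## Growth assays and V_MAX

Raw plate readings are OD600 time series. Each measurement well is paired
with a sterile control well on the same plate column and time point;
corrected OD is the difference, floored at ε = 0.001 OD (default,
configurable) because the subsequent log-calibration is undefined at
non-positive OD.

Cell densities come from a calibration regression of log10(colony
count)/ml on OD600 with a per-species intercept and a single shared slope —
the standard design when species differ in per-cell scattering but respond
linearly over the assayed range. The fit is ordinary least squares
(statsmodels); the model object records the regression F statistic,
degrees of freedom and r².

V_MAX, the maximum growth rate from low density, is the OLS slope of log2
cell density against time in days over all readings within the first 48 h,
reported in doublings/day. The estimator choice (plain OLS over the early
window, rather than a mixed-model slope or a parametric lag/stationary
model such as Gompertz or Baranyi) is deliberate: it is reproducible from
the data alone, linear in the observations, and exactly recovers the rate
of a noiseless exponential. Its standard error comes from the residuals
(zero when only two points fall in the window). Carrying capacity is read
directly as the calibrated log10 density at the reading closest to 96 h
(±4 h tolerance, configurable).

Treatment contrasts (e.g. monoculture vs ancestral V_MAX) use a two-sided
label-permutation test on the difference of group means with the add-one
correction p = (k+1)/(B+1), or exact enumeration of all C(n, n_a) group
assignments when that is feasible. Mixed-effects repeated-measures models
are intentionally not part of the package: the permutation contrast is the
documented, assumption-light replacement, and its operating
characteristics are verified by simulation in the test suite.

## Spent-medium interaction networks

The interaction of a donor species on a recipient is
`effect = mean V_MAX(used medium) − mean V_MAX(fresh medium)`, with the
relative ratio of the two means alongside. Used medium must come from the
same evolutionary treatment as the recipient; the pipeline enforces this
pairing. Significance is the same two-sided permutation test (α = 0.05 by
default); the ratio carries a percentile-bootstrap interval (1000
resamples) because no closed-form SE for a ratio of small-sample means is
trustworthy. Edges are classified negative/positive when significant and
neutral otherwise, and assembled into a directed graph (networkx) written
as CSV, DOT, or GraphML. Effects are mean differences rather than model
coefficients — the simplest estimator consistent with the assay design.

## Metabolic footprints

Peak tables contain integrals relative to an internal standard
(dimensionless). Preprocessing removes named contaminant peaks (methanol
and acetonitrile by default — solvent signals, not medium chemistry) and
merges groups of peaks whose pairwise Pearson correlation across samples
exceeds 0.95 (single-linkage components, replaced by the member sum):
near-proportional resonances are, with high probability, one compound
observed at several chemical shifts. Distances and cross-feeding
statistics are computed on this cleaned axis by default; the raw axis
remains available by skipping the two steps.

A footprint (Δ-profile) is spent-medium minus fresh-medium integrals:
positive entries are net production, negative net consumption.

Principal components use the covariance matrix of the footprints —
centered, **not** variance-scaled — so that compounds with large absolute
concentration changes dominate, which is the question being asked.
Implementation is a numpy SVD; eigenvalues use the n−1 divisor so their
sum equals the total variance (asserted to 1e-8 in tests), and each
component's sign is fixed by making its largest-magnitude loading positive
so that repeated runs and platforms agree.

Two scalar statistics summarise evolution:

* **evolution distance** — the mean over species of the Euclidean distance
  between that species' ancestral and evolved mean footprints (replicates
  averaged within species first);
* **divergence distance** — the mean Euclidean distance over unordered
  species pairs within one treatment.

### Monte Carlo permutation tests

Treatment effects on footprints are tested by shuffling whole profiles
among treatment labels and recomputing the statistic, B = 10,000 draws by
default, two-tailed p as the doubled smaller tail with the add-one
correction, capped at 1.

Two design choices matter and were validated by simulation:

1. **Species are a blocking factor.** Profiles are shuffled among
   treatment slots *within* each species, keeping all group sizes fixed.
   An unrestricted shuffle across species produces a null dominated by
   between-species differences, which are real, large, and not the
   hypothesis under test: with it, the evolution-distance test rejects
   essentially always under a no-effect generator and the divergence test
   essentially never. With species-blocked shuffling both tests sit at the
   nominal 5% level on null data (verified at 500 simulated datasets in
   the acceptance suite). The unrestricted scheme remains available
   (`block_by_species=False`) for completeness.
2. **Divergence is tested as a contrast.** Within a single treatment with
   one profile per species, relabelling leaves the divergence statistic
   numerically unchanged, so the test statistic is divergence(focal
   treatment) − divergence(ancestral) whenever the shuffled pool contains
   the reference treatment; plain within-treatment divergence is used
   otherwise. The contrast is also the scientifically meaningful quantity
   (did species spread out *more than they started*?).

An exhaustive mode enumerates every distinct within-block order (the
product of per-block factorials) and then applies no correction, since the
observed arrangement is one of the enumerated ones; the test suite checks
that the enumeration-mode p equals an independently coded oracle exactly.
Because the permutation null is discrete, very small replicate numbers
make the doubled-tail p conservative; the simulation studies use three
replicates per species × treatment, at which both tests are calibrated.

## Cross-feeding statistics

For a sequential assay (fresh medium → species 1 → species 2),
δ₀,₁ = filtrate₁ − fresh and δ₁,₂ = filtrate₂ − filtrate₁ per compound;
they telescope to filtrate₂ − fresh exactly. Comparing evolved with
ancestral pairs of the same species (and treatment) gives one record per
(pair, compound): x = δ₀,₁(evolved) − δ₀,₁(ancestral), the evolution of
production by the first species, and y = δ₁,₂(evolved) − δ₁,₂(ancestral),
the evolution of the second species' consumption response. Only compounds
the evolved first isolate actually produced (δ₀,₁ strictly > 0) enter;
the ancestral δ₀,₁ is unconstrained. Records are kept per second species —
each (pair, compound) is an observation, not deduplicated.

Per treatment, the x–y association is Pearson's r with the usual t-based
two-sided p. The pooled model is OLS `y ~ x * treatment` with monoculture
as the reference level, so the interaction coefficient is
slope(polyculture) − slope(monoculture); records are unweighted. Note a
structural caveat for interpreting the *mono* slope: y contains −x by
construction (both difference the first filtrate), so when x carries
little real signal the fitted slope is pulled toward −1 mechanically. The
sign of r within each treatment is the robust readout; at demo scale the
interaction coefficient itself is noisy, and the package's validation
tracks r.

## Serial-transfer demography

With pre-transfer densities N(t) and dilution factor d, generations per
transfer are g_t = log2(N(t) / (N(t−1)/d)); the founding density before
the first recorded transfer is taken to be N(1)/d (a culture started by
the same dilution from an equal-density stock), so a constant-density log
over T transfers totals T·log2(d) exactly. Declines below dilution
replacement give negative g_t; these are reported as 0 with a flag rather
than as negative generations. The effective population size is the classic
serial-transfer approximation Ne = N₀·g with N₀ the mean post-dilution
census (cells, i.e. density/d × volume) and g the mean generations per
transfer; a harmonic-mean census alternative is provided, and the
convention used is recorded in every output. The default dilution is
20-fold (overridable, e.g. to 21 for a 100 µl into 2 ml transfer read as
volumetric ratio 21).

## Community respiration

Respired CO₂ acidifies a cresol-red gel; well absorbance ratios
(OD570 end/start) are normalised by the mean ratio of blank wells on the
same plate, so blanks define Ai = 1 and ambient drift divides out. (The
normalisation divides by the blank baseline rather than multiplying by it;
only division makes a well identical to a blank read as exactly
zero net respiration downstream.) The indicator curve
%CO₂ = A + B/(1 + D·Ai) converts Ai to headspace CO₂; its constants are
instrument configuration with MicroResp-style defaults
(A = −0.2265, B = −1.606, D = −6.771) and are never treated as ground
truth. The blank reading (Ai = 1) is subtracted as the zero-respiration
baseline; negative net readings are clipped to zero and flagged (plate
noise), not raised as errors. Mass bookkeeping is ideal-gas:
µg CO₂ = pct/100 · headspace(ml) · (44/22.4) · 273/(273+T) · 1000, and the
rate divides by medium volume and incubation time (6 h default, 25 °C).
Group contrasts reuse the permutation engine.

## The synthetic experiment generator

The generator exists so that every statistic above can be tested against a
known truth; it is not a mechanistic model of any real community and none
of its parameters are estimates of a real system.

A community is: a medium vector over compounds (substrates present in the
base medium at ~0.8–1.5 relative units, plus waste compounds present only
in traces, 0.05); per-species consumption fractions U ∈ [0,1], production
amounts P ≥ 0 (one characteristic waste product per species), growth rates
r (1.5–2.5 doublings/day), capacities K (10^8.3–10^9 cells/ml), and a
measurement layer (log-linear OD calibration with per-species intercepts;
Gaussian OD noise, σ = 0.01; Gaussian peak noise truncated at zero,
σ = 0.05; lognormal regrowth noise). A single integer seed drives every
table through deterministic per-path child seeds.

Spent medium after species i is `medium·(1−U_i) + P_i`. Growth is logistic
with rate r·ln2·φ, where φ is the consumable fraction of the medium
relative to the species' *ancestral* consumable budget on fresh medium,
clamped to [0,1]:

    φ_i(m) = clamp( Σ_c U_i[c]·m[c] / Σ_c U_ref,i[c]·base[c] , 0, 1 ).

The ancestral reference in the denominator is what lets evolved isolates
express a trade-off: a polyculture isolate that shifted consumption onto
other species' waste products has φ < 1 on fresh medium (it grows slower
there than its ancestor did) and a larger φ on donor-conditioned medium —
the negative/neutral/positive sign structure of spent-medium assays. With
an unevolved config, U_ref = U and φ(fresh) = 1.

Evolution transforms, all continuous in `effect_size` with
`effect_size = 0` an exact identity:

* **monoculture** — r increases (×(1+0.25e)); U rows shrink toward the
  community mean (convergence); a weak waste economy appears (P ×(1+0.2e),
  uptake of others' products +0.15·κ·e), so monoculture cross-feed records
  carry real but shallow structure rather than pure noise.
* **polyculture** — substrate specialisation: the strongest consumer of
  each substrate keeps it (+0.3) while the rest largely drop it (×0.1);
  uptake of other species' waste products is added with weight 0.7·κ·e
  (κ = `coupling`, default 1); waste production rises (×(1+0.8e)). This
  produces, simultaneously, larger footprint shifts and between-species
  divergence than monoculture, slower growth on fresh medium, positive
  spent-medium edges toward cross-feeders, and higher community coverage
  of the medium (hence respiration) — the qualitative pattern the analyses
  are designed to detect.

Default study conditions: 4 species, 10 compounds, effect size 1.0, 9
growth-assay replicates per species × treatment × substrate, daily OD
readings at 0–96 h (0–48 h in the estimator-recovery studies, which only
use the early window), 5 peak-table replicates in the demo, 3 in the
repeated null/power studies, 15 transfers at 20-fold dilution, 10
respiration replicates per community plus 4 blanks. Simulation studies use
B = 999 permutation draws per test; single analyses default to B = 10,000.

What the generator does **not** emulate: mechanistic uptake kinetics
(Monod, flux balance), growth-dependent noise, plate position effects,
spectral artefacts (overlap, baseline, phasing — the pipeline starts from
an integrated peak table by design), mutation-level population genetics,
and species extinction. Passing tests therefore demonstrate that the
estimators and tests are correct and calibrated *given* data of the
assumed structure, not that real experiments satisfy that structure.

## Numerical conventions

* Permutation p-values always include the observed arrangement
  ((k+1)/(B+1)); exhaustive modes count it once through enumeration.
  Tail counts use a relative tolerance of 1e-9 so that an independently
  recomputed statistic ties rather than splits on the last ulp.
* PCA component signs: largest-magnitude loading positive.
* Correlation grouping: single linkage, groups replaced by member sums,
  merged names joined with `+`.
* Degenerate inputs error early with offender lists (missing controls,
  duplicate peaks, rank-deficient calibration, non-consecutive transfers);
  the two deliberate exceptions are the V_MAX SE (0 at two points) and
  negative respiration readings (clipped and flagged).
* Pipeline outputs are sorted and written with a fixed float format, so
  identical config + seed gives byte-identical CSVs.

## Known limitations

* The permutation tests assume exchangeability of profiles within species;
  batch structure across plates is not modelled.
* The evolution/divergence SEs printed by some instruments' software have
  no analogue here; the package reports observed statistics and
  permutation p-values only.
* Ne conventions for serial transfer differ across the literature; both
  provided estimators are approximations and the output labels which one
  produced each number.
* The interaction-model coefficient on small record tables inherits the
  mechanical −x component of y described above; treat per-treatment r as
  the primary cross-feeding readout at small n.
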