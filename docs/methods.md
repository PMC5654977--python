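# Methods

`epiclone` models the clonal dynamics of mutant stem cells in the basal
layer of human epidermis and the statistics used to interpret deep
targeted sequencing of normal skin. This note records the models, their
assumptions, the tunable parameters, the numerical choices, and what the
synthetic-data tests do and do not establish.

## Lattice model of the stem-cell compartment

The basal layer is a two-dimensional hexagonal lattice; each site holds a
wild-type stem cell (A), a mutant stem cell (B), a transit-amplifying cell
(C), or is empty. The homogeneous model is a death-first voter model:

* A cells are lost at rate λ (per cell per week) and B cells at rate φ;
  φ < λ encodes a competitive advantage (mutations reduce the probability
  of exiting the stem compartment).
* A vacancy with at least one occupied stem neighbour is filled, within
  the same time step, by the division of a uniformly chosen such
  neighbour.
* Neutral mutations (rate ω per cell per day) assign a fresh clone label;
  non-neutral mutations (rate θ) convert A to B with a fresh label. The
  clonal history is a tree rooted at the unmutated founder label, and the
  size of a clone is the recursive sum over the clone and all descendant
  labels — i.e. the number of cells carrying that mutation, which is what
  sequencing measures.
* Migration swaps the contents of adjacent sites at rate κ per pair per
  day.

The heterogeneous model adds a stem/TA compartment: a binary map diff(i)
marks stem clusters (diff = 0 inside). A cells differentiate to TA at rate
ν where diff(i)=1; TA cells divide into vacancies for at most `q_max`
rounds (both daughters carry the incremented division count) and are lost
at `ta_loss_rate`; B cells never differentiate. Migration is gated on a
lattice energy

    E(i) = |N_i ∩ C| + diff(i)·p              for stem occupants (A or B),
    E(i) = |N_i ∩ A| − |N_i ∩ ∅| + (1−diff(i))·p   for TA occupants,

with a large scalar penalty p: a proposed swap is applied only if it
strictly lowers the summed energy, which keeps stem and TA cells spatially
sorted. B cells count as stem cells in E — they are stem cells by
definition. Accepted moves never raise the total energy (tested).

### Defaults and units

| parameter | default | units | rationale |
|---|---|---|---|
| λ | 0.5 | /cell/week | published estimate for human interfollicular epidermis |
| φ | 0.5 (set <λ for advantage) | /cell/week | only the loss rate differs between A and B; the division rule is shared |
| ω | 1e-3 | /cell/day | neutral (passenger) mutation rate used throughout the simulations |
| θ | 0 (1e-6 in selection runs) | /cell/day | non-neutral mutation rate; detectable-clone distributions are insensitive to it over 1e-6–1e-5 after rescaling (tested) |
| κ | 0 | /pair/day | one cell diameter (σ = 10 µm) per lattice spacing makes ~10 µm/day ≈ 1 swap attempt per cell per day; off by default because neutral clone-size statistics do not depend on it |
| ν | 0 | /cell/day | stem→TA differentiation, applied where diff(i)=1 |
| q_max | 4 | divisions | a few rounds of transit amplification, consistent with estimates for epidermis |
| ta_div_rate, ta_loss_rate | λ/7 | /day | TA belts turn over on the stem-cell loss timescale; both exposed in config |
| cluster radius / spacing | 20 / 70 | cells | radius matches whole-mount stem-cluster estimates; spacing sets cluster density |
| p | 100 | — | penalty far exceeding the ±6-neighbour terms, making diff-map violations dominate E |
| dt | 1 | day | discrete quantised steps; weekly rates become daily probabilities rate/7 (valid since rate·dt ≪ 1) |
| detect_vaf | 0.007 | VAF | sequencing detection threshold for "detectable" clones |

Within a day the order is: simultaneous Bernoulli losses; vacancy refills
in uniformly random order (a site filled earlier in the step can donate to
a later vacancy, so all transitions initiate and complete within one
step without sweep-order bias); mutations; differentiation and TA
division; migration.

Geometry: "odd-row offset" coordinates on a rectangular array (odd rows
shifted half a cell), giving six neighbours per interior site. The default
boundary is a torus, which avoids edge artefacts on clone growth and
requires an even lattice height so row parity matches across the wrap; a
non-wrapping mode is retained. The committed-progenitor output of a stem
division is not represented explicitly: it changes neither the number nor
the position of stem cells.

Initial state: all sites stem cells with the founder label (homogeneous),
or stem inside clusters and TA outside with a configurable empty fraction
(heterogeneous) — the arrangement outside clusters is a modelling choice
exposed in the config. Extinct clone records are purged every 30 days
(memory/CPU trade-off); purging is observationally silent for surviving
clones (tested).

VAF convention everywhere: heterozygous diploid clones, VAF = cell
fraction / 2, anchored to the equivalence 0.2 VAF = 40% of the population.

## Clone-size statistics

* **Neutral drift.** P_n(t) = e^{−n/rλt} / (n·ln rλt) for a clone of n
  cells; the cumulative tail C(s) is the finite sum to the population size
  N, evaluated in log space (log-sum-exp) so values of order 1e-13 are
  exact. Infinite tails are never needed; the finite sum is exact.
* **Klein saturation time.** T = N(ln N + 1/(2r))/λ for two neutral types
  (r = 1/2); weeks convert to years at 52.18 (= 365.25/7), which affects
  the third significant digit only.
* **First incomplete moment.** (1/⟨n⟩)·Σ_{m≥n} m·P_m, normalised to 1 at
  the smallest observed size. Under neutral drift it is exponential,
  e^{−(n−n₀)/rλt}; the fit is unweighted least squares of the log moment
  against n. n₀ is a correction for the sequencing size limit: truncating
  the sample at threshold c moves n₀ by ≈c and leaves the decay unchanged
  (exact for exponential-moment data; tested). Curve points with moment
  < 0.01 are dropped by default — they reflect a handful of extreme clones
  and carry most of the log-scale noise. Degenerate samples (all sizes
  equal, or fewer than 10 clones) are rejected.
* **Boundary nucleation.** Secondary neutral mutations arising on the rim
  of an advantaged clone expanding at r(t) = αt nucleate at rate
  (2πr/σ)γ and reach, on average, the area A(R,r) = R²σ/2r − rσ/2.
  Changing variables gives the clone-count density M(A), implemented in
  the algebraically identical stable form 2πγR⁴/(ασ²(root + A/σ)²·root)
  with root = √((A/σ)² + R²): the raw two-factor product cancels
  catastrophically for A ≫ σR. The density is returned as a magnitude
  (the raw expression is negative because area falls with nucleation
  radius). Its local log-log slope β(A) = −A(A + 2√(A² + σ²R²))/(A² + σ²R²)
  equals the numerical derivative to 1e-6 relative (tested) and tends to
  −3: an inverse-cubic tail. The large-A asymptote (2πγ/α)·σR⁴/4A³ treats
  the cell diameter σ as the expansion's length scale.
* **Exponential growth.** If clones grow as e^{bt} and secondary clones
  nucleate in proportion to primary area, M(A) = γaπσ²e^{bT}/(4bA²) on the
  support (a, a·e^{bT}) with a = π(σ/2)² the single-cell area: an exact
  inverse-square law. The nucleation constant multiplies the initial clone
  area a, the only consistent reading of the nucleation rate γ·a·e^{bt}.
* **Power-law fitting.** Empirical density on logarithmically spaced bins
  (default 20), least-squares slope of log density vs log size, with
  residual sums for the fixed slopes −2 and −3 reported for model
  comparison. At least 20 clones and 3 populated bins are required. No
  maximum-likelihood or bootstrap machinery: the log-log comparison is the
  analysis this package reproduces.

## Variant calling

Background errors at each site/allele/strand follow a beta-binomial with
mean v (the pooled read fraction across the control panel; a per-sample
mean option is retained) and a single genome-wide overdispersion ρ,
parameterised by α = μ(1−ρ)/ρ, β = (1−μ)(1−ρ)/ρ so that ρ is the
intraclass correlation and ρ→0 recovers the binomial. ρ is profiled over
all non-reference cells on a log grid in [1e-6, 0.5] and refined by
bounded minimisation. Sites with zero pooled control coverage are flagged
and excluded. When testing, v is floored at `min_error` (default 1e-5):
a site with zero observed control errors still has a nonzero true error
rate, and an unfloored point-mass null would declare any single read
significant.

Each non-reference allele at each covered position is tested by a strand-
aware likelihood-ratio test — null: strand-specific backgrounds (v, v′);
alternative: one shared variant fraction μ = (x+x′)/(n+n′) on both strands
— with 2·Δℓ referred to χ²(2 df). Splitting the null by strand penalises
single-strand (PCR-artefact-like) signal; the statistic is invariant to
relabelling strands (tested). BH correction is applied across all tested
cells within one sample (per-sample families match per-sample calling;
cross-cohort correction would couple unrelated samples). Post-filters, in
order: q < 0.05; removal of variants also present in the matched control
(significant there, or control VAF > 0.3 — a germline-heterozygote guard);
total coverage > 50 reads in both sample and matched control ("total"
read as summed over strands); ≥ 5 supporting reads; transitive merging of
same-sample calls within 5 bases into one deletion-spanning record whose
VAF is the average of the constituents. Deletion alleles ("−") are tested
like substitutions.

## Synthetic data

The generators emulate the statistical structure of a 10-patient panel:
strand depths Poisson around 500 per strand (1000× total), per-site
per-alternate error means drawn log-uniformly over [1e-5, 10^−2.5] (the
paper-level fact is only that error varies along the genome; the
log-uniform choice exercises the model from clean to noisy regimes),
background counts beta-binomial with one ρ, and spiked variants added
binomially and symmetrically on both strands; a strand-biased mode places
them on one strand to exercise the LRT's artefact penalty. Clone-size
samples are drawn by inverse-CDF from the neutral, boundary (inverse-
cubic), exponential (inverse-square) or custom power-law densities.

What passing tests show: the pipeline's statistics are calibrated and
sensitive *under the model that generated the data*. Real panels have
correlated errors along reads, mapping artefacts, contamination and
copy-number effects that these generators deliberately omit; sensitivity
and FDR measured here are upper bounds on real-data performance.

## Problem sizes used in the checks

Simulation-based checks run at the study's stated conditions where those
are small (200×200 lattices for 3–10 simulated years; 10 neutral
replicates pooled before fitting, mirroring the mean-of-replicates
presentation) and at 400×400 over 100 years for the neutral-ceiling
figure, averaged over two seeds in the acceptance script. The spike-in
benchmark uses 900 sites × 30 controls with 100 VAF-0.10 spikes.

## Known limitations

* Basal layer only; no three-dimensional epidermis, no supra-basal flux.
* One cell per lattice site; the crowded-lattice relaxation is out of
  scope.
* B cells differ from A only in loss rate φ; altered division or
  non-cell-autonomous effects are not modelled.
* The geometric boundary-nucleation and exponential models are
  deterministic mean-field descriptions; stochastic extinction of
  secondary clones enters only through the lattice simulation.
* The caller identifies substitutions and deletions, not copy-number
  changes, and assumes the control panel shares the sample's error
  process.
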