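# epiclone

Clonal dynamics of mutant stem cells in sun-exposed human epidermis:
a spatial lattice simulator, closed-form clone-size models, and a
beta-binomial subclonal variant caller, with synthetic-data generators so
every stage runs without any sequencing data.

Deep targeted sequencing of normal skin reveals thousands of somatic
mutant clones. Whether their sizes reflect neutral drift or positive
selection is decided by the clone-size distribution — and the largest
observed clones (VAF > 0.2, ~64,000 basal cells) are far too large for
neutral drift on a human timescale. This package implements the
quantitative machinery behind that argument, for researchers analysing
clonal architecture in normal epithelia:

* **`epiclone.lattice`** — a death-first voter model on a hexagonal
  lattice: wild-type stem cells (loss/replacement rate λ = 0.5/week),
  advantaged mutants (loss rate φ < λ), neutral (ω) and non-neutral (θ)
  mutations with full clonal-history tracking, migration, and a
  heterogeneous stem/transit-amplifying compartment with energy-gated
  migration.
* **`epiclone.clonestats`** — neutral-drift clone-size distribution
  P_n(t) = e^(−n/rλt)/(n ln rλt) and its cumulative tail; the Klein
  saturation time T = N(ln N + 1/2r)/λ; the first incomplete moment
  (1/⟨n⟩)Σ_{m≥n} m P_m with two-parameter exponential fitting
  e^(−(n−n₀)/rλt); the geometric boundary-nucleation density M(A) with
  local slope β(A) → −3 (inverse-cubic tail); the exponential-growth
  density M(A) ∝ A⁻²; and log-log power-law fitting.
* **`epiclone.caller`** — strand-aware beta-binomial background model
  (per-site error means, one genome-wide overdispersion ρ), likelihood-
  ratio test against χ²(2 df), Benjamini–Hochberg correction (q < 0.05),
  matched-control SNP removal, coverage/support/merge filters, and a
  Monte-Carlo spike-in benchmark (sensitivity and FDR).
* **`epiclone.synthetic`** — strand-specific count panels with
  beta-binomial noise and spiked subclones, clone-size samples from the
  model densities, and UV-spectrum mutation tables.
* **`epiclone.io` / `epiclone.cli`** — TSV/BED/VCF formats, substitution
  spectra, and the `epiclone` command with subcommands
  `simulate-lattice`, `simulate-counts`, `sample-clones`, `call-variants`,
  `fit-distribution`, `analytic`, `spectrum`.

See `docs/methods.md` for models, assumptions, parameter defaults and
numerical choices.

## Worked example

Closed-form results first:

```python
>>> from epiclone import clonestats as cs
>>> cs.klein_saturation_years(64_000, 0.5)      # two neutral types, r=1/2
29600.84
>>> rlt = 0.5 * 70 * cs.WEEKS_PER_YEAR          # 70 years of drift
>>> cs.cumulative_tail(64_000, 160_000, rlt)    # P(clone >= 64,000 cells)
2.23e-18
>>> cs.vaf_to_cells(0.2, area_mm2=16.0, linear_density=100.0)
(64000.0, 6.4)
>>> cs.boundary_beta(1e8, sigma=1.0, R=100.0)   # A = 1e6·σR
-3.000000
```

A 64,000-cell clone would need ~29,600 years to arise by neutral
competition, and the neutral tail probability at any human age is
negligible — the large clones seen in sequencing require a competitive
advantage. The boundary-nucleation model of that advantage predicts an
inverse-cubic clone-size tail (slope −3).

A neutral lattice simulation (200×200, three years, ω = 10⁻³/cell/day)
and its incomplete-moment fit:

```python
from epiclone import lattice as lat, clonestats as cs

p = lat.SimParams(width=200, height=200, omega=1e-3,
                  duration=lat.years_to_days(3), seed=42)
res = lat.run(p)
sample = res.samples[p.duration]
fit = cs.fit_incomplete_moment(sample.sizes)
```

which prints, via the obvious format strings:

```
2978 surviving mutant clones on 40000 sites
largest clone: 277 cells (VAF 0.0035)
incomplete-moment fit: rlt = 40.2 cells, n0 = 5.3, R^2 = 0.993
```

The exponential incomplete moment (R² = 0.993) is the neutral-drift
signature; the largest clone after three years is ~0.7% of the
population, nowhere near the 40% occupancy of the largest clones observed
in real skin. Runs with θ > 0 and φ < λ reproduce the same shape at a
10-fold larger scale.

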