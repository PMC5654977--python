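"""Closed-form clone-size distribution models and fitting.

Covers the neutral-drift clone-size distribution and its cumulative tail,
the Klein voter-model saturation time, the first incomplete moment and its
two-parameter exponential fit, the geometric boundary-nucleation model
(inverse-cubic tail), the exponential-growth model (inverse-square tail),
and log-log power-law fitting of empirical clone sizes.

Conventions
-----------
* ``r_lambda_t`` is the dimensionless product of the stem-cell
  loss/replacement rate and elapsed time (the mean size, in cells, of a
  surviving neutral clone induced at first exposure).
* Clone sizes are in cells unless stated otherwise; VAF assumes a
  heterozygous diploid clone, i.e. VAF = cell fraction / 2.
* The boundary-nucleation and exponential-growth densities are returned as
  magnitudes: the raw change-of-variables expressions are negative because
  secondary-clone area decreases with nucleation radius/time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

WEEKS_PER_YEAR = 365.25 / 7.0  # 52.18 weeks


# ---------------------------------------------------------------------------
# Neutral drift
# ---------------------------------------------------------------------------

@dataclass
class NeutralDriftParams:
    """Neutral-drift scale parameters.

    Parameters
    ----------
    r_lambda : float
        Stem-cell loss/replacement rate, per cell per week (field estimate
        0.5/week for human interfollicular epidermis).
    t_weeks : float
        Elapsed time in weeks.
    N : int
        Total stem-cell population size (cells).
    """

    r_lambda: float
    t_weeks: float
    N: int

    @property
    def r_lambda_t(self) -> float:
        return self.r_lambda * self.t_weeks

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("population size N must be >= 1")
        if self.r_lambda_t <= 1:
            raise ValueError("r_lambda * t must exceed 1 (log term undefined)")


def neutral_pmf(n, r_lambda_t: float):
    """Probability that a neutral mutant clone has size ``n`` at scale ``r_lambda_t``.

    P_n = e^{-n / rλt} / (n · ln(rλt)).  Valid for rλt > 1; n >= 1.
    """
    if r_lambda_t <= 1:
        raise ValueError("r_lambda_t must exceed 1")
    n = np.asarray(n)
    if np.any(n < 1):
        raise ValueError("clone size n must be >= 1")
    out = np.exp(-n / r_lambda_t) / (n * np.log(r_lambda_t))
    return out if out.ndim else float(out)


def cumulative_tail(s: int, N: int, r_lambda_t: float) -> float:
    """Cumulative probability of a neutral clone of size >= ``s`` in a population of ``N``.

    Finite sum of :func:`neutral_pmf` from ``s`` to ``N``, evaluated in log
    space so that astronomically small tails (1e-13 and below) are exact.
    Returns 0 for the empty sum ``s > N``.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    if s > N:
        return 0.0
    n = np.arange(s, N + 1, dtype=np.float64)
    log_terms = -n / r_lambda_t - np.log(n)
    return float(np.exp(logsumexp(log_terms) - np.log(np.log(r_lambda_t))))


def klein_saturation_time(N: int, lam: float, r: float = 0.5) -> float:
    """Voter-model time for one of two neutral lineages to saturate a lattice of N sites.

    T = N (ln N + 1/(2r)) / λ, in the time units of 1/λ.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if lam <= 0:
        raise ValueError("lam must be positive")
    return N * (np.log(N) + 1.0 / (2.0 * r)) / lam


def klein_saturation_years(N: int, lam_per_week: float, r: float = 0.5) -> float:
    """Klein saturation time converted weeks → years (52.18 weeks/year)."""
    return klein_saturation_time(N, lam_per_week, r) / WEEKS_PER_YEAR


# ---------------------------------------------------------------------------
# First incomplete moment
# ---------------------------------------------------------------------------

def first_incomplete_moment(sizes) -> tuple[np.ndarray, np.ndarray]:
    """Empirical first incomplete moment of a clone-size sample.

    For each observed size n, returns (Σ_{m>=n} m·c_m) / (Σ_m m·c_m) where
    c_m are the observed multiplicities — i.e. the partial expectation above
    n normalised by the mean clone size.  Equals 1 at the minimum observed
    size and is non-increasing in n.

    Returns
    -------
    (n, moment) : arrays over the sorted unique sizes.
    """
    sizes = np.asarray(sizes, dtype=np.float64)
    if sizes.size == 0:
        raise ValueError("empty clone-size sample")
    uniq, counts = np.unique(sizes, return_counts=True)
    mass = uniq * counts
    tail = np.cumsum(mass[::-1])[::-1]
    return uniq, tail / tail[0]


@dataclass
class IncompleteMomentFit:
    """Two-parameter exponential fit exp(-(n - n0)/rλt) to the incomplete moment."""

    r_lambda_t: float
    n0: float
    r_squared: float
    n_points: int
    fit_range: tuple[float, float]


def fit_incomplete_moment(sizes, min_size: float | None = None,
                          moment_floor: float = 0.01) -> IncompleteMomentFit:
    """Fit the empirical incomplete moment to exp(-(n - n0) / rλt).

    Unweighted least squares of the log incomplete moment against n.  The
    decay constant rλt sets the scale of the distribution; n0 absorbs the
    detection limit of the assay: truncating the sample at a threshold c
    moves n0 by ≈c and leaves the decay unchanged.

    Parameters
    ----------
    sizes : array-like
        Clone sizes (>= 10 required).
    min_size : float, optional
        Restrict the fit to sizes >= this value (detection threshold).
    moment_floor : float
        Drop curve points below this moment value; the last few points of
        the empirical curve reflect a handful of extreme clones and their
        log values carry most of the sampling noise.
    """
    sizes = np.asarray(sizes, dtype=np.float64)
    if min_size is not None:
        sizes = sizes[sizes >= min_size]
    if sizes.size < 10:
        raise ValueError("need at least 10 clones to fit")
    if np.ptp(sizes) == 0:
        raise ValueError("degenerate sample: all clone sizes equal")
    n, mom = first_incomplete_moment(sizes)
    keep = mom >= moment_floor
    if keep.sum() < 3:
        keep = mom > 0
    n, logm = n[keep], np.log(mom[keep])
    slope, intercept = np.polyfit(n, logm, 1)
    if slope >= 0:
        raise ValueError("incomplete moment does not decay; no exponential fit")
    resid = logm - (slope * n + intercept)
    ss_tot = np.sum((logm - logm.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2)) / float(ss_tot)
    decay = -1.0 / slope
    return IncompleteMomentFit(
        r_lambda_t=decay,
        n0=float(intercept * decay),
        r_squared=r2,
        n_points=int(n.size),
        fit_range=(float(n[0]), float(n[-1])),
    )


# ---------------------------------------------------------------------------
# Geometric boundary-nucleation model
# ---------------------------------------------------------------------------

@dataclass
class BoundaryModelParams:
    """Geometry of the boundary-nucleation model.

    sigma : cell diameter (length); R : final primary-clone radius (same
    units); gamma : boundary nucleation constant (clones per boundary cell
    per unit time); alpha : radial growth speed of the primary clone.
    """

    sigma: float = 1.0
    R: float = 100.0
    gamma: float = 1.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (self.R > self.sigma > 0):
            raise ValueError("require R > sigma > 0")
        if self.gamma <= 0 or self.alpha <= 0:
            raise ValueError("gamma and alpha must be positive")


def boundary_M(A, params: BoundaryModelParams):
    """Density of secondary clones of area A under boundary nucleation.

    |M(A)| with
    M(A) = (2πγ/σ)(1/α)(√((A/σ)² + R²) − A/σ)(A/(σ²√((A/σ)² + R²)) − 1/σ).
    The printed expression is negative (area decreases with nucleation
    radius); the magnitude is the clone-count density.  Tends to
    (2πγ/α)·σR⁴/(4A³) for large A — an inverse-cubic power law.
    """
    A = np.asarray(A, dtype=np.float64)
    if np.any(A <= 0):
        raise ValueError("clone area A must be positive")
    s, R = params.sigma, params.R
    root = np.sqrt((A / s) ** 2 + R**2)
    # algebraically identical to the two-factor product, but stable at
    # large A where (root - A/σ) cancels catastrophically:
    #   root - A/σ = R²/(root + A/σ);  A/(σ²root) - 1/σ = -R²/(σ root (root + A/σ))
    out = (2 * np.pi * params.gamma / params.alpha) * R**4 / (
        s**2 * (root + A / s) ** 2 * root)
    return out if out.ndim else float(out)


def boundary_beta(A, sigma: float = 1.0, R: float = 100.0):
    """Local log-log slope β(A) = d ln|M|/d ln A of the boundary-nucleation density.

    β(A) = −A(A + 2√(A² + σ²R²)) / (A² + σ²R²); β → −3 as A → ∞ and → 0 as
    A → 0⁺, so the density crosses over to an inverse-cubic tail once
    secondary clones are non-negligible relative to the primary clone.
    """
    A = np.asarray(A, dtype=np.float64)
    if np.any(A <= 0):
        raise ValueError("clone area A must be positive")
    s2R2 = sigma**2 * R**2
    out = -A * (A + 2.0 * np.sqrt(A**2 + s2R2)) / (A**2 + s2R2)
    return out if out.ndim else float(out)


def boundary_M_asymptotic(A, params: BoundaryModelParams):
    """Leading-order large-A form (2πγ/α)·σR⁴/(4A³) of |M(A)|."""
    A = np.asarray(A, dtype=np.float64)
    out = (2 * np.pi * params.gamma / params.alpha) * params.sigma * params.R**4 / (4 * A**3)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Exponential-growth model
# ---------------------------------------------------------------------------

@dataclass
class ExpModelParams:
    """Exponential-growth clone model.

    b : exponential growth rate (per unit time); T : observation time;
    gamma : nucleation constant (secondary clones per unit primary area per
    unit time); sigma : cell diameter.  ``a`` is the area of a newly
    nucleated clone, π(σ/2)².
    """

    b: float = 0.1
    T: float = 100.0
    gamma: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.b <= 0 or self.T <= 0:
            raise ValueError("b and T must be positive")

    @property
    def a(self) -> float:
        return np.pi * (self.sigma / 2.0) ** 2

    @property
    def A_max(self) -> float:
        return self.a * np.exp(self.b * self.T)


def exponential_M(A, params: ExpModelParams):
    """Density of secondary-clone areas under transient exponential growth.

    |M(A)| = γ a π σ² e^{bT} / (4 b A²): an exact inverse-square power law
    over the support (a, a·e^{bT}).
    """
    A = np.asarray(A, dtype=np.float64)
    lo, hi = params.a, params.A_max
    if np.any((A <= lo) | (A >= hi)):
        raise ValueError(f"A outside the model support ({lo:.4g}, {hi:.4g})")
    out = (
        params.gamma * params.a * np.pi * params.sigma**2 * np.exp(params.b * params.T)
    ) / (4.0 * A) / (params.b * A)
    return out if out.ndim else float(out)


def exp_clone_area(t, params: ExpModelParams):
    """Final area of a secondary clone nucleated at time t: π(σ/2)² e^{b(T−t)}."""
    t = np.asarray(t, dtype=np.float64)
    out = params.a * np.exp(params.b * (params.T - t))
    return out if out.ndim else float(out)


def exp_nucleation_time(A, params: ExpModelParams):
    """Nucleation time of a secondary clone observed at area A: T − (1/b)ln(4A/(πσ²))."""
    A = np.asarray(A, dtype=np.float64)
    out = params.T - np.log(4.0 * A / (np.pi * params.sigma**2)) / params.b
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Power-law fitting
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    """Least-squares power-law fit on log-binned clone sizes."""

    exponent: float
    intercept: float
    fit_range: tuple[float, float]
    n_clones: int
    # sum of squared log-residuals of the best fit and of fits with the
    # slope fixed at -2 (exponential growth) and -3 (boundary nucleation)
    rss: float = field(default=np.nan)
    rss_slope_m2: float = field(default=np.nan)
    rss_slope_m3: float = field(default=np.nan)


def fit_power_law(sizes, fit_range: tuple[float, float] | None = None,
                  n_bins: int = 20) -> PowerLawFit:
    """Fit a power law to empirical clone sizes on a log-log scale.

    The empirical density is estimated on logarithmically spaced bins and
    the exponent is the least-squares slope of log density against log
    size.  Residual sums of squares for intercept-only fits at the fixed
    slopes −2 and −3 are reported for model comparison.
    """
    sizes = np.asarray(sizes, dtype=np.float64)
    if fit_range is not None:
        sizes = sizes[(sizes >= fit_range[0]) & (sizes <= fit_range[1])]
    if sizes.size < 20:
        raise ValueError("need at least 20 clones in the fit range")
    lo, hi = sizes.min(), sizes.max()
    if lo <= 0:
        raise ValueError("clone sizes must be positive")
    if lo == hi:
        raise ValueError("degenerate sample: all clone sizes equal")
    edges = np.geomspace(lo, hi * (1 + 1e-12), n_bins + 1)
    counts, _ = np.histogram(sizes, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        raise ValueError("too few populated bins for a power-law fit")
    x = np.log(centers[keep])
    y = np.log(counts[keep] / (widths[keep] * sizes.size))
    slope, intercept = np.polyfit(x, y, 1)
    rss = float(np.sum((y - (slope * x + intercept)) ** 2))

    def _rss_fixed(s: float) -> float:
        c = np.mean(y - s * x)
        return float(np.sum((y - (s * x + c)) ** 2))

    return PowerLawFit(
        exponent=float(slope),
        intercept=float(intercept),
        fit_range=(float(lo), float(hi)),
        n_clones=int(sizes.size),
        rss=rss,
        rss_slope_m2=_rss_fixed(-2.0),
        rss_slope_m3=_rss_fixed(-3.0),
    )


# ---------------------------------------------------------------------------
# VAF / cell-count conversion
# ---------------------------------------------------------------------------

def vaf_to_cells(vaf: float, area_mm2: float, linear_density: float = 100.0
                 ) -> tuple[float, float]:
    """Convert a variant allele fraction to a clone cell count and area.

    Assumes a heterozygous diploid clone (cell fraction = 2·VAF) in a biopsy
    of ``area_mm2`` with ``linear_density`` basal progenitors per mm, i.e.
    linear_density² cells per mm².  Returns (cells, clone area in mm²).
    """
    if not 0 < vaf <= 0.5:
        raise ValueError("VAF must lie in (0, 0.5] for a heterozygous diploid clone")
    if area_mm2 <= 0 or linear_density <= 0:
        raise ValueError("area and density must be positive")
    frac = 2.0 * vaf
    cells = frac * linear_density**2 * area_mm2
    return cells, frac * area_mm2
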