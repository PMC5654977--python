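"""Synthetic data generators emulating a deep-sequencing clone study.

Everything downstream of read alignment can be exercised without any real
data: strand-specific allele-count panels with beta-binomial background
noise and spiked subclonal variants (emulating a 10-patient panel of
epidermal samples with matched salivary controls at ~1000× coverage, 500×
per strand), clone-size samples drawn from the closed-form model
distributions, and UV-spectrum mutation tables.

All generators are deterministic given their seed and config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import clonestats
from .caller import ALLELES, CountMatrix

_BASES = ("A", "C", "G", "T")

# The 12 substitution classes on the coding strand.
SUBSTITUTION_CLASSES = tuple(f"{r}>{a}" for r in _BASES for a in _BASES if r != a)

#: Default spectrum for UV-exposed skin: strongly C>T-weighted with a minor
#: CC>TT-driven excess at dipyrimidines (fixture values, not measurements).
UV_SPECTRUM = {
    "C>T": 0.65, "C>A": 0.05, "C>G": 0.03,
    "T>C": 0.10, "T>A": 0.04, "T>G": 0.03,
    "G>A": 0.05, "G>T": 0.02, "G>C": 0.01,
    "A>G": 0.01, "A>T": 0.005, "A>C": 0.005,
}


# ---------------------------------------------------------------------------
# Count matrices with spiked subclones
# ---------------------------------------------------------------------------

@dataclass
class Spike:
    """A spiked subclonal variant: sample index, site index, alt allele, VAF.

    ``alt=None`` lets the generator pick a random non-reference base once
    the reference sequence has been drawn.
    """

    sample: int
    site: int
    alt: str | None
    vaf: float


@dataclass
class SpikeConfig:
    """Generator settings for strand-specific count panels.

    Depths are Poisson around ``depth_per_strand`` per strand (1000× total
    at the 500 default).  Per-site per-alternate mean error fractions are
    drawn log-uniformly over ``error_range`` — spanning clean sites and
    noisy ones — and background alternate counts are beta-binomial with a
    single overdispersion ``rho_true``.  Spikes add binomially sampled
    variant reads symmetrically on both strands (genuine mutations are
    present equally on both strands); ``strand_bias`` places them on the
    forward strand only, emulating a PCR artefact.
    """

    n_controls: int = 10
    n_samples: int = 1
    n_sites: int = 500
    depth_per_strand: float = 500.0
    rho_true: float = 1e-3
    error_range: tuple[float, float] = (1e-5, 10**-2.5)
    spikes: list[Spike] = field(default_factory=list)
    strand_bias: bool = False
    position_spacing: int = 11  # bases between consecutive sites

    def __post_init__(self) -> None:
        if self.depth_per_strand < 1:
            raise ValueError("depth must be >= 1")
        for s in self.spikes:
            if not 0 <= s.site < self.n_sites:
                raise ValueError(f"spike site {s.site} out of range")
            if not 0 < s.vaf <= 0.5:
                raise ValueError("spike VAF must lie in (0, 0.5]")
            if s.alt is not None and s.alt not in ALLELES:
                raise ValueError(f"unknown alternate allele {s.alt!r}")
            if not 0 <= s.sample < self.n_samples:
                raise ValueError(f"spike sample {s.sample} out of range")


def _background_matrix(names, cfg: SpikeConfig, refs: np.ndarray,
                       v_true: np.ndarray, positions: pd.DataFrame,
                       rng: np.random.Generator) -> CountMatrix:
    S, P = len(names), cfg.n_sites
    cov = rng.poisson(cfg.depth_per_strand, size=(S, P, 2)).astype(np.int64)
    cov = np.maximum(cov, 1)
    counts = np.zeros((S, P, len(ALLELES), 2), dtype=np.int64)
    a = v_true * (1 - cfg.rho_true) / cfg.rho_true
    b = (1 - v_true) * (1 - cfg.rho_true) / cfg.rho_true
    for k in range(len(ALLELES)):
        alt = refs != k
        if not alt.any():
            continue
        n = cov[:, alt, :]
        aa = np.broadcast_to(a[alt, k][None, :, None], n.shape)
        bb = np.broadcast_to(b[alt, k][None, :, None], n.shape)
        counts[:, alt, k, :] = stats.betabinom.rvs(n, aa, bb, random_state=rng)
    # cap pathological draws so alternates never exceed coverage
    excess = counts.sum(axis=2) - cov
    if np.any(excess > 0):
        k_max = np.argmax(counts, axis=2)
        idx = np.nonzero(excess > 0)
        counts[idx[0], idx[1], k_max[idx], idx[2]] -= excess[idx]
    # reference reads take up the remaining coverage
    rest = cov - counts.sum(axis=2)
    counts[:, np.arange(P), refs, :] = rest
    return CountMatrix(samples=list(names), positions=positions,
                       counts=counts, coverage=cov)


def simulate_counts(cfg: SpikeConfig, seed: int = 0
                    ) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Generate (sample matrix, control matrix, spike truth table).

    The truth table has one row per spike with columns
    sample (index), site (index), chrom, pos, alt, vaf.
    """
    rng = np.random.default_rng(seed)
    P = cfg.n_sites
    refs = rng.integers(0, 4, size=P)
    positions = pd.DataFrame({
        "chrom": "chr1",
        "pos": 1 + cfg.position_spacing * np.arange(P),
        "ref": [ALLELES[r] for r in refs],
    })
    lo, hi = np.log(cfg.error_range[0]), np.log(cfg.error_range[1])
    v_true = np.exp(rng.uniform(lo, hi, size=(P, len(ALLELES))))
    v_true[np.arange(P), refs] = 0.0

    controls = _background_matrix([f"C{i}" for i in range(cfg.n_controls)],
                                  cfg, refs, v_true, positions, rng)
    samples = _background_matrix([f"S{i}" for i in range(cfg.n_samples)],
                                 cfg, refs, v_true, positions, rng)

    truth_rows = []
    for sp in cfg.spikes:
        alt = sp.alt
        if alt is None:
            choices = [b for i, b in enumerate(ALLELES[:4]) if i != refs[sp.site]]
            alt = choices[rng.integers(len(choices))]
        k = ALLELES.index(alt)
        if k == refs[sp.site]:
            raise ValueError(f"spike at site {sp.site} matches the reference "
                             f"base {alt}; pick a different site or allele")
        for strand in (0, 1):
            vaf = sp.vaf * (2 if cfg.strand_bias else 1)
            if cfg.strand_bias and strand == 1:
                vaf = 0.0
            depth = samples.coverage[sp.sample, sp.site, strand]
            extra = rng.binomial(depth, min(vaf, 1.0))
            ref_k = refs[sp.site]
            extra = min(extra, samples.counts[sp.sample, sp.site, ref_k, strand])
            samples.counts[sp.sample, sp.site, k, strand] += extra
            samples.counts[sp.sample, sp.site, ref_k, strand] -= extra
        truth_rows.append({"sample": sp.sample, "site": sp.site,
                           "chrom": "chr1",
                           "pos": int(positions["pos"].iloc[sp.site]),
                           "alt": alt, "vaf": sp.vaf})
    truth = pd.DataFrame(truth_rows,
                         columns=["sample", "site", "chrom", "pos", "alt", "vaf"])
    return samples, controls, truth


# ---------------------------------------------------------------------------
# Clone-size samples from the model distributions
# ---------------------------------------------------------------------------

@dataclass
class CloneSampleConfig:
    """Settings for drawing clone sizes from a model distribution.

    model: 'neutral' (P_n ∝ e^{-n/rλt}/n on 1..N), 'boundary_cubic'
    (geometric boundary-nucleation density, inverse-cubic tail),
    'exponential_square' (exact inverse-square density), or
    'custom_powerlaw' (density ∝ x^exponent on [x_min, x_max]).
    ``params`` are forwarded to the model.
    """

    model: str = "neutral"
    n_clones: int = 1000
    detect_vaf: float = 0.007
    total_cells: int = 160_000
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")


def _inverse_cdf_sample(grid: np.ndarray, density: np.ndarray, size: int,
                        rng: np.random.Generator) -> np.ndarray:
    cdf = np.cumsum(density)
    cdf /= cdf[-1]
    u = rng.random(size)
    return grid[np.searchsorted(cdf, u)]


def sample_clone_sizes(cfg: CloneSampleConfig, seed: int = 0):
    """Draw a clone-size sample from the chosen model distribution.

    Returns (:class:`epiclone.lattice.CloneSizeSample`, ground-truth param
    dict).  Sizes are in cells for the neutral model and in area units for
    the geometric models.
    """
    from .lattice import CloneSizeSample  # avoid import cycle

    rng = np.random.default_rng(seed)
    p = dict(cfg.params)
    if cfg.model == "neutral":
        rlt = p.setdefault("r_lambda_t", 500.0)
        N = int(p.setdefault("N", cfg.total_cells))
        n = np.arange(1, N + 1, dtype=np.float64)
        dens = np.exp(-n / rlt) / n
        sizes = _inverse_cdf_sample(n, dens, cfg.n_clones, rng)
    elif cfg.model == "boundary_cubic":
        bp = clonestats.BoundaryModelParams(
            sigma=p.setdefault("sigma", 1.0), R=p.setdefault("R", 100.0),
            gamma=p.setdefault("gamma", 1.0), alpha=p.setdefault("alpha", 1.0))
        lo = p.setdefault("A_min", bp.sigma**2)
        hi = p.setdefault("A_max", bp.sigma * bp.R**2 / 2 * 0.999)
        grid = np.geomspace(lo, hi, 4096)
        dens = clonestats.boundary_M(grid, bp) * grid  # log-spaced grid: dA ∝ A
        sizes = _inverse_cdf_sample(grid, dens, cfg.n_clones, rng)
    elif cfg.model == "exponential_square":
        ep = clonestats.ExpModelParams(
            b=p.setdefault("b", 0.1), T=p.setdefault("T", 100.0),
            gamma=p.setdefault("gamma", 1.0), sigma=p.setdefault("sigma", 1.0))
        lo, hi = ep.a * (1 + 1e-9), ep.A_max * (1 - 1e-9)
        u = rng.random(cfg.n_clones)
        sizes = 1.0 / (1.0 / lo - u * (1.0 / lo - 1.0 / hi))  # analytic A^-2 inverse CDF
    elif cfg.model == "custom_powerlaw":
        expo = p.setdefault("exponent", -3.0)
        lo = p.setdefault("x_min", 1.0)
        hi = p.setdefault("x_max", 1e4)
        u = rng.random(cfg.n_clones)
        if expo == -1.0:
            sizes = lo * (hi / lo) ** u
        else:
            g = expo + 1.0
            sizes = (lo**g + u * (hi**g - lo**g)) ** (1.0 / g)
    else:
        raise ValueError(f"unsupported clone-size model {cfg.model!r}")
    total = max(int(cfg.total_cells), int(np.ceil(sizes.max())))
    return CloneSizeSample(sizes, total, cfg.detect_vaf), p


# ---------------------------------------------------------------------------
# UV mutation spectra
# ---------------------------------------------------------------------------

def uv_spectrum_assign(n_mutations: int, spectrum: dict[str, float] | None = None,
                       seed: int = 0, with_context: bool = True) -> pd.DataFrame:
    """Assign substitution classes to ``n_mutations`` mutations.

    ``spectrum`` is a probability vector over the 12 substitution classes
    (default: the C>T-dominated UV fixture spectrum).  Returns a mutation
    table with ref, alt, class and (optionally) a random trinucleotide
    context whose central base matches the reference.
    """
    spectrum = dict(UV_SPECTRUM if spectrum is None else spectrum)
    unknown = set(spectrum) - set(SUBSTITUTION_CLASSES)
    if unknown:
        raise ValueError(f"unknown substitution classes: {sorted(unknown)}")
    classes = list(spectrum)
    probs = np.array([spectrum[c] for c in classes], dtype=np.float64)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-8):
        raise ValueError("spectrum must be a probability vector summing to 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(classes), size=n_mutations, p=probs / probs.sum())
    cls = np.array(classes)[draws]
    refs = np.array([c[0] for c in cls])
    alts = np.array([c[2] for c in cls])
    table = pd.DataFrame({"ref": refs, "alt": alts, "class": cls})
    if with_context:
        flank5 = rng.choice(_BASES, size=n_mutations)
        flank3 = rng.choice(_BASES, size=n_mutations)
        table["context"] = [f"{a}{r}{b}" for a, r, b in zip(flank5, refs, flank3)]
    return table
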