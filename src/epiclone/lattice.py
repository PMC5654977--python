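"""Stochastic simulator of stem-cell clonal dynamics on a hexagonal lattice.

The basal layer of the epidermis is modelled as a two-dimensional hexagonal
lattice in which each site holds a wild-type stem cell (A), a mutant stem
cell with a competitive advantage (B), a transit-amplifying cell (C), or is
empty.  Stem cells are stochastically lost (A at rate λ, B at rate φ < λ
when advantaged) and vacancies are refilled by the division of a uniformly
chosen occupied stem neighbour — a death-first voter model.  Neutral
mutations (rate ω) relabel a cell and its descendants; non-neutral
mutations (rate θ) convert A to B.  Cells may additionally migrate by
swapping with neighbours (rate κ), and a heterogeneous mode adds stem/TA
compartmentalisation: stem cells differentiate to TA cells at rate ν
outside designated stem clusters, TA cells divide into vacancies for at
most q_max rounds, and migration is gated on a lattice energy that keeps
stem and TA cells spatially sorted.

Coordinates use "odd-row offset" indexing on a rectangular array: odd rows
are displaced half a cell to the right, so each interior site has six
neighbours.  The default boundary is toroidal (requires an even height so
row parity matches across the wrap); a non-wrapping mode is available.

Time advances in quantised 1-day steps; weekly rates are converted to daily
probabilities by rate/7, valid since all rates·dt ≪ 1.  All transitions
initiate and complete within a single step, in a fixed order: losses,
vacancy refills, mutations, differentiation/TA division, migration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from ._kernels import EMPTY, STEM_A, STEM_B, TA_C

__all__ = [
    "EMPTY", "STEM_A", "STEM_B", "TA_C",
    "SimParams", "LatticeState", "CloneTree", "CloneSizeSample", "RunResult",
    "neighbors", "build_neighbor_table", "make_cluster_diff_map",
    "lattice_energy", "total_lattice_energy",
    "step_homogeneous", "step_heterogeneous", "migrate",
    "initial_state", "run", "clone_sizes", "years_to_days",
]

DAYS_PER_WEEK = 7.0
MUT_ROOT, MUT_NEUTRAL, MUT_NON_NEUTRAL = 0, 1, 2
MUTATION_CLASS_NAMES = {MUT_ROOT: "root", MUT_NEUTRAL: "neutral",
                        MUT_NON_NEUTRAL: "non_neutral"}


def years_to_days(years: float) -> int:
    return int(round(years * 365.25))


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Simulation parameters.

    Rates follow the units in which they are usually quoted: loss rates λ
    and φ per cell per *week* (λ estimated at 0.5/week in human
    interfollicular epidermis), mutation rates ω and θ per cell per *day*,
    migration κ and differentiation ν per day.  ``dt`` is 1 day.
    """

    width: int = 200
    height: int = 200
    lam: float = 0.5           # stem loss/replacement, per cell per week
    omega: float = 1e-3        # neutral mutation, per cell per day
    theta: float = 0.0         # non-neutral mutation, per cell per day
    phi: float = 0.5           # mutant (B) loss, per cell per week; phi<lam = advantage
    kappa: float = 0.0         # migration swap, per adjacent pair per day
    nu: float = 0.0            # stem->TA differentiation, per cell per day, where diff=1
    q_max: int = 4             # max TA division rounds
    ta_div_rate: float | None = None   # per day; default lam/7
    ta_loss_rate: float | None = None  # per day; default lam/7
    cluster_radius: float = 20.0
    cluster_spacing: float = 70.0
    penalty_p: float = 100.0
    dt: float = 1.0            # days
    duration: int = 365        # days
    seed: int = 0
    boundary: str = "torus"    # or "fixed"
    detect_vaf: float = 0.007
    init_empty_frac: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lam", "omega", "theta", "phi", "kappa", "nu"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be non-negative")
        if self.boundary not in ("torus", "fixed"):
            raise ValueError("boundary must be 'torus' or 'fixed'")
        if self.boundary == "torus" and self.height % 2:
            raise ValueError("toroidal boundary requires an even height "
                             "(row parity must match across the wrap)")
        if self.nu > 0 and self.cluster_radius >= min(self.width, self.height) / 2:
            raise ValueError("cluster_radius must be < min(width, height)/2")
        if self.ta_div_rate is None:
            self.ta_div_rate = self.lam / DAYS_PER_WEEK
        if self.ta_loss_rate is None:
            self.ta_loss_rate = self.lam / DAYS_PER_WEEK

    # daily probabilities
    @property
    def p_loss_a(self) -> float:
        return self.lam * self.dt / DAYS_PER_WEEK

    @property
    def p_loss_b(self) -> float:
        return self.phi * self.dt / DAYS_PER_WEEK

    @property
    def p_loss_c(self) -> float:
        return self.ta_loss_rate * self.dt

    @property
    def p_omega(self) -> float:
        return self.omega * self.dt

    @property
    def p_theta(self) -> float:
        return self.theta * self.dt

    @property
    def p_kappa(self) -> float:
        return self.kappa * self.dt

    @property
    def p_nu(self) -> float:
        return self.nu * self.dt

    @property
    def p_ta_div(self) -> float:
        return self.ta_div_rate * self.dt


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

_OFFSETS_EVEN = {  # odd-row offset scheme, even rows
    "E": (1, 0), "SE": (0, 1), "SW": (-1, 1),
    "W": (-1, 0), "NE": (0, -1), "NW": (-1, -1),
}
_OFFSETS_ODD = {
    "E": (1, 0), "SE": (1, 1), "SW": (0, 1),
    "W": (-1, 0), "NE": (1, -1), "NW": (0, -1),
}
_DIRECTIONS = ("E", "SE", "SW", "W", "NE", "NW")  # first 3 = forward edges


def neighbors(site: tuple[int, int], dims: tuple[int, int],
              boundary: str = "torus") -> set[tuple[int, int]]:
    """Hexagonal neighbourhood of a site (odd-row offset coordinates).

    Returns up to 6 sites; on a torus always exactly 6.  Symmetric:
    j ∈ N(i) iff i ∈ N(j).
    """
    x, y = site
    w, h = dims
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"site {site} outside lattice {dims}")
    offs = _OFFSETS_ODD if y % 2 else _OFFSETS_EVEN
    out = set()
    for dx, dy in offs.values():
        nx, ny = x + dx, y + dy
        if boundary == "torus":
            out.add((nx % w, ny % h))
        elif 0 <= nx < w and 0 <= ny < h:
            out.add((nx, ny))
    return out


def build_neighbor_table(width: int, height: int, boundary: str = "torus") -> np.ndarray:
    """Flat neighbour table (n_sites, 6) with -1 for absent neighbours.

    Column order [E, SE, SW, W, NE, NW]; the first three columns list each
    undirected edge exactly once.
    """
    ys, xs = np.divmod(np.arange(width * height), width)
    nbr = np.full((width * height, 6), -1, dtype=np.int64)
    for col, d in enumerate(_DIRECTIONS):
        dx = np.where(ys % 2, _OFFSETS_ODD[d][0], _OFFSETS_EVEN[d][0])
        dy = np.where(ys % 2, _OFFSETS_ODD[d][1], _OFFSETS_EVEN[d][1])
        nx, ny = xs + dx, ys + dy
        if boundary == "torus":
            nbr[:, col] = (ny % height) * width + (nx % width)
        else:
            ok = (nx >= 0) & (nx < width) & (ny >= 0) & (ny < height)
            nbr[ok, col] = ny[ok] * width + nx[ok]
    return nbr


def make_cluster_diff_map(width: int, height: int, cluster_radius: float,
                          cluster_spacing: float, boundary: str = "torus") -> np.ndarray:
    """Binary differentiation map: 0 inside circular stem clusters, 1 outside.

    Cluster centres sit on a triangular grid of pitch ``cluster_spacing``
    (in cell diameters); distances are measured in the cartesian embedding
    of the offset coordinates, with wrap-around on a torus.
    """
    ys, xs = np.divmod(np.arange(width * height), width)
    cx = xs + 0.5 * (ys % 2)
    cy = ys * (np.sqrt(3.0) / 2.0)
    w_cart, h_cart = float(width), height * np.sqrt(3.0) / 2.0
    row_pitch = cluster_spacing * np.sqrt(3.0) / 2.0
    diff = np.ones(width * height, dtype=np.uint8)
    n_rows = max(1, int(np.ceil(h_cart / row_pitch)))
    n_cols = max(1, int(np.ceil(w_cart / cluster_spacing)))
    for i in range(n_rows):
        for j in range(n_cols):
            ccx = (j + 0.5 * (i % 2)) * cluster_spacing
            ccy = i * row_pitch
            dx = np.abs(cx - ccx)
            dy = np.abs(cy - ccy)
            if boundary == "torus":
                dx = np.minimum(dx, w_cart - dx)
                dy = np.minimum(dy, h_cart - dy)
            diff[dx * dx + dy * dy <= cluster_radius**2] = 0
    return diff


# ---------------------------------------------------------------------------
# State and clone tree
# ---------------------------------------------------------------------------

@dataclass
class LatticeState:
    """Occupancy of the lattice: per-site cell kind, clone label and TA division count."""

    width: int
    height: int
    boundary: str
    kind: np.ndarray   # int8, 0 empty / 1 A / 2 B / 3 C
    label: np.ndarray  # int64 clone label, -1 on empty sites
    q: np.ndarray      # int16 TA divisions completed
    time: float = 0.0  # days elapsed
    nbr: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.nbr is None:
            self.nbr = build_neighbor_table(self.width, self.height, self.boundary)

    @property
    def n_sites(self) -> int:
        return self.width * self.height

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.kind))

    def copy(self) -> "LatticeState":
        return replace(self, kind=self.kind.copy(), label=self.label.copy(),
                       q=self.q.copy(), nbr=self.nbr)

    def grid(self, what: str = "label") -> np.ndarray:
        """2-D view (height, width) of labels or kinds, for snapshots."""
        arr = self.label if what == "label" else self.kind
        return arr.reshape(self.height, self.width)


class CloneTree:
    """Forest of clone records rooted at label 0.

    Every mutation event creates a fresh label whose parent is the label it
    arose in, so the clonal history is a tree and the *recursive* size of a
    clone (its own cells plus all descendant cells) is the number of cells
    carrying that mutation.  Labels are assigned in birth order, which
    guarantees children follow parents and allows recursive sizes to be
    computed in one reverse pass.

    Live cell counts are derived from the lattice on demand rather than
    stored, so the tree holds only (parent, birth_day, mutation_class) per
    record.  :meth:`purge` drops records whose whole subtree is extinct.
    """

    def __init__(self) -> None:
        cap = 1024
        self._ids = np.empty(cap, np.int64)
        self._parent = np.empty(cap, np.int64)
        self._birth = np.empty(cap, np.float64)
        self._mclass = np.empty(cap, np.int8)
        self._n = 1
        self._ids[0], self._parent[0], self._birth[0], self._mclass[0] = 0, -1, 0.0, MUT_ROOT
        self._next_id = 1

    def __len__(self) -> int:
        return self._n

    @property
    def ids(self) -> np.ndarray:
        return self._ids[: self._n]

    @property
    def parent(self) -> np.ndarray:
        return self._parent[: self._n]

    @property
    def birth_day(self) -> np.ndarray:
        return self._birth[: self._n]

    @property
    def mutation_class(self) -> np.ndarray:
        return self._mclass[: self._n]

    def _grow(self, extra: int) -> None:
        need = self._n + extra
        if need <= self._ids.shape[0]:
            return
        cap = max(need, 2 * self._ids.shape[0])
        for name in ("_ids", "_parent", "_birth", "_mclass"):
            old = getattr(self, name)
            new = np.empty(cap, old.dtype)
            new[: self._n] = old[: self._n]
            setattr(self, name, new)

    def add_batch(self, parents: np.ndarray, day: float, classes: np.ndarray) -> np.ndarray:
        """Register mutation events; returns the fresh labels (birth order)."""
        k = len(parents)
        if k == 0:
            return np.empty(0, np.int64)
        self._grow(k)
        new_ids = np.arange(self._next_id, self._next_id + k, dtype=np.int64)
        sl = slice(self._n, self._n + k)
        self._ids[sl] = new_ids
        self._parent[sl] = parents
        self._birth[sl] = day
        self._mclass[sl] = classes
        self._n += k
        self._next_id += k
        return new_ids

    def rows_of(self, labels: np.ndarray) -> np.ndarray:
        rows = np.searchsorted(self.ids, labels)
        bad = (rows >= self._n) | (self.ids[np.minimum(rows, self._n - 1)] != labels)
        if np.any(bad):
            raise KeyError(f"unknown clone label(s): {np.asarray(labels)[bad][:5]}")
        return rows

    def live_counts(self, state: LatticeState) -> np.ndarray:
        """Cells on the lattice carrying each label as their *current* label."""
        labels = state.label[state.kind != EMPTY]
        rows = self.rows_of(labels)
        return np.bincount(rows, minlength=self._n).astype(np.int64)

    def recursive_sizes(self, state: LatticeState) -> np.ndarray:
        """Per-record clone size: own live cells plus all descendants'."""
        totals = self.live_counts(state)
        parent_rows = np.full(self._n, -1, np.int64)
        nonroot = self.parent >= 0
        parent_rows[nonroot] = self.rows_of(self.parent[nonroot])
        _kernels.accumulate_up(totals, parent_rows)
        return totals

    def purge(self, state: LatticeState) -> int:
        """Drop records whose clone and all descendants are extinct.

        Observationally silent: any label still on the lattice has a
        positive recursive size, as do all its ancestors, so surviving
        clones keep their records and labels.  Returns #records removed.
        """
        totals = self.recursive_sizes(state)
        keep = totals > 0
        keep[0] = True
        removed = int(self._n - keep.sum())
        if removed:
            for name in ("_ids", "_parent", "_birth", "_mclass"):
                arr = getattr(self, name)
                arr[: keep.sum()] = arr[: self._n][keep]
            self._n = int(keep.sum())
        return removed


@dataclass
class CloneSizeSample:
    """Sample of clone sizes with the sequencing detection threshold.

    ``sizes`` are recursive clone sizes in cells; VAF assumes heterozygous
    diploid clones: VAF = (size / total_cells) / 2.
    """

    sizes: np.ndarray
    total_cells: int
    detect_vaf: float = 0.007

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.float64)
        if self.sizes.size and (self.sizes.min() <= 0 or self.sizes.max() > self.total_cells):
            raise ValueError("clone sizes must lie in (0, total_cells]")

    @property
    def vaf(self) -> np.ndarray:
        return self.sizes / self.total_cells / 2.0

    def detectable(self) -> "CloneSizeSample":
        """Restrict to clones above the sequencing detection threshold."""
        keep = self.vaf > self.detect_vaf
        return CloneSizeSample(self.sizes[keep], self.total_cells, self.detect_vaf)

    def __len__(self) -> int:
        return int(self.sizes.size)


# ---------------------------------------------------------------------------
# Energy (reference implementation; kernels mirror this)
# ---------------------------------------------------------------------------

def lattice_energy(site: int, state: LatticeState, diff_map: np.ndarray,
                   penalty_p: float) -> float:
    """Lattice energy E(i) of an occupied site.

    Stem occupant (A/B): |TA neighbours| + diff(i)·p.
    TA occupant: |stem neighbours| − |empty neighbours| + (1 − diff(i))·p.
    """
    if state.kind[site] == EMPTY:
        raise ValueError("energy undefined for an empty site")
    return float(_kernels.site_energy(site, state.kind, state.nbr,
                                      diff_map, penalty_p))


def total_lattice_energy(state: LatticeState, diff_map: np.ndarray,
                         penalty_p: float) -> float:
    return float(_kernels.total_energy(state.kind, state.nbr, diff_map, penalty_p))


# ---------------------------------------------------------------------------
# Stepping
# ---------------------------------------------------------------------------

def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def _apply_mutations(state: LatticeState, tree: CloneTree,
                     ev_site: np.ndarray, ev_code: np.ndarray, nev: int) -> None:
    if nev == 0:
        return
    sites = ev_site[:nev]
    codes = ev_code[:nev]
    parents = state.label[sites].copy()
    classes = np.where(codes == 2, MUT_NON_NEUTRAL, MUT_NEUTRAL).astype(np.int8)
    new_ids = tree.add_batch(parents, state.time, classes)
    state.label[sites] = new_ids
    state.kind[sites[codes == 2]] = STEM_B


def step_homogeneous(state: LatticeState, tree: CloneTree, params: SimParams,
                     rng: np.random.Generator,
                     _buffers: tuple[np.ndarray, np.ndarray] | None = None
                     ) -> tuple[LatticeState, CloneTree]:
    """Advance one day in the homogeneous (stem-only) compartment.

    Order within the day: simultaneous losses, vacancy refills in random
    order, mutations, migration.
    """
    if _buffers is None:
        _buffers = (np.empty(state.n_sites, np.int64), np.empty(state.n_sites, np.int8))
    ev_site, ev_code = _buffers
    nev = _kernels.step_losses_fill_mutscan(
        state.kind, state.label, state.q, state.nbr,
        params.p_loss_a, params.p_loss_b, 1.0,  # C cells absent in this mode
        params.p_omega, params.p_theta,
        ev_site, ev_code, _kernel_seed(rng))
    state.time += params.dt
    _apply_mutations(state, tree, ev_site, ev_code, nev)
    if params.p_kappa > 0:
        _kernels.migrate_pairs(state.kind, state.label, state.q, state.nbr,
                               params.p_kappa, _kernel_seed(rng))
    return state, tree


def step_heterogeneous(state: LatticeState, tree: CloneTree, params: SimParams,
                       diff_map: np.ndarray, rng: np.random.Generator,
                       _buffers: tuple[np.ndarray, np.ndarray] | None = None
                       ) -> tuple[LatticeState, CloneTree]:
    """Advance one day in the heterogeneous stem/TA compartment.

    As :func:`step_homogeneous`, plus stem→TA differentiation at rate ν
    where diff(i)=1, TA division into vacancies (≤ q_max rounds, both
    daughters carry q+1), TA loss, and energy-gated migration.  With ν=0,
    no TA cells and κ=0 this reduces exactly to the homogeneous step.
    """
    if _buffers is None:
        _buffers = (np.empty(state.n_sites, np.int64), np.empty(state.n_sites, np.int8))
    ev_site, ev_code = _buffers
    nev = _kernels.step_losses_fill_mutscan(
        state.kind, state.label, state.q, state.nbr,
        params.p_loss_a, params.p_loss_b, params.p_loss_c,
        params.p_omega, params.p_theta,
        ev_site, ev_code, _kernel_seed(rng))
    state.time += params.dt
    _apply_mutations(state, tree, ev_site, ev_code, nev)
    if params.p_nu > 0 or np.any(state.kind == TA_C):
        _kernels.step_ta(state.kind, state.label, state.q, state.nbr, diff_map,
                         params.p_nu, params.p_ta_div, params.q_max,
                         _kernel_seed(rng))
    if params.p_kappa > 0:
        _kernels.migrate_energy_gated(state.kind, state.label, state.q, state.nbr,
                                      diff_map, params.p_kappa, params.penalty_p,
                                      _kernel_seed(rng))
    return state, tree


def migrate(state: LatticeState, params: SimParams, rng: np.random.Generator,
            diff_map: np.ndarray | None = None) -> LatticeState:
    """Migration step alone: unconditional pair swaps, or energy-gated when
    a differentiation map is supplied (heterogeneous mode)."""
    if params.p_kappa <= 0:
        return state
    if diff_map is None:
        _kernels.migrate_pairs(state.kind, state.label, state.q, state.nbr,
                               params.p_kappa, _kernel_seed(rng))
    else:
        _kernels.migrate_energy_gated(state.kind, state.label, state.q, state.nbr,
                                      diff_map, params.p_kappa, params.penalty_p,
                                      _kernel_seed(rng))
    return state


# ---------------------------------------------------------------------------
# Runs
# ---------------------------------------------------------------------------

def initial_state(params: SimParams, mode: str = "homogeneous",
                  diff_map: np.ndarray | None = None,
                  rng: np.random.Generator | None = None) -> LatticeState:
    """All-A₀ lattice (homogeneous) or stem-in-clusters / TA-outside (heterogeneous)."""
    n = params.width * params.height
    kind = np.full(n, STEM_A, np.int8)
    label = np.zeros(n, np.int64)
    q = np.zeros(n, np.int16)
    if mode == "heterogeneous":
        if diff_map is None:
            raise ValueError("heterogeneous mode requires a differentiation map")
        kind[diff_map == 1] = TA_C
    if params.init_empty_frac > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        empty = rng.random(n) < params.init_empty_frac
        kind[empty] = EMPTY
        label[empty] = -1
    return LatticeState(params.width, params.height, params.boundary,
                        kind, label, q)


@dataclass
class RunResult:
    samples: dict[int, CloneSizeSample]
    state: LatticeState
    tree: CloneTree
    params: SimParams


def clone_sizes(state: LatticeState, tree: CloneTree, label: int | None = None,
                detectable_only: bool = False,
                detect_vaf: float = 0.007) -> CloneSizeSample | int:
    """Recursive clone sizes (a cell counts towards its own clone and every ancestor).

    With ``label`` given, returns that single clone's recursive size (the
    root, label 0, spans every occupied site).  Otherwise returns the
    sample of all *mutant* clones with at least one surviving cell, i.e.
    every record except the unmutated root.
    """
    totals = tree.recursive_sizes(state)
    if label is not None:
        row = int(tree.rows_of(np.asarray([label]))[0])
        return int(totals[row])
    sizes = totals[1:][totals[1:] > 0]
    sample = CloneSizeSample(sizes.astype(np.float64), state.n_occupied, detect_vaf)
    return sample.detectable() if detectable_only else sample


def run(params: SimParams, mode: str = "homogeneous",
        diff_map: np.ndarray | None = None,
        checkpoints: list[int] | None = None,
        purge_interval: int = 30) -> RunResult:
    """Run the simulation for ``params.duration`` days.

    Clone-size samples are recorded at the requested checkpoint days (and
    always at the final day); extinct clone records are purged every
    ``purge_interval`` days.  Reproducible given ``params.seed``.
    """
    if params.duration < 0:
        raise ValueError("duration must be non-negative")
    if mode not in ("homogeneous", "heterogeneous"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "heterogeneous" and diff_map is None:
        diff_map = make_cluster_diff_map(params.width, params.height,
                                         params.cluster_radius,
                                         params.cluster_spacing, params.boundary)
    rng = np.random.default_rng(params.seed)
    state = initial_state(params, mode, diff_map, rng)
    tree = CloneTree()
    checkpoints = sorted(set(checkpoints or []) | {params.duration})
    buffers = (np.empty(state.n_sites, np.int64), np.empty(state.n_sites, np.int8))
    samples: dict[int, CloneSizeSample] = {}
    if 0 in checkpoints:
        samples[0] = clone_sizes(state, tree, detect_vaf=params.detect_vaf)
    for day in range(1, params.duration + 1):
        if mode == "homogeneous":
            step_homogeneous(state, tree, params, rng, buffers)
        else:
            step_heterogeneous(state, tree, params, diff_map, rng, buffers)
        if day % purge_interval == 0:
            tree.purge(state)
        if day in checkpoints:
            samples[day] = clone_sizes(state, tree, detect_vaf=params.detect_vaf)
    return RunResult(samples=samples, state=state, tree=tree, params=params)
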