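"""Numba kernels for the hexagonal-lattice simulator.

All kernels operate on flat site arrays (site index = y*width + x) plus a
precomputed neighbour table ``nbr`` of shape (n_sites, 6) with -1 marking
absent neighbours at non-wrapping boundaries.  Column order of ``nbr`` is
[E, SE, SW, W, NE, NW]; the first three columns enumerate each undirected
lattice edge exactly once and are used as the "forward" directions for
pair-swap migration.

Randomness: each kernel call receives an integer seed drawn from the
caller's generator, so runs are reproducible end to end.

Cell kind codes: 0 empty, 1 wild-type stem (A), 2 mutant stem (B),
3 transit-amplifying (C).
"""

import numpy as np
from numba import njit

EMPTY, STEM_A, STEM_B, TA_C = 0, 1, 2, 3


@njit(cache=True)
def _shuffled_empties(kind):
    n = kind.shape[0]
    vac = np.empty(n, np.int64)
    m = 0
    for s in range(n):
        if kind[s] == EMPTY:
            vac[m] = s
            m += 1
    for i in range(m - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = vac[i]
        vac[i] = vac[j]
        vac[j] = tmp
    return vac[:m]


@njit(cache=True)
def step_losses_fill_mutscan(kind, label, q, nbr,
                             p_loss_a, p_loss_b, p_loss_c,
                             p_omega, p_theta,
                             ev_site, ev_code, seed):
    """Daily losses, vacancy refilling and mutation scan.

    1. Every occupied cell is lost with its kind-specific daily probability
       (simultaneous Bernoulli draws).
    2. Vacancies are visited in uniformly random order; each with at least
       one occupied stem (A/B) neighbour is filled by the division of a
       uniformly chosen such neighbour.
    3. Each occupied cell then draws at most one mutation: neutral with
       probability p_omega (code 1), non-neutral (A only) with probability
       p_theta (code 2).  Events are recorded in ev_site/ev_code; label
       assignment is done by the caller, which owns the clone tree.

    Returns the number of mutation events recorded.
    """
    np.random.seed(seed)
    n = kind.shape[0]
    # 1. simultaneous losses
    for s in range(n):
        k = kind[s]
        if k == STEM_A:
            if np.random.random() < p_loss_a:
                kind[s] = EMPTY
                label[s] = -1
        elif k == STEM_B:
            if np.random.random() < p_loss_b:
                kind[s] = EMPTY
                label[s] = -1
        elif k == TA_C:
            if np.random.random() < p_loss_c:
                kind[s] = EMPTY
                label[s] = -1
                q[s] = 0
    # 2. vacancy fill by stem division, random order, chains allowed
    vac = _shuffled_empties(kind)
    donors = np.empty(6, np.int64)
    for vi in range(vac.shape[0]):
        s = vac[vi]
        nd = 0
        for d in range(6):
            t = nbr[s, d]
            if t >= 0 and (kind[t] == STEM_A or kind[t] == STEM_B):
                donors[nd] = t
                nd += 1
        if nd > 0:
            t = donors[np.random.randint(0, nd)]
            kind[s] = kind[t]
            label[s] = label[t]
            q[s] = 0
    # 3. mutation scan
    nev = 0
    for s in range(n):
        k = kind[s]
        if k == EMPTY:
            continue
        u = np.random.random()
        if u < p_omega:
            ev_site[nev] = s
            ev_code[nev] = 1
            nev += 1
        elif k == STEM_A and u < p_omega + p_theta:
            ev_site[nev] = s
            ev_code[nev] = 2
            nev += 1
    return nev


@njit(cache=True)
def step_ta(kind, label, q, nbr, diff, p_nu, p_tadiv, q_max, seed):
    """Stem→TA differentiation and TA division into vacancies.

    A cells sitting where diff(i)=1 differentiate into TA cells (q=0) with
    daily probability p_nu.  Remaining vacancies are then visited in random
    order: with probability p_tadiv a vacancy with at least one TA
    neighbour that has divisions left (q < q_max) is filled by the division
    of one such neighbour chosen uniformly; both daughters carry q+1.
    B cells never differentiate.
    """
    np.random.seed(seed)
    n = kind.shape[0]
    for s in range(n):
        if kind[s] == STEM_A and diff[s] == 1 and np.random.random() < p_nu:
            kind[s] = TA_C
            q[s] = 0
    vac = _shuffled_empties(kind)
    donors = np.empty(6, np.int64)
    for vi in range(vac.shape[0]):
        s = vac[vi]
        nd = 0
        for d in range(6):
            t = nbr[s, d]
            if t >= 0 and kind[t] == TA_C and q[t] < q_max:
                donors[nd] = t
                nd += 1
        if nd > 0 and np.random.random() < p_tadiv:
            t = donors[np.random.randint(0, nd)]
            qq = q[t] + 1
            q[t] = qq
            kind[s] = TA_C
            label[s] = label[t]
            q[s] = qq
    return 0


@njit(cache=True)
def migrate_pairs(kind, label, q, nbr, p_swap, seed):
    """Unconditional migration: each adjacent pair swaps with probability p_swap."""
    np.random.seed(seed)
    n = kind.shape[0]
    for s in range(n):
        for d in range(3):  # forward directions: each edge once
            t = nbr[s, d]
            if t >= 0 and np.random.random() < p_swap:
                kind[s], kind[t] = kind[t], kind[s]
                label[s], label[t] = label[t], label[s]
                q[s], q[t] = q[t], q[s]
    return 0


@njit(cache=True)
def site_energy(s, kind, nbr, diff, penalty):
    """Lattice energy of an occupied site.

    Stem occupants (A or B): number of TA neighbours + diff(i)·p.
    TA occupants: stem neighbours − empty neighbours + (1−diff(i))·p.
    High energy marks stem cells admixed with TA cells or stranded outside
    stem territory, and TA cells sitting inside a stem cluster.
    """
    k = kind[s]
    n_ta = 0
    n_stem = 0
    n_empty = 0
    for d in range(6):
        t = nbr[s, d]
        if t < 0:
            continue
        kt = kind[t]
        if kt == TA_C:
            n_ta += 1
        elif kt == STEM_A or kt == STEM_B:
            n_stem += 1
        else:
            n_empty += 1
    if k == STEM_A or k == STEM_B:
        return n_ta + diff[s] * penalty
    if k == TA_C:
        return n_stem - n_empty + (1 - diff[s]) * penalty
    return 0.0


@njit(cache=True)
def total_energy(kind, nbr, diff, penalty):
    e = 0.0
    for s in range(kind.shape[0]):
        if kind[s] != EMPTY:
            e += site_energy(s, kind, nbr, diff, penalty)
    return e


@njit(cache=True)
def _local_energy(sites, m, kind, nbr, diff, penalty):
    e = 0.0
    for i in range(m):
        s = sites[i]
        if kind[s] != EMPTY:
            e += site_energy(s, kind, nbr, diff, penalty)
    return e


@njit(cache=True)
def migrate_energy_gated(kind, label, q, nbr, diff, p_swap, penalty, seed):
    """Energy-gated migration: a proposed swap of adjacent contents is
    applied only if it strictly reduces total lattice energy.

    Only the energies of the two swapped sites and their neighbourhoods can
    change, so the gate is evaluated on that local set.
    """
    np.random.seed(seed)
    n = kind.shape[0]
    local = np.empty(14, np.int64)
    for s in range(n):
        for d in range(3):
            t = nbr[s, d]
            if t < 0 or np.random.random() >= p_swap:
                continue
            if kind[s] == kind[t] and label[s] == label[t] and q[s] == q[t]:
                continue  # no-op swap
            # affected sites: s, t and all their neighbours (deduplicated)
            m = 0
            local[m] = s
            m += 1
            local[m] = t
            m += 1
            for dd in range(6):
                for u in (nbr[s, dd], nbr[t, dd]):
                    if u >= 0:
                        seen = False
                        for i in range(m):
                            if local[i] == u:
                                seen = True
                                break
                        if not seen:
                            local[m] = u
                            m += 1
            before = _local_energy(local, m, kind, nbr, diff, penalty)
            kind[s], kind[t] = kind[t], kind[s]
            label[s], label[t] = label[t], label[s]
            q[s], q[t] = q[t], q[s]
            after = _local_energy(local, m, kind, nbr, diff, penalty)
            if after >= before:  # reject: swap back
                kind[s], kind[t] = kind[t], kind[s]
                label[s], label[t] = label[t], label[s]
                q[s], q[t] = q[t], q[s]
    return 0


@njit(cache=True)
def accumulate_up(totals, parent_rows):
    """Push recursive clone sizes up the tree.

    Rows are in creation order (children strictly after parents), so a
    single descending pass adds each subtree total onto its parent.
    """
    for row in range(totals.shape[0] - 1, 0, -1):
        p = parent_rows[row]
        if p >= 0:
            totals[p] += totals[row]
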