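"""Exact event-driven stochastic simulation of the tissue model.

The tissue is a continuous-time Markov chain over all per-cell copy numbers
and promoter occupancies.  The engine draws exponential waiting times from
the total propensity and selects channels proportionally to their
propensities (Gillespie's direct method), with per-cell propensity caching:
after an event only the source (and, for transport, destination) cell's
propensities are recomputed, which leaves the sampled law unchanged.

Timed interventions (exogenous FGF4 addition) are deterministic events that
truncate the pending waiting time, modify the state atomically and force a
full propensity refresh; this preserves exactness of the resulting
time-inhomogeneous process.

Trajectories are recorded either as a zero-order-hold grid filled online at
a fixed sampling period (default 0.25 h) or, for small systems, as a full
event log that can be replayed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .lattice import Lattice, derive_signaling_rates
from .params import (PROMOTER_PAIRS, ParameterSet, VARIANTS,
                     derive_expression_rates, promoter_unbinding_rates)
from .reactions import NSPECIES, NSTATE, PAIR_Q, PAIR_TF_POOL, S

__all__ = [
    "GridSeries",
    "Trajectory",
    "Intervention",
    "simulate",
    "resample",
    "run_batch",
    "replicate_seeds",
    "replay_events",
    "NCH",
]

HOUR = 3600.0
DEFAULT_DT = 0.25 * HOUR

# per-cell channel layout ---------------------------------------------------
# 0..7   promoter binding (pair p)
# 8..15  promoter unbinding (pair p)
# 16..20 transcription: Nanog basal, Nanog induced, Gata6 basal,
#        Gata6 induced, Fgf4 induced
# 21..23 mRNA degradation (Nanog, Gata6, Fgf4)
# 24..26 translation (Nanog, Gata6, Fgf4)
# 27..34 protein degradation (species 3..10)
# 35 dimerization, 36 monomerization
# 37 ERK activation, 38 ERK inactivation
# 39 NANOG phosphorylation, 40 NANOG dephosphorylation
# 41 ERK synthesis
# 42 autocrine escape, 43 paracrine escape, 44 membrane exchange
NCH = 45

_Q = np.array(PAIR_Q, dtype=np.int64)
_POOL = np.array(PAIR_TF_POOL, dtype=np.int64)


@dataclass(frozen=True)
class Intervention:
    """Timed, atomic addition of molecules (one species) to every cell."""

    time: float              # seconds
    counts: np.ndarray       # (L,) integer copies added per cell
    species: int             # state index receiving the molecules


@dataclass
class GridSeries:
    """Zero-order-hold resampling of a trajectory on a regular time grid."""

    dt: float                # sampling period [s]
    times: np.ndarray        # (T,) seconds
    data: np.ndarray         # (T, L, NSTATE) int32 copy numbers/occupancies
    variant: str = "ITWT"
    seed: Optional[int] = None

    @property
    def times_h(self) -> np.ndarray:
        return self.times / HOUR

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]


@dataclass
class Trajectory:
    """One simulated sample path plus everything needed to reproduce it."""

    params: ParameterSet
    lattice: Lattice
    variant: str
    seed: int
    t_end: float
    init: np.ndarray                      # (L, NSTATE) int64
    grid: Optional[GridSeries] = None
    events: Optional[dict] = None         # times/cell/channel/dest/aux arrays
    schedule: tuple = ()


@njit(cache=True, inline="always")
def _fill_cell(props, x, i, kb, ku_part, ku_full, k_tx, k_md, k_ts, k_pd,
               k_dime, k_mono, k_phoE, k_dohE, k_phoN, k_dohN, k_synE,
               k_auto, k_para, k_meme, q_arr, pool_arr, fgf4_on):
    xi = x[i]
    occ0 = 11
    pool_n = xi[3] + xi[4]
    # promoter ladders
    for p in range(8):
        occ = xi[occ0 + p]
        if occ < q_arr[p]:
            pl = pool_arr[p]
            tf = pool_n if pl == 0 else (xi[5] if pl == 1 else xi[10])
            props[i, p] = kb * tf
        else:
            props[i, p] = 0.0
        if occ <= 0:
            props[i, 8 + p] = 0.0
        elif occ == q_arr[p]:
            props[i, 8 + p] = ku_full[p]
        else:
            props[i, 8 + p] = ku_part[p]
    # gene switching indicators
    rep_n = (xi[occ0 + 1] == q_arr[1]) or (xi[occ0 + 6] == q_arr[6])
    act_n = xi[occ0 + 0] == q_arr[0]
    rep_g = xi[occ0 + 2] == q_arr[2]
    act_g = (xi[occ0 + 3] == q_arr[3]) or (xi[occ0 + 7] == q_arr[7])
    rep_f = xi[occ0 + 5] == q_arr[5]
    act_f = xi[occ0 + 4] == q_arr[4]
    props[i, 16] = 0.0 if rep_n else k_tx[0]
    props[i, 17] = k_tx[1] if (act_n and not rep_n) else 0.0
    props[i, 18] = 0.0 if rep_g else k_tx[2]
    props[i, 19] = k_tx[3] if (act_g and not rep_g) else 0.0
    props[i, 20] = k_tx[4] if (fgf4_on and act_f and not rep_f) else 0.0
    for g in range(3):
        props[i, 21 + g] = k_md[g] * xi[g]
        props[i, 24 + g] = k_ts[g] * xi[g]
    for sp in range(8):
        props[i, 27 + sp] = k_pd[sp] * xi[3 + sp]
    m = xi[7]
    props[i, 35] = k_dime * m * (m - 1) / 2.0
    props[i, 36] = k_mono * xi[8]
    props[i, 37] = k_phoE * xi[8] * xi[9]
    props[i, 38] = k_dohE * xi[10]
    props[i, 39] = k_phoN * xi[10] * xi[3]
    props[i, 40] = k_dohN * xi[4]
    props[i, 41] = k_synE
    props[i, 42] = k_auto[i] * xi[6]
    props[i, 43] = k_para[i] * xi[6]
    props[i, 44] = k_meme[i] * xi[7]
    tot = 0.0
    for c in range(NCH):
        tot += props[i, c]
    return tot


@njit(cache=True)
def _ssa_kernel(init, neighbors, n_neigh,
                kb, ku_part, ku_full, q_arr, pool_arr,
                k_tx, k_md, k_ts, k_pd,
                k_dime, k_mono, k_phoE, k_dohE, k_phoN, k_dohN, k_synE,
                k_auto, k_para, k_meme,
                sequester, fgf4_on,
                t_end, dt_grid,
                sched_t, sched_add, sched_sp,
                seed, record_events, ev_cap):
    np.random.seed(seed)
    L = init.shape[0]
    x = init.copy()
    T = int(np.floor(t_end / dt_grid + 1e-9)) + 1
    grid = np.zeros((T, L, NSTATE), dtype=np.int32)
    props = np.zeros((L, NCH))
    cell_tot = np.zeros(L)
    for i in range(L):
        cell_tot[i] = _fill_cell(props, x, i, kb, ku_part, ku_full, k_tx, k_md, k_ts, k_pd,
                                 k_dime, k_mono, k_phoE, k_dohE, k_phoN,
                                 k_dohN, k_synE, k_auto, k_para, k_meme,
                                 q_arr, pool_arr, fgf4_on)
    ev_t = np.zeros(ev_cap if record_events else 1)
    ev_cell = np.zeros(ev_cap if record_events else 1, dtype=np.int32)
    ev_ch = np.zeros(ev_cap if record_events else 1, dtype=np.int32)
    ev_dest = np.zeros(ev_cap if record_events else 1, dtype=np.int32)
    ev_aux = np.zeros(ev_cap if record_events else 1, dtype=np.int32)
    n_ev = 0
    status = 0
    t = 0.0
    g_idx = 0
    s_idx = 0
    nsched = sched_t.shape[0]
    occ0 = 11
    while True:
        boundary = t_end
        if s_idx < nsched and sched_t[s_idx] < boundary:
            boundary = sched_t[s_idx]
        total = 0.0
        for i in range(L):
            total += cell_tot[i]
        if total > 0.0:
            t_next = t - np.log(np.random.random()) / total
        else:
            t_next = np.inf
        if t_next >= boundary:
            # fill grid strictly before the boundary, then handle it
            while g_idx < T and g_idx * dt_grid < boundary - 1e-9:
                for i in range(L):
                    for s in range(NSTATE):
                        grid[g_idx, i, s] = x[i, s]
                g_idx += 1
            if s_idx < nsched and boundary == sched_t[s_idx]:
                sp = sched_sp[s_idx]
                for i in range(L):
                    x[i, sp] += sched_add[s_idx, i]
                s_idx += 1
                t = boundary
                for i in range(L):
                    cell_tot[i] = _fill_cell(props, x, i, kb, ku_part, ku_full, k_tx, k_md,
                                             k_ts, k_pd, k_dime, k_mono,
                                             k_phoE, k_dohE, k_phoN, k_dohN,
                                             k_synE, k_auto, k_para, k_meme,
                                             q_arr, pool_arr, fgf4_on)
                continue
            # reached t_end: final grid points take the final state
            while g_idx < T:
                for i in range(L):
                    for s in range(NSTATE):
                        grid[g_idx, i, s] = x[i, s]
                g_idx += 1
            break
        # fill grid strictly before the event time
        while g_idx < T and g_idx * dt_grid < t_next - 1e-12:
            for i in range(L):
                for s in range(NSTATE):
                    grid[g_idx, i, s] = x[i, s]
            g_idx += 1
        t = t_next
        # channel selection proportional to propensity
        r = np.random.random() * total
        cell = L - 1
        acc = 0.0
        for i in range(L):
            if acc + cell_tot[i] > r:
                cell = i
                break
            acc += cell_tot[i]
        rem = r - acc
        chan = -1
        acc2 = 0.0
        last_pos = -1
        for c in range(NCH):
            a = props[cell, c]
            if a > 0.0:
                last_pos = c
                if acc2 + a > rem:
                    chan = c
                    break
                acc2 += a
        if chan < 0:
            chan = last_pos
        if chan < 0:
            continue
        dest = -1
        aux = -1
        i = cell
        # --- execute ------------------------------------------------------
        if chan < 8:  # promoter binding
            p = chan
            x[i, occ0 + p] += 1
            if sequester:
                pl = pool_arr[p]
                if pl == 0:
                    # donor drawn proportionally from the two NANOG forms
                    if np.random.random() * (x[i, 3] + x[i, 4]) < x[i, 3]:
                        x[i, 3] -= 1
                        aux = 3
                    else:
                        x[i, 4] -= 1
                        aux = 4
                elif pl == 1:
                    x[i, 5] -= 1
                    aux = 5
                else:
                    x[i, 10] -= 1
                    aux = 10
        elif chan < 16:  # promoter unbinding
            p = chan - 8
            x[i, occ0 + p] -= 1
            if sequester:
                pl = pool_arr[p]
                if pl == 0:
                    x[i, 3] += 1
                elif pl == 1:
                    x[i, 5] += 1
                else:
                    x[i, 10] += 1
        elif chan < 21:  # transcription
            if chan == 16 or chan == 17:
                x[i, 0] += 1
            elif chan == 18 or chan == 19:
                x[i, 1] += 1
            else:
                x[i, 2] += 1
        elif chan < 24:  # mRNA degradation
            x[i, chan - 21] -= 1
        elif chan < 27:  # translation
            if chan == 24:
                x[i, 3] += 1
            elif chan == 25:
                x[i, 5] += 1
            else:
                x[i, 6] += 1
        elif chan < 35:  # protein degradation
            x[i, 3 + (chan - 27)] -= 1
        elif chan == 35:
            x[i, 7] -= 2
            x[i, 8] += 1
        elif chan == 36:
            x[i, 7] += 2
            x[i, 8] -= 1
        elif chan == 37:
            x[i, 9] -= 1
            x[i, 10] += 1
        elif chan == 38:
            x[i, 9] += 1
            x[i, 10] -= 1
        elif chan == 39:
            x[i, 3] -= 1
            x[i, 4] += 1
        elif chan == 40:
            x[i, 3] += 1
            x[i, 4] -= 1
        elif chan == 41:
            x[i, 9] += 1
        elif chan == 42:  # autocrine: FGF4 -> own membrane monomer
            x[i, 6] -= 1
            x[i, 7] += 1
            dest = i
        elif chan == 43:  # paracrine: FGF4 -> neighbor membrane monomer
            nn = n_neigh[i]
            j = neighbors[i, int(np.random.random() * nn) % nn]
            x[i, 6] -= 1
            x[j, 7] += 1
            dest = j
        else:  # membrane exchange: monomer hops to a neighbor membrane
            nn = n_neigh[i]
            j = neighbors[i, int(np.random.random() * nn) % nn]
            x[i, 7] -= 1
            x[j, 7] += 1
            dest = j
        # no transition may produce a negative count
        for s in range(NSTATE):
            if x[i, s] < 0:
                status = 2
                break
        if status != 0:
            break
        cell_tot[i] = _fill_cell(props, x, i, kb, ku_part, ku_full, k_tx, k_md, k_ts, k_pd,
                                 k_dime, k_mono, k_phoE, k_dohE, k_phoN,
                                 k_dohN, k_synE, k_auto, k_para, k_meme,
                                 q_arr, pool_arr, fgf4_on)
        if dest >= 0 and dest != i:
            cell_tot[dest] = _fill_cell(props, x, dest, kb, ku_part, ku_full, k_tx, k_md,
                                        k_ts, k_pd, k_dime, k_mono, k_phoE,
                                        k_dohE, k_phoN, k_dohN, k_synE,
                                        k_auto, k_para, k_meme, q_arr,
                                        pool_arr, fgf4_on)
        if record_events:
            if n_ev >= ev_cap:
                status = 1
                break
            ev_t[n_ev] = t
            ev_cell[n_ev] = i
            ev_ch[n_ev] = chan
            ev_dest[n_ev] = dest
            ev_aux[n_ev] = aux
            n_ev += 1
    return grid, x, n_ev, ev_t, ev_cell, ev_ch, ev_dest, ev_aux, status


def _kernel_args(params: ParameterSet, lattice: Lattice, variant: str):
    """Pack rate constants and lattice data into kernel-ready arrays."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    kb = params.k_b
    ku_pairs = [promoter_unbinding_rates(params, p.name) for p in PROMOTER_PAIRS]
    ku_part = np.array([k[0] for k in ku_pairs])
    ku_full = np.array([k[1] for k in ku_pairs])
    k_tx = np.zeros(5)
    k_md = np.zeros(3)
    k_ts = np.zeros(3)
    for g, gene in enumerate(("Nanog", "Gata6", "Fgf4")):
        k_basal, k_find, k_m_d, k_p_s, _ = derive_expression_rates(params, gene)
        k_md[g] = k_m_d
        k_ts[g] = k_p_s
        if gene == "Nanog":
            k_tx[0], k_tx[1] = k_basal, k_find
        elif gene == "Gata6":
            k_tx[2], k_tx[3] = k_basal, k_find
        else:
            k_tx[4] = k_find
    k_pd = np.array([
        1.0 / params.tau_p_NANOG,
        1.0 / params.tau_p_PNANOG,
        1.0 / params.tau_p_GATA6,
        1.0 / params.tau_d_fgf4,
        1.0 / params.tau_d_mfgfr,
        1.0 / params.tau_p_DFGFR,
        1.0 / params.tau_p_ERK,
        1.0 / params.tau_p_ERK,
    ])
    L = lattice.n_cells
    k_auto = np.zeros(L)
    k_para = np.zeros(L)
    k_meme = np.zeros(L)
    if variant not in ("RTM", "TM-APM"):
        for i in range(L):
            a, p_, m_ = derive_signaling_rates(params, lattice, i)
            if variant != "TM-A":
                k_auto[i] = a
            if variant != "TM-PM" and lattice.n_neighbors[i] > 0:
                k_para[i] = p_
                k_meme[i] = m_
    fgf4_on = variant != "TM-FGF4"
    return (lattice.neighbors, lattice.n_neighbors, kb, ku_part, ku_full, _Q, _POOL,
            k_tx, k_md, k_ts, k_pd,
            params.k_dime, params.k_mono,
            1.0 / params.tau_pho_erk, 1.0 / params.tau_doh_erk,
            1.0 / params.tau_pho_nanog, 1.0 / params.tau_doh_nanog,
            params.Pbar_ERK / params.tau_p_ERK,
            k_auto, k_para, k_meme,
            params.sequester_bound_tf, fgf4_on)


def simulate(
    params: ParameterSet,
    lattice: Lattice,
    variant: str,
    init: np.ndarray,
    t_end: float,
    seed: int,
    schedule: Sequence[Intervention] = (),
    dt_record: float = DEFAULT_DT,
    record_events: bool = False,
    event_capacity: int = 2_000_000,
) -> Trajectory:
    """Draw one statistically exact sample path of the tissue CTMC.

    ``init`` is a (L, NSTATE) integer array; ``schedule`` holds timed
    interventions within ``[0, t_end]``.  Identical arguments produce an
    identical trajectory.  The returned trajectory carries a zero-order-hold
    grid at period ``dt_record`` and, if requested, the full event log.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    init = np.ascontiguousarray(init, dtype=np.int64)
    if init.shape != (lattice.n_cells, NSTATE):
        raise ValueError(f"init must have shape (L, {NSTATE})")
    if (init < 0).any():
        raise ValueError("initial counts must be non-negative")
    sched = sorted(schedule, key=lambda iv: iv.time)
    for iv in sched:
        if not 0.0 <= iv.time <= t_end:
            raise ValueError("intervention times must lie within [0, t_end]")
    sched_t = np.array([iv.time for iv in sched], dtype=float)
    L = lattice.n_cells
    sched_add = (np.array([iv.counts for iv in sched], dtype=np.int64)
                 if sched else np.zeros((0, L), dtype=np.int64))
    sched_sp = np.array([iv.species for iv in sched], dtype=np.int64)
    args = _kernel_args(params, lattice, variant)
    grid, final, n_ev, ev_t, ev_cell, ev_ch, ev_dest, ev_aux, status = _ssa_kernel(
        init, *args, float(t_end), float(dt_record),
        sched_t, sched_add, sched_sp,
        int(seed) % (2 ** 31), int(record_events), int(event_capacity))
    if status == 1:
        raise RuntimeError("event log capacity exceeded")
    if status == 2:
        raise RuntimeError("internal invariant violation: negative copy number")
    T = grid.shape[0]
    gs = GridSeries(dt_record, np.arange(T) * dt_record, grid, variant, seed)
    events = None
    if record_events:
        events = {
            "time": ev_t[:n_ev].copy(),
            "cell": ev_cell[:n_ev].copy(),
            "channel": ev_ch[:n_ev].copy(),
            "dest": ev_dest[:n_ev].copy(),
            "aux": ev_aux[:n_ev].copy(),
            "final": final,
        }
    return Trajectory(params, lattice, variant, seed, t_end, init, gs, events,
                      tuple(sched))


def resample(traj: Trajectory, dt: float) -> GridSeries:
    """Zero-order-hold resampling of a trajectory at period ``dt``.

    Grid times are ``0, dt, 2 dt, ...`` up to and including the last point
    ``<= t_end``; the value at a grid time is the state at the last event at
    or before it, and the first point equals the initial condition.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    src = traj.grid
    if src is None:
        raise ValueError("trajectory carries no recorded series")
    ratio = dt / src.dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"dt must be a multiple of the recording period {src.dt} s")
    step = int(round(ratio))
    n = int(np.floor(traj.t_end / dt + 1e-9)) + 1
    data = src.data[:: step][:n]
    return GridSeries(dt, np.arange(n) * dt, data, traj.variant, traj.seed)


def replicate_seeds(base_seed: int, n_reps: int) -> np.ndarray:
    """Reproducible independent seeds (< 2**31) derived from a base seed."""
    ss = np.random.SeedSequence(base_seed)
    return ss.generate_state(n_reps, dtype=np.uint64) % (2 ** 31)


def run_batch(
    params: ParameterSet,
    lattice: Lattice,
    variant: str,
    icd_sampler,
    n_reps: int,
    base_seed: int,
    t_end: float,
    schedule: Sequence[Intervention] = (),
    dt_record: float = DEFAULT_DT,
) -> list[GridSeries]:
    """Ensemble of independent replicates with reproducibly derived seeds.

    ``icd_sampler(rng)`` must return a (L, NSTATE) initial state; each
    replicate gets an independent initial condition and simulation stream.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seeds = replicate_seeds(base_seed, 2 * n_reps).reshape(n_reps, 2)
    out = []
    for r in range(n_reps):
        rng = np.random.default_rng(int(seeds[r, 0]))
        init = icd_sampler(rng)
        traj = simulate(params, lattice, variant, init, t_end,
                        int(seeds[r, 1]), schedule, dt_record)
        out.append(traj.grid)
    return out


def replay_events(traj: Trajectory):
    """Replay a recorded event log from the initial state.

    Returns the sequence-final state; used to verify that the event log
    fully determines the trajectory (and for conservation audits).  The
    trajectory must have been simulated with ``record_events=True``.
    """
    if traj.events is None:
        raise ValueError("trajectory carries no event log")
    x = traj.init.copy()
    seq = traj.params.sequester_bound_tf
    pool_arr = _POOL
    sched = list(traj.schedule)
    s_idx = 0
    ev = traj.events
    for n in range(len(ev["time"])):
        t = ev["time"][n]
        while s_idx < len(sched) and sched[s_idx].time <= t:
            iv = sched[s_idx]
            x[:, iv.species] += iv.counts
            s_idx += 1
        i = int(ev["cell"][n])
        chan = int(ev["channel"][n])
        dest = int(ev["dest"][n])
        aux = int(ev["aux"][n])
        occ0 = NSPECIES
        if chan < 8:
            x[i, occ0 + chan] += 1
            if seq:
                x[i, aux] -= 1
        elif chan < 16:
            p = chan - 8
            x[i, occ0 + p] -= 1
            if seq:
                pl = pool_arr[p]
                x[i, 3 if pl == 0 else (5 if pl == 1 else 10)] += 1
        elif chan < 21:
            x[i, 0 if chan in (16, 17) else (1 if chan in (18, 19) else 2)] += 1
        elif chan < 24:
            x[i, chan - 21] -= 1
        elif chan < 27:
            x[i, {24: 3, 25: 5, 26: 6}[chan]] += 1
        elif chan < 35:
            x[i, 3 + (chan - 27)] -= 1
        elif chan == 35:
            x[i, 7] -= 2
            x[i, 8] += 1
        elif chan == 36:
            x[i, 7] += 2
            x[i, 8] -= 1
        elif chan == 37:
            x[i, 9] -= 1
            x[i, 10] += 1
        elif chan == 38:
            x[i, 9] += 1
            x[i, 10] -= 1
        elif chan == 39:
            x[i, 3] -= 1
            x[i, 4] += 1
        elif chan == 40:
            x[i, 3] += 1
            x[i, 4] -= 1
        elif chan == 41:
            x[i, 9] += 1
        elif chan == 42:
            x[i, 6] -= 1
            x[i, 7] += 1
        elif chan == 43:
            x[i, 6] -= 1
            x[dest, 7] += 1
        else:
            x[i, 7] -= 1
            x[dest, 7] += 1
        if (x[i] < 0).any():
            raise RuntimeError("replay produced a negative count")
    while s_idx < len(sched):
        iv = sched[s_idx]
        x[:, iv.species] += iv.counts
        s_idx += 1
    return x
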