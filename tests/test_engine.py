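import numpy as np
import pytest

from icmsim.engine import (
    Intervention,
    replay_events,
    replicate_seeds,
    resample,
    run_batch,
    simulate,
)
from icmsim.experiments import icd_sampler, sample_icd
from icmsim.lattice import build_lattice
from icmsim.params import ParameterSet
from icmsim.reactions import NSTATE, S

from reference import naive_ssa

HOUR = 3600.0


def zero_init(n_cells):
    return np.zeros((n_cells, NSTATE), dtype=np.int64)


class TestDeterminism:
    def test_same_seed_identical_trajectories(self, map_params, lattice_2x2):
        init = sample_icd(map_params, 4, seed=0)
        a = simulate(map_params, lattice_2x2, "ITWT", init, 2 * HOUR, seed=5,
                     record_events=True)
        b = simulate(map_params, lattice_2x2, "ITWT", init, 2 * HOUR, seed=5,
                     record_events=True)
        assert np.array_equal(a.grid.data, b.grid.data)
        assert np.array_equal(a.events["time"], b.events["time"])
        assert np.array_equal(a.events["channel"], b.events["channel"])

    def test_different_seeds_diverge(self, map_params, lattice_2x2):
        init = sample_icd(map_params, 4, seed=0)
        a = simulate(map_params, lattice_2x2, "ITWT", init, 2 * HOUR, seed=5)
        b = simulate(map_params, lattice_2x2, "ITWT", init, 2 * HOUR, seed=6)
        assert not np.array_equal(a.grid.data, b.grid.data)

    def test_event_log_replay_reproduces_final_state(self, map_params, lattice_2x2):
        init = sample_icd(map_params, 4, seed=1)
        traj = simulate(map_params, lattice_2x2, "ITWT", init, 3 * HOUR, seed=9,
                        record_events=True)
        assert np.array_equal(replay_events(traj),
                              traj.grid.data[-1].astype(np.int64))


class TestExactness:
    def test_erk_birth_death_matches_poisson_law(self, erk_only_params):
        """With transcription silenced, inactive ERK is an isolated linear
        birth-death process whose stationary law is Poisson(Pbar_ERK).
        Starting each replicate from a Poisson draw keeps the chain exactly
        stationary, so the endpoint moments must match Poisson moments
        within 3 standard errors."""
        lat = build_lattice(1, 1)
        pbar = erk_only_params.Pbar_ERK
        n_rep = 400
        init_rng = np.random.default_rng(2024)
        samples = np.empty(n_rep)
        for r, seed in enumerate(replicate_seeds(77, n_rep)):
            init = zero_init(1)
            init[0, S.I_ERK] = init_rng.poisson(pbar)
            traj = simulate(erk_only_params, lat, "RTM", init, 6 * HOUR,
                            seed=int(seed), dt_record=6 * HOUR)
            samples[r] = (traj.grid.data[-1, 0, S.I_ERK]
                          + traj.grid.data[-1, 0, S.A_ERK])
        se_mean = np.sqrt(pbar / n_rep)
        assert abs(samples.mean() - pbar) < 3 * se_mean
        se_var = pbar * np.sqrt(2.0 / n_rep)
        assert abs(samples.var(ddof=1) - pbar) < 3 * se_var

    def test_two_cell_transport_matches_naive_oracle(self, rng):
        """Marginal moments of the engine agree with an independent
        brute-force direct-method SSA on a 2-cell FGF4 transport toy."""
        p = ParameterSet(c_basal=0.0, c_find=1.0, mean_init_mrna=0.0,
                         mean_init_protein=0.0, Pbar_ERK=1e-9)
        lat = build_lattice(1, 2)
        t_end = 2000.0

        def init():
            x = zero_init(2)
            x[0, S.FGF4] = 40
            return x

        n_fast, n_slow = 600, 300
        fast = np.empty((n_fast, 2))
        for r, seed in enumerate(replicate_seeds(3, n_fast)):
            traj = simulate(p, lat, "ITWT", init(), t_end, seed=int(seed),
                            dt_record=t_end)
            fast[r] = traj.grid.data[-1, :, S.M_FGFR_FGF4]
        slow = np.empty((n_slow, 2))
        for r in range(n_slow):
            x = naive_ssa(p, lat, "ITWT", init(), t_end, rng)
            slow[r] = x[:, S.M_FGFR_FGF4]
        for cell in (0, 1):
            se = np.sqrt(fast[:, cell].var() / n_fast
                         + slow[:, cell].var() / n_slow)
            assert abs(fast[:, cell].mean() - slow[:, cell].mean()) < 3 * se + 1e-9

    def test_ligand_conserved_by_transport_events(self, map_params, lattice_2x2):
        """Total ligand (cytoplasmic + monomer + 2x dimer) changes only via
        synthesis and degradation channels, never via transport."""
        init = sample_icd(map_params, 4, seed=3)
        init[:, S.FGF4] = 50
        traj = simulate(map_params, lattice_2x2, "ITWT", init, 1 * HOUR, seed=2,
                        record_events=True)
        x = traj.init.copy()
        ligand = lambda s: s[:, S.FGF4].sum() + s[:, S.M_FGFR_FGF4].sum() \
            + 2 * s[:, S.D_FGFR_FGF4].sum()
        ev = traj.events
        for n in range(len(ev["time"])):
            before = ligand(x)
            single = {k: v[n:n + 1] for k, v in ev.items() if k != "final"}
            step = traj.__class__(traj.params, traj.lattice, traj.variant,
                                  traj.seed, traj.t_end, x,
                                  events=single, schedule=())
            x = replay_events(step)
            chan = int(ev["channel"][n])
            if chan in (42, 43, 44, 35, 36):  # transport & (de)dimerization
                assert ligand(x) == before

    def test_fgf4_knockout_produces_no_ligand(self, map_params, lattice_2x2):
        """With Fgf4 transcription removed, no channel sources ligand: the
        tissue-total FGF4 stays at zero for the whole run."""
        init = sample_icd(map_params, 4, seed=6)
        traj = simulate(map_params, lattice_2x2, "TM-FGF4", init, 12 * HOUR,
                        seed=3)
        d = traj.grid.data
        total = (d[:, :, S.Fgf4_mRNA] + d[:, :, S.FGF4]
                 + d[:, :, S.M_FGFR_FGF4] + d[:, :, S.D_FGFR_FGF4])
        assert (total == 0).all()

    def test_no_negative_counts_along_trajectory(self, map_params, lattice_5x5):
        init = sample_icd(map_params, 25, seed=4)
        traj = simulate(map_params, lattice_5x5, "ITWT", init, 12 * HOUR, seed=8)
        assert (traj.grid.data >= 0).all()


class TestResampling:
    def test_grid_length_and_initial_value(self, map_params, lattice_2x2):
        init = sample_icd(map_params, 4, seed=0)
        traj = simulate(map_params, lattice_2x2, "ITWT", init, 48 * HOUR, seed=1)
        assert traj.grid.data.shape[0] == 193  # 48 h at 0.25 h inclusive
        assert np.array_equal(traj.grid.data[0].astype(np.int64), init)

    def test_zero_order_hold_subsampling(self, map_params, lattice_2x2):
        init = sample_icd(map_params, 4, seed=0)
        traj = simulate(map_params, lattice_2x2, "ITWT", init, 4 * HOUR, seed=1)
        coarse = resample(traj, HOUR)
        assert coarse.data.shape[0] == 5
        assert np.array_equal(coarse.data, traj.grid.data[::4])
        with pytest.raises(ValueError):
            resample(traj, 1000.0)  # not a multiple of the recording period

    def test_intervention_applied_atomically(self, map_params, lattice_2x2):
        init = zero_init(4)
        iv = Intervention(2 * HOUR, np.full(4, 100, dtype=np.int64), S.M_FGFR_FGF4)
        p = ParameterSet(c_basal=0.0, c_find=1.0, mean_init_mrna=0.0,
                         mean_init_protein=0.0, Pbar_ERK=1e-9,
                         tau_d_mfgfr=1e9, tau_exchange=1e9)
        traj = simulate(p, lattice_2x2, "TM-FGF4", init, 4 * HOUR, seed=1,
                        schedule=(iv,))
        m = traj.grid.data[:, :, S.M_FGFR_FGF4].sum(axis=1)
        t_idx = int(2 * HOUR / traj.grid.dt)
        assert (m[:t_idx] == 0).all()
        assert m[t_idx] >= 390  # 400 added, minus rare dimerization pairs

    def test_intervention_outside_horizon_rejected(self, map_params, lattice_2x2):
        iv = Intervention(10 * HOUR, np.zeros(4, dtype=np.int64), S.FGF4)
        with pytest.raises(ValueError):
            simulate(map_params, lattice_2x2, "ITWT", zero_init(4), HOUR,
                     seed=1, schedule=(iv,))


class TestBatches:
    def test_batch_reproducibility(self, map_params, lattice_2x2):
        a = run_batch(map_params, lattice_2x2, "ITWT",
                      icd_sampler(map_params, 4), 3, 11, 2 * HOUR)
        b = run_batch(map_params, lattice_2x2, "ITWT",
                      icd_sampler(map_params, 4), 3, 11, 2 * HOUR)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.data, s2.data)

    def test_replicates_are_independent(self, map_params, lattice_2x2):
        ens = run_batch(map_params, lattice_2x2, "ITWT",
                        icd_sampler(map_params, 4), 2, 11, 2 * HOUR)
        assert not np.array_equal(ens[0].data, ens[1].data)

    def test_seed_derivation_below_31_bits(self):
        seeds = replicate_seeds(123, 1000)
        assert (seeds < 2 ** 31).all()
        assert len(np.unique(seeds)) == 1000

    def test_invalid_inputs(self, map_params, lattice_2x2):
        with pytest.raises(ValueError):
            run_batch(map_params, lattice_2x2, "ITWT",
                      icd_sampler(map_params, 4), 0, 1, HOUR)
        with pytest.raises(ValueError):
            simulate(map_params, lattice_2x2, "ITWT", zero_init(4), -1.0, seed=1)
        with pytest.raises(ValueError):
            simulate(map_params, lattice_2x2, "ITWT",
                     -np.ones((4, NSTATE), dtype=np.int64), HOUR, seed=1)
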