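"""Protocol-runner tests: MAFC, conditioning, blocking, baselines."""

import numpy as np
import pytest

from mbrpe.circuit import CircuitState, InterventionSpec, Reinforcement, mbon_rates
from mbrpe.encoding import assign_dedicated
from mbrpe.experiments import (blocking_batches, conditioning_batches,
                               perfect_plasticity_step, run_blocking,
                               run_conditioning, run_mafc,
                               run_perfect_plasticity, run_trial,
                               trial_averaged_reinforcement)
from mbrpe.plasticity import PlasticityConfig
from mbrpe.schedules import ReinforcementSchedule, step_schedule


def _constant_schedule(mus, n_trials, sigma_r=0.0):
    mu = np.tile(np.asarray(mus, dtype=float), (n_trials, 1))
    return ReinforcementSchedule(mu, sigma_r)


class TestMafc:
    def test_only_chosen_cue_synapses_change(self, rng):
        enc = assign_dedicated(3)
        state = CircuitState.random(enc.n_kc, rng, variant="MV")
        sched = _constant_schedule([1.0, 0.0, -1.0], 30, sigma_r=0.1)
        pcfg = PlasticityConfig(eta=0.025)
        prev = state.copy()
        res = run_mafc(state, sched, enc, pcfg, rng, beta=1.0)
        # re-run trial-by-trial bookkeeping via the recorded choices
        state = prev
        for rec in res.records:
            before = state.copy()
            state, _ = run_trial(state, enc.response(rec.choice),
                                 Reinforcement(rec.r), pcfg, stage="mafc")
            changed = np.flatnonzero(
                (state.w_plus != before.w_plus) | (state.w_minus != before.w_minus))
            assert np.isin(changed, enc.subsets[rec.choice]).all()

    def test_beta_zero_choices_uniform(self, rng):
        enc = assign_dedicated(4)
        state = CircuitState.random(enc.n_kc, rng, variant="MV")
        sched = _constant_schedule([1.0, 0.5, 0.0, -1.0], 400, sigma_r=0.1)
        res = run_mafc(state, sched, enc, PlasticityConfig(eta=0.025), rng,
                       beta=0.0)
        counts = np.bincount([r.choice for r in res.records], minlength=4)
        se = np.sqrt(400 * 0.25 * 0.75)
        assert np.all(np.abs(counts - 100) < 4 * se)

    def test_single_cue_tracks_step_schedule_within_bound(self, rng):
        # forced exposure: converged RP follows clip(mu, +-(lambda - gamma*sum k))
        enc = assign_dedicated(1)
        state = CircuitState.random(enc.n_kc, rng, gamma=1.0, lam=11.5,
                                    variant="VSlambda")
        sched = step_schedule(sigma_r=0.0)
        res = run_mafc(state, sched, enc, PlasticityConfig(eta=0.025, lam=11.5),
                       rng, beta=0.0)
        m_max = 11.5 - 10.0
        # final trials of each 20-trial plateau should be near the clipped mean
        for trial, mu in [(20, 0.0), (40, 1.0), (60, 2.0), (140, -2.0), (180, 0.0)]:
            expected = np.clip(mu, -m_max, m_max)
            assert res.records[trial - 1].m_hat == pytest.approx(expected, abs=0.07)

    def test_mv_prefers_rewarded_cue_late(self, rng):
        enc = assign_dedicated(2)
        state = CircuitState.random(enc.n_kc, rng, variant="MV")
        sched = _constant_schedule([1.0, -1.0], 200, sigma_r=0.1)
        res = run_mafc(state, sched, enc, PlasticityConfig(eta=0.05), rng,
                       beta=10.0)
        late = [r.choice for r in res.records[100:]]
        assert np.mean(np.array(late) == 0) > 0.9


class TestBaselines:
    def test_perfect_plasticity_step(self):
        rp = perfect_plasticity_step(np.array([0.0, 0.5]), 1, 2.0)
        assert rp.tolist() == [0.0, 2.0]

    def test_tar_trivial_cases(self):
        assert trial_averaged_reinforcement([1.0, 1.0, 1.0]) == 1.0
        assert trial_averaged_reinforcement([1.0, -1.0, 1.0, -1.0]) == 0.0
        with pytest.raises(ValueError):
            trial_averaged_reinforcement([1.0], burn_in=5)

    def test_perfect_plasticity_beats_circuit_without_noise(self, rng):
        # noiseless constant schedule: the one-shot baseline is an upper bound
        sched = _constant_schedule([1.0, -1.0], 150, sigma_r=0.0)
        tar_perfect = []
        tar_model = []
        for seed in range(8):
            r1 = np.random.default_rng(seed)
            res_p = run_perfect_plasticity(sched, r1, beta=5.0)
            tar_perfect.append(trial_averaged_reinforcement(res_p.records, 50))
            r2 = np.random.default_rng(seed)
            enc = assign_dedicated(2)
            state = CircuitState.random(enc.n_kc, r2, variant="MV")
            res_m = run_mafc(state, sched, enc, PlasticityConfig(eta=0.05), r2,
                             beta=5.0)
            tar_model.append(trial_averaged_reinforcement(res_m.records, 50))
        assert np.mean(tar_perfect) >= np.mean(tar_model) - 1e-9


class TestDualCircuitEquivalence:
    def test_identical_rp_trajectories(self):
        # same seed, same noisy schedule: VSu-A and VSu-B agree to 1e-9
        trajs = []
        for variant in ("VSu-A", "VSu-B"):
            rng = np.random.default_rng(77)
            enc = assign_dedicated(1)
            state = CircuitState.random(enc.n_kc, rng, gamma=1.0,
                                        variant=variant)
            sched = step_schedule(sigma_r=0.1)
            pcfg = PlasticityConfig(eta=0.025)
            traj = []
            for t in range(sched.n_trials):
                r = sched.mu[t, 0] + 0.1 * rng.standard_normal()
                state, _ = run_trial(state, enc.response(0), Reinforcement(r),
                                     pcfg)
                traj.append(mbon_rates(state, enc.response(0))[2])
            trajs.append(np.array(traj))
        assert np.max(np.abs(trajs[0] - trajs[1])) < 1e-9


class TestConditioning:
    def test_neutral_control_pi_near_zero(self, rng):
        pis = conditioning_batches(variant="VSlambda", us="neutral",
                                   n_batches=6, runs_per_batch=40, rng=rng)
        assert abs(pis.mean()) < 0.15

    @pytest.mark.parametrize("variant, lam", [("VSlambda", 12.0), ("MV", None)])
    def test_appetitive_control_pi_positive(self, variant, lam, rng):
        pis = conditioning_batches(variant=variant, us="appetitive", lam=lam,
                                   n_batches=4, runs_per_batch=40, rng=rng)
        assert pis.mean() > 0.3

    def test_test_stage_intervention_affects_choice(self, rng):
        # after aversive training the CS+/CS- RP contrast is carried by the
        # depressed m+ response to the CS+; blocking M+ output during the
        # test compresses that contrast tenfold, releasing the learned
        # avoidance of the CS+ (PI moves towards zero)
        spec = InterventionSpec("M+", "block", "test")
        pis_block = conditioning_batches(variant="VSlambda", us="aversive",
                                         intervention=spec, n_batches=4,
                                         runs_per_batch=40, rng=rng)
        pis_ctrl = conditioning_batches(variant="VSlambda", us="aversive",
                                        n_batches=4, runs_per_batch=40, rng=rng)
        assert pis_block.mean() > pis_ctrl.mean() + 0.1

    def test_invalid_us_rejected(self):
        with pytest.raises(ValueError):
            run_conditioning(us="sugar")


class TestBlocking:
    def test_independent_coding_blocks_y(self, rng):
        rps = [run_blocking(0.0, 0.0, rng=rng)["y_rp_mean"] for _ in range(150)]
        assert abs(np.mean(rps)) < 0.1

    def test_full_x_corruption_releases_blocking(self, rng):
        rps = [run_blocking(1.0, 0.0, rng=rng)["y_rp_mean"] for _ in range(150)]
        assert np.mean(rps) > 0.3

    def test_frozen_corruption_switch_runs(self, rng):
        out = run_blocking(0.5, 0.5, rng=rng, frozen_corruption=True)
        assert out["n_plus"] + out["n_minus"] == 2

    def test_batches_bookkeeping(self, rng):
        pis, y_rps = blocking_batches(0.0, 0.0, n_batches=2, runs_per_batch=10,
                                      rng=rng)
        assert pis.shape == (2,)
        assert y_rps.shape == (20,)
        assert np.all(np.abs(pis) <= 1.0)
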