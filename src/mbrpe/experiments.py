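"""Protocol runners: MAFC bandit, conditioning with interventions, blocking.

Every trial follows the same skeleton: compute RPs with the current weights,
(choose a cue if the stage allows choice), draw the chosen cue's
reinforcement, compute DAN rates for that cue, update that cue's synapses
only, and record.  Training trials in conditioning and blocking are forced
exposures — the softmax is engaged only in test stages and in the MAFC task.

Interventions modify the target neuron's *output* during their scheduled
stages, wherever that output is consumed: MBON interventions alter the RP
used for choice and the feedback reaching DANs; DAN interventions alter the
dopamine signal reaching the synapses (plasticity), which continues during
the test stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .circuit import (CircuitState, InterventionSpec, NO_INTERVENTION,
                      Reinforcement, apply_intervention, dan_rates, mbon_rates)
from .decision import BETA_DEFAULT, choice_probabilities, sample_choice
from .encoding import (CueEncoding, assign_dedicated, blocking_encoding,
                       compound_response, corrupt_response)
from .plasticity import (ETA_CONDITIONING, PlasticityConfig, increments,
                         update_weights)
from .schedules import ReinforcementSchedule, draw_reinforcement

__all__ = [
    "TrialRecord",
    "ProtocolResult",
    "run_trial",
    "run_mafc",
    "run_perfect_plasticity",
    "perfect_plasticity_step",
    "trial_averaged_reinforcement",
    "run_conditioning",
    "conditioning_batches",
    "run_blocking",
    "blocking_batches",
    "US_MU",
]

#: mean reinforcement per US valence in the conditioning protocol
US_MU = {"appetitive": 1.0, "aversive": -1.0, "neutral": 0.0}

CONDITIONING_TRAIN_TRIALS = 10
CONDITIONING_TEST_TRIALS = 2
N_BATCHES_DEFAULT = 20
RUNS_PER_BATCH_DEFAULT = 50


@dataclass(frozen=True)
class TrialRecord:
    """Per-trial log entry."""

    trial: int
    stage: str
    available: tuple
    m_hat_all: tuple
    choice: int
    r: float
    m_plus: float
    m_minus: float
    d_plus: float
    d_minus: float

    @property
    def d_hat(self) -> float:
        return self.d_plus - self.d_minus

    @property
    def m_hat(self) -> float:
        return self.m_plus - self.m_minus


@dataclass
class ProtocolResult:
    """Outcome of one protocol run (or a recorded simulation)."""

    records: List[TrialRecord]
    n_plus: int
    n_minus: int
    final_state: Optional[CircuitState]
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {
                "trial": rec.trial,
                "stage": rec.stage,
                "choice": rec.choice,
                "r": rec.r,
                "m_plus": rec.m_plus,
                "m_minus": rec.m_minus,
                "m_hat": rec.m_hat,
                "d_plus": rec.d_plus,
                "d_minus": rec.d_minus,
                "d_hat": rec.d_hat,
                "m_hat_all": ";".join(f"{v:.10g}" for v in rec.m_hat_all),
            }
            for rec in self.records
        ]
        return pd.DataFrame(rows)


def _effective_mbon(state: CircuitState, kc: np.ndarray,
                    intervention: InterventionSpec, stage: str):
    """MBON output rates after any scheduled intervention."""
    m_plus, m_minus, _ = mbon_rates(state, kc)
    m_plus = apply_intervention(m_plus, intervention, stage, "M+")
    m_minus = apply_intervention(m_minus, intervention, stage, "M-")
    return m_plus, m_minus


def run_trial(state: CircuitState, kc: np.ndarray, reinf: Reinforcement,
              pconfig: PlasticityConfig,
              intervention: InterventionSpec = NO_INTERVENTION,
              stage: str = "CS+"):
    """One exposure of a cue with plasticity; returns (new_state, rates).

    ``rates`` is the tuple (m_plus, m_minus, d_plus, d_minus) of
    intervention-modified output rates actually consumed downstream.
    """
    m_plus, m_minus = _effective_mbon(state, kc, intervention, stage)
    d_plus, d_minus = dan_rates(state, m_plus, m_minus, reinf, kc)
    d_plus = apply_intervention(d_plus, intervention, stage, "D+")
    d_minus = apply_intervention(d_minus, intervention, stage, "D-")
    inc_p, inc_m = increments(state, kc, d_plus, d_minus, pconfig)
    new_state = update_weights(state, inc_p, inc_m)
    return new_state, (m_plus, m_minus, d_plus, d_minus)


def run_mafc(state: CircuitState, schedule: ReinforcementSchedule,
             encoding: CueEncoding, pconfig: PlasticityConfig,
             rng: np.random.Generator, beta: float = BETA_DEFAULT,
             record: bool = True) -> ProtocolResult:
    """Multi-alternative forced choice over the schedule's trials.

    Per trial: RPs for all cues -> softmax -> sampled choice -> reinforcement
    draw for the chosen cue -> DAN rates -> chosen-cue weight update.
    """
    if schedule.n_cues != encoding.n_cues:
        raise ValueError("schedule and encoding disagree on the number of cues")
    records: List[TrialRecord] = []
    for t in range(schedule.n_trials):
        m_hat_all = np.array(
            [mbon_rates(state, encoding.response(c))[2]
             for c in range(encoding.n_cues)]
        )
        dist = choice_probabilities(m_hat_all, beta)
        q = sample_choice(dist, rng)
        reinf = draw_reinforcement(schedule.mu[t, q], schedule.sigma_r, rng)
        kc = encoding.response(q)
        state, rates = run_trial(state, kc, reinf, pconfig, stage="mafc")
        if record:
            records.append(TrialRecord(
                trial=t + 1, stage="mafc",
                available=tuple(range(encoding.n_cues)),
                m_hat_all=tuple(m_hat_all), choice=q, r=reinf.r,
                m_plus=rates[0], m_minus=rates[1],
                d_plus=rates[2], d_minus=rates[3],
            ))
    return ProtocolResult(records, 0, 0, state)


def perfect_plasticity_step(rp_table: np.ndarray, chosen: int,
                            r: float) -> np.ndarray:
    """Perfect-plasticity baseline update: RP of the chosen cue is set to the
    last obtained reinforcement; other cues are untouched."""
    out = np.asarray(rp_table, dtype=float).copy()
    out[chosen] = r
    return out


def run_perfect_plasticity(schedule: ReinforcementSchedule,
                           rng: np.random.Generator,
                           beta: float = BETA_DEFAULT) -> ProtocolResult:
    """MAFC run of the perfect-plasticity baseline (no circuit)."""
    rp = np.zeros(schedule.n_cues)
    records: List[TrialRecord] = []
    for t in range(schedule.n_trials):
        dist = choice_probabilities(rp, beta)
        q = sample_choice(dist, rng)
        reinf = draw_reinforcement(schedule.mu[t, q], schedule.sigma_r, rng)
        records.append(TrialRecord(
            trial=t + 1, stage="mafc", available=tuple(range(schedule.n_cues)),
            m_hat_all=tuple(rp), choice=q, r=reinf.r,
            m_plus=0.0, m_minus=0.0, d_plus=0.0, d_minus=0.0,
        ))
        rp = perfect_plasticity_step(rp, q, reinf.r)
    return ProtocolResult(records, 0, 0, None)


def trial_averaged_reinforcement(records: Sequence, burn_in: int = 0) -> float:
    """Mean obtained reinforcement over trials after ``burn_in`` (TAR)."""
    if burn_in >= len(records):
        raise ValueError("burn_in must be smaller than the number of trials")
    rs = [rec.r if isinstance(rec, TrialRecord) else float(rec)
          for rec in records[burn_in:]]
    return float(np.mean(rs))


def _new_conditioning_state(variant: str, rng: np.random.Generator,
                            gamma: float, lam: Optional[float],
                            n_kc: int) -> CircuitState:
    return CircuitState.random(n_kc, rng, gamma=gamma, lam=lam, variant=variant)


def run_conditioning(variant: str = "VSlambda", us: str = "appetitive",
                     intervention: InterventionSpec = NO_INTERVENTION,
                     eta: float = ETA_CONDITIONING, beta: float = BETA_DEFAULT,
                     lam: Optional[float] = 12.0, gamma: float = 1.0,
                     sigma_r: float = 0.1,
                     rng: Optional[np.random.Generator] = None,
                     mv_form: str = "dan_diff",
                     record: bool = False) -> ProtocolResult:
    """One simulated fly in the two-odour conditioning protocol.

    Stage 1: 10 forced CS+ exposures with r ~ N(mu_US, sigma_r); stage 2: 10
    forced CS- exposures with mu = 0; stage 3: two softmax choices between
    CS+ and CS- with mu = 0 for both, plasticity continuing throughout.
    ``n_plus`` counts test choices of the CS+.
    """
    if us not in US_MU:
        raise ValueError(f"us must be one of {sorted(US_MU)}")
    if rng is None:
        rng = np.random.default_rng()
    encoding = assign_dedicated(2)
    state = _new_conditioning_state(variant, rng, gamma, lam, encoding.n_kc)
    pconfig = PlasticityConfig(eta=eta, lam=lam, mv_form=mv_form)
    records: List[TrialRecord] = []
    trial = 0

    def log(stage, available, m_hat_all, q, reinf, rates):
        records.append(TrialRecord(
            trial=trial, stage=stage, available=available,
            m_hat_all=tuple(m_hat_all), choice=q, r=reinf.r,
            m_plus=rates[0], m_minus=rates[1],
            d_plus=rates[2], d_minus=rates[3],
        ))

    for stage, cue, mu in (("CS+", 0, US_MU[us]), ("CS-", 1, 0.0)):
        kc = encoding.response(cue)
        for _ in range(CONDITIONING_TRAIN_TRIALS):
            trial += 1
            reinf = draw_reinforcement(mu, sigma_r, rng)
            state, rates = run_trial(state, kc, reinf, pconfig, intervention,
                                     stage)
            if record:
                log(stage, (cue,), (rates[0] - rates[1],), cue, reinf, rates)

    n_plus = n_minus = 0
    for _ in range(CONDITIONING_TEST_TRIALS):
        trial += 1
        m_hat_all = np.array([
            (lambda mp_mm: mp_mm[0] - mp_mm[1])(
                _effective_mbon(state, encoding.response(c), intervention,
                                "test"))
            for c in (0, 1)
        ])
        dist = choice_probabilities(m_hat_all, beta)
        q = sample_choice(dist, rng)
        if q == 0:
            n_plus += 1
        else:
            n_minus += 1
        reinf = draw_reinforcement(0.0, sigma_r, rng)
        state, rates = run_trial(state, encoding.response(q), reinf, pconfig,
                                 intervention, "test")
        if record:
            log("test", (0, 1), m_hat_all, q, reinf, rates)

    return ProtocolResult(records, n_plus, n_minus, state)


def conditioning_batches(variant: str = "VSlambda", us: str = "appetitive",
                         intervention: InterventionSpec = NO_INTERVENTION,
                         n_batches: int = N_BATCHES_DEFAULT,
                         runs_per_batch: int = RUNS_PER_BATCH_DEFAULT,
                         rng: Optional[np.random.Generator] = None,
                         **kwargs) -> np.ndarray:
    """Batch PIs for a conditioning protocol.

    Each batch pools the test choices of ``runs_per_batch`` independent runs
    (100 choices for the default 50 runs x 2 test trials) into one
    performance index (n+ - n-) / (n+ + n-).
    """
    if rng is None:
        rng = np.random.default_rng()
    pis = np.empty(n_batches)
    for b in range(n_batches):
        n_plus = n_minus = 0
        for _ in range(runs_per_batch):
            res = run_conditioning(variant=variant, us=us,
                                   intervention=intervention, rng=rng,
                                   **kwargs)
            n_plus += res.n_plus
            n_minus += res.n_minus
        pis[b] = (n_plus - n_minus) / (n_plus + n_minus)
    return pis


#: blocking default learning rate; the compound stimulus doubles sum(k) to 20,
#: so eta must sit at or below the averaging bound 1/(2*20) scaled to the
#: single-stimulus phases: 0.025 keeps the compound phase stable.
ETA_BLOCKING = 0.025


def run_blocking(p_cor_x: float = 0.0, p_cor_y: float = 0.0,
                 eta: float = ETA_BLOCKING, beta: float = BETA_DEFAULT,
                 gamma: float = 1.0, sigma_r: float = 0.1,
                 rng: Optional[np.random.Generator] = None,
                 mv_form: str = "dan_diff",
                 frozen_corruption: bool = False) -> dict:
    """One blocking run with the MV model.

    Phase 1: 10 forced X trials, rewards ~ N(1, sigma_r).  Phase 2: 10 forced
    compound XY trials with each component independently corrupted (redrawn
    every trial unless ``frozen_corruption``) and then summed, same rewards.
    Phase 3: two softmax choices between the uncorrupted Y and a null option
    with a fixed RP of 0; rewards ~ N(0, sigma_r); choosing null updates
    nothing.  Returns the mean test-phase RP for Y, its per-trial values, and
    the test choice counts (n_plus counts Y choices).
    """
    if rng is None:
        rng = np.random.default_rng()
    enc = blocking_encoding()
    state = CircuitState.random(enc.n_kc, rng, gamma=gamma, variant="MV")
    pconfig = PlasticityConfig(eta=eta, mv_form=mv_form)
    resp_x, resp_y = enc.response(0), enc.response(1)
    sub_x, sub_y = enc.subsets

    for _ in range(10):
        reinf = draw_reinforcement(1.0, sigma_r, rng)
        state, _ = run_trial(state, resp_x, reinf, pconfig, stage="X")

    if frozen_corruption:
        cx = corrupt_response(resp_x, sub_x, p_cor_x, rng)
        cy = corrupt_response(resp_y, sub_y, p_cor_y, rng)
    for _ in range(10):
        if not frozen_corruption:
            cx = corrupt_response(resp_x, sub_x, p_cor_x, rng)
            cy = corrupt_response(resp_y, sub_y, p_cor_y, rng)
        reinf = draw_reinforcement(1.0, sigma_r, rng)
        state, _ = run_trial(state, compound_response(cx, cy), reinf, pconfig,
                             stage="XY")

    n_plus = n_minus = 0
    y_rps = []
    for _ in range(2):
        m_hat_y = mbon_rates(state, resp_y)[2]
        y_rps.append(m_hat_y)
        dist = choice_probabilities(np.array([m_hat_y, 0.0]), beta)
        q = sample_choice(dist, rng)
        if q == 0:
            n_plus += 1
            reinf = draw_reinforcement(0.0, sigma_r, rng)
            state, _ = run_trial(state, resp_y, reinf, pconfig, stage="test")
        else:
            n_minus += 1
    return {
        "y_rp_mean": float(np.mean(y_rps)),
        "y_rps": y_rps,
        "n_plus": n_plus,
        "n_minus": n_minus,
        "final_state": state,
    }


def blocking_batches(p_cor_x: float, p_cor_y: float,
                     n_batches: int = N_BATCHES_DEFAULT,
                     runs_per_batch: int = RUNS_PER_BATCH_DEFAULT,
                     rng: Optional[np.random.Generator] = None,
                     **kwargs):
    """Batch PIs (Y vs null) and per-run mean test-phase Y RPs."""
    if rng is None:
        rng = np.random.default_rng()
    pis = np.empty(n_batches)
    y_rps = []
    for b in range(n_batches):
        n_plus = n_minus = 0
        for _ in range(runs_per_batch):
            out = run_blocking(p_cor_x, p_cor_y, rng=rng, **kwargs)
            n_plus += out["n_plus"]
            n_minus += out["n_minus"]
            y_rps.append(out["y_rp_mean"])
        pis[b] = (n_plus - n_minus) / (n_plus + n_minus)
    return pis, np.array(y_rps)
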