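"""Delta-rule plasticity at KC->MBON synapses.

Each rule is the negative gradient of a cost on the reinforcement prediction
error, expressed through DAN firing rates so that it is biologically local:

RPE rule        P+- = eta * k * (d+- - d-+)
VS rule         P+- = eta * k * (gamma*sum(k) - d-+)
VSlambda rule   P+- = eta * k * (lambda - d-+)
VSu-B rule      P+- = eta * k * (d+- - gamma*sum(k))
MV, dan_diff    P+- = (eta/2) * k * (d+- - d-+)
MV, kc_ref      P+- = eta * k * (gamma*sum(k) - d-+)

The 1/2 in the MV dan_diff form absorbs the factor of 2 that the MV circuit
puts into its DAN difference, so the same eta produces weight updates of the
same magnitude as the VS-family rules; eta is therefore never halved a second
time.  Updates apply only to the chosen cue's synapses (enforced by the cue's
KC vector being zero elsewhere) and weights are clipped at zero afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .circuit import CircuitState, rectify

__all__ = [
    "PlasticityConfig",
    "cost_rpe",
    "cost_vs",
    "delta_rpe",
    "delta_vs",
    "delta_vslambda",
    "delta_vsu_b",
    "delta_mv",
    "increments",
    "update_weights",
    "stability_bound",
]

RULES = ("RPE", "VS", "VSlambda", "VSu-B", "MV_dan_diff", "MV_kc_ref")

#: default learning rates used by the reference protocols
ETA_STEP = 0.025     # step-schedule demonstrations
ETA_MAFC = 0.1       # multi-alternative forced choice
ETA_CONDITIONING = 0.05  # conditioning / blocking


@dataclass
class PlasticityConfig:
    """Learning-rate and rule selection for a run.

    ``rule=None`` selects the canonical rule for the circuit variant
    (VS->VS, VSlambda->VSlambda, VSu-A->VS, VSu-B->VSu-B, MV->MV_dan_diff).
    """

    eta: float = ETA_STEP
    rule: Optional[str] = None
    lam: Optional[float] = None
    mv_form: str = "dan_diff"

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.rule is not None and self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}")
        if self.mv_form not in ("dan_diff", "kc_ref"):
            raise ValueError("mv_form must be 'dan_diff' or 'kc_ref'")

    def warn_if_unstable(self, kc: np.ndarray) -> None:
        """Warn when eta reaches the averaging bound 1/(2*sum(k))."""
        total = float(np.sum(kc))
        if total > 0 and self.eta >= 1.0 / (2.0 * total):
            warnings.warn(
                f"eta={self.eta} >= 1/(2*sum(k))={1.0 / (2.0 * total):.4g}: "
                "updates no longer average over reinforcement noise",
                stacklevel=2,
            )


def cost_rpe(r_hat, m_hat) -> float:
    """Squared-RPE cost 0.5 * sum_i (r_hat_i - m_hat_i)^2 (diagnostic only)."""
    r_hat = np.asarray(r_hat, dtype=float)
    m_hat = np.asarray(m_hat, dtype=float)
    if r_hat.shape != m_hat.shape:
        raise ValueError("r_hat and m_hat must have equal length")
    return 0.5 * float(np.sum((r_hat - m_hat) ** 2))


def cost_vs(r_opp, m) -> float:
    """Valence-specific cost 0.5 * sum_i (r_opp_i + m_i)^2 (diagnostic only)."""
    r_opp = np.asarray(r_opp, dtype=float)
    m = np.asarray(m, dtype=float)
    if r_opp.shape != m.shape:
        raise ValueError("inputs must have equal length")
    return 0.5 * float(np.sum((r_opp + m) ** 2))


def delta_rpe(kc, d_plus: float, d_minus: float, eta: float, valence: str = "+"):
    """RPE-rule increment eta * k * (d_val - d_opp)."""
    kc = np.asarray(kc, dtype=float)
    drive = (d_plus - d_minus) if valence == "+" else (d_minus - d_plus)
    return eta * kc * drive


def delta_vs(kc, d_opp: float, eta: float, gamma: float):
    """VS-rule increment eta * k * (gamma*sum(k) - d_opp)."""
    kc = np.asarray(kc, dtype=float)
    return eta * kc * (gamma * float(np.sum(kc)) - d_opp)


def delta_vslambda(kc, d_opp: float, eta: float, lam: float):
    """VSlambda increment eta * k * (lambda - d_opp)."""
    kc = np.asarray(kc, dtype=float)
    return eta * kc * (lam - d_opp)


def delta_vsu_b(kc, d_same: float, eta: float, gamma: float):
    """Dual-circuit potentiation increment eta * k * (d_same - gamma*sum(k)).

    In the VSu-B wiring the same-valence DAN drives potentiation when it
    fires above its KC-input baseline.
    """
    kc = np.asarray(kc, dtype=float)
    return eta * kc * (d_same - gamma * float(np.sum(kc)))


def delta_mv(kc, d_plus: float, d_minus: float, eta: float, gamma: float,
             form: str = "dan_diff", valence: str = "+"):
    """MV-rule increment in either the DAN-difference or KC-reference form."""
    kc = np.asarray(kc, dtype=float)
    if form == "dan_diff":
        drive = (d_plus - d_minus) if valence == "+" else (d_minus - d_plus)
        return 0.5 * eta * kc * drive
    if form == "kc_ref":
        d_opp = d_minus if valence == "+" else d_plus
        return eta * kc * (gamma * float(np.sum(kc)) - d_opp)
    raise ValueError("form must be 'dan_diff' or 'kc_ref'")


def increments(state: CircuitState, kc, d_plus: float, d_minus: float,
               config: PlasticityConfig):
    """Weight increments (dw_plus, dw_minus) for the chosen cue.

    Dispatches on ``config.rule`` or, when that is None, the canonical rule
    for ``state.variant``.
    """
    rule = config.rule
    if rule is None:
        rule = {
            "VS": "VS",
            "VSlambda": "VSlambda",
            "VSu-A": "VS",
            "VSu-B": "VSu-B",
            "MV": "MV_dan_diff" if config.mv_form == "dan_diff" else "MV_kc_ref",
        }[state.variant]
    eta, gamma = config.eta, state.gamma
    if rule == "RPE":
        return (delta_rpe(kc, d_plus, d_minus, eta, "+"),
                delta_rpe(kc, d_plus, d_minus, eta, "-"))
    if rule == "VS":
        return (delta_vs(kc, d_minus, eta, gamma),
                delta_vs(kc, d_plus, eta, gamma))
    if rule == "VSlambda":
        lam = config.lam if config.lam is not None else state.lam
        if lam is None:
            raise ValueError("VSlambda rule requires lam")
        return (delta_vslambda(kc, d_minus, eta, lam),
                delta_vslambda(kc, d_plus, eta, lam))
    if rule == "VSu-B":
        return (delta_vsu_b(kc, d_plus, eta, gamma),
                delta_vsu_b(kc, d_minus, eta, gamma))
    if rule == "MV_dan_diff":
        return (delta_mv(kc, d_plus, d_minus, eta, gamma, "dan_diff", "+"),
                delta_mv(kc, d_plus, d_minus, eta, gamma, "dan_diff", "-"))
    if rule == "MV_kc_ref":
        return (delta_mv(kc, d_plus, d_minus, eta, gamma, "kc_ref", "+"),
                delta_mv(kc, d_plus, d_minus, eta, gamma, "kc_ref", "-"))
    raise ValueError(f"unknown rule {rule!r}")


def update_weights(state: CircuitState, inc_plus, inc_minus) -> CircuitState:
    """Apply increments and clip weights at zero (in place on a copy)."""
    new = state.copy()
    new.w_plus = rectify(new.w_plus + inc_plus)
    new.w_minus = rectify(new.w_minus + inc_minus)
    return new


def stability_bound(kc) -> float:
    """Largest eta that still averages over trials: 1 / (2 * sum(k))."""
    total = float(np.sum(np.asarray(kc, dtype=float)))
    if total <= 0:
        raise ValueError("sum of KC rates must be > 0")
    return 1.0 / (2.0 * total)
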