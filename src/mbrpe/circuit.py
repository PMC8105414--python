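"""Rate equations for the mushroom-body circuit and its variants.

The model reduces the mushroom body to one rate unit per cell class: a
population of Kenyon cells (KCs) carrying the sensory cue, two mushroom body
output neurons (MBONs; M+ biases approach, M- avoidance) read the KCs through
plastic weights, and two dopamine neurons (DANs; D+ appetitive-class, D-
aversive-class) combine feedforward reinforcement with feedback from the
MBONs.  The difference in MBON rates, m_hat = m+ - m-, is the circuit's
reinforcement prediction (RP); the difference in DAN rates signals the
reinforcement prediction error (RPE).

Five wiring variants are implemented:

``VS``        valence-specific: D+- = f(r+- + w_M*m-+ + gamma*sum(k))
``VSlambda``  same rates as VS; differs only in the plasticity rule
``VSu-A``     unbounded VS: reinforcement *inhibits* the opposite DAN,
              d+- = f(-r-+ + w_M*m-+ + gamma*sum(k))
``VSu-B``     dual unbounded VS: same-valence excitation with inhibitory
              same-valence feedback, d+- = f(r+- - w_M*m+- + gamma*sum(k))
``MV``        mixed-valence: every DAN sees both reinforcement valences and
              both feedback signs, d+- = f(+-(r_hat) -+ w_M*m_hat + gamma*sum(k))

All rates are plain nonnegative scalars; "Hz" is nominal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "VARIANTS",
    "CircuitState",
    "NeuronRates",
    "Reinforcement",
    "InterventionSpec",
    "rectify",
    "init_weights",
    "mbon_rates",
    "dan_rates",
    "rpe_from_dans",
    "apply_intervention",
]

VARIANTS = ("VS", "VSlambda", "VSu-A", "VSu-B", "MV")

#: multiplicative factor emulating a shibire-style output block
BLOCK_SCALE = 0.1
#: additive current (rate units) emulating dTrpA1-style activation
ACTIVATE_OFFSET = 5.0

_VARIANT_ALIASES = {
    "vs": "VS",
    "vslambda": "VSlambda",
    "vsl": "VSlambda",
    "vsu-a": "VSu-A",
    "vsua": "VSu-A",
    "vsu-b": "VSu-B",
    "vsub": "VSu-B",
    "mv": "MV",
}


def canonical_variant(name: str) -> str:
    """Normalise a variant name, raising ``ValueError`` for unknown ones."""
    key = name.replace("_", "-").lower()
    if key not in _VARIANT_ALIASES:
        raise ValueError(f"unknown model variant {name!r}; expected one of {VARIANTS}")
    return _VARIANT_ALIASES[key]


def rectify(z):
    """Rectifying nonlinearity f(z) = max(0, z), elementwise."""
    return np.maximum(0.0, z)


def init_weights(n_kc: int, rng: np.random.Generator) -> np.ndarray:
    """Initial KC->MBON weights, 0.1 * Uniform(0, 1) per synapse."""
    return 0.1 * rng.uniform(0.0, 1.0, size=n_kc)


@dataclass
class CircuitState:
    """Plastic weights plus fixed parameters for one simulated fly.

    Parameters
    ----------
    w_plus, w_minus
        KC->M+ and KC->M- synaptic weight vectors (dimensionless, >= 0).
    gamma
        KC->DAN weight; the full weight vector is w_K = gamma * ones.
    w_m
        MBON->DAN feedback weight (1 throughout the reference simulations).
    lam
        Constant potentiation target lambda (VSlambda plasticity only).
    variant
        One of :data:`VARIANTS`.
    """

    w_plus: np.ndarray
    w_minus: np.ndarray
    gamma: float = 1.0
    w_m: float = 1.0
    lam: Optional[float] = None
    variant: str = "VS"

    def __post_init__(self):
        self.variant = canonical_variant(self.variant)
        self.w_plus = np.asarray(self.w_plus, dtype=float)
        self.w_minus = np.asarray(self.w_minus, dtype=float)
        if self.w_plus.shape != self.w_minus.shape:
            raise ValueError("w_plus and w_minus must have the same length")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if np.any(self.w_plus < 0) or np.any(self.w_minus < 0):
            raise ValueError("synaptic weights must be nonnegative")
        if self.variant == "VSlambda" and self.lam is None:
            raise ValueError("VSlambda requires lam")

    @property
    def n_kc(self) -> int:
        return self.w_plus.size

    def copy(self) -> "CircuitState":
        return replace(self, w_plus=self.w_plus.copy(), w_minus=self.w_minus.copy())

    @classmethod
    def random(cls, n_kc: int, rng: np.random.Generator, **kwargs) -> "CircuitState":
        """State with the standard random weight initialisation."""
        return cls(init_weights(n_kc, rng), init_weights(n_kc, rng), **kwargs)


@dataclass(frozen=True)
class NeuronRates:
    """Firing rates for one cue presentation (all rectified, >= 0)."""

    m_plus: float
    m_minus: float
    d_plus: float
    d_minus: float

    @property
    def m_hat(self) -> float:
        """Net reinforcement prediction m+ - m-."""
        return self.m_plus - self.m_minus

    @property
    def d_hat(self) -> float:
        """DAN rate difference d+ - d- (the RPE signal)."""
        return self.d_plus - self.d_minus


@dataclass(frozen=True)
class Reinforcement:
    """One trial's reinforcement, split into nonnegative valence channels.

    ``r`` is the signed draw; ``r_plus = max(0, r)`` and ``r_minus`` is the
    *magnitude* of the negative part, so that ``r_hat = r_plus - r_minus = r``.
    """

    r: float

    @property
    def r_plus(self) -> float:
        return max(0.0, self.r)

    @property
    def r_minus(self) -> float:
        return max(0.0, -self.r)

    @property
    def r_hat(self) -> float:
        return self.r


NEUTRAL_REINFORCEMENT = Reinforcement(0.0)

_TARGETS = ("M+", "M-", "D+", "D-")
_KINDS = ("block", "activate", "none")
_SCHEDULES = ("CS+", "training", "test", "all")
#: protocol stages covered by each intervention schedule
_SCHEDULE_STAGES = {
    "CS+": frozenset({"CS+"}),
    "training": frozenset({"CS+", "CS-"}),
    "test": frozenset({"test"}),
    "all": frozenset({"CS+", "CS-", "test"}),
}


@dataclass(frozen=True)
class InterventionSpec:
    """A genetic-tool intervention: which neuron, what, and when.

    ``block`` rescales the target neuron's output rate by 0.1 (shibire-style
    synaptic block); ``activate`` adds a constant 5 rate units (dTrpA1-style
    depolarising current).  The modified output is consumed everywhere the
    neuron's output is used during the scheduled stages: decision making,
    feedback to DANs, and plasticity.
    """

    target: str = "M+"
    kind: str = "none"
    schedule: str = "training"

    def __post_init__(self):
        if self.target not in _TARGETS:
            raise ValueError(f"target must be one of {_TARGETS}")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.schedule not in _SCHEDULES:
            raise ValueError(f"schedule must be one of {_SCHEDULES}")

    def active(self, stage: str) -> bool:
        return self.kind != "none" and stage in _SCHEDULE_STAGES[self.schedule]

    @classmethod
    def parse(cls, text: str) -> "InterventionSpec":
        """Parse a ``target:kind:schedule`` string, e.g. ``"M+:block:training"``."""
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError("intervention spec must be 'target:kind:schedule'")
        return cls(target=parts[0], kind=parts[1], schedule=parts[2])


NO_INTERVENTION = InterventionSpec(kind="none")


def apply_intervention(rate: float, spec: InterventionSpec, stage: str,
                       neuron: Optional[str] = None) -> float:
    """Return the target neuron's modified output rate for this stage.

    If ``neuron`` is given, the modification only applies when it matches
    ``spec.target``; rates of untargeted neurons pass through unchanged.
    """
    if neuron is not None and neuron != spec.target:
        return rate
    if not spec.active(stage):
        return rate
    if spec.kind == "block":
        return BLOCK_SCALE * rate
    return rate + ACTIVATE_OFFSET


def mbon_rates(state: CircuitState, kc: np.ndarray):
    """MBON rates m+- = f(w+-^T k) and the RP m_hat for one cue.

    Parameters
    ----------
    state : CircuitState
    kc : array of KC firing rates for the presented cue (length n_kc, >= 0)

    Returns
    -------
    (m_plus, m_minus, m_hat)
    """
    kc = np.asarray(kc, dtype=float)
    if kc.shape != state.w_plus.shape:
        raise ValueError(
            f"KC vector length {kc.size} does not match weight length {state.n_kc}"
        )
    m_plus = float(rectify(state.w_plus @ kc))
    m_minus = float(rectify(state.w_minus @ kc))
    return m_plus, m_minus, m_plus - m_minus


def dan_rates(state: CircuitState, m_plus: float, m_minus: float,
              reinf: Reinforcement, kc: np.ndarray):
    """DAN rates (d+, d-) for the chosen cue, dispatched on the wiring variant.

    ``m_plus``/``m_minus`` are the (already rectified, possibly
    intervention-modified) MBON output rates fed back to the DANs.
    """
    kc_drive = state.gamma * float(np.sum(kc))
    wm = state.w_m
    rp, rm = reinf.r_plus, reinf.r_minus
    v = state.variant
    if v in ("VS", "VSlambda"):
        d_plus = rp + wm * m_minus + kc_drive
        d_minus = rm + wm * m_plus + kc_drive
    elif v == "VSu-A":
        # reinforcement inhibits the opposite-valence DAN
        d_plus = -rm + wm * m_minus + kc_drive
        d_minus = -rp + wm * m_plus + kc_drive
    elif v == "VSu-B":
        # same-valence excitation, inhibitory same-valence feedback
        d_plus = rp - wm * m_plus + kc_drive
        d_minus = rm - wm * m_minus + kc_drive
    elif v == "MV":
        m_hat = m_plus - m_minus
        d_plus = rp - rm - wm * m_hat + kc_drive
        d_minus = rm - rp + wm * m_hat + kc_drive
    else:  # pragma: no cover - guarded by canonical_variant
        raise ValueError(f"unknown variant {v!r}")
    return float(rectify(d_plus)), float(rectify(d_minus))


def rpe_from_dans(d_plus: float, d_minus: float, variant: str = "VS") -> float:
    """DAN difference d_hat = d+ - d-.

    Whenever neither DAN is clipped by rectification this equals r_hat - m_hat
    for the VS-family circuits and 2*(r_hat - m_hat) for the MV circuit; when
    one MV DAN is clipped it equals
    (r_hat - m_hat) + sgn(r_hat - m_hat) * min(|r_hat - m_hat|, gamma*sum(k)).
    """
    if d_plus < 0 or d_minus < 0:
        raise ValueError("DAN rates must be nonnegative (rectified)")
    return d_plus - d_minus
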