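"""Softmax decision making over reinforcement predictions.

The probability of choosing cue i among the available options is
p(i) = exp(beta * m_hat_i) / sum_j exp(beta * m_hat_j), where beta is the
inverse temperature.  beta = 0 yields uniform choice; beta = inf yields a
deterministic argmax with uniform tie-breaking.  Sampling uses the standard
inverse-CDF rule: the chosen index is the smallest q whose cumulative
probability reaches a uniform draw xi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChoiceDistribution", "choice_probabilities", "sample_choice"]

BETA_DEFAULT = 3.0


@dataclass(frozen=True)
class ChoiceDistribution:
    probs: np.ndarray
    beta: float

    def __post_init__(self):
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        p = self.probs
        if p.size == 0:
            raise ValueError("empty choice distribution")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probs must be nonnegative and sum to 1")


def choice_probabilities(m_hat, beta: float = BETA_DEFAULT) -> ChoiceDistribution:
    """Softmax over the available cues' RPs (overflow-safe).

    Invariant to adding a constant to every RP.  ``beta = inf`` puts equal
    mass on the argmax set and zero elsewhere.
    """
    m_hat = np.asarray(m_hat, dtype=float)
    if m_hat.size == 0:
        raise ValueError("at least one cue must be available")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if np.isinf(beta):
        best = m_hat == m_hat.max()
        probs = best / best.sum()
    else:
        z = beta * m_hat
        z -= z.max()
        e = np.exp(z)
        probs = e / e.sum()
    return ChoiceDistribution(probs, beta)


def sample_choice(dist: ChoiceDistribution, rng: np.random.Generator) -> int:
    """Inverse-CDF sample: smallest q with cumsum(p)[q] >= xi, xi ~ U(0, 1)."""
    xi = rng.uniform()
    cdf = np.cumsum(dist.probs)
    cdf[-1] = 1.0  # guard against rounding shortfall
    return int(np.searchsorted(cdf, xi, side="left"))
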