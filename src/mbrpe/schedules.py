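"""Reinforcement schedules: per-cue means over trials and per-trial draws.

Reinforcements are scalar and signed; on each trial the delivered value is
r ~ Normal(mu_i(t), sigma_R) for the chosen cue i, split into a reward
magnitude r+ = max(0, r) and a punishment magnitude r- = max(0, -r) so that
r+ - r- recovers the signed draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import Reinforcement

__all__ = [
    "ReinforcementSchedule",
    "step_schedule",
    "filtered_noise_schedule",
    "draw_reinforcement",
]

SIGMA_R_DEFAULT = 0.1


@dataclass
class ReinforcementSchedule:
    """Per-cue mean reinforcement over trials.

    ``mu`` has shape (n_trials, n_cues); ``sigma_r`` is the s.d. of the
    per-trial Gaussian noise added when a reinforcement is drawn.
    """

    mu: np.ndarray
    sigma_r: float = SIGMA_R_DEFAULT

    def __post_init__(self):
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        if self.sigma_r < 0:
            raise ValueError("sigma_r must be >= 0")
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("mu must be finite")

    @property
    def n_trials(self) -> int:
        return self.mu.shape[0]

    @property
    def n_cues(self) -> int:
        return self.mu.shape[1]

    def to_csv(self) -> str:
        lines = ["trial,cue,mu"]
        for t in range(self.n_trials):
            for c in range(self.n_cues):
                lines.append(f"{t + 1},{c},{self.mu[t, c]:.12g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_csv(cls, text: str, sigma_r: float = SIGMA_R_DEFAULT):
        rows = [line.split(",") for line in text.strip().splitlines()[1:]]
        n_trials = max(int(r[0]) for r in rows)
        n_cues = max(int(r[1]) for r in rows) + 1
        mu = np.zeros((n_trials, n_cues))
        for r in rows:
            mu[int(r[0]) - 1, int(r[1])] = float(r[2])
        return cls(mu, sigma_r)


#: step-schedule change points (1-indexed trials) and step signs
_STEP_UP = (21, 41, 141, 161)
_STEP_DOWN = (61, 81, 101, 121)


def step_schedule(sigma_r: float = SIGMA_R_DEFAULT) -> ReinforcementSchedule:
    """Single-cue, 180-trial staircase: mu levels 0,1,2,1,0,-1,-2,-1,0.

    Starts at 0 for 20 trials, with cumulative +1 steps at trials 21, 41, 141,
    161 and -1 steps at trials 61, 81, 101, 121.
    """
    mu = np.zeros(180)
    for t in _STEP_UP:
        mu[t - 1:] += 1.0
    for t in _STEP_DOWN:
        mu[t - 1:] -= 1.0
    return ReinforcementSchedule(mu[:, None], sigma_r)


def _circular_gaussian_kernel(n: int, tau: float) -> np.ndarray:
    """Unit-area Gaussian kernel (s.d. tau) on a circular grid of length n."""
    pos = np.arange(n, dtype=float)
    dist = np.minimum(pos, n - pos)
    kernel = np.exp(-0.5 * (dist / tau) ** 2)
    return kernel / kernel.sum()


def filtered_noise_schedule(n_cues: int, n_trials: int = 200, tau: float = 10.0,
                            sigma_r: float = SIGMA_R_DEFAULT,
                            rng: np.random.Generator | None = None,
                            amplitude: float = 2.0) -> ReinforcementSchedule:
    """Slowly drifting schedule: low-pass-filtered white noise per cue.

    Per cue, 250 samples of unit white Gaussian noise are circularly convolved
    (via the frequency domain) with a unit-area Gaussian kernel of s.d. ``tau``
    trials; the first 50 samples are discarded as burn-in and the trace is
    scaled by A = amplitude / max_t(g) so the retained trace peaks at
    ``amplitude`` exactly.  The per-trial noise term sigma_r * xi(t) is folded
    directly into mu, so the returned schedule carries ``sigma_r = 0`` and
    drawing from it reproduces mu exactly.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    burn_in = 50
    n_gen = n_trials + burn_in
    if n_trials > 200:
        n_gen = n_trials + burn_in  # generate longer traces for longer tasks
    if rng is None:
        rng = np.random.default_rng()
    kernel = _circular_gaussian_kernel(n_gen, tau)
    mu = np.zeros((n_trials, n_cues))
    for c in range(n_cues):
        xi = rng.standard_normal(n_gen)
        g = np.fft.irfft(np.fft.rfft(xi) * np.fft.rfft(kernel), n=n_gen)
        g = g[burn_in:burn_in + n_trials]
        a = amplitude / np.max(g)
        mu[:, c] = a * g + sigma_r * rng.standard_normal(n_trials)
    return ReinforcementSchedule(mu, sigma_r=0.0)


def draw_reinforcement(mu_t: float, sigma_r: float,
                       rng: np.random.Generator) -> Reinforcement:
    """Draw r ~ Normal(mu_t, sigma_r) and split it into valence channels."""
    r = mu_t if sigma_r == 0 else mu_t + sigma_r * rng.standard_normal()
    return Reinforcement(float(r))
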