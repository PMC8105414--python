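"""Kenyon-cell responses per cue, and the blocking-paradigm stimulus operators.

Two coding schemes are provided.  Dedicated coding assigns a disjoint block of
10 KCs per cue, each firing at 1 Hz when its cue is shown (N_K = 10 * N_c).
Random-sparse coding assigns each of 2000 KCs to each cue with probability
p = 0.05 and rescales every cue's response so its total rate is 10 Hz, which
keeps the rate-dependent learning speed identical across coding schemes.

For the blocking paradigm each stimulus owns a 20-KC subset with 10 cells
active at 1 Hz; corruption silences active cells with probability p_cor and
re-activates an equal number of silent cells of the same subset, so the active
count and the subset membership are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np

__all__ = [
    "CueEncoding",
    "assign_dedicated",
    "assign_random",
    "blocking_encoding",
    "corrupt_response",
    "compound_response",
]

logger = logging.getLogger(__name__)

DEDICATED_KC_PER_CUE = 10
DEDICATED_RATE = 1.0  # Hz
RANDOM_N_KC = 2000
RANDOM_P = 0.05
TOTAL_RATE = 10.0  # Hz, normalisation target per cue


@dataclass
class CueEncoding:
    """Per-cue KC firing-rate vectors.

    ``responses`` has shape (n_cues, n_kc); ``subsets`` lists, per cue, the
    indices of KCs assignable to that cue (for dedicated coding, its block).
    """

    responses: np.ndarray
    subsets: List[np.ndarray]

    @property
    def n_cues(self) -> int:
        return self.responses.shape[0]

    @property
    def n_kc(self) -> int:
        return self.responses.shape[1]

    def response(self, cue: int) -> np.ndarray:
        return self.responses[cue]

    def to_text(self) -> str:
        """Tab-separated cues x KCs matrix."""
        return "\n".join(
            "\t".join(f"{v:.12g}" for v in row) for row in self.responses
        )

    @classmethod
    def from_text(cls, text: str) -> "CueEncoding":
        rows = [
            [float(v) for v in line.split("\t")]
            for line in text.strip().splitlines()
        ]
        responses = np.asarray(rows, dtype=float)
        subsets = [np.flatnonzero(r > 0) for r in responses]
        return cls(responses, subsets)


def assign_dedicated(n_cues: int) -> CueEncoding:
    """Disjoint blocks of 10 KCs at 1 Hz per cue (N_K = 10 * n_cues)."""
    if n_cues < 1:
        raise ValueError("n_cues must be >= 1")
    n_kc = DEDICATED_KC_PER_CUE * n_cues
    responses = np.zeros((n_cues, n_kc))
    subsets = []
    for i in range(n_cues):
        idx = np.arange(i * DEDICATED_KC_PER_CUE, (i + 1) * DEDICATED_KC_PER_CUE)
        responses[i, idx] = DEDICATED_RATE
        subsets.append(idx)
    return CueEncoding(responses, subsets)


def assign_random(n_cues: int, n_kc: int = RANDOM_N_KC, p: float = RANDOM_P,
                  rng: np.random.Generator | None = None) -> CueEncoding:
    """Random-sparse coding: Bernoulli(p) membership, total rate 10 Hz per cue.

    A cue that draws zero members is resampled (and the event logged).
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    responses = np.zeros((n_cues, n_kc))
    subsets = []
    for i in range(n_cues):
        member = rng.random(n_kc) < p
        while not member.any():
            logger.warning("cue %d drew no KCs; resampling", i)
            member = rng.random(n_kc) < p
        rate = TOTAL_RATE / member.sum()
        responses[i, member] = rate
        subsets.append(np.flatnonzero(member))
    return CueEncoding(responses, subsets)


def blocking_encoding() -> CueEncoding:
    """Stimuli X and Y on disjoint 20-KC subsets, 10 cells active each."""
    n_kc = 40
    responses = np.zeros((2, n_kc))
    subsets = [np.arange(0, 20), np.arange(20, 40)]
    responses[0, 0:10] = DEDICATED_RATE
    responses[1, 20:30] = DEDICATED_RATE
    return CueEncoding(responses, subsets)


def corrupt_response(response: np.ndarray, subset: np.ndarray, p_cor: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Corrupt a stimulus response within its own KC subset.

    Each active KC is silenced independently with probability ``p_cor``; for
    every silenced cell one previously silent cell of the same subset is
    activated at 1 Hz (sampled without replacement).  The number of active
    cells, and their confinement to ``subset``, are both preserved.
    """
    if not 0.0 <= p_cor <= 1.0:
        raise ValueError("p_cor must be in [0, 1]")
    response = np.asarray(response, dtype=float)
    out = response.copy()
    active = subset[response[subset] > 0]
    silent = subset[response[subset] == 0]
    kill = active[rng.random(active.size) < p_cor]
    if kill.size > silent.size:
        raise ValueError("subset has too few silent cells to swap into")
    if kill.size:
        wake = rng.choice(silent, size=kill.size, replace=False)
        out[kill] = 0.0
        out[wake] = DEDICATED_RATE
    return out


def compound_response(resp_x: np.ndarray, resp_y: np.ndarray) -> np.ndarray:
    """Compound-stimulus response: elementwise sum of the component responses."""
    resp_x = np.asarray(resp_x, dtype=float)
    resp_y = np.asarray(resp_y, dtype=float)
    if resp_x.shape != resp_y.shape:
        raise ValueError("component responses must have the same length")
    return resp_x + resp_y
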