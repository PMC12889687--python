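"""Masked-resampling sequence generation and oracle-guided beam-search design.

Untargeted generation iteratively masks a fraction of positions and
resamples them from the model's temperature-scaled predictive distribution.
Targeted design wraps this proposal move in a beam search: each retained
sequence spawns candidates, a user objective scores the pool, and only the
top k survive. Parents compete with their children at retention, so the
best objective value is non-decreasing across steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import ALPHABET

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenerationConfig:
    """Masked-resampling parameters: iterations, mask rate, temperature."""

    n_iterations: int = 3
    mask_prob: float = 0.15
    temperature: float = 1.0

    def __post_init__(self):
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if not 0.0 <= self.mask_prob <= 1.0:
            raise ValueError("mask_prob must be in [0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class DesignConfig:
    """Beam-search parameters: outer steps, beam width, children per parent."""

    n_steps: int = 10
    keep: int = 5
    children_per_parent: int = 4

    def __post_init__(self):
        if self.n_steps < 1 or self.keep < 1 or self.children_per_parent < 1:
            raise ValueError("n_steps, keep and children_per_parent must be >= 1")


@dataclass
class BeamState:
    """Candidate pool with scores and the best-score trajectory."""

    pool: list[tuple[str, float]] = field(default_factory=list)
    step: int = 0
    trajectory: list[dict] = field(default_factory=list)

    @property
    def best(self) -> tuple[str, float]:
        return max(self.pool, key=lambda sc: sc[1])


def untargeted_generate(
    seq: str, config: GenerationConfig, model, rng: np.random.Generator
) -> str:
    """Iteratively mask and resample a sequence from the model.

    Each iteration masks every non-N token independently with probability
    ``mask_prob``, computes softmax(logits / temperature), and resamples only
    the masked positions. N positions are never masked or resampled; with
    ``mask_prob`` 0 or ``n_iterations`` 0 the input is returned unchanged.
    """
    tokens = ALPHABET.encode(seq)
    maskable = tokens != ALPHABET.N
    for _ in range(config.n_iterations):
        sel = maskable & (rng.random(len(tokens)) < config.mask_prob)
        if not sel.any():
            continue
        masked = tokens.copy()
        masked[sel] = ALPHABET.MASK
        logits = model.predict_logits(masked[None])[0] / config.temperature
        logits -= logits.max(-1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(-1, keepdims=True)
        for pos in np.flatnonzero(sel):
            tokens[pos] = rng.choice(4, p=probs[pos])
    return ALPHABET.decode(tokens)


def targeted_design(
    seed_seq: str,
    gen_config: GenerationConfig,
    design_config: DesignConfig,
    model,
    objective,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, float]], BeamState]:
    """Beam-search optimization of ``objective`` (higher is better).

    The pool starts as {seed}. Per step, every pool member spawns
    ``children_per_parent`` candidates via untargeted generation; candidates
    join the pool, the objective is applied to new members, and if the pool
    exceeds ``keep`` only the top-scoring sequences are retained (ties broken
    by earlier insertion). Objective failures discard the candidate with a
    logged reason. Returns the final top-k pool and the full trajectory.
    """
    state = BeamState(pool=[(seed_seq, float(objective(seed_seq)))])
    for step in range(design_config.n_steps):
        new: list[tuple[str, float]] = []
        for parent, _score in state.pool:
            for _ in range(design_config.children_per_parent):
                child = untargeted_generate(parent, gen_config, model, rng)
                try:
                    new.append((child, float(objective(child))))
                except Exception as exc:  # noqa: BLE001 - oracle contract
                    log.warning("objective failed on candidate: %s", exc)
        pool = state.pool + new
        if len(pool) > design_config.keep:
            order = sorted(range(len(pool)), key=lambda i: (-pool[i][1], i))
            pool = [pool[i] for i in order[: design_config.keep]]
        state.pool = pool
        state.step = step + 1
        best = state.best[1]
        if state.trajectory and best < state.trajectory[-1]["best_score"] - 1e-12:
            raise AssertionError("best-of-pool objective decreased; retention bug")
        state.trajectory.append(
            {"step": step, "best_score": best, "pool_size": len(pool)}
        )
    topk = sorted(state.pool, key=lambda sc: -sc[1])
    return topk, state


# ---------------------------------------------------------------------------
# Built-in objectives
# ---------------------------------------------------------------------------


class TargetValueObjective:
    """Minimize |g(S) - target| for a positive-valued oracle g (maximized as
    the negative absolute error)."""

    def __init__(self, oracle, target: float):
        self.oracle, self.target = oracle, target

    def __call__(self, seq: str) -> float:
        return -abs(float(self.oracle(seq)) - self.target)


class DifferentialObjective:
    """Maximize g1 while minimizing g2 as a weighted difference (cell-type
    specificity style objective)."""

    def __init__(self, oracle_up, oracle_down, weight: float = 1.0):
        self.oracle_up, self.oracle_down, self.weight = oracle_up, oracle_down, weight

    def __call__(self, seq: str) -> float:
        return float(self.oracle_up(seq)) - self.weight * float(self.oracle_down(seq))


class CentralWindowObjective:
    """Adapt an oracle expecting long inputs to design on a central window.

    The seed's flanks are frozen; candidates (length = editable window, e.g.
    350) are spliced into the center of the stored full-length sequence
    before the oracle is called.
    """

    def __init__(self, oracle, full_seq: str, window: int = 350):
        if len(full_seq) < window:
            raise ValueError("full sequence shorter than editable window")
        self.oracle = oracle
        self.full_seq = full_seq
        start = len(full_seq) // 2 - window // 2
        self.start, self.window = start, window

    def central_seed(self) -> str:
        return self.full_seq[self.start : self.start + self.window]

    def __call__(self, seq: str) -> float:
        if len(seq) != self.window:
            raise ValueError("candidate length must equal the editable window")
        full = (self.full_seq[: self.start] + seq
                + self.full_seq[self.start + self.window :])
        return float(self.oracle(full))


def write_trajectory_tsv(state: BeamState, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("step\tbest_score\tpool_size\tseed\n")
        for row in state.trajectory:
            fh.write(f"{row['step']}\t{row['best_score']:.6g}\t"
                     f"{row['pool_size']}\t{seed if seed is not None else 'NA'}\n")
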