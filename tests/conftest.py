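"""Shared fixtures: toy models and the (expensive) trained-model sweep.

The trained-model sweep fixture trains the tiny-preset model with and
without the Fourier prior across several matched seeds on the default
synthetic corpus; it is session-scoped because training is the dominant
cost of the suite, and the motif-recovery, variant-scoring, dependency and
design checks all consume the same models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from motiflm.nn import MaskedLM, ModelConfig, N_BASES
from motiflm.synth import SyntheticCorpusSpec, generate_corpus, make_variant_set
from motiflm.training import TrainingConfig, train_model

# Problem sizes for the trained-model sweep: the full default corpus with
# matched-seed prior/no-prior pairs; a short constant-rate schedule keeps the
# whole sweep tractable on one CPU.
N_SWEEP_SEEDS = 5
SWEEP_EPOCHS = 2
CORPUS_SEED = 20260301


class UniformModel:
    """Predicts 0.25 for every base everywhere; context length 350."""

    def __init__(self, context_length: int = 350):
        self.cfg = ModelConfig.tiny()
        self.cfg = replace_context(self.cfg, context_length)

    def predict_logits(self, tokens, batch_size: int = 64):
        tokens = np.asarray(tokens)
        return np.zeros((*tokens.shape, N_BASES))

    def predict_probs(self, tokens, batch_size: int = 64):
        tokens = np.asarray(tokens)
        return np.full((*tokens.shape, N_BASES), 0.25)


class TableModel:
    """Wraps an arbitrary tokens->probs function as a model."""

    def __init__(self, fn, context_length: int = 350):
        self.fn = fn
        self.cfg = replace_context(ModelConfig.tiny(), context_length)

    def predict_probs(self, tokens, batch_size: int = 64):
        tokens = np.asarray(tokens)
        if tokens.ndim == 1:
            tokens = tokens[None]
        return np.stack([self.fn(t) for t in tokens])

    def predict_logits(self, tokens, batch_size: int = 64):
        return np.log(np.maximum(self.predict_probs(tokens, batch_size), 1e-12))


def replace_context(cfg: ModelConfig, context_length: int) -> ModelConfig:
    import dataclasses

    return dataclasses.replace(cfg, context_length=context_length)


@dataclass
class TrainedSweep:
    records: list
    annotations: list
    variants: list
    prior: dict      # seed -> TrainResult
    no_prior: dict   # seed -> TrainResult
    stats: dict      # seed -> dict of reconstruction summaries


@pytest.fixture(scope="session")
def synthetic_corpus():
    rng = np.random.default_rng(CORPUS_SEED)
    records, annotations = generate_corpus(SyntheticCorpusSpec(), rng)
    variants = make_variant_set(records, annotations, (50, 50), rng)
    return records, annotations, variants


def reconstruction_stats(records, annotations, model, val_idx,
                         batch_size: int = 350):
    """Motif-vs-background mean p_norm and in-band spectral fraction over a
    fixed panel of validation sequences."""
    from motiflm.training import inband_fraction
    from motiflm.zeroshot import reconstruct_likelihoods

    motif_vals, bg_vals, fracs = [], [], []
    for i in val_idx:
        prof = reconstruct_likelihoods(records[i].seq, model,
                                       batch_size=batch_size)
        in_motif = np.zeros(len(records[i].seq), bool)
        for p in annotations[i]:
            in_motif[p.start:p.end] = True
        ok = np.isfinite(prof.p_norm)
        motif_vals.extend(prof.p_norm[in_motif & ok])
        bg_vals.extend(prof.p_norm[~in_motif & ok])
        fracs.append(inband_fraction(np.nan_to_num(prof.p_norm, nan=1.0)))
    return (float(np.mean(motif_vals)), float(np.mean(bg_vals)),
            float(np.mean(fracs)))


@pytest.fixture(scope="session")
def trained_sweep(synthetic_corpus) -> TrainedSweep:
    records, annotations, variants = synthetic_corpus
    val_idx = [i for i, r in enumerate(records)
               if r.split == "val" and annotations[i]][:3]
    prior, no_prior, stats = {}, {}, {}
    for seed in range(N_SWEEP_SEEDS):
        for flag, store in ((False, prior), (True, no_prior)):
            cfg = TrainingConfig.tiny(seed=seed, epochs=SWEEP_EPOCHS,
                                      no_prior=flag)
            store[seed] = train_model(records, ModelConfig.tiny(), cfg)
        m_p, b_p, f_p = reconstruction_stats(records, annotations,
                                             prior[seed].model, val_idx)
        _, _, f_n = reconstruction_stats(records, annotations,
                                         no_prior[seed].model, val_idx)
        stats[seed] = {"motif_pnorm": m_p, "bg_pnorm": b_p,
                       "inband_prior": f_p, "inband_no_prior": f_n}
    return TrainedSweep(records, annotations, variants, prior, no_prior, stats)


@pytest.fixture(scope="session")
def tiny_trained_model(trained_sweep) -> MaskedLM:
    """The seed-0 with-prior model, shared by downstream analyses."""
    return trained_sweep.prior[0].model


@pytest.fixture(scope="session")
def micro_model() -> MaskedLM:
    """An untrained micro model for fast mechanical checks."""
    return MaskedLM(ModelConfig.micro(context_length=64), seed=7)
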