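# motiflm

Masked language modeling of regulatory DNA at short (350 bp) context, with
a frequency-domain prior that steers the model toward transcription-factor
motif discovery — plus the zero-shot analysis suite built on the trained
model: per-base likelihood reconstruction, nucleotide dependency maps,
variant-effect scoring, long-sequence embeddings, and oracle-guided
sequence design.

## Who this is for

Regulatory genomics groups who want a compact, fully inspectable DNA
language model of cis-regulatory elements: promoters and enhancers act
through short (6–20 bp) binding motifs whose signal is easily drowned out
in genome-wide pretraining. This package trains only on regulatory windows
and regularizes the model's own likelihood landscape toward motif-scale
structure, then turns the pretrained model into analysis tools. Every stage
runs at desk scale on synthetic motif-planted corpora, so the whole
pipeline is testable without downloads; the same code ingests real
genome FASTA + BED input.

## The model and objective

A transformer encoder (rotary positions in all layers, pre-LayerNorm) maps
single-nucleotide tokens A/C/G/T/N/MASK to a 4-way distribution per
position. Training is standard masked language modeling — 15% of eligible
tokens selected, 80/10/10 masked/mutated/unchanged, N and soft-masked
repeat runs ≥ 30 bp excluded — plus a spectral prior on the per-position
profile p of the predicted probability of the original base. With a the
L1-normalized non-DC magnitude spectrum of p and band-pass weights w equal
to 1 between C_L = L/20 and C_H = L/6 cycles (decaying as 1/(1 + dist/s)
outside):

    L_att   = 1 − Σᵢ wᵢ aᵢ
    L_total = L_MLM + λ·L_att        (λ = 0.002, s = 5)

Profiles whose variation lives at motif scale (6–20 bp) score L_att ≈ 0;
flat or noise-dominated profiles are penalized. See `docs/methods.md` for
the complete treatment, including the analytic gradient and the
normalization p_norm = p/p̄_nuc used by the zero-shot analyses.

The implementation is pure numpy (explicit backpropagation, verified
against finite differences) with fused numba kernels for attention softmax
— no deep-learning framework required.

## Worked example

```python
import numpy as np
from motiflm import (SyntheticCorpusSpec, generate_corpus, make_variant_set,
                     ModelConfig, TrainingConfig, train_model,
                     reconstruct_likelihoods, llr_for_sequence)

rng = np.random.default_rng(0)
records, annotations = generate_corpus(SyntheticCorpusSpec(), rng)
variants = make_variant_set(records, annotations, (50, 50), rng)

result = train_model(records, ModelConfig.tiny(),
                     TrainingConfig.tiny(seed=0, epochs=2))
print(f"validation MLM loss: {result.log[-1]['val_mlm']:.4f}")

rec = next(r for i, r in enumerate(records)
           if r.split == "val" and annotations[i])
profile = reconstruct_likelihoods(rec.seq, result.model)
print(f"mean p_norm: {np.nanmean(profile.p_norm):.4f}")

v = variants[0]
seqs = {r.chrom: r.seq for r in records}
s = llr_for_sequence(seqs[v.seq_id], v.offset, v.ref, v.alt, result.model)
print(f"zero-shot LLR of a motif-disrupting variant: {s:+.3f}")
```

Output (one CPU, a few minutes):

```
validation MLM loss: 1.3534
mean p_norm: 1.0001
zero-shot LLR of a motif-disrupting variant: -0.048
```

The validation loss sits below the background-composition entropy (1.366
nats) once the model starts exploiting context; p_norm hovers around 1 by
construction (it is the per-base likelihood relative to that base's
sequence-wide average), rising inside learned motifs; and a variant that
destroys a planted motif receives a negative log-likelihood ratio — the
model finds the alternate allele less plausible than the reference.

A full end-to-end run (simulate → train with and without the prior →
reconstruction → dependency map → variant scoring → guided design) is one
command:

```bash
motiflm demo --seed 11 --out-dir runs/demo
```

which prints a JSON report including the in-band spectral fractions of the
two models, the variant-scoring AUROC, and the design trajectory summary.

## Command-line interface

`motiflm simulate | corpus | train | zeroshot | score | generate | demo`,
each with `--seed`, `--out-dir` and `--log-level`; every run writes a
`manifest.json` with the resolved configuration, seeds and SHA-256 digests
of inputs and outputs.
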