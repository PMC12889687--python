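"""Zero-shot likelihood analysis: reconstruction, normalization, dependencies.

Likelihood reconstruction masks each position in turn and predicts it from
the remaining context; the resulting per-position probability of the
observed base is normalized by that base's sequence-wide average predicted
probability (p_norm = p / p_bar_nuc). Nucleotide dependency maps quantify,
via unmasked substitution passes, how much the predicted odds of each base
at position j move when the base at position i is substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .nn import ALPHABET, N_BASES

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Likelihood reconstruction
# ---------------------------------------------------------------------------


@dataclass
class LikelihoodProfile:
    """Per-position reconstruction probabilities and normalized track.

    ``p_norm[i] = probs[i, b_i] / p_bar[b_i]`` where ``p_bar`` averages each
    base's predicted probability over all non-N positions. Entries at N
    positions are NaN (missing) and excluded from means.
    """

    seq: str
    probs: np.ndarray      # (L, 4) from iterated masking
    p_norm: np.ndarray     # (L,) with NaN at N positions
    p_bar: np.ndarray      # (4,) per-nucleotide mean predicted probability


def reconstruct_likelihoods(seq: str, model, batch_size: int = 128) -> LikelihoodProfile:
    """Iterated-masking probability profile of a sequence.

    Row i of ``probs`` comes from a forward pass in which only position i is
    replaced by MASK (L passes total, batched internally). The result is
    invariant to ``batch_size``.
    """
    tokens = ALPHABET.encode(seq)
    L = len(tokens)
    if L > model.cfg.context_length:
        raise ValueError("sequence exceeds model context length")
    masked = np.tile(tokens, (L, 1))
    masked[np.arange(L), np.arange(L)] = ALPHABET.MASK
    probs = np.empty((L, N_BASES), dtype=np.float64)
    for lo in range(0, L, batch_size):
        out = model.predict_probs(masked[lo : lo + batch_size])
        probs[lo : lo + batch_size] = out[np.arange(out.shape[0]),
                                          np.arange(lo, lo + out.shape[0])]
    p_norm, p_bar = normalize_profile(probs, seq)
    return LikelihoodProfile(seq, probs, p_norm, p_bar)


def normalize_profile(probs: np.ndarray, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Normalize observed-base probabilities by per-nucleotide averages.

    ``p_bar[k]`` is the mean of ``probs[:, k]`` over all non-N positions;
    ``p_norm[i] = probs[i, b_i] / p_bar[b_i]`` (NaN at N).
    """
    probs = np.asarray(probs, dtype=np.float64)
    tokens = ALPHABET.encode(seq)
    if probs.shape != (len(tokens), N_BASES):
        raise ValueError("probs shape does not match sequence length")
    if not np.allclose(probs.sum(-1), 1.0, atol=1e-4):
        raise ValueError("probs rows must be normalized")
    non_n = tokens != ALPHABET.N
    if not non_n.any():
        raise ValueError("sequence is all N")
    p_bar = probs[non_n].mean(axis=0)
    if np.any(p_bar < 1e-12):
        raise ValueError("degenerate model: per-nucleotide mean probability ~ 0")
    p_norm = np.full(len(tokens), np.nan)
    idx = np.flatnonzero(non_n)
    p_norm[idx] = probs[idx, tokens[idx]] / p_bar[tokens[idx]]
    return p_norm, p_bar


def contribution_track(profile: LikelihoodProfile, hypothetical: bool = False) -> np.ndarray:
    """(L, 4) signed contribution matrix for seqlet-based motif discovery.

    The observed base's channel carries ln(p_norm[i]); other channels are 0.
    With ``hypothetical`` the full matrix ln(probs[i, .] / p_bar) is returned
    instead (the all-base 'what-if' track). Missing p_norm entries become 0.
    """
    tokens = ALPHABET.encode(profile.seq)
    L = len(tokens)
    if hypothetical:
        return np.log(np.maximum(profile.probs, 1e-12) / profile.p_bar)
    track = np.zeros((L, N_BASES))
    missing = 0
    for i, tok in enumerate(tokens):
        if tok == ALPHABET.N or not np.isfinite(profile.p_norm[i]):
            missing += 1
            continue
        track[i, tok] = np.log(profile.p_norm[i])
    if missing:
        log.debug("contribution track: %d missing positions set to 0", missing)
    return track


def write_contributions_h5(profiles: list[LikelihoodProfile], path) -> None:
    """Contribution tracks + one-hot sequences in the layout seqlet tools read.

    Datasets: 'contrib_scores' and 'hypothetical_contrib_scores' of shape
    (N, L, 4), 'one_hot' of shape (N, L, 4). Column order A,C,G,T; the actual
    track is ln p_norm on the observed base, the hypothetical track is
    ln(probs / p_bar) on all bases (documented in the file attrs).
    """
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["column_order"] = "ACGT"
        fh.attrs["actual_track"] = "ln(p_norm) on observed base"
        fh.attrs["hypothetical_track"] = "ln(probs / p_bar) on all bases"
        contrib = np.stack([contribution_track(p) for p in profiles])
        hyp = np.stack([contribution_track(p, hypothetical=True) for p in profiles])
        onehot = np.stack([_one_hot(p.seq) for p in profiles])
        fh.create_dataset("contrib_scores", data=contrib)
        fh.create_dataset("hypothetical_contrib_scores", data=hyp)
        fh.create_dataset("one_hot", data=onehot)


def _one_hot(seq: str) -> np.ndarray:
    tokens = ALPHABET.encode(seq)
    out = np.zeros((len(tokens), N_BASES))
    idx = tokens < N_BASES
    out[np.flatnonzero(idx), tokens[idx]] = 1.0
    return out


def write_profile_bedgraph(profile: LikelihoodProfile, chrom: str,
                           start: int, path) -> None:
    """Genome-anchored p_norm track as bedGraph (missing positions skipped)."""
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name=p_norm\n")
        for i, v in enumerate(profile.p_norm):
            if np.isfinite(v):
                fh.write(f"{chrom}\t{start + i}\t{start + i + 1}\t{v:.6g}\n")


def write_profile_tsv(profile: LikelihoodProfile, path) -> None:
    """Sequence-anchored p_norm track as TSV (pos, base, pA..pT, p_norm)."""
    with open(path, "w") as fh:
        fh.write("pos\tbase\tp_A\tp_C\tp_G\tp_T\tp_norm\n")
        for i, b in enumerate(profile.seq):
            row = "\t".join(f"{x:.6g}" for x in profile.probs[i])
            pn = profile.p_norm[i]
            pn_s = f"{pn:.6g}" if np.isfinite(pn) else "NA"
            fh.write(f"{i}\t{b}\t{row}\t{pn_s}\n")


# ---------------------------------------------------------------------------
# Motif vs. shuffled-motif likelihood comparison
# ---------------------------------------------------------------------------


@dataclass
class MotifShuffleResult:
    span: tuple[int, int]
    observed: float                  # mean log p_norm over the span
    replicates: list[float]
    exceedance: float | None         # fraction of replicates observed exceeds


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Uniform random sequence preserving exact dinucleotide counts.

    Altschul-Erickson Eulerian-path shuffle: the multigraph of adjacent
    character pairs is traversed after drawing a random arborescence toward
    the terminal vertex, guaranteeing the shuffle is a valid Eulerian path
    with the same start and end characters.
    """
    if len(seq) < 3:
        return seq
    chars = list(seq)
    edges: dict[str, list[str]] = {}
    for a, b in zip(chars, chars[1:]):
        edges.setdefault(a, []).append(b)
    last = chars[-1]
    # draw last exit edge per vertex until they form a tree into `last`
    vertices = [v for v in edges if v != last]
    for _attempt in range(1000):
        last_edge = {v: edges[v][int(rng.integers(len(edges[v])))] for v in vertices}
        # connectivity check: every vertex must reach `last` via last_edge
        ok = True
        for v in vertices:
            seen, cur = set(), v
            while cur != last and cur in last_edge and cur not in seen:
                seen.add(cur)
                cur = last_edge[cur]
            if cur != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("failed to draw a connected arborescence")
    shuffled_edges = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        shuffled_edges[v] = rest + ([last_edge[v]] if v in last_edge else [])
    out = [chars[0]]
    counters = {v: 0 for v in shuffled_edges}
    cur = chars[0]
    for _ in range(len(chars) - 1):
        nxt = shuffled_edges[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def motif_vs_shuffle_score(
    seq: str,
    span: tuple[int, int],
    n_shuffles: int,
    rng: np.random.Generator,
    model,
) -> MotifShuffleResult:
    """Does the model assign higher likelihood to a motif than to its shuffles?

    The observed score is the mean log p_norm over the span; each replicate
    dinucleotide-shuffles only the span (context fixed), recomputes the full
    reconstruction profile and scores the same span. The exceedance fraction
    is the share of replicates the observed score strictly exceeds.
    """
    s, e = span
    if not (0 <= s < e <= len(seq)) or e - s < 2:
        raise ValueError("span must lie within the sequence and have length >= 2")
    observed = _span_score(seq, span, model)
    reps = []
    for _ in range(n_shuffles):
        shuf = dinucleotide_shuffle(seq[s:e], rng)
        if shuf == seq[s:e]:
            log.debug("degenerate shuffle equals the original span")
        reps.append(_span_score(seq[:s] + shuf + seq[e:], span, model))
    exceed = float(np.mean([observed > r for r in reps])) if reps else None
    return MotifShuffleResult(span, observed, reps, exceed)


def _span_score(seq: str, span: tuple[int, int], model) -> float:
    prof = reconstruct_likelihoods(seq, model)
    vals = prof.p_norm[span[0] : span[1]]
    vals = vals[np.isfinite(vals)]
    return float(np.log(np.maximum(vals, 1e-12)).mean())


# ---------------------------------------------------------------------------
# Nucleotide dependency maps
# ---------------------------------------------------------------------------


@dataclass
class DependencyMap:
    seq: str
    e: np.ndarray  # (L, L), diagonal fixed at 0


def dependency_map(seq: str, model, clamp: float = 1e-6,
                   batch_size: int = 128) -> DependencyMap:
    """Substitution-based dependency strengths between all position pairs.

    For each position i, one unmasked reference pass and three passes with
    the base at i substituted by each alternate are run (1 + 3L forward
    passes). With odds(p) = p/(1-p), for each alternate a and base k at
    position j the log2 odds ratio against the reference pass is computed;
    e[i][j] is the signed value of maximal absolute magnitude over the
    3 alternates x 4 bases. Probabilities are clamped to [clamp, 1-clamp];
    the diagonal is 0 by convention. N positions at i are skipped (zero row).
    """
    tokens = ALPHABET.encode(seq)
    L = len(tokens)
    ref_probs = np.clip(model.predict_probs(tokens[None])[0], clamp, 1 - clamp)
    ref_logodds = np.log2(ref_probs / (1 - ref_probs))  # (L, 4)

    variants = []
    owners = []  # (i, alt)
    for i in range(L):
        if tokens[i] == ALPHABET.N:
            continue
        for alt in range(N_BASES):
            if alt == tokens[i]:
                continue
            t = tokens.copy()
            t[i] = alt
            variants.append(t)
            owners.append(i)
    e = np.zeros((L, L))
    if variants:
        variants = np.stack(variants)
        best_mag = np.zeros((L, L))
        for lo in range(0, len(variants), batch_size):
            probs = model.predict_probs(variants[lo : lo + batch_size])
            probs = np.clip(probs, clamp, 1 - clamp)
            ratios = np.log2(probs / (1 - probs)) - ref_logodds  # (b, L, 4)
            flat = ratios.reshape(ratios.shape[0], L, N_BASES)
            kmax = np.abs(flat).argmax(-1)
            signed = np.take_along_axis(flat, kmax[..., None], -1)[..., 0]  # (b, L)
            for bi, i in enumerate(owners[lo : lo + batch_size]):
                upd = np.abs(signed[bi]) > best_mag[i]
                e[i, upd] = signed[bi, upd]
                best_mag[i, upd] = np.abs(signed[bi, upd])
    np.fill_diagonal(e, 0.0)
    return DependencyMap(seq, e)


def write_dependency_h5(dep: DependencyMap, path, png_path=None) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("e", data=dep.e)
        fh.attrs["seq"] = dep.seq
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        lim = np.abs(dep.e).max() or 1.0
        im = ax.imshow(dep.e, cmap="RdBu_r", vmin=-lim, vmax=lim)
        fig.colorbar(im, ax=ax, label="dependency (log2 odds ratio)")
        ax.set_xlabel("position j")
        ax.set_ylabel("substituted position i")
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
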