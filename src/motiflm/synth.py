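"""Synthetic motif-planted corpora for desk-scale testing and validation.

Generates fixed-length sequences with short position-weight-matrix (PWM)
motifs planted sparsely on an i.i.d. background, optional lowercase repeat
runs, and labeled variant sets split into motif-disrupting vs. background
variants with PWM-derived effect sizes. Also provides the PWM log-odds
scanner used as a reference oracle by the generation and variant tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import SequenceRecord, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# pseudo-probability floor keeps PWM log-odds finite
PWM_FLOOR = 0.01


class GenerationError(RuntimeError):
    """Infeasible synthetic-corpus request (e.g. motif packing)."""


# ---------------------------------------------------------------------------
# Motif models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifModel:
    """A PWM over columns A, C, G, T. Width is the number of rows."""

    name: str
    pwm: np.ndarray  # (width, 4), rows sum to 1

    def __post_init__(self):
        pwm = np.asarray(self.pwm, dtype=float)
        if pwm.ndim != 2 or pwm.shape[1] != 4:
            raise ValueError(f"PWM for {self.name!r} must be (width, 4)")
        if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM rows for {self.name!r} must sum to 1")
        object.__setattr__(self, "pwm", pwm)

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=1))

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(self.name + "_rc", self.pwm[::-1, ::-1].copy())


def _pwm_from_consensus(name: str, consensus: str, dominant: float = 0.92) -> MotifModel:
    """One dominant base per column; remaining mass spread evenly (~1.5 bits/col)."""
    off = (1.0 - dominant) / 3.0
    pwm = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        pwm[i, _BASE_INDEX[b]] = dominant
    return MotifModel(name, pwm)


def default_motifs() -> list[MotifModel]:
    """Four distinct PWMs of widths 6/8/10/12 with strong consensus.

    Consensus strings echo common regulatory families (AP-1, SP1, NF-kB,
    CTCF-like) purely as recognisable shapes; information content is
    ~1.5 bits per column so that small models can learn them quickly.
    """
    return [
        _pwm_from_consensus("ap1_like", "TGACTC"),
        _pwm_from_consensus("sp1_like", "GGGGCGGG"),
        _pwm_from_consensus("nfkb_like", "GGGACTTTCC"),
        _pwm_from_consensus("ctcf_like", "CCACTAGGGGGC"),
    ]


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Study conditions for the synthetic corpus.

    Defaults: 2,000 sequences of 350 bp, human-like background composition,
    a Poisson(2) number of planted motifs per sequence drawn from the default
    motif set, and a 10% chance per sequence of one 30-80 bp lowercase repeat
    run outside planted spans. Splits are assigned 85/10/5 train/val/test.
    """

    n_sequences: int = 2000
    length: int = 350
    background: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    motifs: tuple[MotifModel, ...] = field(default_factory=lambda: tuple(default_motifs()))
    motifs_per_seq: float = 2.0  # Poisson mean
    repeat_rate: float = 0.1
    repeat_run_range: tuple[int, int] = (30, 80)
    val_fraction: float = 0.10
    test_fraction: float = 0.05

    def __post_init__(self):
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if self.length <= 0 or self.n_sequences <= 0:
            raise ValueError("n_sequences and length must be positive")
        for m in self.motifs:
            if m.width > self.length:
                raise GenerationError(f"motif {m.name} wider than sequence length")


@dataclass
class PlantedInstance:
    motif: str
    start: int
    strand: str  # '+' or '-'
    width: int

    @property
    def end(self) -> int:
        return self.start + self.width


def _sample_instance(motif: MotifModel, strand: str, rng: np.random.Generator) -> str:
    pwm = motif.pwm if strand == "+" else motif.reverse_complement().pwm
    idx = np.array([rng.choice(4, p=row) for row in pwm])
    return "".join(BASES[i] for i in idx)


def generate_corpus(
    spec: SyntheticCorpusSpec, rng: np.random.Generator
) -> tuple[list[SequenceRecord], list[list[PlantedInstance]]]:
    """Sample sequences with non-overlapping planted motifs and annotations.

    Background bases are i.i.d. from the stated frequencies; each motif
    instance is sampled column-wise from its PWM on a uniformly chosen strand.
    Repeat runs are written as lowercase outside planted spans. Regenerating
    with the same seed is byte-identical.
    """
    mean_w = float(np.mean([m.width for m in spec.motifs])) if spec.motifs else 0.0
    if spec.motifs and spec.motifs_per_seq * mean_w > 0.5 * spec.length:
        raise GenerationError(
            "requested motif density leaves no room for non-overlapping placement"
        )
    bg = np.asarray(spec.background)
    records: list[SequenceRecord] = []
    annotations: list[list[PlantedInstance]] = []

    n_val = int(round(spec.n_sequences * spec.val_fraction))
    n_test = int(round(spec.n_sequences * spec.test_fraction))
    splits = ["val"] * n_val + ["test"] * n_test
    splits += ["train"] * (spec.n_sequences - len(splits))
    splits = [splits[i] for i in rng.permutation(spec.n_sequences)]

    for si in range(spec.n_sequences):
        L = spec.length
        chars = [BASES[i] for i in rng.choice(4, size=L, p=bg)]
        planted: list[PlantedInstance] = []
        n_motifs = int(rng.poisson(spec.motifs_per_seq)) if spec.motifs else 0
        for _ in range(n_motifs):
            motif = spec.motifs[int(rng.integers(len(spec.motifs)))]
            strand = "+" if rng.random() < 0.5 else "-"
            placed = False
            for _attempt in range(200):
                start = int(rng.integers(0, L - motif.width + 1))
                end = start + motif.width
                if all(end <= p.start or start >= p.end for p in planted):
                    placed = True
                    break
            if not placed:
                raise GenerationError(
                    f"could not place motif {motif.name} in sequence {si} "
                    f"after 200 attempts"
                )
            inst = _sample_instance(motif, strand, rng)
            chars[start:end] = list(inst)
            planted.append(PlantedInstance(motif.name, start, strand, motif.width))

        if spec.repeat_rate > 0 and rng.random() < spec.repeat_rate:
            lo, hi = spec.repeat_run_range
            run_len = int(rng.integers(lo, hi + 1))
            run_len = min(run_len, L)
            for _attempt in range(200):
                start = int(rng.integers(0, L - run_len + 1))
                end = start + run_len
                if all(end <= p.start or start >= p.end for p in planted):
                    chars[start:end] = [c.lower() for c in chars[start:end]]
                    break

        seq = "".join(chars)
        runs = _lowercase_runs(seq)
        records.append(
            SequenceRecord(
                chrom=f"seq{si:05d}",
                start=0,
                end=L,
                seq=seq,
                split=splits[si],
                repeat_runs=runs,
            )
        )
        annotations.append(sorted(planted, key=lambda p: p.start))
    return records, annotations


def _lowercase_runs(seq: str, min_run: int = 30) -> list[tuple[int, int]]:
    from .corpus import annotate_repeat_runs

    return annotate_repeat_runs(seq, min_run)


# ---------------------------------------------------------------------------
# Variant sets
# ---------------------------------------------------------------------------


@dataclass
class SyntheticVariant:
    """A labeled single-nucleotide variant on a synthetic sequence."""

    seq_id: str
    offset: int  # 0-based within the sequence
    ref: str
    alt: str
    effect_size: float
    var_class: str  # 'motif_disrupting' | 'background'
    significant: bool


def make_variant_set(
    corpus: list[SequenceRecord],
    annotations: list[list[PlantedInstance]],
    n_per_class: tuple[int, int],
    rng: np.random.Generator,
    motifs: list[MotifModel] | None = None,
) -> list[SyntheticVariant]:
    """Build motif-disrupting and background variants with PWM effect sizes.

    Motif-disrupting variants substitute the highest-information PWM column of
    a planted instance with the column's lowest-probability base; the effect
    size is the PWM log-odds delta ln(p_alt/p_ref) (strand-aware). Background
    variants fall outside all planted spans with small zero-centered noise as
    the effect and are not flagged significant.
    """
    motifs = motifs if motifs is not None else default_motifs()
    by_name = {m.name: m for m in motifs}
    n_motif, n_bg = n_per_class

    sites = []  # (record index, instance)
    for ri, planted in enumerate(annotations):
        for inst in planted:
            if inst.motif in by_name:
                sites.append((ri, inst))
    if n_motif > len(sites):
        raise GenerationError(
            f"requested {n_motif} motif-disrupting variants but only "
            f"{len(sites)} planted instances are available"
        )

    variants: list[SyntheticVariant] = []
    for k in rng.permutation(len(sites)):
        if len(variants) == n_motif:
            break
        ri, inst = sites[int(k)]
        rec = corpus[ri]
        motif = by_name[inst.motif]
        pwm = motif.pwm if inst.strand == "+" else motif.reverse_complement().pwm
        col = int(pwm.max(axis=1).argmax())  # highest-information column
        offset = inst.start + col
        probs = np.maximum(pwm[col], PWM_FLOOR)
        ref = rec.seq[offset].upper()
        order = np.argsort(probs)
        alt_i = int(order[0]) if BASES[order[0]] != ref else int(order[1])
        alt = BASES[alt_i]
        # keep only sites whose mutation strictly lowers the sequence's best
        # PWM match; the planted instance is not always the top placement
        mutated = rec.seq[:offset] + alt + rec.seq[offset + 1 :]
        if not (pwm_log_odds_score(mutated.upper(), motif)
                < pwm_log_odds_score(rec.seq.upper(), motif)):
            continue
        effect = float(np.log(probs[alt_i] / probs[_BASE_INDEX[ref]]))
        variants.append(
            SyntheticVariant(rec.chrom, offset, ref, alt, effect, "motif_disrupting", True)
        )
    if len(variants) < n_motif:
        raise GenerationError(
            f"only {len(variants)} of {n_motif} requested motif-disrupting "
            f"variants could be constructed"
        )

    for _ in range(n_bg):
        for _attempt in range(500):
            ri = int(rng.integers(len(corpus)))
            rec = corpus[ri]
            offset = int(rng.integers(len(rec.seq)))
            if all(not (p.start <= offset < p.end) for p in annotations[ri]):
                break
        else:
            raise GenerationError("could not find a background position")
        ref = rec.seq[offset].upper()
        if ref == "N":
            continue
        alt = BASES[int(rng.choice([i for i in range(4) if BASES[i] != ref]))]
        effect = float(rng.normal(0.0, 0.05))
        variants.append(
            SyntheticVariant(rec.chrom, offset, ref, alt, effect, "background", False)
        )
    return variants


def write_variants_tsv(variants, path) -> None:
    """Variant table as TSV with 1-based positions."""
    with open(path, "w") as fh:
        fh.write("seq_id\tpos\tref\talt\teffect_size\tclass\tsignificant\n")
        for v in variants:
            fh.write(
                f"{v.seq_id}\t{v.offset + 1}\t{v.ref}\t{v.alt}\t"
                f"{v.effect_size:.6g}\t{v.var_class}\t{int(v.significant)}\n"
            )


def read_variants_tsv(path) -> list[SyntheticVariant]:
    variants = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            variants.append(
                SyntheticVariant(
                    seq_id=f[idx["seq_id"]],
                    offset=int(f[idx["pos"]]) - 1,
                    ref=f[idx["ref"]],
                    alt=f[idx["alt"]],
                    effect_size=float(f[idx["effect_size"]]),
                    var_class=f[idx["class"]],
                    significant=bool(int(f[idx["significant"]])),
                )
            )
    return variants


# ---------------------------------------------------------------------------
# PWM scanning oracle
# ---------------------------------------------------------------------------


def pwm_log_odds_score(
    seq: str,
    motif: MotifModel,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> float:
    """Best log-odds PWM match over all offsets and both strands.

    Score of a placement is sum_i ln(pwm[i, base] / background[base]); N
    positions contribute 0. Deterministic.
    """
    L, w = len(seq), motif.width
    if L < w:
        raise ValueError("sequence shorter than motif width")
    bg = np.asarray(background)
    best = -np.inf
    for pwm in (motif.pwm, motif.reverse_complement().pwm):
        logratio = np.log(np.maximum(pwm, PWM_FLOOR) / bg)  # (w, 4)
        for off in range(L - w + 1):
            s = 0.0
            for i, ch in enumerate(seq[off : off + w].upper()):
                if ch == "N":
                    continue
                s += logratio[i, _BASE_INDEX[ch]]
            best = max(best, s)
    return float(best)


class PwmSumOracle:
    """Strictly positive sequence scorer built from PWM scans.

    g(S) = eps + sum over motifs of exp(best log-odds score / width); behaves
    like a smooth 'regulatory activity' readout: disrupting a planted motif
    lowers g. Used as the fixture oracle for supervised-style variant scoring
    and design objectives.
    """

    def __init__(self, motifs=None, eps: float = 1e-3,
                 background=(0.25, 0.25, 0.25, 0.25)):
        self.motifs = list(motifs) if motifs is not None else default_motifs()
        self.eps = eps
        self.background = background

    def __call__(self, seq: str) -> float:
        total = self.eps
        for m in self.motifs:
            total += float(
                np.exp(pwm_log_odds_score(seq, m, self.background) / m.width)
            )
        return total


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------


def write_meme(motifs, path, background=(0.25, 0.25, 0.25, 0.25)) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            f"A {background[0]:.5f} C {background[1]:.5f} "
            f"G {background[2]:.5f} T {background[3]:.5f}\n\n"
        )
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.pwm:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[MotifModel]:
    motifs = []
    name, rows, expect = None, [], 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                expect = int(line.split("w=")[1].split()[0])
                rows = []
            elif name is not None and expect and line and line[0] in "0123456789.":
                rows.append([float(x) for x in line.split()])
                if len(rows) == expect:
                    pwm = np.array(rows)
                    pwm = pwm / pwm.sum(axis=1, keepdims=True)
                    motifs.append(MotifModel(name, pwm))
                    name, rows, expect = None, [], 0
    return motifs
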