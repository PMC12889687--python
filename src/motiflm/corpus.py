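"""Corpus construction for a short-context regulatory DNA language model.

Reads a case-preserving reference genome (lowercase = soft-masked repeats) and a
BED file of regulatory-element intervals, and produces fixed-length training
windows with chromosome-based train/val/test splits, repeat-run annotation, and
stochastic augmentation (reverse complement, coordinate shift).

All coordinates are 0-based half-open, matching the BED convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

VALID_ALPHABET = set("ACGTNacgtn")

# Chromosome-based splits used for pretraining on regulatory elements.
DEFAULT_VAL_CHROMS = frozenset({"6", "21"})
DEFAULT_TEST_CHROMS = frozenset({"5", "10", "14", "18", "20", "22"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class CorpusError(ValueError):
    """Malformed input (BED line, alphabet violation, bad configuration)."""


# ---------------------------------------------------------------------------
# Genome access
# ---------------------------------------------------------------------------


class GenomeSource:
    """Case-preserving per-chromosome sequence access.

    Wraps any mapping from chromosome name to a full sequence string. Use
    :meth:`from_fasta` for an indexed on-disk FASTA. Lookups outside chromosome
    bounds are rejected; case is never folded on read.
    """

    def __init__(self, chroms: dict[str, str]):
        for name, seq in chroms.items():
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise CorpusError(
                    f"chromosome {name!r} contains invalid characters: {sorted(bad)!r}"
                )
        self._chroms = dict(chroms)

    @classmethod
    def from_fasta(cls, path) -> "GenomeSource":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), sequence_always_upper=False)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def chromosomes(self) -> list[str]:
        return list(self._chroms)

    def length(self, chrom: str) -> int:
        self._check_chrom(chrom)
        return len(self._chroms[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        self._check_chrom(chrom)
        n = len(self._chroms[chrom])
        if not (0 <= start <= end <= n):
            raise CorpusError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds [0, {n})"
            )
        return self._chroms[chrom][start:end]

    def _check_chrom(self, chrom: str) -> None:
        if chrom not in self._chroms:
            raise CorpusError(f"unknown chromosome {chrom!r}")


# ---------------------------------------------------------------------------
# Records and splits
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """A fixed-length, case-preserving genomic window.

    ``repeat_runs`` holds maximal, non-overlapping [start, end) offsets of
    soft-masked (lowercase) runs within ``seq``, each at least ``min_run`` long
    at annotation time.
    """

    chrom: str
    start: int
    end: int
    seq: str
    split: str = "train"
    repeat_runs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.seq) != self.end - self.start:
            raise CorpusError(
                f"sequence length {len(self.seq)} != end-start "
                f"({self.end}-{self.start}) for {self.chrom}"
            )
        if self.split not in ("train", "val", "test"):
            raise CorpusError(f"invalid split label {self.split!r}")


@dataclass(frozen=True)
class SplitSpec:
    """Chromosome-based split assignment; unlisted chromosomes are training."""

    val_chroms: frozenset = DEFAULT_VAL_CHROMS
    test_chroms: frozenset = DEFAULT_TEST_CHROMS

    def __post_init__(self):
        val = {_norm_chrom(c) for c in self.val_chroms}
        test = {_norm_chrom(c) for c in self.test_chroms}
        both = val & test
        if both:
            raise CorpusError(f"chromosomes in both val and test sets: {sorted(both)}")
        object.__setattr__(self, "val_chroms", frozenset(val))
        object.__setattr__(self, "test_chroms", frozenset(test))


def _norm_chrom(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def assign_split(chrom: str, spec: SplitSpec = SplitSpec()) -> str:
    """Map a chromosome name to 'train', 'val' or 'test'.

    Names are compared with the 'chr' prefix stripped, so 'chr6' and '6' agree.
    """
    if not chrom:
        raise CorpusError("empty chromosome name")
    c = _norm_chrom(chrom)
    if c in spec.val_chroms:
        return "val"
    if c in spec.test_chroms:
        return "test"
    return "train"


@dataclass(frozen=True)
class AugmentationPolicy:
    """Stochastic training augmentation: reverse complement and window shift."""

    rc_prob: float = 0.5
    shift_range: tuple[int, int] = (-50, 50)

    def __post_init__(self):
        if not 0.0 <= self.rc_prob <= 1.0:
            raise CorpusError("rc_prob must be in [0, 1]")
        lo, hi = self.shift_range
        if lo > hi:
            raise CorpusError("shift_range must be (lo, hi) with lo <= hi")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def annotate_repeat_runs(seq: str, min_run: int = 30) -> list[tuple[int, int]]:
    """Maximal runs of lowercase (soft-masked) characters of length >= min_run."""
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise CorpusError(f"sequence contains invalid characters: {sorted(bad)!r}")
    return [
        (m.start(), m.end())
        for m in re.finditer(r"[acgtn]+", seq)
        if m.end() - m.start() >= min_run
    ]


def expand_interval(start: int, end: int, window: int) -> tuple[int, int]:
    """Center an interval inside a fixed window.

    Expansion is symmetric about the interval midpoint with the extra base on
    the 3' side when the deficit is odd; intervals longer than ``window`` are
    center-cropped (same convention).
    """
    new_start = (start + end - window + 1) // 2
    return new_start, new_start + window


def load_windows(
    bed_path,
    genome: GenomeSource,
    window: int = 350,
    split_spec: SplitSpec = SplitSpec(),
    min_run: int = 30,
) -> list[SequenceRecord]:
    """Read BED intervals and return fixed-length windows with splits and repeats.

    Short intervals are center-expanded to ``window``; long ones center-cropped.
    Windows that would cross a chromosome edge are clamped to the bounds; a
    chromosome shorter than ``window`` causes the record to be skipped with a
    warning.
    """
    if window <= 0:
        raise CorpusError("window must be positive")
    records = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CorpusError(f"{bed_path}:{lineno}: expected >=3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise CorpusError(f"{bed_path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise CorpusError(f"{bed_path}:{lineno}: invalid interval {start}-{end}")
            clen = genome.length(chrom)
            if clen < window:
                log.warning(
                    "%s:%d: chromosome %s shorter than window (%d < %d); skipped",
                    bed_path, lineno, chrom, clen, window,
                )
                continue
            w_start, w_end = expand_interval(start, end, window)
            if w_start < 0:
                w_start, w_end = 0, window
            elif w_end > clen:
                w_start, w_end = clen - window, clen
            seq = genome.fetch(chrom, w_start, w_end)
            records.append(
                SequenceRecord(
                    chrom=chrom,
                    start=w_start,
                    end=w_end,
                    seq=seq,
                    split=assign_split(chrom, split_spec),
                    repeat_runs=annotate_repeat_runs(seq, min_run),
                )
            )
    return records


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving case; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def augment(
    record: SequenceRecord,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
    genome: GenomeSource | None = None,
    min_run: int = 30,
) -> SequenceRecord:
    """Apply stochastic reverse complement and window shift to a record.

    The shift re-extracts the window displaced by an offset drawn uniformly
    from the closed shift range; it requires ``genome`` (shift is skipped when
    no genome is available, e.g. for synthetic windows with no flanks). A shift
    that would cross a chromosome edge is clamped to the largest legal offset.
    The reverse-complement flag is drawn independently of the shift.
    """
    out = record
    lo, hi = policy.shift_range
    do_rc = rng.random() < policy.rc_prob
    shift = int(rng.integers(lo, hi + 1)) if (lo, hi) != (0, 0) else 0

    if shift != 0 and genome is not None:
        clen = genome.length(record.chrom)
        window = record.end - record.start
        new_start = record.start + shift
        clamped = min(max(new_start, 0), clen - window)
        if clamped != new_start:
            log.debug(
                "shift %+d clamped to %+d at %s:%d", shift,
                clamped - record.start, record.chrom, record.start,
            )
        new_start = clamped
        seq = genome.fetch(record.chrom, new_start, new_start + window)
        out = replace(
            out,
            start=new_start,
            end=new_start + window,
            seq=seq,
            repeat_runs=annotate_repeat_runs(seq, min_run),
        )

    if do_rc:
        L = len(out.seq)
        out = replace(
            out,
            seq=reverse_complement(out.seq),
            repeat_runs=sorted((L - e, L - s) for s, e in out.repeat_runs),
        )
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_fasta(records, path, line_width: int = 60) -> None:
    """Write records to FASTA, preserving case. Header: chrom:start-end split."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.chrom}:{rec.start}-{rec.end} split={rec.split}\n")
            for i in range(0, len(rec.seq), line_width):
                fh.write(rec.seq[i : i + line_width] + "\n")


def read_fasta(path, min_run: int = 30) -> list[SequenceRecord]:
    """Read FASTA written by :func:`write_fasta` back into records."""
    records = []
    name, meta, chunks = None, {}, []

    def flush():
        if name is None:
            return
        seq = "".join(chunks)
        chrom, _, span = name.partition(":")
        if span:
            start, end = (int(x) for x in span.split("-"))
        else:
            start, end = 0, len(seq)
        records.append(
            SequenceRecord(
                chrom=chrom,
                start=start,
                end=end,
                seq=seq,
                split=meta.get("split", "train"),
                repeat_runs=annotate_repeat_runs(seq, min_run),
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                name = parts[0]
                meta = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
                chunks = []
            elif line:
                chunks.append(line)
    flush()
    return records


def write_manifest(records, path) -> None:
    """Window manifest as TSV: chrom, start, end, split."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsplit\n")
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.split}\n")
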