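"""Variant effect scoring: zero-shot log-likelihood ratios and oracle scores.

The zero-shot score of a single-nucleotide variant masks the variant
position at the center of a 350-bp window and compares the model-assigned
probability of the alternate vs. reference base:

    s = ln[ p(alt) / p(ref) ]

(natural log; rank metrics are base-invariant). Supervised-style scoring
runs a pluggable oracle g on reference/alternate windows and reports
log2[g(S_alt)/g(S_ref)]. Evaluation follows the regulatory-QTL protocol:
correlations on significant variants only, AUROC (on |score|) for
significant vs. non-significant discrimination over all variants.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import roc_auc_score

from .nn import ALPHABET

log = logging.getLogger(__name__)

LLR_LOG_BASE = "e"  # natural log; recorded in output headers


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV with an observed effect size and significance flag."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    effect_size: float = math.nan
    significant: bool = False

    def __post_init__(self):
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise VariantError(f"alleles must be A/C/G/T, got {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise VariantError("ref and alt alleles must differ")
        if self.pos < 1:
            raise VariantError("positions are 1-based")


@dataclass
class ScoredVariant:
    variant: VariantRecord
    llr: float | None = None
    oracle_score: float | None = None
    flag: str = "ok"  # 'ok' | 'ref_mismatch' | 'oracle_error'


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------


def _extract_window(genome, variant: VariantRecord, window: int) -> tuple[str, int]:
    """Window centered on the variant, clamped to chromosome bounds.

    Returns (sequence, offset of the variant within it). The variant sits at
    window//2 except near chromosome edges.
    """
    pos0 = variant.pos - 1
    clen = genome.length(variant.chrom)
    if clen < window:
        raise VariantError(f"chromosome {variant.chrom} shorter than window")
    start = pos0 - window // 2
    start = min(max(start, 0), clen - window)
    return genome.fetch(variant.chrom, start, start + window), pos0 - start


# ---------------------------------------------------------------------------
# Zero-shot scoring
# ---------------------------------------------------------------------------


def llr_for_sequence(seq: str, offset: int, ref: str, alt: str, model) -> float:
    """Masked log-likelihood ratio ln p(alt)/p(ref) at ``offset`` of ``seq``."""
    tokens = ALPHABET.encode(seq)
    tokens[offset] = ALPHABET.MASK
    probs = model.predict_probs(tokens[None])[0, offset]
    p_alt = max(float(probs[ALPHABET.encode(alt)[0]]), 1e-12)
    p_ref = max(float(probs[ALPHABET.encode(ref)[0]]), 1e-12)
    return math.log(p_alt / p_ref)


def zero_shot_llr(
    variant: VariantRecord, genome, model, window: int = 350
) -> ScoredVariant:
    """Score one variant with the masked LLR; mismatched reference is withheld.

    The genome base at the variant position must equal the stated reference
    allele; otherwise the variant is flagged 'ref_mismatch' and no score is
    produced (alleles are never auto-swapped).
    """
    seq, offset = _extract_window(genome, variant, window)
    if seq[offset].upper() != variant.ref:
        log.warning("reference mismatch at %s:%d (genome %s, variant %s)",
                    variant.chrom, variant.pos, seq[offset].upper(), variant.ref)
        return ScoredVariant(variant, flag="ref_mismatch")
    return ScoredVariant(variant, llr=llr_for_sequence(seq, offset, variant.ref,
                                                       variant.alt, model))


# ---------------------------------------------------------------------------
# Oracle scoring
# ---------------------------------------------------------------------------


def oracle_log_fold_change(
    variant: VariantRecord, genome, oracle, window: int = 2114
) -> ScoredVariant:
    """log2 fold change of a positive-valued oracle between alt and ref windows.

    Builds two windows differing only at the center position and scores
    log2[g(S_alt)/g(S_ref)]. Non-positive oracle output raises.
    """
    seq, offset = _extract_window(genome, variant, window)
    if seq[offset].upper() != variant.ref:
        return ScoredVariant(variant, flag="ref_mismatch")
    s_ref = seq[:offset] + variant.ref + seq[offset + 1:]
    s_alt = seq[:offset] + variant.alt + seq[offset + 1:]
    g_ref, g_alt = float(oracle(s_ref)), float(oracle(s_alt))
    if g_ref <= 0 or g_alt <= 0:
        raise VariantError(
            f"oracle returned non-positive value for {variant.chrom}:{variant.pos}"
        )
    return ScoredVariant(variant, oracle_score=math.log2(g_alt / g_ref))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Correlations on significant variants; AUROC over all variants."""

    pearson_r: float | None
    spearman_rho: float | None
    auroc: float | None
    n_significant: int
    n_total: int
    missing_reason: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def evaluate_variant_scores(
    scored: list[ScoredVariant], score_attr: str = "llr"
) -> EvalReport:
    """Compare scores to observed effect sizes under the QTL protocol.

    Pearson/Spearman are computed between the score and the observed effect
    size on significant variants only; AUROC discriminates significant from
    non-significant variants using |score|. Variants without a score
    (flagged) are excluded with a log message.
    """
    rows = [(getattr(s, score_attr), s.variant.effect_size, s.variant.significant)
            for s in scored if getattr(s, score_attr) is not None]
    dropped = len(scored) - len(rows)
    if dropped:
        log.info("evaluation excludes %d unscored variants", dropped)
    if not rows:
        return EvalReport(None, None, None, 0, 0, "no scored variants")
    score = np.array([r[0] for r in rows])
    effect = np.array([r[1] for r in rows])
    sig = np.array([r[2] for r in rows], dtype=bool)

    pear = spear = auroc = None
    reason = None
    if sig.sum() >= 3:
        pear = float(pearsonr(score[sig], effect[sig]).statistic)
        spear = float(spearmanr(score[sig], effect[sig]).statistic)
    else:
        reason = "fewer than 3 significant variants for correlations"
    if 0 < sig.sum() < len(sig):
        auroc = float(roc_auc_score(sig, np.abs(score)))
    else:
        reason = (reason + "; " if reason else "") + "one class absent for AUROC"
    return EvalReport(pear, spear, auroc, int(sig.sum()), len(sig), reason)


# ---------------------------------------------------------------------------
# File I/O (minimal VCF and TSV dialects)
# ---------------------------------------------------------------------------


def read_variants_vcf(path) -> list[VariantRecord]:
    """Minimal VCF: CHROM POS ID REF ALT ...; INFO keys ES= and SIG=."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            info = dict(
                kv.split("=", 1) for kv in (f[7].split(";") if len(f) > 7 else [])
                if "=" in kv
            )
            out.append(VariantRecord(
                chrom=f[0], pos=int(f[1]), ref=f[3], alt=f[4],
                effect_size=float(info.get("ES", "nan")),
                significant=info.get("SIG", "0") == "1",
            ))
    return out


def write_variants_vcf(variants: list[VariantRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##INFO=<ID=ES,Number=1,Type=Float,Description=\"Observed effect size\">\n")
        fh.write("##INFO=<ID=SIG,Number=1,Type=Integer,Description=\"Significant flag\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                     f"ES={v.effect_size:.6g};SIG={int(v.significant)}\n")


def write_scores_tsv(scored: list[ScoredVariant], path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# llr_log_base={LLR_LOG_BASE}; oracle_score_log_base=2\n")
        fh.write("chrom\tpos\tref\talt\teffect_size\tsignificant\tllr\toracle_score\tflag\n")
        for s in scored:
            v = s.variant
            llr = f"{s.llr:.6g}" if s.llr is not None else "NA"
            osc = f"{s.oracle_score:.6g}" if s.oracle_score is not None else "NA"
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.effect_size:.6g}\t"
                     f"{int(v.significant)}\t{llr}\t{osc}\t{s.flag}\n")
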