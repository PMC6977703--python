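"""Cis and trans lncRNA target prediction.

Cis: a gene is a cis target when it lies on the same chromosome within a
fixed window (10 kb by default) up- or downstream of the lncRNA locus.
Distance between non-overlapping 1-based inclusive spans is
``later.start - earlier.end - 1``; overlapping spans are at distance 0.
Strand is ignored (the window is purely positional).

Trans: a two-stage screen-then-score over spliced sequences.  Stage 1
keeps candidates sharing at least one exact reverse-complement k-mer with
the lncRNA (a fast complementarity screen); stage 2 scores the best
ungapped antisense alignment, counting paired positions (Watson-Crick 1,
optional G:U 1, mismatch 0) over all offsets.  The match-count duplex
score is a transparent stand-in for a thermodynamic duplex energy; it
preserves the screen-then-score architecture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core_io import TranscriptRecord

__all__ = ["CisHit", "TransHit", "cis_targets", "span_gap", "trans_targets"]

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class CisHit:
    lncrna_id: str
    gene_id: str
    distance_bp: int


@dataclass(frozen=True)
class TransHit:
    lncrna_id: str
    target_id: str
    best_score: int
    lnc_offset: int  # 0-based start of the scored window in the lncRNA
    target_offset: int  # 0-based start in the target


def span_gap(span_a: tuple[int, int], span_b: tuple[int, int]) -> int:
    """Gap in bp between two 1-based inclusive spans; 0 when they overlap."""
    (a1, a2), (b1, b2) = span_a, span_b
    if a1 > b1:
        (a1, a2), (b1, b2) = (b1, b2), (a1, a2)
    if b1 <= a2:  # overlap or containment
        return 0
    return b1 - a2 - 1


def cis_targets(
    lncrnas: Sequence[TranscriptRecord],
    genes: Sequence[TranscriptRecord],
    window_bp: int = 10_000,
) -> list[CisHit]:
    """Genes within ``window_bp`` of each lncRNA span (same chromosome).

    Symmetric in up/downstream; overlap counts as distance 0.  A record
    appearing in both input lists never pairs with itself.
    """
    hits = []
    for lnc in lncrnas:
        for gene in genes:
            if gene.transcript_id == lnc.transcript_id:
                continue
            if gene.chrom != lnc.chrom:
                continue
            gap = span_gap(lnc.span, gene.span)
            if gap <= window_bp:
                hits.append(CisHit(lnc.transcript_id, gene.transcript_id, gap))
    hits.sort(key=lambda h: (h.lncrna_id, h.gene_id))
    return hits


def _normalize(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    if set(s) - set("ACGTN"):
        raise ValueError("sequence has characters outside ACGTUN")
    return s


def _best_antisense_alignment(
    lnc: str, rc_target: str, allow_gu: bool, target_len: int
) -> tuple[int, int, int]:
    """Best ungapped alignment of ``lnc`` against the reverse-complemented
    target, over all relative offsets.  Returns (score, lnc_offset,
    target_offset), target_offset on the original (sense) target."""
    n, m = len(lnc), len(rc_target)
    best = (0, 0, 0)
    for shift in range(-(m - 1), n):
        score = 0
        lo = max(0, shift)
        hi = min(n, shift + m)
        for i in range(lo, hi):
            a, b = lnc[i], rc_target[i - shift]
            if a == b and a != "N":
                score += 1
            elif allow_gu:
                # rc already complements, so equality = WC pair; a G:U pair in
                # the duplex shows up here as (A,G) or (C,T) after complement
                if (a == "A" and b == "G") or (a == "C" and b == "T"):
                    score += 1
        if score > best[0]:
            # overlap on rc_target spans [lo-shift, hi-shift); map to sense coords
            best = (score, lo, m - (hi - shift))
    return best


def trans_targets(
    lncrna_seq: str,
    candidate_seqs: dict[str, str],
    min_score: int,
    screen_kmer: int = 12,
    lncrna_id: str = "lncRNA",
    allow_gu: bool = False,
) -> list[TransHit]:
    """Two-stage trans-target screen for one lncRNA.

    Stage 1 keeps candidates whose reverse complement shares an exact
    ``screen_kmer``-mer with the lncRNA; stage 2 scores the best ungapped
    antisense alignment and keeps hits with score >= ``min_score``.
    """
    if screen_kmer < 6:
        raise ValueError("screen_kmer must be >= 6")
    if not lncrna_seq:
        raise ValueError("empty lncRNA sequence")
    lnc = _normalize(lncrna_seq)
    lnc_kmers = {
        lnc[i : i + screen_kmer]
        for i in range(len(lnc) - screen_kmer + 1)
        if "N" not in lnc[i : i + screen_kmer]
    }
    hits = []
    for tid in sorted(candidate_seqs):
        target = _normalize(candidate_seqs[tid])
        if not target:
            raise ValueError(f"empty candidate sequence {tid!r}")
        rc = target.translate(_DNA_COMPLEMENT)[::-1]
        shares = any(
            rc[i : i + screen_kmer] in lnc_kmers
            for i in range(len(rc) - screen_kmer + 1)
        )
        if not shares:
            continue
        score, lnc_off, tgt_off = _best_antisense_alignment(lnc, rc, allow_gu, len(target))
        if score >= min_score:
            hits.append(TransHit(lncrna_id, tid, score, lnc_off, tgt_off))
    hits.sort(key=lambda h: (h.lncrna_id, h.target_id))
    return hits
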