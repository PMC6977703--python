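"""Novel-lncRNA candidate classification.

A novel transcript is called a lncRNA candidate when it passes every rule
of the filter chain: spliced length >= 200 nt, >= 2 exons, longest open
reading frame <= 300 nt, coding-potential scores (CPC and CNCI-style)
below 0, and no significant Pfam hit.  Thresholds are inclusive as
printed (>=, <=).  The coding-potential engines themselves are external;
their scores arrive as inputs.  The longest-ORF finder is built in.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

__all__ = [
    "CodingEvidence",
    "LncRNAVerdict",
    "longest_orf",
    "classify_lncrna",
    "merge_with_known",
]

_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class CodingEvidence:
    """Externally computed coding-potential scores for one transcript."""

    cpc_score: float
    cnci_score: float
    pfam_significant: bool

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cpc_score) and math.isfinite(self.cnci_score)):
            raise ValueError("coding-potential scores must be finite")


@dataclass
class LncRNAVerdict:
    transcript_id: str
    rule_results: dict[str, bool]
    is_candidate: bool
    longest_orf_nt: int


def _orf_scan(seq: str) -> int:
    """Longest ATG..stop ORF (nt, stop included) on the given strand."""
    best = 0
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            # a codon containing N matches neither start nor stop
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best


def longest_orf(sequence: str, six_frame: bool = False) -> int:
    """Length (nt, including the stop codon) of the longest ORF.

    Scans the three sense-strand reading frames for ATG...{TAA,TAG,TGA};
    returns 0 when no complete ORF exists.  U is treated as T; N matches
    nothing.  ``six_frame=True`` additionally scans the reverse complement
    (off by default: transcripts are stranded spliced sequences).
    """
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")
    best = _orf_scan(seq)
    if six_frame:
        rc = seq.translate(_COMPLEMENT)[::-1]
        best = max(best, _orf_scan(rc))
    return best


def classify_lncrna(
    record,
    evidence: CodingEvidence,
    min_len: int = 200,
    min_exons: int = 2,
    max_orf: int = 300,
    orf_length: int | None = None,
) -> LncRNAVerdict:
    """Run the full filter chain on one transcript.

    ``record`` is a :class:`~cerna_profiler.core_io.TranscriptRecord`;
    its sequence is used for the ORF rule unless ``orf_length`` is given.
    Every rule is evaluated and reported individually; candidacy is the
    conjunction.
    """
    if orf_length is None:
        if record.sequence is None:
            raise ValueError(
                f"{record.transcript_id}: need a sequence or a precomputed "
                "ORF length for the ORF rule"
            )
        orf_length = longest_orf(record.sequence)
    rules = {
        "length>=200": record.spliced_length >= min_len,
        "exons>=2": record.n_exons >= min_exons,
        "orf<=300": orf_length <= max_orf,
        "cpc<0": evidence.cpc_score < 0,
        "cnci<0": evidence.cnci_score < 0,
        "no_pfam": not evidence.pfam_significant,
    }
    return LncRNAVerdict(
        transcript_id=record.transcript_id,
        rule_results=rules,
        is_candidate=all(rules.values()),
        longest_orf_nt=orf_length,
    )


def merge_with_known(
    candidates: list[LncRNAVerdict],
    known_lncrnas: set[str],
) -> dict[str, str]:
    """Unified lncRNA set: passing novel candidates plus known annotations.

    Returns id -> provenance ("novel" or "known").  On an id collision the
    known annotation wins.
    """
    merged = {tid: "known" for tid in known_lncrnas}
    for v in candidates:
        if not v.is_candidate:
            continue
        if v.transcript_id in merged:
            continue  # known wins
        merged[v.transcript_id] = "novel"
    return merged
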