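"""Reverse complementary sequence (RCS) detection in flanking introns.

RCS pairs that base-pair across the two introns flanking an exonic circRNA
promote back-splicing. One intron is locally aligned (Smith-Waterman,
affine gaps) against the reverse complement of the other; raw scores are
converted to Karlin-Altschul bitscores, bits = (lambda*S - ln K)/ln 2, and
an RCS is called when any alignment exceeds 100 bits. The default scoring
scheme (+2/-3, gap open 5, extend 2, lambda 0.625, K 0.41) matches the
megablast-style nucleotide defaults of the blastn task this mirrors.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align

from .simulate import revcomp

MIN_RAW_SCORE = 20  # floor below which local maxima are not reported


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 5.0  # cost of opening a gap (a length-k gap costs open + k*extend)
    gap_extend: float = 2.0
    lam: float = 0.625
    K: float = 0.41

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match reward > 0 > mismatch penalty")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class RcsHit:
    """One local alignment between intron A and the reverse complement of
    intron B. Intervals are 0-based half-open; the B interval is reported on
    the original (forward) B sequence."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    score: float
    bits: float


def bitscore(score: float, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Karlin-Altschul bitscore (lambda*S - ln K) / ln 2."""
    return (scheme.lam * score - math.log(scheme.K)) / math.log(2.0)


def min_repeat_length(bits_threshold: float = 100.0, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Shortest exact reverse-complement repeat whose bitscore exceeds the
    threshold: smallest L with bitscore(match * L) > threshold."""
    s_min = (bits_threshold * math.log(2.0) + math.log(scheme.K)) / scheme.lam
    return int(math.floor(s_min / scheme.match)) + 1


def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    # first gapped position costs open + extend, further positions extend
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    # N is treated as a mismatch against everything, including itself
    aligner.wildcard = None
    return aligner


def align_revcomp(
    seq_a: str,
    seq_b: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    max_hits: int = 5,
    min_score: float = MIN_RAW_SCORE,
) -> list[RcsHit]:
    """Best non-overlapping local alignments of seq_a vs revcomp(seq_b).

    Hits are found iteratively: the optimal local alignment is recorded and
    its footprint on seq_a is masked (with a symbol scoring as mismatch)
    before re-searching, so returned hits do not overlap on intron A. Hits
    below ``min_score`` raw score are not reported.
    """
    seq_a = seq_a.upper()
    seq_b = seq_b.upper()
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    bad = set(seq_a + seq_b) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    target = revcomp(seq_b)
    nb = len(seq_b)
    aligner = _aligner(scheme)
    hits: list[RcsHit] = []
    # distinct placeholders so N scores as mismatch even against another N
    work = seq_a.replace("N", "X")
    target = target.replace("N", "Z")
    for _ in range(max_hits):
        aln = aligner.align(work, target)
        if len(aln) == 0:
            break
        best = aln[0]
        score = float(best.score)
        if score < min_score:
            break
        (a0, a1) = (int(best.aligned[0][0][0]), int(best.aligned[0][-1][1]))
        (t0, t1) = (int(best.aligned[1][0][0]), int(best.aligned[1][-1][1]))
        hits.append(
            RcsHit(
                a_start=a0,
                a_end=a1,
                b_start=nb - t1,  # map back to forward strand of B
                b_end=nb - t0,
                score=score,
                bits=bitscore(score, scheme),
            )
        )
        work = work[:a0] + "N" * (a1 - a0) + work[a1:]
    hits.sort(key=lambda h: -h.bits)
    return hits


def detect_rcs(
    intron_a: str,
    intron_b: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    threshold: float = 100.0,
) -> tuple[bool, list[RcsHit]]:
    """RCS call for one flanking-intron pair: True when any local alignment
    of intron A against the reverse complement of intron B exceeds the
    bitscore threshold (strictly). Hits come sorted by bitscore."""
    hits = align_revcomp(intron_a, intron_b, scheme)
    return any(h.bits > threshold for h in hits), hits


def scan_introns(
    introns: dict[str, tuple[str, str]],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    threshold: float = 100.0,
):
    """Run detect_rcs over {circ_id: (upstream, downstream)} intron pairs.

    Returns a DataFrame with one row per hit plus a per-circRNA flag table.
    """
    import pandas as pd

    hit_rows, flag_rows = [], []
    for cid, (a, b) in introns.items():
        flag, hits = detect_rcs(a, b, scheme, threshold)
        flag_rows.append({"circ_id": cid, "has_rcs": flag})
        for h in hits:
            hit_rows.append(
                {"circ_id": cid, "a_start": h.a_start, "a_end": h.a_end,
                 "b_start": h.b_start, "b_end": h.b_end, "score": h.score, "bits": h.bits}
            )
    hits_df = pd.DataFrame(hit_rows, columns=["circ_id", "a_start", "a_end", "b_start", "b_end", "score", "bits"])
    flags_df = pd.DataFrame(flag_rows, columns=["circ_id", "has_rcs"]).set_index("circ_id")
    return flags_df, hits_df
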