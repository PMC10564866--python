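"""Paired-end read merging and sequence-level quality control.

Merging reimplements the computation the pipeline needs from a
paired-end merger: reverse-complement the 3' read, find the overlap
offset maximizing matches (at least 10 overlapping nucleotides, capped
mismatch rate), vote overlap bases by quality, trim low-quality ends
and drop short products. QC applies the four sequence filters: stop
codon, V-gene E-value > 1e-3, unlocatable CDR_H3-closing W-G-x-G
motif, and V alignment starting past germline position 9.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .repertoire_io import Rearrangement, SequenceRecord, ValidationError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MergeParams:
    min_overlap: int = 10
    min_length: int = 300
    quality_threshold: int = 20
    max_overlap_mismatch_rate: float = 0.25

    def __post_init__(self):
        if self.min_overlap < 1:
            raise ValidationError("min_overlap must be >= 1")


@dataclass
class QCParams:
    evalue_max: float = 1e-3
    subject_start_max: int = 9

    def __post_init__(self):
        if self.evalue_max <= 0:
            raise ValidationError("evalue_max must be > 0")


def _pair_key(read_id: str) -> str:
    return read_id.rsplit("/", 1)[0]


def _best_overlap(a: np.ndarray, b: np.ndarray, min_overlap: int, max_rate: float):
    """Offset of b within a maximizing overlap matches among admissible
    placements (overlap >= min_overlap, mismatch rate <= max_rate).

    Returns (offset, overlap_len, matches) or None when no admissible
    placement exists.
    """
    la, lb = len(a), len(b)
    best = None
    for s in range(0, la - min_overlap + 1):
        ov = min(la - s, lb)
        if ov < min_overlap:
            break
        matches = int((a[s : s + ov] == b[:ov]).sum())
        rate = (ov - matches) / ov
        if rate > max_rate:
            continue
        key = (matches, -rate, -s)
        if best is None or key > best[0]:
            best = (key, s, ov, matches)
    if best is None:
        return None
    return best[1], best[2], best[3]


def merge_pairs(
    r1_stream: Iterable[SequenceRecord],
    r2_stream: Iterable[SequenceRecord],
    params: MergeParams | None = None,
) -> tuple[list[SequenceRecord], dict]:
    """Merge mate pairs into full-length amplicon sequences.

    In the overlap the higher-quality base wins (tie: the 5' read's base)
    and the merged quality is the max of the two. Terminal bases below
    ``quality_threshold`` are trimmed; products shorter than
    ``min_length`` are discarded.
    """
    params = params or MergeParams()
    merged: list[SequenceRecord] = []
    report = {"input": 0, "merged": 0, "discarded_overlap": 0, "discarded_length": 0}
    for r1, r2 in zip(r1_stream, r2_stream):
        if _pair_key(r1.id) != _pair_key(r2.id):
            raise ValidationError(f"unpaired reads: {r1.id!r} vs {r2.id!r}")
        report["input"] += 1
        b_seq = reverse_complement(r2.sequence)
        b_qual = (r2.qualities or [40] * len(r2.sequence))[::-1]
        a_qual = r1.qualities or [40] * len(r1.sequence)
        a = np.frombuffer(r1.sequence.encode(), dtype=np.uint8)
        b = np.frombuffer(b_seq.encode(), dtype=np.uint8)
        placement = _best_overlap(
            a, b, params.min_overlap, params.max_overlap_mismatch_rate
        )
        if placement is None:
            report["discarded_overlap"] += 1
            continue
        s, ov, matches = placement
        seq = list(r1.sequence[:s])
        qual = list(a_qual[:s])
        for i in range(ov):
            qa, qb = a_qual[s + i], b_qual[i]
            if qb > qa:
                seq.append(b_seq[i])
            else:
                seq.append(r1.sequence[s + i])
            qual.append(max(qa, qb))
        if s + len(b_seq) >= len(r1.sequence):
            seq += list(b_seq[ov:])
            qual += list(b_qual[ov:])
        else:
            seq += list(r1.sequence[s + ov :])
            qual += list(a_qual[s + ov :])
        # terminal quality trimming
        lo, hi = 0, len(seq)
        while lo < hi and qual[lo] < params.quality_threshold:
            lo += 1
        while hi > lo and qual[hi - 1] < params.quality_threshold:
            hi -= 1
        if hi - lo < params.min_length:
            report["discarded_length"] += 1
            continue
        merged.append(
            SequenceRecord(
                id=_pair_key(r1.id),
                sequence="".join(seq[lo:hi]),
                qualities=qual[lo:hi],
                metadata=dict(r1.metadata),
            )
        )
        report["merged"] += 1
    return merged, report


QC_FLAGS = ("stop_codon", "evalue_fail", "cdr3_motif_fail", "subject_start_fail")


def apply_qc(
    records: Iterable[Rearrangement], params: QCParams | None = None
) -> tuple[list[Rearrangement], list[Rearrangement], dict]:
    """Partition annotated records into QC-pass and QC-reject streams.

    A record is rejected iff any filter fires; all triggered flags are
    recorded on the rejected record. Records must already be annotated.
    """
    params = params or QCParams()
    passing: list[Rearrangement] = []
    rejected: list[Rearrangement] = []
    flag_counts = dict.fromkeys(QC_FLAGS, 0)
    for rec in records:
        if rec.productive is None and rec.v_call is not None:
            raise ValidationError(f"{rec.sequence_id}: record not annotated (productive unset)")
        flags = set()
        if rec.productive is False:
            flags.add("stop_codon")
        if rec.v_call is None or rec.v_evalue is None or rec.v_evalue > params.evalue_max:
            flags.add("evalue_fail")
        if rec.cdr3_aa is None:
            flags.add("cdr3_motif_fail")
        if rec.v_subject_start is not None and rec.v_subject_start > params.subject_start_max:
            flags.add("subject_start_fail")
        rec.qc_flags = frozenset(flags)
        if flags:
            for f in flags:
                flag_counts[f] += 1
            rejected.append(rec)
        else:
            passing.append(rec)
    report = {
        "input": len(passing) + len(rejected),
        "pass": len(passing),
        "reject": len(rejected),
        "flags": flag_counts,
    }
    return passing, rejected, report
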