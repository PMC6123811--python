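"""Deterministic semi-global pairwise alignment with affine gap costs.

This module replaces an external mapper + variant caller with an in-repo,
fully specified stage.  Amplicon reads are substrings of the reference, so
alignment is *semi-global* ("glocal"): the query must be aligned end to
end, while reference overhangs on either side are free.

Scoring
-------
A gap run of length ``g`` costs ``gap_open + g * gap_extend`` (bwa-style);
matches score ``+match`` and mismatches ``-mismatch``.  ``N`` never matches.

Determinism
-----------
Ties are broken the same way on every run:

* among equal-scoring end positions, the smallest reference end wins and a
  match/mismatch column is preferred over a gap column;
* in the traceback, a diagonal (match/mismatch) predecessor is preferred
  over a deletion (gap in the query), which is preferred over an insertion
  (gap in the reference).

Two provably optimal fast paths (exact substring; gapless alignment whose
mismatch cost cannot be beaten by opening any gap) bypass the dynamic
program; they reproduce the same leftmost placement the DP would choose.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .errors import ConfigurationError, InputError
from .variants import DEL, INS, SUB, Variant, left_normalize

__all__ = [
    "Scoring",
    "Alignment",
    "DEFAULT_SCORING",
    "align_semi_global",
    "extract_variants",
    "merge_pair_variants",
    "write_sam",
    "write_vcf",
]

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring parameters (all penalties are magnitudes >= 0)."""

    match: int = 2
    mismatch: int = 4
    gap_open: int = 6
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ConfigurationError("match reward must be > 0")
        if self.mismatch < 0 or self.gap_open < 0 or self.gap_extend < 0:
            raise ConfigurationError("penalties must be >= 0")
        if self.gap_open < self.gap_extend:
            raise ConfigurationError("gap_open must be >= gap_extend")


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class Alignment:
    """Result of a semi-global alignment of a query against a reference.

    ``cigar`` is a tuple of ``(op, length)`` runs with ops ``=`` (match),
    ``X`` (mismatch), ``I`` (insertion to the reference) and ``D``
    (deletion from the reference).  ``=``/``X``/``I`` consume query;
    ``=``/``X``/``D`` consume reference.
    """

    score: int
    cigar: tuple[tuple[str, int], ...]
    ref_start: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in "=XD")

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "=XI")

    def covers(self, start: int, end: int) -> bool:
        """Does the aligned reference span contain ``[start, end)``?"""
        return self.ref_start <= start and self.ref_end >= end


_NEG = np.int32(-(2**28))  # far below any reachable score; no int32 overflow risk


@njit(cache=True)
def _gotoh_kernel(q, r, match, mismatch, go, ge):  # pragma: no cover - exercised via align_semi_global
    """Affine-gap semi-global DP with traceback.

    Returns ``(score, ref_start, ops)`` where ops are int8 codes in query
    order: 0 = diagonal (match/mismatch), 1 = D (gap in query, consumes
    reference), 2 = I (gap in reference, consumes query).
    """
    L = q.shape[0]
    R = r.shape[0]
    M = np.full((L + 1, R + 1), _NEG, dtype=np.int32)
    D = np.full((L + 1, R + 1), _NEG, dtype=np.int32)
    I = np.full((L + 1, R + 1), _NEG, dtype=np.int32)
    pM = np.zeros((L + 1, R + 1), dtype=np.int8)
    pD = np.zeros((L + 1, R + 1), dtype=np.int8)
    pI = np.zeros((L + 1, R + 1), dtype=np.int8)
    for j in range(R + 1):
        M[0, j] = 0  # free leading reference skip: start anywhere
    for i in range(1, L + 1):
        # query overhang hanging off the reference start
        b = M[i - 1, 0] - go - ge
        st = 0
        if I[i - 1, 0] - ge > b:
            b = I[i - 1, 0] - ge
            st = 2
        I[i, 0] = b
        pI[i, 0] = st
        qi = q[i - 1]
        for j in range(1, R + 1):
            if qi == r[j - 1] and qi != 78:  # 78 == 'N'
                s = match
            else:
                s = -mismatch
            # diagonal state: prefer M > D > I predecessors on ties
            b = M[i - 1, j - 1]
            st = 0
            if D[i - 1, j - 1] > b:
                b = D[i - 1, j - 1]
                st = 1
            if I[i - 1, j - 1] > b:
                b = I[i - 1, j - 1]
                st = 2
            M[i, j] = b + s
            pM[i, j] = st
            # I: gap in reference (consumes query), vertical move
            b = M[i - 1, j] - go - ge
            st = 0
            if D[i - 1, j] - go - ge > b:
                b = D[i - 1, j] - go - ge
                st = 1
            if I[i - 1, j] - ge > b:
                b = I[i - 1, j] - ge
                st = 2
            I[i, j] = b
            pI[i, j] = st
            # D: gap in query (consumes reference), horizontal move
            b = M[i, j - 1] - go - ge
            st = 0
            if D[i, j - 1] - ge > b:
                b = D[i, j - 1] - ge
                st = 1
            if I[i, j - 1] - go - ge > b:
                b = I[i, j - 1] - go - ge
                st = 2
            D[i, j] = b
            pD[i, j] = st
    # end anywhere on the reference; trailing reference skip is free
    best = _NEG
    bj = 0
    bs = 0
    for j in range(R + 1):
        if M[L, j] > best:
            best = M[L, j]
            bj = j
            bs = 0
        if I[L, j] > best:
            best = I[L, j]
            bj = j
            bs = 2
    ops = np.empty(L + R + 2, dtype=np.int8)
    n = 0
    i = L
    j = bj
    s = bs
    while i > 0:
        if s == 0:
            ops[n] = 0
            n += 1
            s = pM[i, j]
            i -= 1
            j -= 1
        elif s == 2:
            ops[n] = 2
            n += 1
            s = pI[i, j]
            i -= 1
        else:
            ops[n] = 1
            n += 1
            s = pD[i, j]
            j -= 1
    return best, j, ops[:n][::-1].copy()


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _cigar_from_ops(ops: np.ndarray, query: str, reference: str, ref_start: int) -> tuple[tuple[str, int], ...]:
    runs: list[tuple[str, int]] = []
    qpos = 0
    rpos = ref_start
    for code in ops:
        if code == 0:
            qc = query[qpos]
            op = "=" if (qc == reference[rpos] and qc != "N") else "X"
            qpos += 1
            rpos += 1
        elif code == 1:
            op = "D"
            rpos += 1
        else:
            op = "I"
            qpos += 1
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + 1)
        else:
            runs.append((op, 1))
    return tuple(runs)


def _gapless_candidate(q: np.ndarray, r: np.ndarray) -> tuple[int, int] | None:
    """Best (fewest-mismatch, leftmost) gapless placement of q within r."""
    L, R = q.shape[0], r.shape[0]
    if L > R or L == 0:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(r, L)
    neq = (windows != q) | (windows == 78) | (q == 78)
    mism = neq.sum(axis=1)
    off = int(np.argmin(mism))  # argmin returns the first (leftmost) minimum
    return off, int(mism[off])


def _align_uncached(query: str, reference: str, scoring: Scoring, fast_paths: bool = True) -> Alignment:
    q = _encode(query)
    r = _encode(reference)
    go, ge = scoring.gap_open, scoring.gap_extend
    cand = _gapless_candidate(q, r) if fast_paths else None
    if cand is not None:
        off, k = cand
        # A gapless alignment with k mismatches scores match*L - k*(match+mismatch).
        # Any alignment containing a gap scores at most match*L - (gap_open+gap_extend),
        # so the gapless placement is provably optimal when
        # k*(match+mismatch) <= gap_open + gap_extend (ties prefer the mismatch).
        if k * (scoring.match + scoring.mismatch) <= go + ge:
            score = scoring.match * len(query) - k * (scoring.match + scoring.mismatch)
            ops = np.zeros(len(query), dtype=np.int8)
            cigar = _cigar_from_ops(ops, query, reference, off)
            return Alignment(score=score, cigar=cigar, ref_start=off)
    score, ref_start, ops = _gotoh_kernel(
        q, r, np.int32(scoring.match), np.int32(scoring.mismatch), np.int32(go), np.int32(ge)
    )
    cigar = _cigar_from_ops(ops, query, reference, ref_start)
    return Alignment(score=int(score), cigar=cigar, ref_start=int(ref_start))


@lru_cache(maxsize=100_000)
def _align_cached(query: str, reference: str, scoring: Scoring) -> Alignment:
    return _align_uncached(query, reference, scoring)


def align_semi_global(query: str, reference: str, scoring: Scoring = DEFAULT_SCORING) -> Alignment:
    """Optimal semi-global alignment of ``query`` against ``reference``.

    Parameters
    ----------
    query, reference:
        Non-empty strings over ``ACGTN``.
    scoring:
        Affine gap scoring; see :class:`Scoring`.

    Returns
    -------
    Alignment
        Optimal-score alignment with deterministic tie-breaking (see module
        docstring).  Results are memoized on ``(query, reference, scoring)``.
    """
    if not query or not reference:
        raise InputError("query and reference must be non-empty")
    for name, seq in (("query", query), ("reference", reference)):
        if set(seq) - _VALID:
            raise InputError(f"{name} contains characters outside ACGTN")
    return _align_cached(query, reference, scoring)


def extract_variants(
    aln: Alignment,
    reference: str,
    query: str,
    quals: Sequence[int] | None = None,
) -> list[Variant]:
    """Turn the non-match runs of an alignment into left-normalized variants.

    Each maximal run of ``X``/``I``/``D`` columns yields one variant.  The
    variant quality is the mean Phred quality of the query bases involved
    (for deletions: the mean of the two flanking query bases).  With
    ``quals=None`` all variant qualities are ``None``.
    """
    variants: list[Variant] = []
    qpos = 0
    rpos = aln.ref_start
    for op, n in aln.cigar:
        if op == "=":
            qpos += n
            rpos += n
        elif op == "X":
            qual = float(np.mean(quals[qpos:qpos + n])) if quals is not None else None
            variants.append(Variant(rpos, SUB, reference[rpos:rpos + n], query[qpos:qpos + n], qual))
            qpos += n
            rpos += n
        elif op == "I":
            qual = float(np.mean(quals[qpos:qpos + n])) if quals is not None else None
            variants.append(left_normalize(Variant(rpos, INS, "", query[qpos:qpos + n], qual), reference))
            qpos += n
        elif op == "D":
            if quals is not None:
                flanks = [quals[i] for i in (qpos - 1, qpos) if 0 <= i < len(quals)]
                qual = float(np.mean(flanks)) if flanks else None
            else:
                qual = None
            variants.append(left_normalize(Variant(rpos, DEL, reference[rpos:rpos + n], "", qual), reference))
            rpos += n
        else:  # pragma: no cover - cigar ops are produced internally
            raise InputError(f"unknown cigar op {op!r}")
    return variants


def merge_pair_variants(variants_by_mate: Iterable[Sequence[Variant]]) -> list[Variant]:
    """Union of per-mate variant sets.

    Identical variants seen on both mates are kept once with the higher
    quality; conflicting calls at the same (position, kind) keep only the
    higher-quality one.
    """
    chosen: dict[tuple[int, str], Variant] = {}
    for mate in variants_by_mate:
        for v in mate:
            key = (v.ref_pos, v.kind)
            cur = chosen.get(key)
            if cur is None:
                chosen[key] = v
            else:
                vq = v.qual if v.qual is not None else float("inf")
                cq = cur.qual if cur.qual is not None else float("inf")
                if vq > cq:
                    chosen[key] = v
    return sorted(chosen.values(), key=lambda v: (v.ref_pos, v.kind, v.alt_allele))


# ---------------------------------------------------------------------------
# Standard-format export (SAM via pysam, minimal VCF records)
# ---------------------------------------------------------------------------


def write_sam(
    records: Iterable[tuple[str, str, Alignment]],
    reference_name: str,
    reference_length: int,
    path: str,
) -> None:
    """Write ``(read_name, query_seq, alignment)`` triples as a text SAM file."""
    import pysam

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": reference_name, "LN": reference_length}],
        }
    )
    op_codes = {"=": 7, "X": 8, "I": 1, "D": 2}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for name, query, aln in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = name
            seg.query_sequence = query
            seg.reference_id = 0
            seg.reference_start = aln.ref_start
            seg.mapping_quality = 255
            seg.cigartuples = [(op_codes[op], n) for op, n in aln.cigar]
            seg.flag = 0
            out.write(seg)


def write_vcf(
    variants: Sequence[Variant],
    reference: str,
    reference_name: str,
    path: str,
) -> None:
    """Write variants as minimal VCF records (1-based, anchor-base indels)."""
    import pysam

    header = pysam.VariantHeader()
    header.contigs.add(reference_name, length=len(reference))
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in sorted(variants, key=lambda x: (x.ref_pos, x.kind)):
            if v.kind == SUB:
                start = v.ref_pos
                ref_allele, alt_allele = v.ref_allele, v.alt_allele
            elif v.kind == DEL:
                if v.ref_pos > 0:
                    start = v.ref_pos - 1
                    anchor = reference[start]
                    ref_allele, alt_allele = anchor + v.ref_allele, anchor
                else:
                    start = 0
                    anchor = reference[v.ref_span[1]]
                    ref_allele, alt_allele = v.ref_allele + anchor, anchor
            else:  # INS
                if v.ref_pos > 0:
                    start = v.ref_pos - 1
                    anchor = reference[start]
                    ref_allele, alt_allele = anchor, anchor + v.alt_allele
                else:
                    start = 0
                    anchor = reference[0]
                    ref_allele, alt_allele = anchor, v.alt_allele + anchor
            rec = out.new_record(
                contig=reference_name,
                start=start,
                alleles=(ref_allele, alt_allele),
            )
            if v.qual is not None:
                rec.qual = v.qual
            out.write(rec)
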