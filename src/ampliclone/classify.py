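"""Read-level allele classification (WT / HDR / NHEJ) and per-clone tallies.

A read pair is aligned independently to the wild-type and to the edited
(HDR) reference.  Only variants inside the edit window with quality at or
above ``qual_threshold`` count; everything else (flank noise, low-quality
sequencing errors) is ignored for classification but kept in the call for
inspection.  The decision rule:

* WT   — the wild-type alignment has no qualifying window variant;
* HDR  — the edited-sequence alignment has no qualifying window variant;
* both — the pair misses every diagnostic position: UNINFORMATIVE;
* neither — NHEJ, with a signature built from the WT-relative qualifying
  window variants.

Pairs in which no mate spans the edit window are UNINFORMATIVE.  Reads
best explained by HDR-plus-indel are still reported as NHEJ (the three-way
scheme has no mixed class); their signature is WT-relative.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import Alignment, DEFAULT_SCORING, Scoring, align_semi_global, extract_variants, merge_pair_variants
from .errors import ConfigurationError, InputError
from .io import ReadRecord
from .references import ReferencePair
from .variants import Variant, canonical_signature, overlaps_window

WT = "WT"
HDR = "HDR"
NHEJ = "NHEJ"
UNINFORMATIVE = "UNINFORMATIVE"

DEFAULT_QUAL_THRESHOLD = 30.0


@dataclass(frozen=True)
class ReadCall:
    """Classification of one read pair."""

    class_: str
    signature: str
    wt_variants: tuple[Variant, ...]
    hdr_variants: tuple[Variant, ...]
    flank_variants: tuple[Variant, ...]

    @property
    def informative(self) -> bool:
        return self.class_ != UNINFORMATIVE


def _qualifying(variants: Iterable[Variant], window: tuple[int, int], threshold: float) -> list[Variant]:
    return [
        v
        for v in variants
        if overlaps_window(v, *window) and (v.qual is None or v.qual >= threshold)
    ]


def _mate_variants(
    read: ReadRecord, reference: str, window: tuple[int, int], scoring: Scoring
) -> tuple[Alignment, list[Variant]]:
    aln = align_semi_global(read.seq, reference, scoring)
    return aln, extract_variants(aln, reference, read.seq, read.quals)


def classify_read(
    read_pair: tuple[ReadRecord, ReadRecord | None],
    refs: ReferencePair,
    scoring: Scoring = DEFAULT_SCORING,
    qual_threshold: float = DEFAULT_QUAL_THRESHOLD,
    r2_is_reverse: bool = True,
) -> ReadCall:
    """Classify one read pair against a WT/HDR reference pair.

    ``r2_is_reverse`` reverse-complements the second mate before alignment
    (standard paired-end amplicon orientation).  A pair's variant set is the
    union over mates; identical calls merge keeping the higher quality, and
    conflicting calls at one position keep only the higher-quality one.
    """
    if refs.is_edit_silent:
        raise ConfigurationError("wt_seq and hdr_seq are identical: classification is impossible")
    r1, r2 = read_pair
    mates = [r1]
    if r2 is not None:
        mates.append(r2.reverse_complement() if r2_is_reverse else r2)
    for m in mates:
        if not m.seq:
            raise InputError(f"read {m.id} is empty")

    wt_window = refs.edit_window
    hdr_window = refs.hdr_window
    wt_sets: list[list[Variant]] = []
    hdr_sets: list[list[Variant]] = []
    informative = False
    for mate in mates:
        wt_aln, wt_vars = _mate_variants(mate, refs.wt_seq, wt_window, scoring)
        hdr_aln, hdr_vars = _mate_variants(mate, refs.hdr_seq, hdr_window, scoring)
        if wt_aln.covers(*wt_window) and hdr_aln.covers(*hdr_window):
            informative = True
            wt_sets.append(wt_vars)
            hdr_sets.append(hdr_vars)
    if not informative:
        return ReadCall(UNINFORMATIVE, "", (), (), ())

    wt_merged = merge_pair_variants(wt_sets)
    hdr_merged = merge_pair_variants(hdr_sets)
    wt_qual = _qualifying(wt_merged, wt_window, qual_threshold)
    hdr_qual = _qualifying(hdr_merged, hdr_window, qual_threshold)
    flank = tuple(v for v in wt_merged if not overlaps_window(v, *wt_window))

    wt_clean = not wt_qual
    hdr_clean = not hdr_qual
    if wt_clean and hdr_clean:
        # possible only when the pair misses all diagnostic positions
        return ReadCall(UNINFORMATIVE, "", tuple(wt_merged), tuple(hdr_merged), flank)
    if wt_clean:
        return ReadCall(WT, "", tuple(wt_merged), tuple(hdr_merged), flank)
    if hdr_clean:
        return ReadCall(HDR, "", tuple(wt_merged), tuple(hdr_merged), flank)
    return ReadCall(
        NHEJ,
        canonical_signature(wt_qual),
        tuple(wt_merged),
        tuple(hdr_merged),
        flank,
    )


@dataclass(frozen=True)
class AlleleRow:
    class_: str
    signature: str
    reads: int
    frequency: float


@dataclass(frozen=True)
class AlleleTable:
    """Per-clone tally of distinct observed alleles."""

    clone_id: str
    rows: tuple[AlleleRow, ...]
    informative_reads: int
    uninformative_reads: int

    @property
    def total_reads(self) -> int:
        return self.informative_reads + self.uninformative_reads


def tally_alleles(calls: Sequence[ReadCall], clone_id: str) -> AlleleTable:
    """Group informative calls by (class, signature).

    Frequencies are computed over informative reads only; uninformative
    reads are counted separately.  Rows are ordered by descending read
    count then (class, signature), so the table is independent of input
    read order.
    """
    informative = [c for c in calls if c.informative]
    uninformative = len(calls) - len(informative)
    counts = Counter((c.class_, c.signature) for c in informative)
    n = len(informative)
    rows = tuple(
        AlleleRow(class_=k[0], signature=k[1], reads=v, frequency=v / n)
        for k, v in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return AlleleTable(
        clone_id=clone_id,
        rows=rows,
        informative_reads=n,
        uninformative_reads=uninformative,
    )


def allele_table_tsv_rows(table: AlleleTable) -> list[dict]:
    rows = [
        {
            "clone_id": table.clone_id,
            "class": r.class_,
            "signature": r.signature,
            "reads": r.reads,
            "frequency": round(r.frequency, 6),
            "uninformative_reads": table.uninformative_reads,
        }
        for r in table.rows
    ]
    if not rows:
        rows.append(
            {
                "clone_id": table.clone_id,
                "class": "",
                "signature": "",
                "reads": 0,
                "frequency": 0.0,
                "uninformative_reads": table.uninformative_reads,
            }
        )
    return rows
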