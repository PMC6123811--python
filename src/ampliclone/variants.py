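"""Variant records and their canonical (left-normalized) representation.

A :class:`Variant` describes a single difference between a query haplotype
and a reference sequence, in 0-based reference coordinates:

* ``SUB`` — ``ref_allele`` and ``alt_allele`` have equal, non-zero length;
* ``INS`` — ``ref_allele`` is empty, the ``alt_allele`` bases are inserted
  *before* reference position ``ref_pos``;
* ``DEL`` — ``alt_allele`` is empty, the bases ``ref[ref_pos:ref_pos+len]``
  are removed.

Indels are ambiguous in repetitive context; :func:`left_normalize` shifts
them to the smallest reference position that preserves the alternate
haplotype, which makes variant sets comparable across alignments and is the
basis of allele *signatures* (see :func:`canonical_signature`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .errors import InputError

SUB = "SUB"
INS = "INS"
DEL = "DEL"

_KINDS = (SUB, INS, DEL)


@dataclass(frozen=True, order=True)
class Variant:
    """A single reference-relative sequence difference."""

    ref_pos: int
    kind: str
    ref_allele: str
    alt_allele: str
    qual: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InputError(f"unknown variant kind {self.kind!r}")
        if self.kind == SUB:
            if len(self.ref_allele) != len(self.alt_allele) or not self.ref_allele:
                raise InputError("SUB requires equal-length, non-empty alleles")
        elif self.kind == INS:
            if self.ref_allele or not self.alt_allele:
                raise InputError("INS requires empty ref_allele and non-empty alt_allele")
        elif self.kind == DEL:
            if self.alt_allele or not self.ref_allele:
                raise InputError("DEL requires empty alt_allele and non-empty ref_allele")
        if self.ref_pos < 0:
            raise InputError("ref_pos must be >= 0")

    @property
    def ref_span(self) -> tuple[int, int]:
        """Half-open reference interval consumed by the variant.

        Insertions consume no reference; their span is the empty interval
        at the insertion point.
        """
        return self.ref_pos, self.ref_pos + len(self.ref_allele)

    @property
    def token(self) -> str:
        """Position/kind/allele token used in allele signatures (no quality)."""
        return f"{self.ref_pos}:{self.kind}:{self.ref_allele}>{self.alt_allele}"


def left_normalize(variant: Variant, reference: str) -> Variant:
    """Shift an indel to its leftmost equivalent reference position.

    Substitutions are returned unchanged.  The operation is idempotent.
    """
    if variant.kind == SUB:
        return variant
    pos = variant.ref_pos
    if variant.kind == DEL:
        length = len(variant.ref_allele)
        while pos > 0 and reference[pos - 1] == reference[pos + length - 1]:
            pos -= 1
        if pos == variant.ref_pos:
            return variant
        return replace(variant, ref_pos=pos, ref_allele=reference[pos:pos + length])
    # INS
    seq = variant.alt_allele
    while pos > 0 and reference[pos - 1] == seq[-1]:
        seq = reference[pos - 1] + seq[:-1]
        pos -= 1
    if pos == variant.ref_pos:
        return variant
    return replace(variant, ref_pos=pos, alt_allele=seq)


def canonical_signature(variants: Iterable[Variant]) -> str:
    """Canonical string for a set of variants: sorted, quality-free tokens.

    The empty string denotes "no variants" (a reference-identical allele).
    """
    toks = sorted(
        (v.ref_pos, v.kind, v.token) for v in variants
    )
    return ";".join(t[2] for t in toks)


def overlaps_window(variant: Variant, start: int, end: int) -> bool:
    """True if the variant touches the half-open window ``[start, end)``.

    SUB/DEL overlap by reference span; an INS counts when its insertion
    point lies inside the window.
    """
    if variant.kind == INS:
        return start <= variant.ref_pos < end
    a, b = variant.ref_span
    return a < end and b > start


def apply_variants(reference: str, variants: Sequence[Variant]) -> str:
    """Construct the alternate haplotype carrying ``variants``.

    Variants must not overlap on the reference.
    """
    ordered = sorted(variants, key=lambda v: (v.ref_pos, v.kind))
    last_end = -1
    for v in ordered:
        a, b = v.ref_span
        if a < last_end or b > len(reference):
            raise InputError(f"variant {v.token} overlaps a previous variant or runs off the reference")
        if v.kind == SUB and reference[a:b] != v.ref_allele:
            raise InputError(f"SUB ref_allele mismatch at {v.ref_pos}")
        if v.kind == DEL and reference[a:b] != v.ref_allele:
            raise InputError(f"DEL ref_allele mismatch at {v.ref_pos}")
        last_end = max(last_end, b) if v.kind != INS else max(last_end, a)
    out = []
    cursor = 0
    for v in ordered:
        out.append(reference[cursor:v.ref_pos])
        out.append(v.alt_allele)
        cursor = v.ref_pos + len(v.ref_allele)
    out.append(reference[cursor:])
    return "".join(out)
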