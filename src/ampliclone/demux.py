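"""Inline-barcode demultiplexing of paired FASTQ reads.

The sample barcode is read from the R1 prefix only; R2 is paired with R1
by record order.  A read pair is assigned to a sample when exactly one
barcode lies within ``max_mismatch`` Hamming distance of the R1 prefix;
otherwise (no barcode, or more than one) it goes to the unassigned set.
Assigned R1 reads are emitted with the barcode prefix stripped.

Every input pair lands in exactly one output set, so counts are conserved
(partition property) and per-sample sets preserve input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

from .errors import ConfigurationError
from .io import ReadPair
from .references import _check_dna

UNASSIGNED = "unassigned"


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class BarcodeMap:
    """Sample-id -> inline barcode mapping (all barcodes same length)."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigurationError("barcode map is empty")
        lengths = {len(bc) for bc in self.entries.values()}
        if len(lengths) != 1:
            raise ConfigurationError("all barcodes must have the same length")
        if len(set(self.entries.values())) != len(self.entries):
            raise ConfigurationError("barcodes must be pairwise distinct")
        for sample, bc in self.entries.items():
            _check_dna(bc, f"barcode for {sample}", allow_n=False)

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.entries.values())))

    def min_pairwise_distance(self) -> int:
        if len(self.entries) == 1:
            return self.barcode_length
        return min(hamming(a, b) for a, b in combinations(self.entries.values(), 2))

    def validate_for_mismatch(self, max_mismatch: int) -> None:
        """Raise when some read prefix could match two barcodes at once."""
        if self.min_pairwise_distance() <= 2 * max_mismatch:
            raise ConfigurationError(
                f"barcode set has pairwise Hamming distance <= {2 * max_mismatch}; "
                f"ambiguous assignments are unavoidable at max_mismatch={max_mismatch}"
            )

    @classmethod
    def from_tsv(cls, path: str) -> "BarcodeMap":
        entries: dict[str, str] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("sample_id"):
                raise ConfigurationError(f"{path}: expected header 'sample_id\\tbarcode'")
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                sample, bc = line.split("\t")[:2]
                if sample in entries:
                    raise ConfigurationError(f"duplicate sample_id {sample!r}")
                entries[sample] = bc.upper()
        return cls(entries)


@dataclass
class DemuxResult:
    """Partition of the input read pairs."""

    by_sample: dict[str, list[ReadPair]]
    unassigned: list[ReadPair] = field(default_factory=list)

    @property
    def total_assigned(self) -> int:
        return sum(len(v) for v in self.by_sample.values())

    @property
    def total(self) -> int:
        return self.total_assigned + len(self.unassigned)

    def summary_rows(self) -> list[dict]:
        total = self.total or 1
        rows = [
            {"sample_id": s, "assigned": len(v), "fraction": len(v) / total}
            for s, v in self.by_sample.items()
        ]
        rows.append(
            {
                "sample_id": UNASSIGNED,
                "assigned": len(self.unassigned),
                "fraction": len(self.unassigned) / total,
            }
        )
        return rows


def demultiplex(
    read_pairs: Iterable[ReadPair],
    barcode_map: BarcodeMap,
    max_mismatch: int = 0,
    strict: bool = False,
) -> DemuxResult:
    """Split read pairs by R1 barcode prefix.

    With ``strict=True`` a barcode set whose pairwise distance makes
    ambiguity possible at this ``max_mismatch`` raises a
    :class:`ConfigurationError`; by default it only warns, and any
    ambiguous read pair is routed to the unassigned set.
    """
    if max_mismatch < 0:
        raise ConfigurationError("max_mismatch must be >= 0")
    if strict:
        barcode_map.validate_for_mismatch(max_mismatch)
    elif barcode_map.min_pairwise_distance() <= 2 * max_mismatch:
        warnings.warn(
            "barcode set allows ambiguous prefixes at this max_mismatch; "
            "ambiguous reads will be unassigned",
            stacklevel=2,
        )
    bl = barcode_map.barcode_length
    exact = {bc: sample for sample, bc in barcode_map.entries.items()}
    result = DemuxResult(by_sample={sample: [] for sample in barcode_map.entries})
    for r1, r2 in read_pairs:
        if len(r1.seq) < bl:
            result.unassigned.append((r1, r2))
            continue
        prefix = r1.seq[:bl]
        if max_mismatch == 0:
            sample = exact.get(prefix)
        else:
            hits = [
                s for s, bc in barcode_map.entries.items() if hamming(prefix, bc) <= max_mismatch
            ]
            sample = hits[0] if len(hits) == 1 else None
        if sample is None:
            result.unassigned.append((r1, r2))
        else:
            result.by_sample[sample].append((r1.strip_prefix(bl), r2))
    return result
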