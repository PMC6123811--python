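"""Reference amplicon pairs: the wild-type and edited (knock-in) sequences.

The :class:`ReferencePair` is the coordinate frame for the whole analysis:
the cut site and edit window are given on wild-type coordinates, and the
edited sequence may only differ from the wild type inside the edit window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import ConfigurationError, InputError

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _check_dna(seq: str, name: str, allow_n: bool = True) -> None:
    allowed = VALID_BASES if allow_n else VALID_BASES - {"N"}
    bad = set(seq) - allowed
    if bad:
        raise InputError(f"{name} contains non-DNA characters: {sorted(bad)}")


@dataclass(frozen=True)
class ReferencePair:
    """Wild-type and edited amplicon with the edit-window coordinate frame.

    Attributes
    ----------
    name:
        Locus / amplicon name (used in SAM/VCF output).
    wt_seq, hdr_seq:
        Uppercase ACGT amplicon sequences.  ``hdr_seq`` must equal
        ``wt_seq`` outside ``edit_window``.
    cut_site:
        0-based nuclease cut position on ``wt_seq``; must fall inside the
        edit window.
    edit_window:
        Half-open ``[start, end)`` interval on wild-type coordinates
        covering the replaced block plus flanking context.
    """

    name: str
    wt_seq: str
    hdr_seq: str
    cut_site: int
    edit_window: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.wt_seq or not self.hdr_seq:
            raise ConfigurationError("reference sequences must be non-empty")
        _check_dna(self.wt_seq, "wt_seq")
        _check_dna(self.hdr_seq, "hdr_seq")
        start, end = self.edit_window
        if not (0 <= start < end <= len(self.wt_seq)):
            raise ConfigurationError(f"edit_window {self.edit_window} outside wt_seq")
        if not (start <= self.cut_site < end):
            raise ConfigurationError("cut_site must lie inside edit_window")
        shift = len(self.hdr_seq) - len(self.wt_seq)
        if self.wt_seq[:start] != self.hdr_seq[:start] or self.wt_seq[end:] != self.hdr_seq[end + shift:]:
            raise ConfigurationError("hdr_seq differs from wt_seq outside edit_window")

    @property
    def hdr_window(self) -> tuple[int, int]:
        """The edit window in edited-sequence coordinates."""
        start, end = self.edit_window
        return start, end + len(self.hdr_seq) - len(self.wt_seq)

    @property
    def is_edit_silent(self) -> bool:
        """True when the edited sequence is identical to wild type."""
        return self.wt_seq == self.hdr_seq

    def warn_if_short(self, read_length: int) -> None:
        """Warn about read geometries that undermine edit-window coverage."""
        if len(self.wt_seq) < read_length:
            warnings.warn(
                f"amplicon {self.name!r} is shorter than the read length "
                f"({len(self.wt_seq)} < {read_length}); fragments will be truncated",
                stacklevel=2,
            )
        elif len(self.wt_seq) > 2 * read_length:
            warnings.warn(
                f"amplicon {self.name!r} is longer than 2x read length "
                f"({len(self.wt_seq)} > {2 * read_length}); mates cannot overlap and "
                "the edit window may be uncovered",
                stacklevel=2,
            )


def default_reference_pair(
    length: int = 400,
    cut_site: int = 200,
    replace_len: int = 12,
    flank: int = 6,
    seed: int = 12345,
) -> ReferencePair:
    """Packaged synthetic fixture: a random amplicon with a centred
    ``replace_len``-nt replacement around the cut site.

    The replacement block differs from wild type at every position, giving
    the classifier a fully diagnostic window.  Deterministic for a given
    seed.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    wt = "".join(rng.choice(bases, size=length))
    start = cut_site - replace_len // 2
    end = start + replace_len
    block = []
    for i in range(start, end):
        others = [b for b in "ACGT" if b != wt[i]]
        block.append(others[rng.integers(3)])
    hdr = wt[:start] + "".join(block) + wt[end:]
    window = (max(0, start - flank), min(length, end + flank))
    return ReferencePair(
        name="synthetic_amplicon",
        wt_seq=wt,
        hdr_seq=hdr,
        cut_site=cut_site,
        edit_window=window,
    )


def reference_pair_from_fasta(
    path: str,
    cut_site: int,
    window_start: int,
    window_end: int,
    name: str | None = None,
) -> ReferencePair:
    """Load a WT/HDR pair from a two-record FASTA (WT first, HDR second)."""
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) != 2:
        raise InputError(f"expected exactly 2 FASTA records (WT, HDR) in {path}, found {len(records)}")
    wt, hdr = records
    return ReferencePair(
        name=name or wt.id,
        wt_seq=str(wt.seq).upper(),
        hdr_seq=str(hdr.seq).upper(),
        cut_site=cut_site,
        edit_window=(window_start, window_end),
    )


def write_reference_fasta(refs: ReferencePair, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{refs.name}_WT\n{refs.wt_seq}\n>{refs.name}_HDR\n{refs.hdr_seq}\n")
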