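"""Synthetic ground-truth data: edited clones, amplicon reads, pens, exports.

Every downstream stage of the pipeline is testable against this module
without any external data.  The model is deliberately small:

* a diploid clone resolves its two Cas9-cut alleles either before the first
  division (two lineages at fraction 0.5) or, with probability
  ``p_late_edit``, after one division (four independently drawn lineages at
  fraction 0.25) — the simplest model that produces clones with more than
  two distinct alleles;
* repair outcomes are HDR (the knock-in template sequence), NHEJ (a single
  indel with its left edge at the cut site, or 1–3 point mutations inside
  the edit window), or unedited wild type;
* reads are fixed-length fragments anchored at the amplicon ends
  (primer-anchored amplicon sequencing): R1 reads the start of the
  amplicon behind an inline sample barcode, R2 reads the reverse
  complement of the amplicon end;
* sequencing errors are per-base substitutions and (rare) indels; correct
  bases get ``qual_profile["correct"]`` (default Q37) and errored bases
  ``qual_profile["error"]`` (default Q12), which gives a quality-30 filter
  discriminating power.

Reproducibility: every public entry point takes a seed (or a
``numpy.random.Generator``); per-clone/per-pen child streams are derived by
stable hashing of ``(master_seed, label)`` so datasets are byte-identical
across runs and machines.  Inline barcodes are written error-free by
default so that demultiplexing fidelity can be controlled independently of
the sequencing error model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .chip import ExportRecord, PenRecord
from .errors import ConfigurationError, SimulationError
from .io import ReadRecord
from .references import ReferencePair, revcomp, _check_dna
from .variants import (
    DEL,
    INS,
    SUB,
    Variant,
    apply_variants,
    canonical_signature,
    left_normalize,
)

WT = "WT"
HDR = "HDR"
NHEJ = "NHEJ"

_Q_DEFAULT = {"correct": 37, "error": 12}


def _default_indel_dist() -> dict[int, float]:
    """Geometric-ish indel length distribution over -10..10 (no zero),
    deletions twice as likely as insertions."""
    weights = {}
    for length in range(1, 11):
        w = 0.62 ** length
        weights[-length] = 2.0 * w
        weights[length] = w
    total = sum(weights.values())
    return {k: v / total for k, v in sorted(weights.items())}


def as_rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def child_rng(master_seed: int, label: str) -> np.random.Generator:
    """Derive a reproducible child stream from a master seed and a label."""
    digest = hashlib.blake2b(label.encode(), digest_size=8).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int.from_bytes(digest, "big")])
    )


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EditModel:
    """Per-allele editing-outcome probabilities.

    ``p_hdr + p_nhej <= 1``; the remainder is unedited wild type.  An NHEJ
    outcome is a point-mutation cluster with probability ``p_point_nhej``,
    otherwise an indel with signed length drawn from ``indel_length_dist``.
    """

    p_hdr: float = 0.2
    p_nhej: float = 0.55
    indel_length_dist: Mapping[int, float] = field(default_factory=_default_indel_dist)
    p_late_edit: float = 0.0
    p_point_nhej: float = 0.05
    contamination_rate: float = 0.0
    contaminant_fraction: float = 0.1

    def __post_init__(self) -> None:
        probs = (
            self.p_hdr,
            self.p_nhej,
            self.p_late_edit,
            self.p_point_nhej,
            self.contamination_rate,
            self.contaminant_fraction,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        if self.p_hdr + self.p_nhej > 1.0 + 1e-12:
            raise ConfigurationError("p_hdr + p_nhej must be <= 1")
        if self.p_nhej > 0:
            dist = dict(self.indel_length_dist)
            if not dist:
                raise ConfigurationError("indel_length_dist must be non-empty when p_nhej > 0")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigurationError("indel_length_dist must sum to 1")
            if dist.get(0, 0.0) != 0.0:
                raise ConfigurationError("indel_length_dist must assign zero mass to length 0")
            if any(p < 0 for p in dist.values()):
                raise ConfigurationError("indel_length_dist probabilities must be >= 0")


@dataclass(frozen=True)
class Allele:
    """One repair outcome: class, WT-relative variants and their signature."""

    class_: str
    variants: tuple[Variant, ...]
    signature: str

    @property
    def key(self) -> tuple[str, str]:
        return self.class_, self.signature


@dataclass(frozen=True)
class AlleleLineage:
    class_: str
    signature: str
    variants: tuple[Variant, ...]
    fraction: float


@dataclass(frozen=True)
class CloneTruth:
    """Ground truth for one simulated clone."""

    clone_id: str
    alleles: tuple[AlleleLineage, ...]
    contaminated: bool = False

    def __post_init__(self) -> None:
        total = sum(a.fraction for a in self.alleles)
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"{self.clone_id}: lineage fractions sum to {total}, not 1")
        if len(self.alleles) > 4:
            raise SimulationError(f"{self.clone_id}: more than 4 allele lineages")


@dataclass(frozen=True)
class ErrorModel:
    """Sequencing error and read-geometry parameters (artifact plumbing)."""

    sub_rate: float = 0.003
    seq_indel_rate: float = 0.0001
    qual_profile: Mapping[str, int] = field(default_factory=lambda: dict(_Q_DEFAULT))
    read_length: int = 250
    depth: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.sub_rate < 1.0) or not (0.0 <= self.seq_indel_rate < 1.0):
            raise ConfigurationError("error rates must lie in [0, 1)")
        if self.read_length <= 0 or self.depth <= 0:
            raise ConfigurationError("read_length and depth must be > 0")
        for key in ("correct", "error"):
            if key not in self.qual_profile:
                raise ConfigurationError(f"qual_profile missing {key!r}")

    @property
    def q_correct(self) -> int:
        return int(self.qual_profile["correct"])

    @property
    def q_error(self) -> int:
        return int(self.qual_profile["error"])


@dataclass(frozen=True)
class GrowthModel:
    """On-chip colony growth parameters."""

    doubling_time_h: float = 24.0
    p_no_growth: float = 0.6
    p_contam_pen: float = 0.02
    timepoints_h: tuple[int, ...] = (0, 24, 48, 72)

    def __post_init__(self) -> None:
        if self.doubling_time_h <= 0:
            raise ConfigurationError("doubling_time_h must be > 0")
        if not (0.0 <= self.p_no_growth <= 1.0) or not (0.0 <= self.p_contam_pen <= 1.0):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if 0 not in self.timepoints_h:
            raise ConfigurationError("timepoints_h must include hour 0")


# ---------------------------------------------------------------------------
# Allele and clone simulation
# ---------------------------------------------------------------------------

_WT_ALLELE = ("WT", (), "")


def draw_allele_outcome(
    model: EditModel,
    refs: ReferencePair,
    rng_seed: int | np.random.Generator,
) -> Allele:
    """Draw one per-allele repair outcome.

    Returns a WT allele (empty signature), the canonical HDR allele, or an
    NHEJ allele whose indel is placed with its left edge at the cut site
    and then left-normalized.
    """
    rng = as_rng(rng_seed)
    u = rng.random()
    if u < model.p_hdr:
        return Allele(HDR, (), "")
    if u < model.p_hdr + model.p_nhej:
        return _draw_nhej(model, refs, rng)
    return Allele(WT, (), "")


def _draw_nhej(model: EditModel, refs: ReferencePair, rng: np.random.Generator) -> Allele:
    wt = refs.wt_seq
    cut = refs.cut_site
    if rng.random() < model.p_point_nhej:
        start, end = refs.edit_window
        k = int(rng.integers(1, 4))
        positions = sorted(rng.choice(np.arange(start, end), size=k, replace=False).tolist())
        variants = []
        for pos in positions:
            others = [b for b in "ACGT" if b != wt[pos]]
            alt = others[int(rng.integers(3))]
            variants.append(Variant(int(pos), SUB, wt[pos], alt))
        variants = tuple(variants)
        return Allele(NHEJ, variants, canonical_signature(variants))
    lengths = sorted(model.indel_length_dist)
    probs = np.array([model.indel_length_dist[l] for l in lengths])
    length = int(rng.choice(lengths, p=probs / probs.sum()))
    if length < 0:
        size = -length
        if cut + size > len(wt):
            raise SimulationError(f"deletion of {size} at cut site {cut} runs off the amplicon")
        var = left_normalize(Variant(cut, DEL, wt[cut:cut + size], ""), wt)
    else:
        bases = "".join(np.random.default_rng(rng.integers(2**32)).choice(list("ACGT"), size=length))
        var = left_normalize(Variant(cut, INS, "", bases), wt)
    variants = (var,)
    return Allele(NHEJ, variants, canonical_signature(variants))


def simulate_clone(
    model: EditModel,
    refs: ReferencePair,
    rng_seed: int | np.random.Generator,
    clone_id: str = "clone",
) -> CloneTruth:
    """Simulate one diploid clone.

    With probability ``1 - p_late_edit`` the two parental alleles resolve
    before division (two lineages at 0.5); otherwise editing resolves after
    one division, giving four independent outcome draws at 0.25 each (two
    per parental allele).  Lineages with identical (class, signature) are
    merged by summing fractions.
    """
    rng = as_rng(rng_seed)
    late = rng.random() < model.p_late_edit
    n_draws = 4 if late else 2
    draws = [draw_allele_outcome(model, refs, rng) for _ in range(n_draws)]
    merged: dict[tuple[str, str], AlleleLineage] = {}
    for allele in draws:
        cur = merged.get(allele.key)
        if cur is None:
            merged[allele.key] = AlleleLineage(
                allele.class_, allele.signature, allele.variants, 1.0 / n_draws
            )
        else:
            merged[allele.key] = replace(cur, fraction=cur.fraction + 1.0 / n_draws)
    lineages = tuple(
        sorted(merged.values(), key=lambda a: (-a.fraction, a.class_, a.signature))
    )
    return CloneTruth(clone_id=clone_id, alleles=lineages)


def allele_sequence(lineage: AlleleLineage, refs: ReferencePair) -> str:
    if lineage.class_ == WT:
        return refs.wt_seq
    if lineage.class_ == HDR:
        return refs.hdr_seq
    return apply_variants(refs.wt_seq, lineage.variants)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedPair:
    """A read pair plus its provenance (which allele of which clone)."""

    r1: ReadRecord
    r2: ReadRecord
    source_clone: str
    allele_index: int
    allele_class: str
    is_contaminant: bool

    @property
    def pair(self) -> tuple[ReadRecord, ReadRecord]:
        return self.r1, self.r2


def provenance_string(pair: SimulatedPair) -> str:
    return (
        f"src={pair.source_clone} allele={pair.allele_index} "
        f"class={pair.allele_class} contam={int(pair.is_contaminant)}"
    )


def parse_provenance(description: str) -> dict[str, str]:
    return dict(tok.split("=", 1) for tok in description.split() if "=" in tok)


def _apply_errors(
    fragment: str, err: ErrorModel, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    """Apply substitution and (rare) indel sequencing errors to a fragment."""
    n = len(fragment)
    arr = np.frombuffer(fragment.encode("ascii"), dtype=np.uint8).copy()
    quals = np.full(n, err.q_correct, dtype=np.int64)
    if err.sub_rate > 0:
        sub_mask = rng.random(n) < err.sub_rate
        idx = np.nonzero(sub_mask)[0]
        base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in idx:
            others = base_codes[base_codes != arr[i]]
            arr[i] = others[int(rng.integers(others.shape[0]))]
        quals[idx] = err.q_error
    if err.seq_indel_rate > 0:
        del_mask = rng.random(n) < err.seq_indel_rate / 2.0
        ins_mask = rng.random(n) < err.seq_indel_rate / 2.0
        if del_mask.any() or ins_mask.any():
            out_b: list[int] = []
            out_q: list[int] = []
            for i in range(n):
                if not del_mask[i]:
                    out_b.append(int(arr[i]))
                    out_q.append(int(quals[i]))
                if ins_mask[i]:
                    out_b.append(ord("ACGT"[int(rng.integers(4))]))
                    out_q.append(err.q_error)
            return bytes(out_b).decode("ascii"), tuple(out_q)
    return arr.tobytes().decode("ascii"), tuple(int(q) for q in quals)


def simulate_reads(
    truth: CloneTruth,
    refs: ReferencePair,
    err: ErrorModel,
    barcode: str,
    rng_seed: int | np.random.Generator,
    contaminant: CloneTruth | None = None,
    contaminant_fraction: float | None = None,
) -> list[SimulatedPair]:
    """Simulate ``err.depth`` barcoded, paired amplicon reads for a clone.

    Each pair is drawn from one of the clone's allele lineages with
    probability equal to its lineage fraction; if ``contaminant`` is given,
    each pair instead comes from the contaminating clone with probability
    ``contaminant_fraction``.  R1 carries ``barcode`` as an error-free
    prefix; R2 is the reverse complement of the fragment at the far
    amplicon end.  Deterministic for a given seed.
    """
    if len(barcode) < 6:
        raise SimulationError("barcode must be at least 6 nt")
    _check_dna(barcode, "barcode", allow_n=False)
    refs.warn_if_short(err.read_length)
    rng = as_rng(rng_seed)
    own_seqs = [allele_sequence(a, refs) for a in truth.alleles]
    own_fracs = np.array([a.fraction for a in truth.alleles])
    own_fracs = own_fracs / own_fracs.sum()
    if contaminant is not None:
        cont_seqs = [allele_sequence(a, refs) for a in contaminant.alleles]
        cont_fracs = np.array([a.fraction for a in contaminant.alleles])
        cont_fracs = cont_fracs / cont_fracs.sum()
        cfrac = contaminant_fraction if contaminant_fraction is not None else 0.0
    else:
        cfrac = 0.0
    bc_quals = (err.q_correct,) * len(barcode)
    pairs: list[SimulatedPair] = []
    for i in range(err.depth):
        from_contaminant = cfrac > 0 and rng.random() < cfrac
        if from_contaminant:
            src = contaminant
            ai = int(rng.choice(len(cont_seqs), p=cont_fracs))
            aseq = cont_seqs[ai]
        else:
            src = truth
            ai = int(rng.choice(len(own_seqs), p=own_fracs))
            aseq = own_seqs[ai]
        frag1 = aseq[: err.read_length]
        frag2 = revcomp(aseq[-err.read_length:]) if len(aseq) > err.read_length else revcomp(aseq)
        seq1, q1 = _apply_errors(frag1, err, rng)
        seq2, q2 = _apply_errors(frag2, err, rng)
        name = f"{truth.clone_id}_{i:05d}"
        sim = SimulatedPair(
            r1=ReadRecord(id=name, seq=barcode + seq1, quals=bc_quals + q1, description=""),
            r2=ReadRecord(id=name, seq=seq2, quals=q2, description=""),
            source_clone=src.clone_id,
            allele_index=ai,
            allele_class=src.alleles[ai].class_,
            is_contaminant=from_contaminant,
        )
        desc = provenance_string(sim)
        sim = replace(
            sim,
            r1=replace(sim.r1, description=desc),
            r2=replace(sim.r2, description=desc),
        )
        pairs.append(sim)
    return pairs


# ---------------------------------------------------------------------------
# Pen and export simulation
# ---------------------------------------------------------------------------


def _grown_count(hours: float, doubling_time_h: float) -> int:
    return int(round(2.0 ** (hours / doubling_time_h)))


def simulate_pens(
    growth: GrowthModel,
    n_pens: int,
    single_cell_fraction: float,
    rng_seed: int | np.random.Generator,
    condition: str = "edited",
    p_positive: float | None = None,
    positive_intensity: tuple[float, float] = (1000.0, 100.0),
    negative_intensity: tuple[float, float] = (100.0, 20.0),
    colony_min_cells: int = 6,
    pen_prefix: str = "pen",
) -> list[PenRecord]:
    """Simulate per-pen cell-count time series.

    Pens are loaded with 0 or 1 cell.  A single-cell pen grows
    exponentially (``count = round(2^(t/doubling_time))``) unless it fails
    to expand (probability ``p_no_growth``, count stays 1).  An initially
    empty pen acquires a cell during culture with probability
    ``p_contam_pen`` and grows from the acquisition timepoint onward.  If
    ``p_positive`` is given, colonies (final count >= ``colony_min_cells``)
    receive a fluorescence intensity drawn from the positive or negative
    normal component.
    """
    if n_pens <= 0:
        raise ConfigurationError("n_pens must be > 0")
    rng = as_rng(rng_seed)
    timepoints = tuple(growth.timepoints_h)
    pens: list[PenRecord] = []
    for i in range(n_pens):
        initial = 1 if rng.random() < single_cell_fraction else 0
        counts: dict[int, int] = {}
        if initial == 1:
            grows = rng.random() >= growth.p_no_growth
            for t in timepoints:
                counts[t] = _grown_count(t, growth.doubling_time_h) if grows else 1
        else:
            acquires = rng.random() < growth.p_contam_pen
            if acquires and len(timepoints) > 1:
                t_acq = int(rng.choice(timepoints[1:]))
                for t in timepoints:
                    counts[t] = 0 if t < t_acq else _grown_count(t - t_acq, growth.doubling_time_h)
            else:
                for t in timepoints:
                    counts[t] = 0
        fluorescence = None
        if p_positive is not None and counts[max(timepoints)] >= colony_min_cells:
            if rng.random() < p_positive:
                mu, sd = positive_intensity
            else:
                mu, sd = negative_intensity
            fluorescence = float(max(0.0, rng.normal(mu, sd)))
        pens.append(
            PenRecord(
                pen_id=f"{pen_prefix}{i:05d}",
                condition=condition,
                initial_count=initial,
                counts=counts,
                fluorescence=fluorescence,
            )
        )
    return pens


def simulate_exports(
    n: int,
    rng_seed: int | np.random.Generator,
    mean_cells: float = 12.0,
    survival_midpoint: float = 10.0,
    survival_scale: float = 3.0,
    p_export_fail: float = 0.15,
    survival_prob: float | None = None,
    clone_prefix: str = "clone",
) -> list[ExportRecord]:
    """Simulate split-export outcomes.

    The number of exported cells is Poisson(``mean_cells``); a failed
    export (probability ``p_export_fail``) transfers 0–1 cells.  Survival
    of successfully exported clones follows a logistic curve in the cell
    count (``survival_prob`` overrides it with a flat probability).
    """
    rng = as_rng(rng_seed)
    records: list[ExportRecord] = []
    for i in range(n):
        if rng.random() < p_export_fail:
            cells = int(rng.integers(0, 2))
        else:
            cells = int(rng.poisson(mean_cells))
        exported_ok = cells > 1
        survived = False
        if exported_ok:
            if survival_prob is not None:
                p = survival_prob
            else:
                p = 1.0 / (1.0 + np.exp(-(cells - survival_midpoint) / survival_scale))
            survived = bool(rng.random() < p)
        records.append(
            ExportRecord(
                clone_id=f"{clone_prefix}{i:04d}",
                cells_exported=cells,
                exported_ok=exported_ok,
                survived=survived,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Dataset assembly and text-table output
# ---------------------------------------------------------------------------


def make_barcodes(
    n: int,
    rng_seed: int | np.random.Generator,
    length: int = 8,
    min_dist: int = 3,
) -> list[str]:
    """Random same-length barcodes with pairwise Hamming distance >= min_dist."""
    rng = as_rng(rng_seed)
    bases = np.array(list("ACGT"))
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 200_000:
            raise SimulationError("could not find enough well-separated barcodes; increase length")
        cand = "".join(rng.choice(bases, size=length))
        if all(sum(a != b for a, b in zip(cand, c)) >= min_dist for c in chosen):
            chosen.append(cand)
    return chosen


@dataclass(frozen=True)
class SimulatedDataset:
    """A complete multiplexed synthetic run with ground truth attached."""

    truths: tuple[CloneTruth, ...]
    barcode_map: dict[str, str]
    pairs: tuple[SimulatedPair, ...]

    @property
    def read_pairs(self) -> list[tuple[ReadRecord, ReadRecord]]:
        return [p.pair for p in self.pairs]


def simulate_dataset(
    refs: ReferencePair,
    edit: EditModel,
    err: ErrorModel,
    n_clones: int,
    master_seed: int,
    barcode_length: int = 8,
    clone_prefix: str = "clone",
) -> SimulatedDataset:
    """Simulate ``n_clones`` clones and their multiplexed read pool."""
    if n_clones <= 0:
        raise ConfigurationError("n_clones must be > 0")
    barcodes = make_barcodes(n_clones, child_rng(master_seed, "barcodes"), length=barcode_length)
    truths = [
        simulate_clone(edit, refs, child_rng(master_seed, f"clone:{i}"), f"{clone_prefix}{i:04d}")
        for i in range(n_clones)
    ]
    cont_rng = child_rng(master_seed, "contamination")
    donors: list[CloneTruth | None] = []
    for i in range(n_clones):
        if n_clones > 1 and edit.contamination_rate > 0 and cont_rng.random() < edit.contamination_rate:
            j = int(cont_rng.integers(n_clones - 1))
            if j >= i:
                j += 1
            donors.append(truths[j])
            truths[i] = replace(truths[i], contaminated=True)
        else:
            donors.append(None)
    all_pairs: list[SimulatedPair] = []
    for i, truth in enumerate(truths):
        all_pairs.extend(
            simulate_reads(
                truth,
                refs,
                err,
                barcodes[i],
                child_rng(master_seed, f"reads:{i}"),
                contaminant=donors[i],
                contaminant_fraction=edit.contaminant_fraction,
            )
        )
    barcode_map = {t.clone_id: bc for t, bc in zip(truths, barcodes)}
    return SimulatedDataset(truths=tuple(truths), barcode_map=barcode_map, pairs=tuple(all_pairs))


def write_truth_tsv(truths: Sequence[CloneTruth], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("clone_id\tallele_class\tsignature\tfraction\tcontaminated\n")
        for t in truths:
            for a in t.alleles:
                fh.write(
                    f"{t.clone_id}\t{a.class_}\t{a.signature}\t{a.fraction:.4f}\t{int(t.contaminated)}\n"
                )


def write_barcode_tsv(barcode_map: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tbarcode\n")
        for sample, bc in barcode_map.items():
            fh.write(f"{sample}\t{bc}\n")
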