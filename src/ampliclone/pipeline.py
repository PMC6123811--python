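"""End-to-end orchestration: simulate -> demux -> classify -> genotype -> report.

A :class:`RunConfig` fully determines a run; the output manifest embeds the
config, the master seed, per-stage record counts and the SHA-256 checksum
of every written file, so re-running the same config reproduces the outputs
byte for byte (no timestamps are recorded).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .chip import exports_to_tsv, pens_to_tsv, summarize_chip
from .classify import allele_table_tsv_rows, classify_read, tally_alleles
from .demux import BarcodeMap, demultiplex
from .errors import ConfigurationError
from .genotype import (
    call_genotype,
    expected_label,
    genotype_tsv_rows,
    summarize_run,
)
from .align import Scoring
from .io import read_fastq_pairs, sha256_of, write_fastq_pairs
from .references import ReferencePair, default_reference_pair, reference_pair_from_fasta, write_reference_fasta
from .simulate import (
    EditModel,
    ErrorModel,
    GrowthModel,
    SimulatedDataset,
    simulate_dataset,
    simulate_exports,
    simulate_pens,
    write_barcode_tsv,
    write_truth_tsv,
)

FIXTURE_PROFILES = ("bi-allelic-hdr", "control-scrambled", "mixed-day4")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run (fully serializable)."""

    seed: int = 1
    n_clones: int = 12
    barcode_length: int = 8
    edit: EditModel = field(default_factory=EditModel)
    error: ErrorModel = field(default_factory=ErrorModel)
    growth: GrowthModel = field(default_factory=GrowthModel)
    scoring: Scoring = field(default_factory=Scoring)
    qual_threshold: float = 30.0
    min_reads: int = 10
    min_allele_frac: float = 0.20
    max_mismatch: int = 0
    # reference: None -> packaged synthetic fixture
    reference_fasta: str | None = None
    reference_cut_site: int | None = None
    reference_window: tuple[int, int] | None = None
    # pre-existing reads: skip simulation when set
    fastq1: str | None = None
    fastq2: str | None = None
    barcodes_tsv: str | None = None
    # chip tables
    n_pens: int = 0
    single_cell_fraction: float = 0.7
    n_exports: int = 0
    condition: str = "edited"

    def references(self) -> ReferencePair:
        if self.reference_fasta is None:
            return default_reference_pair()
        if self.reference_cut_site is None or self.reference_window is None:
            raise ConfigurationError(
                "reference_fasta requires reference_cut_site and reference_window"
            )
        return reference_pair_from_fasta(
            self.reference_fasta,
            self.reference_cut_site,
            self.reference_window[0],
            self.reference_window[1],
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["edit"]["indel_length_dist"] = {
            str(k): v for k, v in d["edit"]["indel_length_dist"].items()
        }
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        for key, typ in (("edit", EditModel), ("error", ErrorModel), ("growth", GrowthModel), ("scoring", Scoring)):
            if key in data and isinstance(data[key], dict):
                sub = dict(data[key])
                if key == "edit" and "indel_length_dist" in sub:
                    sub["indel_length_dist"] = {
                        int(k): float(v) for k, v in sub["indel_length_dist"].items()
                    }
                if key == "error" and "qual_profile" in sub:
                    sub["qual_profile"] = {str(k): int(v) for k, v in sub["qual_profile"].items()}
                if key == "growth" and "timepoints_h" in sub:
                    sub["timepoints_h"] = tuple(int(t) for t in sub["timepoints_h"])
                data[key] = typ(**sub)
        if data.get("reference_window") is not None:
            data["reference_window"] = tuple(data["reference_window"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _write_tsv(rows: list[dict], path: str) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AnalysisResult:
    """In-memory result of the demux -> classify -> genotype chain."""

    demux: Any  # DemuxResult
    tables: tuple
    genotypes: tuple

    def genotype_of(self, clone_id: str) -> str:
        for g in self.genotypes:
            if g.clone_id == clone_id:
                return g.label
        raise KeyError(clone_id)


def analyze_read_pairs(
    pairs,
    barcode_map: BarcodeMap,
    refs: ReferencePair,
    scoring: Scoring | None = None,
    qual_threshold: float = 30.0,
    min_reads: int = 10,
    min_allele_frac: float = 0.20,
    max_mismatch: int = 0,
) -> AnalysisResult:
    """Run demultiplexing, per-read classification and genotype calling on
    in-memory read pairs (the non-writing core of :func:`run_pipeline`)."""
    scoring = scoring or Scoring()
    demux_result = demultiplex(pairs, barcode_map, max_mismatch=max_mismatch)
    tables = []
    for sample in sorted(demux_result.by_sample):
        calls = [
            classify_read(pair, refs, scoring, qual_threshold)
            for pair in demux_result.by_sample[sample]
        ]
        tables.append(tally_alleles(calls, sample))
    genotypes = tuple(call_genotype(t, min_reads, min_allele_frac) for t in tables)
    return AnalysisResult(demux=demux_result, tables=tuple(tables), genotypes=genotypes)


def run_pipeline(config: RunConfig, outdir: str) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    os.makedirs(outdir, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "ampliclone",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
        "outputs": {},
        "warnings": [],
    }

    def _register(name: str, path: str, n: int | None = None) -> None:
        entry: dict[str, Any] = {"path": os.path.basename(path), "sha256": sha256_of(path)}
        if n is not None:
            entry["n_records"] = n
        manifest["outputs"][name] = entry

    refs = config.references()
    write_reference_fasta(refs, os.path.join(outdir, "references.fasta"))
    _register("references", os.path.join(outdir, "references.fasta"))

    # --- stage: reads (simulate or load) -----------------------------------
    dataset: SimulatedDataset | None = None
    if config.fastq1 is not None:
        if config.fastq2 is None or config.barcodes_tsv is None:
            raise ConfigurationError("fastq1 requires fastq2 and barcodes_tsv")
        pairs = list(read_fastq_pairs(config.fastq1, config.fastq2))
        barcode_map = BarcodeMap.from_tsv(config.barcodes_tsv)
        manifest["stages"].append({"name": "load_reads", "n_records": len(pairs)})
    else:
        dataset = simulate_dataset(
            refs,
            config.edit,
            config.error,
            config.n_clones,
            config.seed,
            barcode_length=config.barcode_length,
        )
        pairs = dataset.read_pairs
        barcode_map = BarcodeMap(dataset.barcode_map)
        r1_path = os.path.join(outdir, "reads_R1.fastq")
        r2_path = os.path.join(outdir, "reads_R2.fastq")
        n = write_fastq_pairs(pairs, r1_path, r2_path)
        _register("fastq_r1", r1_path, n)
        _register("fastq_r2", r2_path, n)
        truth_path = os.path.join(outdir, "truth.tsv")
        write_truth_tsv(dataset.truths, truth_path)
        _register("truth", truth_path, len(dataset.truths))
        bc_path = os.path.join(outdir, "barcodes.tsv")
        write_barcode_tsv(dataset.barcode_map, bc_path)
        _register("barcodes", bc_path, len(dataset.barcode_map))
        manifest["stages"].append({"name": "simulate", "n_records": len(pairs)})

    # --- stages: demultiplex, classify, genotype ---------------------------
    analysis = analyze_read_pairs(
        pairs,
        barcode_map,
        refs,
        scoring=config.scoring,
        qual_threshold=config.qual_threshold,
        min_reads=config.min_reads,
        min_allele_frac=config.min_allele_frac,
        max_mismatch=config.max_mismatch,
    )
    demux_result = analysis.demux
    demux_path = os.path.join(outdir, "demux_summary.tsv")
    _write_tsv(demux_result.summary_rows(), demux_path)
    _register("demux_summary", demux_path)
    manifest["stages"].append(
        {
            "name": "demux",
            "assigned": demux_result.total_assigned,
            "unassigned": len(demux_result.unassigned),
        }
    )

    tables = list(analysis.tables)
    allele_rows: list[dict] = []
    for table in tables:
        allele_rows.extend(allele_table_tsv_rows(table))
    alleles_path = os.path.join(outdir, "alleles.tsv")
    _write_tsv(allele_rows, alleles_path)
    _register("alleles", alleles_path, len(allele_rows))
    n_uninformative = sum(t.uninformative_reads for t in tables)
    manifest["stages"].append(
        {"name": "classify", "n_clones": len(tables), "uninformative_reads": n_uninformative}
    )
    if n_uninformative:
        manifest["warnings"].append(f"{n_uninformative} uninformative read pairs")

    # --- stage: genotype ----------------------------------------------------
    genotypes = list(analysis.genotypes)
    genotypes_path = os.path.join(outdir, "genotypes.tsv")
    _write_tsv(genotype_tsv_rows(genotypes), genotypes_path)
    _register("genotypes", genotypes_path, len(genotypes))
    low_cov = [g.clone_id for g in genotypes if g.label == "LOW_COVERAGE"]
    if low_cov:
        manifest["warnings"].append(f"low-coverage clones: {','.join(low_cov)}")
    summaries = summarize_run(genotypes) if genotypes else {}
    summary_path = os.path.join(outdir, "summary.json")
    with open(summary_path, "w") as fh:
        json.dump(
            {k: dataclasses.asdict(v) for k, v in summaries.items()},
            fh,
            indent=2,
            sort_keys=True,
        )
    _register("summary", summary_path)
    manifest["stages"].append({"name": "genotype", "n_clones": len(genotypes)})

    # --- stage: recovery report (simulated runs only) -----------------------
    if dataset is not None:
        called = {g.clone_id: g.label for g in genotypes}
        confusion: dict[str, int] = {}
        correct = 0
        for truth in dataset.truths:
            true = expected_label(
                [(a.class_, a.fraction) for a in truth.alleles], config.min_allele_frac
            )
            got = called.get(truth.clone_id, "MISSING")
            key = f"{true}->{got}"
            confusion[key] = confusion.get(key, 0) + 1
            if true == got:
                correct += 1
        manifest["recovery"] = {
            "n_clones": len(dataset.truths),
            "accuracy": correct / len(dataset.truths),
            "confusion": dict(sorted(confusion.items())),
        }

    # --- stage: chip tables --------------------------------------------------
    if config.n_pens > 0:
        pens = simulate_pens(
            config.growth,
            config.n_pens,
            config.single_cell_fraction,
            rng_seed=config.seed + 1,
            condition=config.condition,
            p_positive=0.85,
        )
        pens_path = os.path.join(outdir, "pens.tsv")
        pens_to_tsv(pens, pens_path)
        _register("pens", pens_path, len(pens))
    else:
        pens = []
    if config.n_exports > 0:
        exports = simulate_exports(config.n_exports, rng_seed=config.seed + 2)
        exports_path = os.path.join(outdir, "exports.tsv")
        exports_to_tsv(exports, exports_path)
        _register("exports", exports_path, len(exports))
    else:
        exports = []
    if pens or exports:
        chip_path = os.path.join(outdir, "chip_summary.json")
        with open(chip_path, "w") as fh:
            json.dump(
                summarize_chip(pens, exports, intensity_threshold=500.0),
                fh,
                indent=2,
                sort_keys=True,
                default=str,
            )
        _register("chip_summary", chip_path)
        manifest["stages"].append(
            {"name": "chipstats", "n_pens": len(pens), "n_exports": len(exports)}
        )

    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def fixture_config(profile: str, seed: int = 1) -> RunConfig:
    """Small, fast-to-analyze dataset configurations with ground truth."""
    zero_error = ErrorModel(sub_rate=0.0, seq_indel_rate=0.0, depth=40)
    if profile == "bi-allelic-hdr":
        return RunConfig(
            seed=seed,
            n_clones=8,
            edit=EditModel(p_hdr=1.0, p_nhej=0.0, p_late_edit=0.0),
            error=zero_error,
        )
    if profile == "control-scrambled":
        return RunConfig(
            seed=seed,
            n_clones=8,
            edit=EditModel(p_hdr=0.0, p_nhej=0.0, p_late_edit=0.0),
            error=ErrorModel(sub_rate=0.003, seq_indel_rate=0.0, depth=40),
        )
    if profile == "mixed-day4":
        return RunConfig(
            seed=seed,
            n_clones=12,
            edit=EditModel(p_hdr=0.2, p_nhej=0.55, p_late_edit=0.1),
            error=ErrorModel(sub_rate=0.003, seq_indel_rate=0.0, depth=60),
            n_pens=300,
            n_exports=48,
        )
    raise ConfigurationError(f"unknown fixture profile {profile!r}; choose from {FIXTURE_PROFILES}")


def make_fixture(profile: str, seed: int, outdir: str) -> dict:
    """Write a packaged fixture dataset and its full analysis to ``outdir``."""
    return run_pipeline(fixture_config(profile, seed), outdir)
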