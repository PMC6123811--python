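"""Clone-level genotype calling from allele tables, and run summaries.

An allele survives filtering when its frequency is at least
``min_allele_frac`` and it is supported by at least ``min_reads`` reads.
One retained allele gives a homozygous label, two a heterozygous label,
more than two the terminal MULTI_ALLELIC label (late editing or
cross-contamination — deliberately not resolved to a diploid call).
Clones with fewer than ``min_reads`` informative reads are LOW_COVERAGE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .classify import HDR, NHEJ, WT, AlleleRow, AlleleTable
from .errors import InputError

LABELS = (
    "WT/WT",
    "HDR/WT",
    "HDR/NHEJ",
    "NHEJ/WT",
    "NHEJ/NHEJ_same",
    "NHEJ/NHEJ_diff",
    "HDR/HDR",
    "MULTI_ALLELIC",
    "LOW_COVERAGE",
)

DEFAULT_MIN_READS = 10
DEFAULT_MIN_ALLELE_FRAC = 0.20

FLAG_MULTI = "possible_contamination_or_late_editing"
FLAG_NO_ALLELE = "no_allele_passed_filters"


@dataclass(frozen=True)
class CloneGenotype:
    clone_id: str
    label: str
    alleles: tuple[AlleleRow, ...]
    flags: tuple[str, ...] = ()


def _homozygous_label(class_: str) -> str:
    return {WT: "WT/WT", HDR: "HDR/HDR", NHEJ: "NHEJ/NHEJ_same"}[class_]


def _heterozygous_label(a: str, b: str) -> str:
    pair = tuple(sorted((a, b)))
    table = {
        (HDR, WT): "HDR/WT",
        (HDR, NHEJ): "HDR/NHEJ",
        (NHEJ, WT): "NHEJ/WT",
        (NHEJ, NHEJ): "NHEJ/NHEJ_diff",
    }
    try:
        return table[pair]
    except KeyError:  # pragma: no cover - WT/WT, HDR/HDR merge into one allele
        raise InputError(f"impossible heterozygous class pair {pair}")


def label_for_alleles(classes: Sequence[str]) -> str:
    """Genotype label for a list of retained allele classes (>=1)."""
    if len(classes) == 1:
        return _homozygous_label(classes[0])
    if len(classes) == 2:
        return _heterozygous_label(classes[0], classes[1])
    return "MULTI_ALLELIC"


def call_genotype(
    table: AlleleTable,
    min_reads: int = DEFAULT_MIN_READS,
    min_allele_frac: float = DEFAULT_MIN_ALLELE_FRAC,
) -> CloneGenotype:
    """Assign a diploid genotype label to one clone.

    The label depends only on the retained alleles, so it is invariant to
    uniform scaling of all read counts (frequencies are scale-free and the
    per-allele read minimum only interacts with ``min_reads``).
    """
    if table.informative_reads < min_reads:
        return CloneGenotype(table.clone_id, "LOW_COVERAGE", (), ())
    retained = tuple(
        r for r in table.rows if r.frequency >= min_allele_frac and r.reads >= min_reads
    )
    if not retained:
        return CloneGenotype(table.clone_id, "LOW_COVERAGE", (), (FLAG_NO_ALLELE,))
    label = label_for_alleles([r.class_ for r in retained])
    flags = (FLAG_MULTI,) if label == "MULTI_ALLELIC" else ()
    return CloneGenotype(table.clone_id, label, retained, flags)


def expected_label(
    truth_alleles: Sequence[tuple[str, float]],
    min_allele_frac: float = DEFAULT_MIN_ALLELE_FRAC,
) -> str:
    """Genotype label implied by ground-truth (class, lineage fraction) pairs.

    Used for recovery reports: applies the same frequency filter and
    labelling rule to the true lineage fractions.
    """
    retained = [c for c, f in truth_alleles if f >= min_allele_frac]
    if not retained:
        return "LOW_COVERAGE"
    return label_for_alleles(retained)


@dataclass(frozen=True)
class RunSummary:
    n_clones: int
    label_counts: dict[str, int]
    label_proportions: dict[str, float]
    hdr_allele_rate: float | None
    nhej_allele_rate: float | None


def _summary(genotypes: Sequence[CloneGenotype]) -> RunSummary:
    counts: dict[str, int] = {}
    for g in genotypes:
        counts[g.label] = counts.get(g.label, 0) + 1
    n = len(genotypes)
    props = {k: v / n for k, v in counts.items()}
    diploid = [g for g in genotypes if g.label not in ("MULTI_ALLELIC", "LOW_COVERAGE")]
    hdr_rate = nhej_rate = None
    if diploid:
        slots = 0
        hdr_slots = 0
        nhej_slots = 0
        for g in diploid:
            classes = g.label.replace("_same", "").replace("_diff", "").split("/")
            slots += 2
            hdr_slots += classes.count("HDR")
            nhej_slots += classes.count("NHEJ")
        hdr_rate = hdr_slots / slots
        nhej_rate = nhej_slots / slots
    return RunSummary(
        n_clones=n,
        label_counts=dict(sorted(counts.items())),
        label_proportions=dict(sorted(props.items())),
        hdr_allele_rate=hdr_rate,
        nhej_allele_rate=nhej_rate,
    )


def summarize_run(
    genotypes: Sequence[CloneGenotype],
    conditions: Mapping[str, str] | None = None,
) -> dict[str, RunSummary]:
    """Summaries keyed by group: ``"all"`` plus one entry per condition.

    Empty condition groups are simply absent from the result (never a
    zero-division).
    """
    if not genotypes:
        raise InputError("summarize_run requires at least one genotype")
    out = {"all": _summary(genotypes)}
    if conditions:
        groups: dict[str, list[CloneGenotype]] = {}
        for g in genotypes:
            cond = conditions.get(g.clone_id)
            if cond is not None:
                groups.setdefault(cond, []).append(g)
        for cond, members in sorted(groups.items()):
            out[cond] = _summary(members)
    return out


def genotype_tsv_rows(genotypes: Sequence[CloneGenotype]) -> list[dict]:
    rows = []
    for g in genotypes:
        allele_str = ",".join(
            f"{r.class_}[{r.signature}]@{r.frequency:.3f}" for r in g.alleles
        )
        rows.append(
            {
                "clone_id": g.clone_id,
                "label": g.label,
                "alleles": allele_str,
                "flags": ";".join(g.flags),
            }
        )
    return rows


def plot_clone_proportions(tables: Sequence[AlleleTable], path: str) -> None:
    """Stacked per-clone class-proportion bar chart (WT/NHEJ/HDR)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = (WT, NHEJ, HDR)
    colors = {WT: "#4878cf", NHEJ: "#ee854a", HDR: "#c44e9e"}
    ids = [t.clone_id for t in tables]
    fractions = {c: [] for c in classes}
    for t in tables:
        for c in classes:
            fractions[c].append(sum(r.frequency for r in t.rows if r.class_ == c))
    fig, ax = plt.subplots(figsize=(max(4, 0.35 * len(ids)), 4))
    bottom = [0.0] * len(ids)
    for c in classes:
        ax.bar(ids, fractions[c], bottom=bottom, color=colors[c], label=c)
        bottom = [b + f for b, f in zip(bottom, fractions[c])]
    for i, t in enumerate(tables):
        ax.text(i, 1.02, str(t.total_reads), ha="center", fontsize=7, rotation=90)
    ax.set_ylabel("fraction of informative reads")
    ax.set_ylim(0, 1.15)
    ax.legend(loc="upper right", fontsize=8)
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
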