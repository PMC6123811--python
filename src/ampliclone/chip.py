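"""On-chip and post-export workflow statistics from tabular pen/export data.

All statistics operate on plain records (no imaging): per-pen cell-count
time series with initial occupancy and optional fluorescence, and per-clone
export outcomes.  Undefined quantities (no single-cell pens, non-increasing
growth series, ...) raise :class:`UndefinedStatisticError` rather than
returning a silent NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError, UndefinedStatisticError

COLONY_MIN_CELLS = 6
COLONY_HOUR = 72


@dataclass(frozen=True)
class PenRecord:
    """Per-NanoPen time series of cell counts.

    ``counts`` maps observation hour to cell count; hour 0 must equal
    ``initial_count``.
    """

    pen_id: str
    condition: str
    initial_count: int
    counts: Mapping[int, int]
    fluorescence: float | None = None

    def __post_init__(self) -> None:
        if self.initial_count < 0 or any(c < 0 for c in self.counts.values()):
            raise InputError(f"{self.pen_id}: negative cell counts")
        if 0 in self.counts and self.counts[0] != self.initial_count:
            raise InputError(f"{self.pen_id}: hour-0 count must equal initial_count")


@dataclass(frozen=True)
class ExportRecord:
    """Outcome of one split export."""

    clone_id: str
    cells_exported: int
    exported_ok: bool
    survived: bool

    def __post_init__(self) -> None:
        if self.cells_exported < 0:
            raise InputError(f"{self.clone_id}: cells_exported must be >= 0")
        if self.survived and not self.exported_ok:
            raise InputError(f"{self.clone_id}: survived is only meaningful when exported_ok")


def occe(
    pens: Iterable[PenRecord],
    colony_min_cells: int = COLONY_MIN_CELLS,
    at_hour: int = COLONY_HOUR,
) -> float:
    """On-chip clonal expansion: the fraction of single-cell pens whose
    colony reached ``colony_min_cells`` cells at ``at_hour``.

    Pens loaded with anything other than exactly one cell are excluded from
    both numerator and denominator (clonality rule).
    """
    singles = [p for p in pens if p.initial_count == 1]
    if not singles:
        raise UndefinedStatisticError("OCCE undefined: no single-cell pens")
    for p in singles:
        if at_hour not in p.counts:
            raise InputError(f"{p.pen_id}: no count at hour {at_hour}")
    grown = sum(1 for p in singles if p.counts[at_hour] >= colony_min_cells)
    return grown / len(singles)


def contamination_rate(pens: Iterable[PenRecord]) -> float:
    """Fraction of initially empty pens that acquired cells during culture."""
    empty = [p for p in pens if p.initial_count == 0]
    if not empty:
        raise UndefinedStatisticError("contamination rate undefined: no initially empty pens")
    gained = sum(
        1 for p in empty if any(c > 0 for t, c in p.counts.items() if t > 0)
    )
    return gained / len(empty)


def doubling_time(counts: Mapping[float, float], method: str = "regression") -> float:
    """Doubling time in hours from a count time series.

    ``regression`` fits log2(count) against hours by least squares and
    returns the reciprocal slope; ``endpoint`` uses only the first and last
    positive counts.  Zero counts are excluded from the fit.  Raises
    :class:`UndefinedStatisticError` when fewer than two positive counts
    remain or the series is non-increasing (slope <= 0).
    """
    pts = sorted((float(t), float(c)) for t, c in counts.items() if c > 0)
    if len(pts) < 2:
        raise UndefinedStatisticError("doubling time undefined: fewer than 2 positive counts")
    hours = np.array([t for t, _ in pts])
    log2c = np.log2([c for _, c in pts])
    if method == "regression":
        slope = np.polyfit(hours, log2c, 1)[0]
    elif method == "endpoint":
        slope = (log2c[-1] - log2c[0]) / (hours[-1] - hours[0])
    else:
        raise ConfigurationError(f"unknown doubling-time method {method!r}")
    if slope <= 0:
        raise UndefinedStatisticError("doubling time undefined: counts are non-increasing")
    return float(1.0 / slope)


def export_efficiency(records: Sequence[ExportRecord]) -> float:
    """Fraction of exports that transferred more than one cell."""
    if not records:
        raise UndefinedStatisticError("export efficiency undefined: no export records")
    return sum(r.exported_ok for r in records) / len(records)


@dataclass(frozen=True)
class ViabilitySummary:
    """Post-export survival stratified by number of cells exported."""

    threshold_cells: int
    high_n: int
    high_survival: float | None
    low_n: int
    low_survival: float | None
    rank_correlation: float | None
    rank_pvalue: float | None


def viability_by_export_size(
    records: Sequence[ExportRecord], threshold_cells: int = 10
) -> ViabilitySummary:
    """Survival fractions above/below a cells-exported threshold, plus the
    Spearman rank correlation between cells exported and survival.

    Only successfully exported clones (``exported_ok``) are considered.
    Empty strata are reported as ``None``, not zero.
    """
    ok = [r for r in records if r.exported_ok]
    if not ok:
        raise UndefinedStatisticError("viability undefined: no successfully exported clones")
    high = [r for r in ok if r.cells_exported >= threshold_cells]
    low = [r for r in ok if r.cells_exported < threshold_cells]
    cells = [r.cells_exported for r in ok]
    surv = [int(r.survived) for r in ok]
    if len(set(cells)) > 1 and len(set(surv)) > 1:
        rho, pval = stats.spearmanr(cells, surv)
        rho, pval = float(rho), float(pval)
    else:
        rho = pval = None
    return ViabilitySummary(
        threshold_cells=threshold_cells,
        high_n=len(high),
        high_survival=(sum(r.survived for r in high) / len(high)) if high else None,
        low_n=len(low),
        low_survival=(sum(r.survived for r in low) / len(low)) if low else None,
        rank_correlation=rho,
        rank_pvalue=pval,
    )


@dataclass(frozen=True)
class PositivityResult:
    fraction_positive: float
    n_colonies: int
    n_missing_intensity: int


def staining_positivity(
    pens: Iterable[PenRecord],
    intensity_threshold: float,
    colony_min_cells: int = COLONY_MIN_CELLS,
    at_hour: int = COLONY_HOUR,
) -> dict[str, PositivityResult]:
    """Fraction of colonized pens at or above an intensity threshold,
    grouped by condition tag.

    Colonized means >= ``colony_min_cells`` cells at ``at_hour`` (same
    criterion as OCCE).  Pens without a recorded intensity are excluded and
    counted in ``n_missing_intensity``.
    """
    by_condition: dict[str, list[PenRecord]] = {}
    for p in pens:
        if p.counts.get(at_hour, 0) >= colony_min_cells:
            by_condition.setdefault(p.condition, []).append(p)
    out: dict[str, PositivityResult] = {}
    for condition, colonized in by_condition.items():
        with_signal = [p for p in colonized if p.fluorescence is not None]
        missing = len(colonized) - len(with_signal)
        if not with_signal:
            raise UndefinedStatisticError(
                f"staining positivity undefined for condition {condition!r}: no intensities"
            )
        positive = sum(1 for p in with_signal if p.fluorescence >= intensity_threshold)
        out[condition] = PositivityResult(
            fraction_positive=positive / len(with_signal),
            n_colonies=len(with_signal),
            n_missing_intensity=missing,
        )
    return out


@dataclass(frozen=True)
class ScreeningPlan:
    """Expected yield of a screening campaign.

    ``p_success`` is the per-clone probability of the desired genotype,
    ``viability`` the post-export survival probability; a screened clone is
    a usable hit with probability ``p_success * viability``.
    """

    n_screened: int
    p_success: float
    viability: float
    k: int
    expected_viable: float
    p_at_least_k: float


def screening_plan(
    p_success: float,
    viability: float,
    n_screened: int | None = None,
    k: int = 1,
    target_prob: float | None = None,
) -> ScreeningPlan:
    """Size a clone-screening campaign.

    Forward mode (``n_screened`` given): expected number of usable clones
    ``n * p_success * viability`` and the binomial tail ``P(>= k usable)``.
    Inverse mode (``target_prob`` given): the smallest ``n`` achieving
    ``P(>= k usable) >= target_prob``.
    """
    if not (0.0 < p_success <= 1.0) or not (0.0 < viability <= 1.0):
        raise ConfigurationError("p_success and viability must lie in (0, 1]")
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    pv = p_success * viability
    if n_screened is not None:
        if n_screened < 1:
            raise ConfigurationError("n_screened must be >= 1")
        n = n_screened
    elif target_prob is not None:
        if not (0.0 < target_prob < 1.0):
            raise UndefinedStatisticError("target probability must lie in (0, 1)")
        n = k
        while float(stats.binom.sf(k - 1, n, pv)) < target_prob:
            n += 1
            if n > 10_000_000:
                raise UndefinedStatisticError("no feasible screening size below 1e7")
    else:
        raise ConfigurationError("provide either n_screened or target_prob")
    return ScreeningPlan(
        n_screened=n,
        p_success=p_success,
        viability=viability,
        k=k,
        expected_viable=n * pv,
        p_at_least_k=float(stats.binom.sf(k - 1, n, pv)),
    )


# ---------------------------------------------------------------------------
# TSV round-trips (pandas-backed)
# ---------------------------------------------------------------------------


def pens_to_tsv(pens: Sequence[PenRecord], path: str) -> None:
    hours = sorted({t for p in pens for t in p.counts})
    rows = []
    for p in pens:
        row: dict[str, object] = {
            "pen_id": p.pen_id,
            "condition": p.condition,
            "initial_count": p.initial_count,
        }
        for t in hours:
            row[f"count_{t}h"] = p.counts.get(t, "")
        row["fluorescence"] = "" if p.fluorescence is None else p.fluorescence
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def pens_from_tsv(path: str) -> list[PenRecord]:
    df = pd.read_csv(path, sep="\t")
    count_cols = {}
    for col in df.columns:
        if col.startswith("count_") and col.endswith("h"):
            count_cols[col] = int(col[len("count_"):-1])
    if not count_cols:
        raise InputError(f"{path}: no count_<hour>h columns found")
    pens = []
    for _, row in df.iterrows():
        counts = {
            hour: int(row[col]) for col, hour in count_cols.items() if not pd.isna(row[col])
        }
        fl = row.get("fluorescence")
        pens.append(
            PenRecord(
                pen_id=str(row["pen_id"]),
                condition=str(row.get("condition", "edited")),
                initial_count=int(row["initial_count"]),
                counts=counts,
                fluorescence=None if fl is None or (isinstance(fl, float) and math.isnan(fl)) else float(fl),
            )
        )
    return pens


def exports_to_tsv(records: Sequence[ExportRecord], path: str) -> None:
    pd.DataFrame(
        [
            {
                "clone_id": r.clone_id,
                "cells_exported": r.cells_exported,
                "exported_ok": int(r.exported_ok),
                "survived": int(r.survived),
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def exports_from_tsv(path: str) -> list[ExportRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        ExportRecord(
            clone_id=str(row["clone_id"]),
            cells_exported=int(row["cells_exported"]),
            exported_ok=bool(row["exported_ok"]),
            survived=bool(row["survived"]),
        )
        for _, row in df.iterrows()
    ]


def summarize_chip(
    pens: Sequence[PenRecord] | None = None,
    exports: Sequence[ExportRecord] | None = None,
    intensity_threshold: float | None = None,
    viability_threshold_cells: int = 10,
) -> dict:
    """One-call summary used by the CLI: every statistic that is defined
    for the given inputs, keyed by name."""
    out: dict = {}
    if pens:
        for name, fn in (("occe", occe), ("contamination_rate", contamination_rate)):
            try:
                out[name] = fn(pens)
            except UndefinedStatisticError as exc:
                out[name] = {"undefined": str(exc)}
        if intensity_threshold is not None:
            try:
                out["staining_positivity"] = {
                    cond: res.__dict__
                    for cond, res in staining_positivity(pens, intensity_threshold).items()
                }
            except UndefinedStatisticError as exc:
                out["staining_positivity"] = {"undefined": str(exc)}
    if exports:
        out["export_efficiency"] = export_efficiency(exports)
        try:
            out["viability"] = viability_by_export_size(
                exports, threshold_cells=viability_threshold_cells
            ).__dict__
        except UndefinedStatisticError as exc:
            out["viability"] = {"undefined": str(exc)}
    return out
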