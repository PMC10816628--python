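"""Cell-based decision stage: viability normalization, the three-step
decision cascade with a reduced-concentration rescue branch, 4PL
dose-response fitting, and relative gene expression (2^-dCt).

Thresholds are strict inequalities throughout: a combination must fall
strictly below 85% of the cisplatin control to advance, compound-alone
viability strictly below 30% routes to the 10 uM retest, and the
enhancement effect must strictly exceed 10 percentage points to call a
hit.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

CISPLATIN_ID = "CISPLATIN"
VEHICLE_ID = "CONTROL"


class Condition(enum.Enum):
    VEHICLE = "VEHICLE"
    CISPLATIN_1uM = "CISPLATIN_1uM"
    COMPOUND_ALONE = "COMPOUND_ALONE"
    COMBINATION = "COMBINATION"


class Category(enum.Enum):
    BEST = "BEST"
    NO_ENHANCEMENT = "NO_ENHANCEMENT"
    CYTOTOXIC_10uM = "CYTOTOXIC_10uM"
    NO_ENHANCEMENT_10uM = "NO_ENHANCEMENT_10uM"
    LOW_EFFECT = "LOW_EFFECT"
    UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class PlateRecord:
    compound_id: str
    condition: Condition
    concentration: float  # uM; 0 for vehicle
    replicate: int
    experiment: int
    od: float
    od_ref: float | None = None  # reference wavelength, subtracted if given

    @property
    def net_od(self) -> float:
        return self.od - (self.od_ref or 0.0)


@dataclass
class AssaySummary:
    compound_id: str
    v_cis: float  # % viability, cisplatin alone
    v_alone: float  # % viability, compound alone (screening concentration)
    v_combo: float  # % viability, combination
    v_alone_10: float | None = None
    v_combo_10: float | None = None
    n_experiments: int = 1


@dataclass(frozen=True)
class CascadeThresholds:
    stage1_rel_viab: float = 85.0  # % relative to cisplatin
    cytotox_viability: float = 30.0  # % compound-alone
    effect_min: float = 10.0  # percentage points
    retest_death: float = 50.0  # % death at 10 uM


@dataclass
class CascadeDecision:
    compound_id: str
    stage1_rel_viab: float
    stage1_pass: bool
    cytotoxic_flag: bool = False
    retested: bool = False
    effect: float | None = None
    category: Category = Category.UNRESOLVED
    notes: str = ""


# ---------------------------------------------------------------------------
# Viability normalization
# ---------------------------------------------------------------------------

def normalize_viability(records: Sequence[PlateRecord]) -> dict[str, AssaySummary]:
    """Per-compound viability summaries normalized to vehicle = 100%.

    Each experiment is normalized to its own vehicle mean, then averaged
    across experiments. The cisplatin control applies to every compound.
    A missing vehicle in any experiment is an error.
    """
    if not records:
        return {}
    experiments = sorted({r.experiment for r in records})
    vehicle_mean: dict[int, float] = {}
    for exp in experiments:
        veh = [r.net_od for r in records
               if r.experiment == exp and r.condition is Condition.VEHICLE]
        if not veh:
            raise ValueError(f"experiment {exp}: no vehicle records")
        m = float(np.mean(veh))
        if m <= 0:
            raise ValueError(f"experiment {exp}: nonpositive vehicle mean")
        vehicle_mean[exp] = m

    def pct(sub: list[PlateRecord]) -> float | None:
        by_exp = []
        for exp in experiments:
            ods = [r.net_od for r in sub if r.experiment == exp]
            if ods:
                by_exp.append(100.0 * float(np.mean(ods)) / vehicle_mean[exp])
        return float(np.mean(by_exp)) if by_exp else None

    cis = pct([r for r in records if r.condition is Condition.CISPLATIN_1uM])
    compound_ids = sorted({
        r.compound_id for r in records
        if r.condition in (Condition.COMPOUND_ALONE, Condition.COMBINATION)
    })
    out: dict[str, AssaySummary] = {}
    for cid in compound_ids:
        mine = [r for r in records if r.compound_id == cid]
        concs = sorted({r.concentration for r in mine
                        if r.condition is not Condition.VEHICLE}, reverse=True)
        primary = concs[0] if concs else 0.0
        retest = 10.0 if (10.0 in concs and primary != 10.0) else None

        def cond(c: Condition, conc: float) -> list[PlateRecord]:
            return [r for r in mine if r.condition is c and r.concentration == conc]

        v_alone = pct(cond(Condition.COMPOUND_ALONE, primary))
        v_combo = pct(cond(Condition.COMBINATION, primary))
        summary = AssaySummary(
            compound_id=cid,
            v_cis=cis if cis is not None else float("nan"),
            v_alone=v_alone if v_alone is not None else float("nan"),
            v_combo=v_combo if v_combo is not None else float("nan"),
            n_experiments=len({r.experiment for r in mine}),
        )
        if retest is not None:
            summary.v_alone_10 = pct(cond(Condition.COMPOUND_ALONE, retest))
            summary.v_combo_10 = pct(cond(Condition.COMBINATION, retest))
        out[cid] = summary
    return out


# ---------------------------------------------------------------------------
# Decision cascade
# ---------------------------------------------------------------------------

def relative_to_cisplatin(s: AssaySummary) -> float:
    """Combination viability as a percentage of the cisplatin-alone control."""
    if not s.v_cis > 0:
        raise ValueError(f"{s.compound_id}: degenerate cisplatin control (v_cis={s.v_cis})")
    return 100.0 * s.v_combo / s.v_cis


def inhibitor_effect(s: AssaySummary) -> float:
    """Enhancement statistic: compound-alone minus combination viability.

    Positive values mean the combination kills more than the compound
    alone does; the subtraction direction is the convention under which
    'effect > 10' selects enhancers.
    """
    return s.v_alone - s.v_combo


def run_cascade(
    summaries: Iterable[AssaySummary],
    thresholds: CascadeThresholds | None = None,
) -> list[CascadeDecision]:
    """Three-stage decision tree with the 10 uM rescue branch.

    Stage 1: relative-to-cisplatin viability >= 85% -> NO_ENHANCEMENT.
    Stage 2: compound-alone viability < 30% -> 10 uM retest branch,
    where >50% death at 10 uM -> CYTOTOXIC_10uM; a retested compound
    that still fails the enhancement rules -> NO_ENHANCEMENT_10uM.
    Stage 3: effect > 10 pp -> BEST, else LOW_EFFECT.
    Missing retest data routes to UNRESOLVED, never a silent drop.
    """
    th = thresholds or CascadeThresholds()
    decisions = []
    for s in summaries:
        rel = relative_to_cisplatin(s)
        d = CascadeDecision(
            compound_id=s.compound_id, stage1_rel_viab=rel,
            stage1_pass=rel < th.stage1_rel_viab,
        )
        if not d.stage1_pass:
            d.category = Category.NO_ENHANCEMENT
            decisions.append(d)
            continue
        d.cytotoxic_flag = s.v_alone < th.cytotox_viability
        if d.cytotoxic_flag:
            if s.v_alone_10 is None or s.v_combo_10 is None:
                d.category = Category.UNRESOLVED
                d.notes = "routed to 10uM retest but no 10uM data"
                decisions.append(d)
                continue
            d.retested = True
            min_viab_10 = min(s.v_alone_10, s.v_combo_10)
            if 100.0 - min_viab_10 > th.retest_death:
                d.category = Category.CYTOTOXIC_10uM
                decisions.append(d)
                continue
            rel10 = 100.0 * s.v_combo_10 / s.v_cis
            effect10 = s.v_alone_10 - s.v_combo_10
            if rel10 < th.stage1_rel_viab and effect10 > th.effect_min:
                d.effect = effect10
                d.category = Category.BEST
            else:
                d.category = Category.NO_ENHANCEMENT_10uM
            decisions.append(d)
            continue
        d.effect = inhibitor_effect(s)
        d.category = Category.BEST if d.effect > th.effect_min else Category.LOW_EFFECT
        decisions.append(d)
    return decisions


def cascade_counts(decisions: Iterable[CascadeDecision]) -> dict[str, int]:
    counts = {c.value: 0 for c in Category}
    for d in decisions:
        counts[d.category.value] += 1
    return counts


def decisions_frame(decisions: Iterable[CascadeDecision]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "compound_id": d.compound_id,
            "stage1_rel_viab": round(d.stage1_rel_viab, 2),
            "stage1_pass": d.stage1_pass,
            "cytotoxic_flag": d.cytotoxic_flag,
            "retested": d.retested,
            "effect": round(d.effect, 2) if d.effect is not None else "",
            "category": d.category.value,
            "notes": d.notes,
        }
        for d in decisions
    ])


# ---------------------------------------------------------------------------
# 4PL dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponse:
    top: float
    bottom: float
    ic50: float
    hill: float
    residual_norm: float

    def predict(self, conc: float | np.ndarray) -> float | np.ndarray:
        return four_pl(np.asarray(conc, dtype=float), self.top, self.bottom,
                       self.ic50, self.hill)


def four_pl(c, top, bottom, ic50, hill):
    """V(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)."""
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def fit_dose_response(points: Sequence[tuple[float, float]]) -> DoseResponse:
    """Least-squares 4PL fit on (concentration uM, viability %) pairs.

    Fitted on log-concentration internally; bottom is constrained >= 0
    and top initialized at the vehicle level (100%). Flat data (IC50
    unidentifiable) and non-convergence raise with diagnostics.
    """
    pts = [(float(c), float(v)) for c, v in points]
    if any(c <= 0 for c, _ in pts):
        raise ValueError("concentrations must be positive")
    concs = np.array([c for c, _ in pts])
    viab = np.array([v for _, v in pts])
    if len(set(concs)) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if float(np.ptp(viab)) < 1e-9:
        raise ValueError("flat response: IC50 unidentifiable")

    logc = np.log10(concs)

    def model(lc, top, bottom, log_ic50, hill):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (lc - log_ic50)))

    p0 = [100.0, max(0.0, float(viab.min())), float(np.median(logc)), 1.0]
    bounds = ([-np.inf, 0.0, logc.min() - 3, 0.01],
              [np.inf, np.inf, logc.max() + 3, 20.0])
    try:
        popt, _ = curve_fit(model, logc, viab, p0=p0, bounds=bounds,
                            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except RuntimeError as exc:
        raise RuntimeError(f"4PL fit did not converge: {exc}") from exc
    top, bottom, log_ic50, hill = popt
    resid = viab - model(logc, *popt)
    return DoseResponse(
        top=float(top), bottom=float(bottom), ic50=float(10.0 ** log_ic50),
        hill=float(hill), residual_norm=float(np.linalg.norm(resid)),
    )


# ---------------------------------------------------------------------------
# Relative expression (2^-dCt)
# ---------------------------------------------------------------------------

REFERENCE_GENE = "ACTB"


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    cell_line: str
    collection: int
    ct: float  # mean Ct over technical replicates
    rel_expr: float  # 2^-(Ct_gene - Ct_reference)


def relative_expression(
    ct_table: pd.DataFrame, reference_gene: str = REFERENCE_GENE
) -> tuple[list[ExpressionRecord], dict[str, list[str]]]:
    """Relative expression per (cell line, gene, collection) and rankings.

    ``ct_table`` columns: cell_line, gene, collection, ct. Technical
    replicates within a (cell_line, gene, collection) are averaged before
    computing dCt against the reference gene of the same collection.
    Returns the records plus, per gene, cell lines ranked by mean
    relative expression across collections (highest first).
    """
    required = {"cell_line", "gene", "collection", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct table missing columns: {sorted(missing)}")
    means = (ct_table.groupby(["cell_line", "gene", "collection"])["ct"]
             .mean().reset_index())
    records: list[ExpressionRecord] = []
    for (cell, coll), grp in means.groupby(["cell_line", "collection"]):
        ref = grp[grp["gene"] == reference_gene]
        if ref.empty:
            raise ValueError(
                f"missing reference gene {reference_gene!r} for "
                f"cell line {cell!r}, collection {coll}"
            )
        ct_ref = float(ref["ct"].iloc[0])
        for _, row in grp[grp["gene"] != reference_gene].iterrows():
            dct = float(row["ct"]) - ct_ref
            records.append(ExpressionRecord(
                gene=row["gene"], cell_line=cell, collection=int(coll),
                ct=float(row["ct"]), rel_expr=2.0 ** (-dct),
            ))
    rankings: dict[str, list[str]] = {}
    by_gene: dict[str, dict[str, list[float]]] = {}
    for r in records:
        by_gene.setdefault(r.gene, {}).setdefault(r.cell_line, []).append(r.rel_expr)
    for gene, cells in by_gene.items():
        rankings[gene] = sorted(cells, key=lambda c: -float(np.mean(cells[c])))
    return records, rankings
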