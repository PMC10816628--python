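"""Synthetic-data generators and the packaged bookkeeping fixture.

Everything here is a pure function of (spec, seed): libraries with a
drug-like "active" stratum, docking-score tables with a requested
score/activity correlation, viability plates with replicate noise, toy
protein-ligand complexes with exact-margin geometry, qPCR Ct tables, and
the packaged fixture that encodes the screening campaign's per-stage
compound counts and identities.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from scipy.stats import spearmanr

from .chem import Compound, Source, compute_descriptors
from .hitcalling import AssaySummary, Category, Condition, PlateRecord
from .structure import Atom, Residue, Structure
from .triage import DockingRecord

ACTIVE = "ACTIVE"
INACTIVE = "INACTIVE"

# Fragment grammar: aromatic/heteroaromatic cores with two substitution
# points, plus substituent pools biased polar (actives) or greasy
# (inactives). Candidate SMILES are rejection-sampled against the
# stratum's descriptor box.
_CORES = [
    "c1ccc(-c2ccc({0})c({1})c2)cc1",
    "c1ccc2nc({0})c({1})cc2c1",
    "O=C(Nc1ccc({0})cc1)c1ccc({1})cc1",
    "c1ccc(Cc2ccc({0})c({1})c2)cc1",
    "c1cnc({0})c(-c2ccc({1})cc2)c1",
    "c1ccc2[nH]c({0})c(C{1})c2c1",
    "O=S(=O)(c1ccc({0})cc1)c1ccc({1})cc1",
    "c1ccc(Oc2ccc({0})c({1})c2)cc1",
    "c1ccc(N2CCN(C{0})CC2)c({1})c1",
]
_POLAR_SUBS = [
    "O", "N", "OC", "C(N)=O", "C(=O)NC", "NC(C)=O", "NC(=O)CO",
    "S(N)(=O)=O", "CO", "OCC", "OCCO", "C(=O)O", "CNC(C)=O",
    "OCC(N)=O", "F", "Cl", "C", "CC", "N(C)C", "C#N", "CCO", "NCCO",
]
_GREASY_SUBS = [
    "CCCCCC", "CCCCCCCC", "C(C)(C)C", "Cl", "Br", "I", "CCCC",
    "c2ccccc2", "C(F)(F)F", "SCCC", "CCCCC", "C", "OCCCCCC",
]


@dataclass(frozen=True)
class LibrarySpec:
    n_active: int
    n_inactive: int
    seed: int
    mw_range: tuple[float, float] = (200.0, 400.0)
    hbd_allowed: tuple[int, ...] = (2, 3)
    hba_min: int = 4
    logp_range: tuple[float, float] = (1.0, 3.0)
    max_attempts_per_molecule: int = 500


@dataclass(frozen=True)
class LibraryEntry:
    compound: Compound
    stratum: str  # ACTIVE / INACTIVE


def _active_ok(d) -> bool:
    return True  # replaced below per spec; kept for readability


def gen_library(spec: LibrarySpec) -> list[LibraryEntry]:
    """Rejection-sample a compound library from the fragment grammar.

    Actives satisfy the drug-like descriptor box (MW in range, HBD in
    the allowed set, HBA >= min, LogP in range, zero rule-of-five
    violations); inactives are drawn without those constraints from a
    pool that skews heavier and greasier.
    """
    rng = np.random.default_rng(spec.seed)
    entries: list[LibraryEntry] = []
    seen: set[str] = set()

    def accept_active(d) -> bool:
        return (
            spec.mw_range[0] <= d.mw <= spec.mw_range[1]
            and d.hbd in spec.hbd_allowed
            and d.hba >= spec.hba_min
            and spec.logp_range[0] <= d.logp <= spec.logp_range[1]
            and d.lipinski_violations == 0
        )

    def sample(stratum: str, idx: int) -> LibraryEntry:
        subs = _POLAR_SUBS if stratum == ACTIVE else (_POLAR_SUBS + 2 * _GREASY_SUBS)
        for _ in range(spec.max_attempts_per_molecule):
            core = _CORES[rng.integers(len(_CORES))]
            smi = core.format(subs[rng.integers(len(subs))],
                              subs[rng.integers(len(subs))])
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            canonical = Chem.MolToSmiles(mol)
            cid = f"SYN-{stratum[0]}{idx}"
            comp = Compound(id=cid, smiles=canonical, source=Source.SYNTHETIC)
            if stratum == ACTIVE and not accept_active(compute_descriptors(comp)):
                continue
            # allow duplicates only after a few retries, to keep variety
            if canonical in seen and _ < spec.max_attempts_per_molecule // 2:
                continue
            seen.add(canonical)
            return LibraryEntry(compound=comp, stratum=stratum)
        raise RuntimeError(
            f"descriptor targets infeasible: no acceptable molecule for "
            f"stratum {stratum} after {spec.max_attempts_per_molecule} attempts"
        )

    for i in range(spec.n_active):
        entries.append(sample(ACTIVE, i + 1))
    for i in range(spec.n_inactive):
        entries.append(sample(INACTIVE, i + 1))
    return entries


# ---------------------------------------------------------------------------
# Docking-score tables
# ---------------------------------------------------------------------------

def gen_scores(
    library: Sequence[LibraryEntry],
    correlation_with_activity: float,
    seed: int,
    score_center: float = 75.0,
    score_spread: float = 12.0,
) -> list[DockingRecord]:
    """Scores whose rank correlation with the ACTIVE stratum approximates
    the requested value.

    The active-stratum shift is calibrated by bisection against the
    measured Spearman correlation on the generated noise, so the target
    is approached deterministically for the given seed. Targets beyond
    what a binary stratum can support are clamped to the achievable
    maximum.
    """
    if abs(correlation_with_activity) > 1:
        raise ValueError("|correlation| must be <= 1")
    rng = np.random.default_rng(seed)
    n = len(library)
    active = np.array([1.0 if e.stratum == ACTIVE else 0.0 for e in library])
    noise = rng.normal(0.0, 1.0, n)
    target = abs(correlation_with_activity)
    sign = 1.0 if correlation_with_activity >= 0 else -1.0

    def measured(delta: float) -> float:
        if active.std() == 0:
            return 0.0
        rho = spearmanr(active, noise + delta * active).statistic
        return 0.0 if np.isnan(rho) else float(rho)

    delta = 0.0
    if target > 1e-9 and active.std() > 0:
        lo, hi = 0.0, 60.0
        if measured(hi) <= target:
            delta = hi
        else:
            for _ in range(60):
                mid = (lo + hi) / 2
                if measured(mid) < target:
                    lo = mid
                else:
                    hi = mid
            delta = (lo + hi) / 2
    raw = noise + sign * delta * active
    raw = (raw - raw.mean()) / (raw.std() or 1.0)
    scores = score_center + score_spread * raw
    records = []
    for entry, s in zip(library, scores):
        heavy = entry.compound.mol().GetNumHeavyAtoms()
        records.append(DockingRecord(
            compound_id=entry.compound.id, score=float(s),
            ligand_efficiency=float(s) / heavy,
        ))
    return records


# ---------------------------------------------------------------------------
# Viability plates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateSpec:
    seed: int
    cisplatin_viability_target: float = 87.5  # % (paper band: 85-90)
    replicate_sd: float = 5.0  # percentage points on the OD scale
    replicates: int = 3
    experiments: int = 2
    vehicle_od: float = 1.0
    compound_concentration: float = 50.0  # uM


@dataclass(frozen=True)
class CompoundTruth:
    v_alone: float
    v_combo: float
    v_alone_10: float | None = None
    v_combo_10: float | None = None


def gen_plates(
    spec: PlateSpec, truth: Mapping[str, CompoundTruth]
) -> list[PlateRecord]:
    """Simulate OD plates: od = vehicle_od * viability/100 * (1 + noise)."""
    for cid, t in truth.items():
        for v in (t.v_alone, t.v_combo, t.v_alone_10, t.v_combo_10):
            if v is not None and v < 0:
                raise ValueError(f"{cid}: negative target viability {v}")
    rng = np.random.default_rng(spec.seed)
    records: list[PlateRecord] = []

    def well(cid: str, cond: Condition, conc: float, viab: float,
             rep: int, exp: int) -> PlateRecord:
        noise = rng.normal(0.0, spec.replicate_sd / 100.0)
        od = spec.vehicle_od * (viab / 100.0) * (1.0 + noise)
        return PlateRecord(compound_id=cid, condition=cond, concentration=conc,
                           replicate=rep, experiment=exp, od=od)

    for exp in range(1, spec.experiments + 1):
        for rep in range(1, spec.replicates + 1):
            records.append(well("CONTROL", Condition.VEHICLE, 0.0, 100.0, rep, exp))
            records.append(well("CISPLATIN", Condition.CISPLATIN_1uM, 1.0,
                                spec.cisplatin_viability_target, rep, exp))
        for cid, t in truth.items():
            for rep in range(1, spec.replicates + 1):
                records.append(well(cid, Condition.COMPOUND_ALONE,
                                    spec.compound_concentration, t.v_alone, rep, exp))
                records.append(well(cid, Condition.COMBINATION,
                                    spec.compound_concentration, t.v_combo, rep, exp))
                if t.v_alone_10 is not None and t.v_combo_10 is not None:
                    records.append(well(cid, Condition.COMPOUND_ALONE, 10.0,
                                        t.v_alone_10, rep, exp))
                    records.append(well(cid, Condition.COMBINATION, 10.0,
                                        t.v_combo_10, rep, exp))
    return records


# ---------------------------------------------------------------------------
# Dose-response curves
# ---------------------------------------------------------------------------

# Generator truth for the cisplatin concentration-response simulations.
CISPLATIN_CURVE_TRUTH = {
    "CV": {"top": 100.0, "bottom": 5.0, "ic50": 3.0, "hill": 1.3},
    "MTS": {"top": 100.0, "bottom": 5.0, "ic50": 3.7, "hill": 1.3},
}


def gen_cisplatin_curve(
    assay: str = "CV",
    seed: int = 0,
    noise_sd: float = 5.0,
    n_replicates: int = 6,
    conc_range: tuple[float, float] = (1.0, 30.0),
    n_concentrations: int = 8,
) -> list[tuple[float, float]]:
    """Simulated viability points from the 4PL truth for one assay."""
    if assay not in CISPLATIN_CURVE_TRUTH:
        raise ValueError(f"unknown assay {assay!r}")
    p = CISPLATIN_CURVE_TRUTH[assay]
    rng = np.random.default_rng(seed)
    concs = np.geomspace(conc_range[0], conc_range[1], n_concentrations)
    pts = []
    for c in concs:
        v_true = p["bottom"] + (p["top"] - p["bottom"]) / (
            1.0 + (c / p["ic50"]) ** p["hill"]
        )
        for _ in range(n_replicates):
            pts.append((float(c), float(v_true + rng.normal(0.0, noise_sd))))
    return pts


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

# Mean delta-Ct (gene minus reference) per cell line; smaller = higher
# expression. The ERCC1 ordering puts H1299 on top with a robust gap.
_ERCC1_DCT = {
    "H1299": 5.0, "A549": 5.9, "H460": 6.6,
    "H1993": 7.4, "HCC827": 7.6, "H1975": 7.8,
}
_ERCC4_DCT = {c: 6.2 for c in _ERCC1_DCT}
_ACTB_CT = 18.0


def gen_ct_table(seed: int = 0, collections: int = 3, tech_reps: int = 2,
                 noise_sd: float = 0.12):
    """Synthetic qRT-PCR Ct table (cell_line, gene, collection, ct)."""
    import pandas as pd
    rng = np.random.default_rng(seed)
    rows = []
    for coll in range(1, collections + 1):
        for cell in _ERCC1_DCT:
            actb = _ACTB_CT + rng.normal(0, noise_sd)
            for gene, dct in (("ERCC1", _ERCC1_DCT[cell]),
                              ("ERCC4", _ERCC4_DCT[cell])):
                for _ in range(tech_reps):
                    rows.append({
                        "cell_line": cell, "gene": gene, "collection": coll,
                        "ct": actb + dct + rng.normal(0, noise_sd),
                    })
            for _ in range(tech_reps):
                rows.append({"cell_line": cell, "gene": "ACTB",
                             "collection": coll,
                             "ct": actb + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Toy protein-ligand complexes
# ---------------------------------------------------------------------------

def _lysine(chain: str, seq: int) -> Residue:
    """A lysine whose NZ sits at the origin, side chain along -x."""
    coords = {
        "NZ": (0.0, 0.0, 0.0), "CE": (-1.5, 0.0, 0.0), "CD": (-3.0, 0.0, 0.0),
        "CG": (-4.5, 0.0, 0.0), "CB": (-6.0, 0.0, 0.0), "CA": (-7.5, 0.0, 0.0),
        "N": (-9.0, 0.0, 0.0), "C": (-7.5, 1.5, 0.0), "O": (-7.5, 2.7, 0.0),
    }
    atoms = [Atom(name=n, element=("N" if n.startswith("N") else
                                   "O" if n.startswith("O") else "C"),
                  coord=np.array(c)) for n, c in coords.items()]
    return Residue(chain=chain, name="LYS", seq=seq, atoms=atoms)


def gen_toy_complex(
    motif: str, margin: float, chain: str = "A", seq: int = 1
) -> tuple[Structure, list[Atom]]:
    """A single-residue protein plus a ligand realizing one contact motif.

    The critical geometry sits inside its detection threshold by exactly
    ``margin`` Angstrom (or safely outside everything for NONE).
    """
    if margin <= 0:
        raise ValueError("margin must be > 0")
    res = _lysine(chain, seq)
    if motif == "HBOND":
        d = 4.1 - margin
        lig = [
            Atom(name="N1", element="N", coord=np.array([d, 0.0, 0.0])),
            Atom(name="H1", element="H", coord=np.array([d - 1.0, 0.0, 0.0])),
            Atom(name="C1", element="C", coord=np.array([d, 1.47, 0.0])),
        ]
    elif motif == "HYDROPHOBIC":
        d = 4.0 - margin
        lig = [
            Atom(name="C1", element="C", coord=np.array([-3.0, d, 0.0])),
            Atom(name="C2", element="C", coord=np.array([-3.0, d, 1.5])),
        ]
    elif motif == "PI_CATION":
        z = 6.0 - margin
        r = 1.39
        lig = [
            Atom(name=f"C{i+1}", element="C",
                 coord=np.array([r * np.cos(i * np.pi / 3),
                                 r * np.sin(i * np.pi / 3), z]))
            for i in range(6)
        ]
    elif motif == "NONE":
        far = 10.0 + margin
        lig = [Atom(name="C1", element="C", coord=np.array([far + 40.0, 0.0, 0.0]))]
    else:
        raise ValueError(f"unknown motif {motif!r}")
    lig_res = Residue(chain="L", name="LIG", seq=1, het=True, atoms=lig)
    return Structure(residues=[res, lig_res]), lig


# ---------------------------------------------------------------------------
# Packaged screening-campaign fixture
# ---------------------------------------------------------------------------

@dataclass
class FixtureCompound:
    id: str
    source: str  # CHEMBRIDGE / NCI / DRUGBANK
    name: str = ""
    excluded_reason: str = ""


@dataclass
class PaperFixture:
    acquisition: list[FixtureCompound]
    exclusions: dict[str, str]
    best_ids: list[str]
    cytotoxic_10um_ids: list[str]
    stage_counts: dict[str, dict[str, int]]
    expected_category: dict[str, Category] = field(default_factory=dict)
    summaries: list[AssaySummary] = field(default_factory=list)
    v_cis: float = 87.5

    @property
    def evaluated_ids(self) -> list[str]:
        return [c.id for c in self.acquisition if not c.excluded_reason]


def _natural_key(cid: str):
    m = re.match(r"([A-Za-z]+)(\d+)", cid)
    return (m.group(1), int(m.group(2))) if m else (cid, 0)


def _fixture_dir():
    return resources.files("hittriage").joinpath("data/fixture")


def load_acquisition_lists() -> list[FixtureCompound]:
    """The three per-database selection files, concatenated."""
    out: list[FixtureCompound] = []
    for fname in ("selection_chembridge.tsv", "selection_nci.tsv",
                  "selection_drugbank.tsv"):
        lines = _fixture_dir().joinpath(fname).read_text().splitlines()
        for line in lines[1:]:
            cid, source, name = (line.split("\t") + [""])[:3]
            out.append(FixtureCompound(id=cid, source=source, name=name))
    return out


# Per-category synthesized viabilities (percent); every value keeps at
# least a 5-point margin from each decision threshold it meets.
_CATEGORY_VIABILITIES = {
    Category.NO_ENHANCEMENT: AssaySummary("", 87.5, 80.0, 83.125),
    Category.CYTOTOXIC_10uM: AssaySummary("", 87.5, 10.0, 15.0,
                                          v_alone_10=30.0, v_combo_10=25.0),
    Category.NO_ENHANCEMENT_10uM: AssaySummary("", 87.5, 12.0, 18.0,
                                               v_alone_10=90.0, v_combo_10=85.0),
    Category.BEST: AssaySummary("", 87.5, 75.0, 55.0),
    Category.LOW_EFFECT: AssaySummary("", 87.5, 60.0, 57.0),
}


def build_paper_fixture() -> PaperFixture:
    """Assemble the packaged campaign fixture and its viability summaries.

    Named compounds (the BEST list, the cytotoxic-at-10uM list) get their
    recorded outcomes; the remaining compounds are assigned categories in
    natural id order so that every per-database stage count is matched
    exactly. Aggregate self-consistency is asserted at build time.
    """
    acquisition = load_acquisition_lists()
    exclusions: dict[str, str] = {}
    lines = _fixture_dir().joinpath("exclusions.tsv").read_text().splitlines()
    for line in lines[1:]:
        cid, reason = line.split("\t")
        exclusions[cid] = reason
    for c in acquisition:
        c.excluded_reason = exclusions.get(c.id, "")

    best_ids = _fixture_dir().joinpath("best_ids.txt").read_text().split()
    cytotoxic_ids = _fixture_dir().joinpath("cytotoxic_10um_ids.txt").read_text().split()
    stage_counts = json.loads(_fixture_dir().joinpath("stage_counts.json").read_text())

    fixture = PaperFixture(
        acquisition=acquisition, exclusions=exclusions, best_ids=best_ids,
        cytotoxic_10um_ids=cytotoxic_ids, stage_counts=stage_counts,
    )

    expected: dict[str, Category] = {}
    for source, members in _group_by_source(acquisition).items():
        evaluated = sorted(
            (c.id for c in members if not c.excluded_reason), key=_natural_key
        )
        named_best = [c for c in evaluated if c in best_ids]
        named_cyto = [c for c in evaluated if c in cytotoxic_ids]
        n_stage1 = stage_counts[source]["stage1_discarded"]
        n_routed = stage_counts[source]["routed_10uM"]
        pool = [c for c in evaluated if c not in named_best and c not in named_cyto]
        ne, pool = pool[:n_stage1], pool[n_stage1:]
        n_fill_routed = n_routed - len(named_cyto)
        routed_ne10, pool = pool[:n_fill_routed], pool[n_fill_routed:]
        for cid in named_best:
            expected[cid] = Category.BEST
        for cid in named_cyto:
            expected[cid] = Category.CYTOTOXIC_10uM
        for cid in ne:
            expected[cid] = Category.NO_ENHANCEMENT
        for cid in routed_ne10:
            expected[cid] = Category.NO_ENHANCEMENT_10uM
        for cid in pool:
            expected[cid] = Category.LOW_EFFECT
    fixture.expected_category = expected

    for cid in sorted(expected, key=_natural_key):
        tmpl = _CATEGORY_VIABILITIES[expected[cid]]
        fixture.summaries.append(AssaySummary(
            compound_id=cid, v_cis=fixture.v_cis, v_alone=tmpl.v_alone,
            v_combo=tmpl.v_combo, v_alone_10=tmpl.v_alone_10,
            v_combo_10=tmpl.v_combo_10, n_experiments=2,
        ))

    _assert_self_consistent(fixture)
    return fixture


def _group_by_source(acquisition: Iterable[FixtureCompound]):
    groups: dict[str, list[FixtureCompound]] = {}
    for c in acquisition:
        groups.setdefault(c.source, []).append(c)
    return groups


def _assert_self_consistent(f: PaperFixture) -> None:
    n_acq = len(f.acquisition)
    n_eval = len(f.evaluated_ids)
    assert n_acq == 106 and len(f.exclusions) == 4 and n_eval == 102, (
        n_acq, len(f.exclusions), n_eval)
    counts: dict[Category, int] = {}
    for cat in f.expected_category.values():
        counts[cat] = counts.get(cat, 0) + 1
    ne = counts.get(Category.NO_ENHANCEMENT, 0)
    routed = counts.get(Category.CYTOTOXIC_10uM, 0) + counts.get(
        Category.NO_ENHANCEMENT_10uM, 0)
    stage3 = counts.get(Category.BEST, 0) + counts.get(Category.LOW_EFFECT, 0)
    assert ne + routed + stage3 == 102, counts
    assert ne == 46 and routed == 23 and stage3 == 33, counts
    assert counts.get(Category.BEST, 0) == 22 and counts.get(
        Category.LOW_EFFECT, 0) == 11, counts
    assert counts.get(Category.CYTOTOXIC_10uM, 0) == 5 and counts.get(
        Category.NO_ENHANCEMENT_10uM, 0) == 18, counts
    assert set(f.best_ids) == {
        cid for cid, c in f.expected_category.items() if c is Category.BEST}
    assert set(f.cytotoxic_10um_ids) == {
        cid for cid, c in f.expected_category.items()
        if c is Category.CYTOTOXIC_10uM}
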