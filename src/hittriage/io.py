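"""Readers/writers for the pipeline's tabular formats, run configuration,
and input validation diagnostics."""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chem import Compound, Source
from .hitcalling import CascadeThresholds, Condition, PlateRecord
from .triage import DockingRecord, TriageConfig


@dataclass
class RunConfig:
    """Flat, JSON-serializable configuration for a full run.

    Every decision threshold is a named key with the campaign default:
    stage1 85%, cytotoxicity 30%, effect 10 pp, retest death 50%, score
    cuts 90 (screening) / 75 (approved drugs), top 5000, pocket radius
    15 A, 1024-bit fingerprints.
    """

    scores: str | None = None
    library: str | None = None
    plates: str | None = None
    structure: str | None = None
    out_dir: str = "out"
    seed: int = 7
    log_level: str = "INFO"
    top_n: int = 5000
    score_min: float = 90.0
    score_min_approved: float = 75.0
    stage1_rel_viab: float = 85.0
    cytotox_viability: float = 30.0
    effect_min: float = 10.0
    retest_death: float = 50.0
    pocket_radius: float = 15.0
    fingerprint_nbits: int = 1024
    fingerprint_radius: int = 2
    similarity_threshold: float = 0.6
    max_lipinski_violations: int = 0
    tsne_perplexity: float = 30.0

    def triage_config(self) -> TriageConfig:
        return TriageConfig(
            top_n=self.top_n, score_min=self.score_min,
            score_min_approved=self.score_min_approved,
            max_lipinski_violations=self.max_lipinski_violations,
            similarity_threshold=self.similarity_threshold,
            fingerprint_radius=self.fingerprint_radius,
            fingerprint_nbits=self.fingerprint_nbits,
        )

    def cascade_thresholds(self) -> CascadeThresholds:
        return CascadeThresholds(
            stage1_rel_viab=self.stage1_rel_viab,
            cytotox_viability=self.cytotox_viability,
            effect_min=self.effect_min, retest_death=self.retest_death,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_scores_csv(path: str | Path) -> list[DockingRecord]:
    """CSV with columns compound_id, score [, ligand_efficiency]."""
    df = pd.read_csv(path)
    _require_columns(df, {"compound_id", "score"}, path)
    out = []
    for _, row in df.iterrows():
        le = row.get("ligand_efficiency")
        out.append(DockingRecord(
            compound_id=str(row["compound_id"]), score=float(row["score"]),
            ligand_efficiency=float(le) if pd.notna(le) else None,
        ))
    return out


def read_smiles_file(path: str | Path) -> tuple[list[Compound], list[str]]:
    """Delimited SMILES records: id, smiles [, name, source].

    Tab- or comma-separated; a header line containing 'smiles' is
    skipped. Unparseable records are rejected and reported (id + line),
    never silently kept.
    """
    from rdkit import Chem as RDChem

    compounds: list[Compound] = []
    errors: list[str] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        sep = "\t" if "\t" in line else ","
        parts = [p.strip() for p in line.split(sep)]
        if lineno == 1 and "smiles" in [p.lower() for p in parts]:
            continue
        if len(parts) < 2:
            errors.append(f"line {lineno}: expected at least (id, smiles)")
            continue
        cid, smiles = parts[0], parts[1]
        if RDChem.MolFromSmiles(smiles) is None:
            errors.append(f"line {lineno}: unparseable SMILES for id {cid!r}")
            continue
        name = parts[2] if len(parts) > 2 and parts[2] else None
        source = Source.SYNTHETIC
        if len(parts) > 3 and parts[3]:
            try:
                source = Source(parts[3].upper())
            except ValueError:
                errors.append(f"line {lineno}: unknown source {parts[3]!r}")
                continue
        compounds.append(Compound(id=cid, smiles=smiles, source=source, name=name))
    return compounds, errors


def read_sdf(path: str | Path) -> tuple[list[Compound], list[str]]:
    """SDF input; compound id from the title block (or _Name property)."""
    from rdkit import Chem as RDChem

    compounds, errors = [], []
    supplier = RDChem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            errors.append(f"record {i + 1}: unparseable SDF entry")
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if not cid:
            cid = f"SDF{i + 1}"
        compounds.append(Compound(id=cid, smiles=RDChem.MolToSmiles(mol)))
    return compounds, errors


PLATE_COLUMNS = {"experiment", "replicate", "compound_id", "condition",
                 "concentration_uM", "od"}


def read_plates_csv(path: str | Path) -> list[PlateRecord]:
    """Plate CSV with columns experiment, replicate, compound_id,
    condition, concentration_uM, od [, od_ref]."""
    df = pd.read_csv(path)
    _require_columns(df, PLATE_COLUMNS, path)
    records = []
    for _, row in df.iterrows():
        od_ref = row.get("od_ref")
        records.append(PlateRecord(
            compound_id=str(row["compound_id"]),
            condition=Condition(row["condition"]),
            concentration=float(row["concentration_uM"]),
            replicate=int(row["replicate"]),
            experiment=int(row["experiment"]),
            od=float(row["od"]),
            od_ref=float(od_ref) if pd.notna(od_ref) else None,
        ))
    return records


def write_plates_csv(records, path: str | Path) -> None:
    rows = [{
        "experiment": r.experiment, "replicate": r.replicate,
        "compound_id": r.compound_id, "condition": r.condition.value,
        "concentration_uM": r.concentration, "od": r.od,
        "od_ref": r.od_ref if r.od_ref is not None else "",
    } for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_smiles_file(compounds, path: str | Path) -> None:
    lines = ["id\tsmiles\tname\tsource"]
    for c in compounds:
        lines.append(f"{c.id}\t{c.smiles}\t{c.name or ''}\t{c.source.value}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_scores_csv(records, path: str | Path) -> None:
    rows = [{
        "compound_id": r.compound_id, "score": f"{r.score:.6f}",
        "ligand_efficiency": (f"{r.ligand_efficiency:.6f}"
                              if r.ligand_efficiency is not None else ""),
    } for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")


# ---------------------------------------------------------------------------
# Validation diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Diagnostic:
    path: str
    severity: str  # "error" | "warning"
    message: str
    line: int | None = None


def validate_inputs(
    scores: str | Path | None = None,
    library: str | Path | None = None,
    plates: str | Path | None = None,
) -> list[Diagnostic]:
    """Schema-check input files; returns diagnostics, never raises."""
    diags: list[Diagnostic] = []

    def check(path, kind):
        if path is None:
            return
        p = Path(path)
        if not p.exists():
            diags.append(Diagnostic(str(p), "error", "file not found"))
            return
        try:
            if kind == "scores":
                df = pd.read_csv(p)
                missing = {"compound_id", "score"} - set(df.columns)
                for col in sorted(missing):
                    diags.append(Diagnostic(str(p), "error",
                                            f"missing column {col!r}"))
            elif kind == "plates":
                df = pd.read_csv(p)
                missing = PLATE_COLUMNS - set(df.columns)
                for col in sorted(missing):
                    diags.append(Diagnostic(str(p), "error",
                                            f"missing column {col!r}"))
            elif kind == "library":
                _, errors = read_smiles_file(p)
                for msg in errors:
                    line = None
                    if msg.startswith("line "):
                        line = int(msg.split(":")[0].split()[1])
                    diags.append(Diagnostic(str(p), "warning", msg, line=line))
        except Exception as exc:  # diagnostics, not exceptions
            diags.append(Diagnostic(str(p), "error", f"unreadable: {exc}"))

    check(scores, "scores")
    check(library, "library")
    check(plates, "plates")
    return diags
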