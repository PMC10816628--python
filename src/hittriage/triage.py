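"""Virtual-screening post-processing: rank-and-cut on docking scores,
property/PAINS filtering with per-rejection reasons, a required-contact
gate, scaffold clustering, and 2-D chemical-space projection.

Every stage partitions its input (``in == kept + rejected``) and labels
each rejection with a machine-readable reason, so the whole cascade is
auditable.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.manifold import TSNE

from . import chem
from .chem import Compound, DescriptorSet, Fingerprint, PainsPattern, Scaffold
from .structure import (
    Atom,
    InteractionThresholds,
    PocketDefinition,
    Structure,
    detect_interactions,
)


@dataclass(frozen=True)
class DockingRecord:
    compound_id: str
    score: float  # higher is better
    ligand_efficiency: float | None = None  # score per heavy atom


# Residues flanking the key pocket lysine; contacts to any of these
# satisfy the required-contact gate. (resname, seq) on the XPF chain.
DEFAULT_ADJACENT_RESIDUES: tuple[tuple[str, int], ...] = (
    ("TYR", 833), ("ASN", 834), ("PRO", 837), ("PHE", 840),
    ("LEU", 841), ("MET", 856), ("VAL", 859), ("ILE", 862),
)
DEFAULT_CONTACT_RESIDUE = ("LYS", 860)


@dataclass
class TriageConfig:
    top_n: int = 5000
    score_min: float = 90.0
    score_min_approved: float = 75.0  # approved-drug source threshold
    max_lipinski_violations: int = 0
    pains_patterns: str | Path | None = None  # None -> packaged default
    contact_residue: tuple[str, int] = DEFAULT_CONTACT_RESIDUE
    adjacent_residues: tuple[tuple[str, int], ...] = DEFAULT_ADJACENT_RESIDUES
    similarity_threshold: float = 0.6
    fingerprint_radius: int = chem.DEFAULT_RADIUS
    fingerprint_nbits: int = chem.DEFAULT_NBITS

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not math.isfinite(self.score_min):
            raise ValueError("score_min must be finite")


@dataclass(frozen=True)
class Rejection:
    compound_id: str
    reason: str


def rank_and_cut(
    records: Sequence[DockingRecord], cfg: TriageConfig,
    score_min: float | None = None,
) -> list[DockingRecord]:
    """Keep the top-N scores, then drop scores at or below the threshold.

    Output is sorted descending by score with stable compound-id tie
    order. NaN scores are rejected with a warning. The top-N cut is
    applied before the score threshold.
    """
    cut = cfg.score_min if score_min is None else score_min
    clean = []
    for r in records:
        if math.isnan(r.score):
            warnings.warn(f"NaN score for {r.compound_id}; record dropped")
            continue
        clean.append(r)
    ranked = sorted(clean, key=lambda r: (-r.score, r.compound_id))
    top = ranked[: cfg.top_n]
    return [r for r in top if r.score > cut]


def apply_property_filters(
    survivors: Sequence[DockingRecord],
    descriptors: Mapping[str, DescriptorSet],
    cfg: TriageConfig,
    compounds: Mapping[str, Compound] | None = None,
    patterns: Sequence[PainsPattern] | None = None,
) -> tuple[list[DockingRecord], list[Rejection]]:
    """Drug-likeness and PAINS gate; each rejection names its first
    failed rule (``lipinski:<n>`` or ``PAINS:<pattern-id>``)."""
    if patterns is None and compounds is not None:
        patterns = chem.load_pains_patterns(cfg.pains_patterns)
    kept: list[DockingRecord] = []
    rejected: list[Rejection] = []
    for rec in survivors:
        d = descriptors.get(rec.compound_id)
        if d is None:
            raise ValueError(f"missing descriptors for compound {rec.compound_id}")
        if d.lipinski_violations > cfg.max_lipinski_violations:
            rejected.append(Rejection(rec.compound_id,
                                      f"lipinski:{d.lipinski_violations}"))
            continue
        if compounds is not None:
            comp = compounds.get(rec.compound_id)
            if comp is None:
                raise ValueError(f"missing structure for compound {rec.compound_id}")
            _, flagged = chem.pains_filter([comp], patterns)
            if flagged:
                rejected.append(Rejection(rec.compound_id,
                                          f"PAINS:{flagged[0].pattern_id}"))
                continue
        kept.append(rec)
    return kept, rejected


def require_contact(
    poses: Mapping[str, Sequence[Atom]],
    structure: Structure,
    pocket: PocketDefinition,
    cfg: TriageConfig | None = None,
    thresholds: InteractionThresholds | None = None,
) -> list[str]:
    """Ids of compounds with >= 1 typed interaction to the key residue or
    its adjacency set. The key residue must exist in the structure."""
    cfg = cfg or TriageConfig()
    wanted = {cfg.contact_residue} | set(cfg.adjacent_residues)
    present = {(r.name, r.seq) for r in structure.residues}
    if cfg.contact_residue not in present:
        raise ValueError(
            f"contact residue {cfg.contact_residue} absent from structure")
    kept = []
    for cid, atoms in poses.items():
        recs = detect_interactions(structure, list(atoms), pocket,
                                   compound_id=cid, thresholds=thresholds)
        names = {(r.residue_name, r.residue[1]) for r in recs}
        if names & wanted:
            kept.append(cid)
    return kept


# ---------------------------------------------------------------------------
# Scaffold clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterAssignment:
    compound_id: str
    cluster_id: int  # dense from 1; 1 = most populated
    scaffold: Scaffold


def cluster_compounds(
    compounds: Sequence[Compound],
    similarity_threshold: float = 0.6,
    fingerprint_radius: int = chem.DEFAULT_RADIUS,
    fingerprint_nbits: int = chem.DEFAULT_NBITS,
) -> list[ClusterAssignment]:
    """Two-level scaffold clustering.

    Compounds are first grouped by exact Murcko scaffold; scaffold groups
    whose representative fingerprints (fingerprint of the scaffold
    itself) reach the Tanimoto threshold are then merged by single
    linkage. Acyclic molecules form a dedicated no-scaffold cluster that
    never merges. Clusters are numbered largest-first; size ties break
    on the lexicographically smallest scaffold SMILES.
    """
    groups: dict[str, list[str]] = {}
    for c in compounds:
        scaf = chem.murcko_scaffold(c)
        groups.setdefault(scaf.smiles, []).append(c.id)

    keys = sorted(groups)
    fps: dict[str, Fingerprint] = {}
    for smi in keys:
        if smi == "":
            continue
        fps[smi] = chem.morgan_fingerprint(
            Compound(id=f"scaffold:{smi}", smiles=smi),
            radius=fingerprint_radius, nbits=fingerprint_nbits,
        )
    parent = {k: k for k in keys}

    def find(k: str) -> str:
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    ringed = [k for k in keys if k != ""]
    for i, a in enumerate(ringed):
        for b in ringed[i + 1:]:
            if chem.tanimoto(fps[a], fps[b]) >= similarity_threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    merged: dict[str, list[tuple[str, str]]] = {}
    for smi, ids in groups.items():
        root = find(smi)
        merged.setdefault(root, []).extend((cid, smi) for cid in ids)
    ordered = sorted(
        merged.items(), key=lambda kv: (-len(kv[1]), min(s for _, s in kv[1]))
    )
    out: list[ClusterAssignment] = []
    for cluster_id, (_, members) in enumerate(ordered, start=1):
        for cid, smi in members:
            out.append(ClusterAssignment(
                compound_id=cid, cluster_id=cluster_id, scaffold=Scaffold(smi)))
    return out


# ---------------------------------------------------------------------------
# Chemical-space projection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChemicalSpacePoint:
    compound_id: str
    x: float
    y: float
    stratum: str


def project_chemical_space(
    fingerprints: Mapping[str, Fingerprint],
    seed: int,
    strata: Mapping[str, str] | None = None,
    perplexity: float = 30.0,
) -> list[ChemicalSpacePoint]:
    """Deterministic 2-D t-SNE embedding of fingerprint bit vectors."""
    ids = list(fingerprints)
    if len(ids) < 5:
        raise ValueError("need >= 5 compounds for a chemical-space map")
    nbits = next(iter(fingerprints.values())).nbits
    x = np.zeros((len(ids), nbits), dtype=float)
    for i, cid in enumerate(ids):
        fp = fingerprints[cid]
        if fp.nbits != nbits:
            raise ValueError("mixed fingerprint lengths")
        x[i, list(fp.bits)] = 1.0
    if perplexity >= len(ids):
        raise ValueError(
            f"perplexity {perplexity} too large for {len(ids)} points; "
            "lower the perplexity below the number of compounds")
    emb = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca",
        max_iter=500,
    ).fit_transform(x)
    strata = strata or {}
    return [
        ChemicalSpacePoint(compound_id=cid, x=float(emb[i, 0]),
                           y=float(emb[i, 1]),
                           stratum=strata.get(cid, "UNKNOWN"))
        for i, cid in enumerate(ids)
    ]
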