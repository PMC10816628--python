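"""Structural analysis: PDB-subset parsing, rigid superposition, binding
pocket definition, buried interface area, and rule-based protein-ligand
interaction typing.

Interaction detection is purely geometric. Default thresholds:

=============  ==================================================
HBOND          donor-acceptor <= 4.1 A, donor angle >= 100 deg
               (angle waived when no hydrogens are present)
HYDROPHOBIC    apolar C ... apolar C <= 4.0 A
PI_STACK       ring centroids <= 5.5 A, plane angle < 30 deg
               (parallel) or in [60, 90] deg (T-shaped)
PI_CATION      ring centroid ... cation <= 6.0 A
SALT_BRIDGE    charged-group centroids <= 5.5 A
HALOGEN        ligand X (Cl/Br/I/F) ... acceptor N/O <= 4.0 A
WATER_BRIDGE   donor/acceptor <= 4.1 A to a shared water oxygen
=============  ==================================================
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

WATER_RESNAMES = {"HOH", "WAT", "DOD"}
COVALENT_CUTOFF = 1.9  # A, heavy-atom bond inference
_H_BOND_CUTOFF = 1.3  # A, X-H bond inference


@dataclass(frozen=True)
class InteractionThresholds:
    hbond_dist: float = 4.1
    hbond_angle_min: float = 100.0
    hydrophobic_dist: float = 4.0
    pi_stack_dist: float = 5.5
    pi_stack_parallel_max: float = 30.0
    pi_stack_tshape_min: float = 60.0
    pi_stack_tshape_max: float = 90.0
    pi_cation_dist: float = 6.0
    salt_bridge_dist: float = 5.5
    halogen_dist: float = 4.0


class InteractionType(enum.Enum):
    HBOND = "HBOND"
    HYDROPHOBIC = "HYDROPHOBIC"
    PI_STACK = "PI_STACK"
    PI_CATION = "PI_CATION"
    SALT_BRIDGE = "SALT_BRIDGE"
    HALOGEN = "HALOGEN"
    WATER_BRIDGE = "WATER_BRIDGE"


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) Angstrom
    serial: int = 0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: bad coordinates {self.coord}")


@dataclass
class Residue:
    chain: str
    name: str
    seq: int  # 1-based, as deposited
    icode: str = ""
    het: bool = False
    atoms: list[Atom] = field(default_factory=list)

    @property
    def spec(self) -> tuple[str, int, str]:
        """Residue identity: (chain, PDB number, insertion code)."""
        return (self.chain, self.seq, self.icode)

    @property
    def label(self) -> str:
        return f"{self.name}{self.seq}{self.icode}({self.chain})"

    @property
    def is_water(self) -> bool:
        return self.name in WATER_RESNAMES

    def atom(self, name: str) -> Atom | None:
        return next((a for a in self.atoms if a.name == name), None)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclass
class Structure:
    residues: list[Residue] = field(default_factory=list)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain, None)
        return list(seen)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def polymer(self) -> list[Residue]:
        return [r for r in self.residues if not r.het and not r.is_water]

    def waters(self) -> list[Residue]:
        return [r for r in self.residues if r.is_water]

    def ligands(self) -> list[Residue]:
        return [r for r in self.residues if r.het and not r.is_water]

    def chain(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain == chain_id]

    def find_residue(
        self, chain: str, seq: int, icode: str = ""
    ) -> Residue | None:
        for r in self.residues:
            if r.spec == (chain, seq, icode):
                return r
        return None


# ---------------------------------------------------------------------------
# PDB subset I/O (ATOM/HETATM/TER/MODEL/ENDMDL fixed columns)
# ---------------------------------------------------------------------------

def parse_pdb(path: str | Path) -> Structure:
    """Read ATOM/HETATM records from a PDB file into a Structure.

    Only the first MODEL of a multi-model file is kept. Lines with
    malformed coordinate fields are skipped with a warning. A file with
    no ATOM/HETATM records is an error.
    """
    path = Path(path)
    residues: dict[tuple, Residue] = {}
    in_later_model = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "ENDMDL":
            in_later_model = True
        if in_later_model or rec not in ("ATOM", "HETATM"):
            continue
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            resname = line[17:20].strip()
            chain = line[21].strip()
            seq = int(line[22:26])
            icode = line[26].strip()
            xyz = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
            element = line[76:78].strip() if len(line) >= 78 else ""
        except (ValueError, IndexError):
            warnings.warn(f"{path}:{lineno}: malformed record skipped")
            continue
        if not element:
            element = _element_from_name(name)
        key = (chain, seq, icode, resname)
        res = residues.get(key)
        if res is None:
            res = Residue(
                chain=chain, name=resname, seq=seq, icode=icode,
                het=(rec == "HETATM"),
            )
            residues[key] = res
        res.atoms.append(Atom(name=name, element=element, coord=xyz, serial=serial))
    if not residues:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    return Structure(residues=list(residues.values()))


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE"):
        return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else "C"


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure back to PDB fixed-column format."""
    lines = []
    serial = 0
    for res in structure.residues:
        rec = "HETATM" if res.het or res.is_water else "ATOM  "
        for atom in res.atoms:
            serial += 1
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"{rec}{serial:5d} {name:<4s}{res.name:>4s}{res.chain:>2s}"
                f"{res.seq:4d}{res.icode:1s}   "
                f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of point set ``b`` onto ``a`` (Kabsch).

    Returns (rotation R, translation t, rmsd) minimizing ||(R @ b.T).T + t - a||.
    Requires matching counts and >= 3 non-collinear points.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"selection size mismatch: {a.shape} vs {b.shape}")
    if a.shape[0] < 3 or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("need >= 3 points of dimension 3")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(a0) < 2 or np.linalg.matrix_rank(b0) < 2:
        raise ValueError("degenerate (collinear) point set")
    h = b0.T @ a0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - rot @ cb
    moved = (rot @ b.T).T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return rot, trans, rmsd


def superpose_ca(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray, float]:
    """Superpose two structures on C-alpha atoms of their shared residues."""
    ca_a = {r.spec: r.atom("CA") for r in a.polymer() if r.atom("CA")}
    ca_b = {r.spec: r.atom("CA") for r in b.polymer() if r.atom("CA")}
    common = sorted(set(ca_a) & set(ca_b))
    if len(common) < 3:
        raise ValueError("fewer than 3 shared C-alpha atoms")
    pa = np.array([ca_a[k].coord for k in common])
    pb = np.array([ca_b[k].coord for k in common])
    return superpose(pa, pb)


# ---------------------------------------------------------------------------
# Pocket definition
# ---------------------------------------------------------------------------

@dataclass
class PocketDefinition:
    center_residue: tuple[str, int, str]
    radius: float
    member_residues: list[Residue]
    contact_area: float | None = None

    def member_specs(self) -> set[tuple[str, int, str]]:
        return {r.spec for r in self.member_residues}


def define_pocket(
    structure: Structure, chain: str, seq: int, radius: float, icode: str = ""
) -> PocketDefinition:
    """Residues with any atom within ``radius`` A of any center-residue atom."""
    center = structure.find_residue(chain, seq, icode)
    if center is None:
        raise ValueError(f"center residue ({chain}, {seq}{icode}) not in structure")
    ccoords = center.coords()
    members = []
    for res in structure.residues:
        if res.is_water:
            continue
        d = np.linalg.norm(
            res.coords()[:, None, :] - ccoords[None, :, :], axis=2
        )
        if d.min() <= radius:
            members.append(res)
    return PocketDefinition(
        center_residue=center.spec, radius=radius, member_residues=members
    )


# ---------------------------------------------------------------------------
# Solvent-accessible / buried surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

_VDW_CACHE: dict[str, float] | None = None


def vdw_radius(element: str) -> float:
    global _VDW_CACHE
    if _VDW_CACHE is None:
        _VDW_CACHE = {}
        text = resources.files("hittriage").joinpath("data/vdw_radii.tsv").read_text()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            el, r = line.split("\t")
            _VDW_CACHE[el.upper()] = float(r)
    return _VDW_CACHE.get(element.upper(), 1.70)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(
    atoms: Sequence[Atom], probe: float = 1.4, n_points: int = 960
) -> float:
    """Total solvent-accessible surface area (A^2), sphere sampling."""
    coords = np.array([a.coord for a in atoms])
    radii = np.array([vdw_radius(a.element) + probe for a in atoms])
    pts = _sphere_points(n_points)
    total = 0.0
    for i in range(len(atoms)):
        shell = coords[i] + radii[i] * pts
        accessible = np.ones(n_points, dtype=bool)
        d2 = np.sum((coords - coords[i]) ** 2, axis=1)
        near = np.where((d2 > 0) & (d2 < (radii + radii[i]) ** 2))[0]
        for j in near:
            dist2 = np.sum((shell - coords[j]) ** 2, axis=1)
            accessible &= dist2 > radii[j] ** 2
        total += accessible.mean() * 4.0 * math.pi * radii[i] ** 2
    return float(total)


def contact_surface_area(
    structure: Structure,
    chain_a: str,
    chain_b: str,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Buried interface area: (SASA(a) + SASA(b) - SASA(ab)) / 2."""
    atoms_a = [a for r in structure.chain(chain_a) if not r.is_water for a in r.atoms]
    atoms_b = [a for r in structure.chain(chain_b) if not r.is_water for a in r.atoms]
    if not atoms_a:
        raise ValueError(f"chain {chain_a!r} absent or empty")
    if not atoms_b:
        raise ValueError(f"chain {chain_b!r} absent or empty")
    s_a = sasa(atoms_a, probe, n_points)
    s_b = sasa(atoms_b, probe, n_points)
    s_ab = sasa(list(atoms_a) + list(atoms_b), probe, n_points)
    return max(0.0, (s_a + s_b - s_ab) / 2.0)


# ---------------------------------------------------------------------------
# Interaction typing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionRecord:
    compound_id: str
    residue: tuple[str, int, str]
    residue_name: str
    type: InteractionType
    distance: float
    angle: float | None = None
    distance_only: bool = False  # H-bond detected without hydrogens

    def __post_init__(self) -> None:
        if not self.distance > 0:
            raise ValueError("interaction distance must be > 0")


_AROMATIC_RING_ATOMS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [["CG", "CD1", "CD2", "NE1", "CE2"],
            ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}
_CATION_GROUPS = {"LYS": [["NZ"]], "ARG": [["NE", "NH1", "NH2"]]}
_ANION_GROUPS = {"ASP": [["OD1", "OD2"]], "GLU": [["OE1", "OE2"]]}
# polar protein atoms able to donate/accept (heavy-atom level)
_POLAR_ELEMENTS = {"N", "O"}
_HALOGENS = {"F", "CL", "BR", "I"}
_KNOWN_ELEMENTS = {"H", "C", "N", "O", "F", "P", "S", "CL", "BR", "I", "B", "SE"}


def _bond_graph(atoms: Sequence[Atom]) -> nx.Graph:
    """Heavy-atom bond inference by distance; H attached within 1.3 A."""
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    coords = np.array([a.coord for a in atoms])
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            ei, ej = atoms[i].element.upper(), atoms[j].element.upper()
            cutoff = _H_BOND_CUTOFF if "H" in (ei, ej) else COVALENT_CUTOFF
            if d <= cutoff:
                g.add_edge(i, j, length=d)
    return g


def _apolar_carbons(atoms: Sequence[Atom], graph: nx.Graph) -> list[int]:
    out = []
    for i, a in enumerate(atoms):
        if a.element.upper() != "C":
            continue
        if any(atoms[j].element.upper() in _POLAR_ELEMENTS for j in graph.neighbors(i)):
            continue
        out.append(i)
    return out


def _ligand_rings(atoms: Sequence[Atom], graph: nx.Graph) -> list[list[int]]:
    rings = []
    for cycle in nx.cycle_basis(graph):
        if 5 <= len(cycle) <= 6 and _is_planar([atoms[i].coord for i in cycle]):
            rings.append(cycle)
    return rings


def _is_planar(coords: list[np.ndarray], tol: float = 0.35) -> bool:
    pts = np.array(coords)
    pts = pts - pts.mean(axis=0)
    _, s, _ = np.linalg.svd(pts)
    return s[2] < tol


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    pts = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(pts)
    return vt[2]


def _ligand_cations(atoms: Sequence[Atom], graph: nx.Graph) -> list[int]:
    """Nitrogens with >= 3 heavy/H neighbors or explicit lone N-H3 count.

    Formal charges are unavailable from bare coordinates; an amine-like
    nitrogen (sp3, fully substituted by C/H) is treated as protonatable.
    """
    out = []
    for i, a in enumerate(atoms):
        if a.element.upper() != "N":
            continue
        neigh = list(graph.neighbors(i))
        if not neigh:
            continue
        if all(atoms[j].element.upper() in {"C", "H"} for j in neigh):
            out.append(i)
    return out


def _ligand_anion_groups(atoms: Sequence[Atom], graph: nx.Graph) -> list[list[int]]:
    """Carboxylate-like groups: a carbon bound to two terminal oxygens."""
    groups = []
    for i, a in enumerate(atoms):
        if a.element.upper() != "C":
            continue
        oxys = [
            j for j in graph.neighbors(i)
            if atoms[j].element.upper() == "O" and graph.degree[j] == 1
        ]
        if len(oxys) == 2:
            groups.append(oxys)
    return groups


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosv, -1.0, 1.0)))


def detect_interactions(
    structure: Structure,
    ligand_atoms: Sequence[Atom],
    pocket: PocketDefinition,
    compound_id: str = "LIG",
    thresholds: InteractionThresholds | None = None,
) -> list[InteractionRecord]:
    """Type all protein-ligand contacts within the pocket, geometrically.

    Atoms with unrecognized element symbols are excluded from typed roles
    with a warning. Emitted records always satisfy their rule's distance
    cutoff and angle window.
    """
    th = thresholds or InteractionThresholds()
    lig = []
    for a in ligand_atoms:
        if a.element.upper() not in _KNOWN_ELEMENTS:
            warnings.warn(f"unknown element {a.element!r} on ligand atom {a.name!r}; ignored")
            continue
        lig.append(a)
    if not lig:
        return []
    lgraph = _bond_graph(lig)
    lcoords = np.array([a.coord for a in lig])
    lig_has_h = any(a.element.upper() == "H" for a in lig)

    records: list[InteractionRecord] = []
    seen: set[tuple] = set()

    def emit(res: Residue, itype: InteractionType, dist: float,
             angle: float | None = None, distance_only: bool = False) -> None:
        key = (res.spec, itype)
        if key in seen:
            return
        seen.add(key)
        records.append(InteractionRecord(
            compound_id=compound_id, residue=res.spec, residue_name=res.name,
            type=itype, distance=round(dist, 3), angle=angle,
            distance_only=distance_only,
        ))

    lig_rings = _ligand_rings(lig, lgraph)
    lig_cations = _ligand_cations(lig, lgraph)
    lig_anions = _ligand_anion_groups(lig, lgraph)
    lig_apolar = _apolar_carbons(lig, lgraph)
    lig_polar = [i for i, a in enumerate(lig) if a.element.upper() in _POLAR_ELEMENTS]
    lig_halogens = [i for i, a in enumerate(lig) if a.element.upper() in _HALOGENS]

    for res in pocket.member_residues:
        if res.is_water or all(a in ligand_atoms for a in res.atoms):
            continue
        ratoms = res.atoms
        rgraph = _bond_graph(ratoms)
        res_has_h = any(a.element.upper() == "H" for a in ratoms)

        # --- hydrogen bonds (both directions, heavy-atom D...A distance) ---
        for li in lig_polar:
            for rj, ra in enumerate(ratoms):
                if ra.element.upper() not in _POLAR_ELEMENTS:
                    continue
                d = float(np.linalg.norm(lcoords[li] - ra.coord))
                if not 0 < d <= th.hbond_dist:
                    continue
                ok, ang, dist_only = _hbond_geometry(
                    lig, lgraph, li, ratoms, rgraph, rj,
                    lig_has_h, res_has_h, th,
                )
                if ok:
                    emit(res, InteractionType.HBOND, d, ang, dist_only)

        # --- hydrophobic ---
        r_apolar = _apolar_carbons(ratoms, rgraph)
        for li in lig_apolar:
            for rj in r_apolar:
                d = float(np.linalg.norm(lcoords[li] - ratoms[rj].coord))
                if 0 < d <= th.hydrophobic_dist:
                    emit(res, InteractionType.HYDROPHOBIC, d)

        # --- aromatic ring geometry on the protein side ---
        prot_rings = []
        for names in _AROMATIC_RING_ATOMS.get(res.name, []):
            got = [res.atom(n) for n in names]
            if all(got):
                prot_rings.append(np.array([a.coord for a in got]))

        for ring in prot_rings:
            centroid = ring.mean(axis=0)
            normal = _ring_normal(ring)
            # pi-stacking against ligand rings
            for lring in lig_rings:
                lr = lcoords[lring]
                lcent, lnorm = lr.mean(axis=0), _ring_normal(lr)
                d = float(np.linalg.norm(centroid - lcent))
                if not 0 < d <= th.pi_stack_dist:
                    continue
                ang = math.degrees(math.acos(np.clip(abs(np.dot(normal, lnorm)), 0, 1)))
                if ang < th.pi_stack_parallel_max or (
                    th.pi_stack_tshape_min <= ang <= th.pi_stack_tshape_max
                ):
                    emit(res, InteractionType.PI_STACK, d, ang)
            # protein ring vs ligand cation
            for li in lig_cations:
                d = float(np.linalg.norm(centroid - lcoords[li]))
                if 0 < d <= th.pi_cation_dist:
                    emit(res, InteractionType.PI_CATION, d)

        # ligand ring vs protein cation
        for names in _CATION_GROUPS.get(res.name, []):
            got = [res.atom(n) for n in names]
            if not all(got):
                continue
            ccent = np.array([a.coord for a in got]).mean(axis=0)
            for lring in lig_rings:
                lcent = lcoords[lring].mean(axis=0)
                d = float(np.linalg.norm(ccent - lcent))
                if 0 < d <= th.pi_cation_dist:
                    emit(res, InteractionType.PI_CATION, d)
            # salt bridge: protein cation vs ligand anion group
            for grp in lig_anions:
                acent = lcoords[grp].mean(axis=0)
                d = float(np.linalg.norm(ccent - acent))
                if 0 < d <= th.salt_bridge_dist:
                    emit(res, InteractionType.SALT_BRIDGE, d)

        for names in _ANION_GROUPS.get(res.name, []):
            got = [res.atom(n) for n in names]
            if not all(got):
                continue
            acent = np.array([a.coord for a in got]).mean(axis=0)
            for li in lig_cations:
                d = float(np.linalg.norm(acent - lcoords[li]))
                if 0 < d <= th.salt_bridge_dist:
                    emit(res, InteractionType.SALT_BRIDGE, d)

        # --- halogen bonds: ligand halogen to protein N/O ---
        for li in lig_halogens:
            for ra in ratoms:
                if ra.element.upper() not in _POLAR_ELEMENTS:
                    continue
                d = float(np.linalg.norm(lcoords[li] - ra.coord))
                if 0 < d <= th.halogen_dist:
                    emit(res, InteractionType.HALOGEN, d)

    # --- water bridges: ligand polar -- water O -- protein polar ---
    pocket_specs = pocket.member_specs()
    for wat in structure.waters():
        ox = next((a for a in wat.atoms if a.element.upper() == "O"), None)
        if ox is None:
            continue
        lig_close = any(
            0 < np.linalg.norm(lcoords[li] - ox.coord) <= th.hbond_dist
            for li in lig_polar
        )
        if not lig_close:
            continue
        for res in structure.polymer():
            if res.spec not in pocket_specs:
                continue
            for ra in res.atoms:
                if ra.element.upper() not in _POLAR_ELEMENTS:
                    continue
                d = float(np.linalg.norm(ra.coord - ox.coord))
                if 0 < d <= th.hbond_dist:
                    emit(res, InteractionType.WATER_BRIDGE, d)
                    break
    return records


def _hbond_geometry(lig, lgraph, li, ratoms, rgraph, rj,
                    lig_has_h, res_has_h, th):
    """Check donor-H geometry for a candidate heavy-atom pair.

    Returns (ok, angle_or_None, distance_only). The pair qualifies if
    either side can donate: a side with hydrogens donates through an
    attached H meeting the angle minimum; a side without hydrogens
    donates on distance alone (flagged).
    """
    # ligand donates
    lig_hs = [j for j in lgraph.neighbors(li) if lig[j].element.upper() == "H"]
    if lig_hs:
        for h in lig_hs:
            ang = _angle(lig[li].coord, lig[h].coord, ratoms[rj].coord)
            if ang >= th.hbond_angle_min:
                return True, round(ang, 1), False
    elif not lig_has_h:
        return True, None, True
    # residue donates
    res_hs = [j for j in rgraph.neighbors(rj) if ratoms[j].element.upper() == "H"]
    if res_hs:
        for h in res_hs:
            ang = _angle(ratoms[rj].coord, ratoms[h].coord, lig[li].coord)
            if ang >= th.hbond_angle_min:
                return True, round(ang, 1), False
    elif not res_has_h:
        return True, None, True
    return False, None, False


# ---------------------------------------------------------------------------
# Interaction matrix (residues x compounds)
# ---------------------------------------------------------------------------

@dataclass
class InteractionMatrix:
    residues: list[tuple[str, int, str]]
    residue_names: dict[tuple[str, int, str], str]
    compounds: list[str]
    cells: dict[tuple[tuple[str, int, str], str], set[InteractionType]]

    def types(self, residue: tuple[str, int, str], compound: str) -> set[InteractionType]:
        return self.cells.get((residue, compound), set())

    def residue_marginal(self, residue: tuple[str, int, str]) -> int:
        """Number of compounds contacting the residue (any type)."""
        return sum(1 for c in self.compounds if self.cells.get((residue, c)))

    def to_frame(self):
        import pandas as pd
        data = {}
        for c in self.compounds:
            col = []
            for r in self.residues:
                ts = self.cells.get((r, c), set())
                col.append(",".join(sorted(t.value for t in ts)))
            data[c] = col
        idx = [f"{self.residue_names[r]}{r[1]}{r[2]}({r[0]})" for r in self.residues]
        return pd.DataFrame(data, index=idx)


def build_interaction_matrix(records: Iterable[InteractionRecord]) -> InteractionMatrix:
    """Aggregate typed contacts into the residues x compounds matrix."""
    cells: dict[tuple, set[InteractionType]] = {}
    residues: dict[tuple, str] = {}
    compounds: dict[str, None] = {}
    for rec in records:
        residues.setdefault(rec.residue, rec.residue_name)
        compounds.setdefault(rec.compound_id, None)
        cells.setdefault((rec.residue, rec.compound_id), set()).add(rec.type)
    res_order = sorted(residues, key=lambda r: (r[0], r[1], r[2]))
    return InteractionMatrix(
        residues=res_order,
        residue_names=residues,
        compounds=list(compounds),
        cells=cells,
    )
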