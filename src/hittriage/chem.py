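"""Compound-level chemistry: descriptors, drug-likeness, fingerprints,
scaffolds, similarity, and PAINS substructure filtering.

All operations are deterministic functions of the canonical structure:
two SMILES spellings of the same molecule yield identical descriptors,
fingerprints and scaffolds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

DEFAULT_NBITS = 1024
DEFAULT_RADIUS = 2  # ECFP4-equivalent


class Source(enum.Enum):
    NCI = "NCI"
    CHEMBRIDGE = "CHEMBRIDGE"
    DRUGBANK = "DRUGBANK"
    CHEMBL = "CHEMBL"
    SYNTHETIC = "SYNTHETIC"


class CompoundError(ValueError):
    """Raised when a compound record cannot be parsed."""


@dataclass(frozen=True)
class Compound:
    """A small molecule identified by id, carrying a parseable SMILES."""

    id: str
    smiles: str
    source: Source = Source.SYNTHETIC
    name: str | None = None

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise CompoundError(f"unparseable SMILES for compound {self.id!r}: {self.smiles!r}")
        return m


@dataclass(frozen=True)
class DescriptorSet:
    """Drug-likeness descriptors.

    ``hba``/``hbd`` use Lipinski's original definitions (N+O count and
    NH+OH count); ``logp`` is the Crippen atom-contribution estimate.
    """

    mw: float
    hbd: int
    hba: int
    logp: float
    rotatable_bonds: int
    heavy_atoms: int
    lipinski_violations: int
    logp_method: str = "crippen"

    def __post_init__(self) -> None:
        if self.mw < 0 or self.heavy_atoms < 1:
            raise ValueError("invalid descriptor values")


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary fingerprint (circular environments)."""

    bits: frozenset
    nbits: int
    radius: int

    def __post_init__(self) -> None:
        if any(b < 0 or b >= self.nbits for b in self.bits):
            raise ValueError("bit index out of range")

    @property
    def popcount(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class Scaffold:
    """Murcko framework (rings + linkers); empty for acyclic molecules."""

    smiles: str

    @property
    def is_empty(self) -> bool:
        return self.smiles == ""


def compute_descriptors(compound: Compound) -> DescriptorSet:
    """Compute the drug-likeness descriptor panel for one compound.

    The molecule is rebuilt from its canonical SMILES first so that
    atom-ordering-dependent float summation cannot leak into the values:
    any spelling of one molecule gives a bitwise-identical DescriptorSet.
    """
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(compound.mol()))
    mw = Descriptors.MolWt(mol)
    hbd = Lipinski.NHOHCount(mol)
    hba = Lipinski.NOCount(mol)
    logp = Crippen.MolLogP(mol)
    return DescriptorSet(
        mw=mw,
        hbd=hbd,
        hba=hba,
        logp=logp,
        rotatable_bonds=Lipinski.NumRotatableBonds(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        lipinski_violations=_rule_of_five_breaches(mw, logp, hbd, hba),
    )


def _rule_of_five_breaches(mw: float, logp: float, hbd: int, hba: int) -> int:
    return sum([mw > 500, logp > 5, hbd > 5, hba > 10])


def lipinski_violations(d: DescriptorSet) -> int:
    """Count of rule-of-five breaches (MW>500, LogP>5, HBD>5, HBA>10)."""
    return _rule_of_five_breaches(d.mw, d.logp, d.hbd, d.hba)


def morgan_fingerprint(
    compound: Compound, radius: int = DEFAULT_RADIUS, nbits: int = DEFAULT_NBITS
) -> Fingerprint:
    """Folded circular (Morgan) fingerprint; canonicalization-invariant."""
    mol = compound.mol()
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), nbits=nbits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B|.

    Two empty fingerprints compare as identical (1.0), preserving
    ``tanimoto(x, x) == 1`` for every x.
    """
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint length mismatch: {a.nbits} vs {b.nbits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def murcko_scaffold(compound: Compound) -> Scaffold:
    """Murcko framework of the molecule; empty scaffold when acyclic."""
    mol = compound.mol()
    core = MurckoScaffold.GetScaffoldForMol(mol)
    return Scaffold(smiles=Chem.MolToSmiles(core) if core.GetNumAtoms() else "")


@dataclass(frozen=True)
class PainsPattern:
    id: str
    smarts: str
    query: Chem.Mol = field(compare=False, repr=False, default=None)


@dataclass(frozen=True)
class PainsHit:
    compound: Compound
    pattern_id: str


def default_pains_path() -> Path:
    return Path(resources.files("hittriage").joinpath("data/pains.smarts"))


def load_pains_patterns(path: str | Path | None = None) -> list[PainsPattern]:
    """Load substructure alerts: one ``id<TAB>SMARTS`` per line, '#' comments.

    A pattern that fails to compile aborts loading and names the pattern.
    """
    path = Path(path) if path is not None else default_pains_path()
    patterns: list[PainsPattern] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            pid, smarts = line.split("\t", 1)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: expected 'id<TAB>SMARTS'") from exc
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise ValueError(f"{path}:{lineno}: malformed SMARTS for pattern {pid!r}")
        patterns.append(PainsPattern(id=pid, smarts=smarts, query=query))
    return patterns


def pains_filter(
    compounds: Sequence[Compound], patterns: Iterable[PainsPattern]
) -> tuple[list[Compound], list[PainsHit]]:
    """Partition compounds into (kept, flagged-with-pattern-id).

    The alert SMARTS use explicit hydrogens, so matching is done on the
    H-added graph. A compound matching several patterns is flagged once,
    with the first matching pattern id in file order.
    """
    patterns = list(patterns)
    kept: list[Compound] = []
    flagged: list[PainsHit] = []
    for c in compounds:
        mol = Chem.AddHs(c.mol())
        hit = next((p for p in patterns if mol.HasSubstructMatch(p.query)), None)
        if hit is None:
            kept.append(c)
        else:
            flagged.append(PainsHit(compound=c, pattern_id=hit.id))
    return kept, flagged
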