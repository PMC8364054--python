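"""Structure input, binding-site assembly, and dataset splitting.

Protein structures are read from PDB using the explicit element column
(columns 77-78); records without it are rejected rather than guessed from
atom names. Ligands are read from SDF/MOL2 (via RDKit) or PDB. Bond orders
and connectivity are ignored throughout: the downstream model consumes
only elements and coordinates.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Complex",
    "AtomicSystem",
    "SpeciesMap",
    "StructureError",
    "load_complex",
    "select_binding_site",
    "split_dataset",
    "read_manifest",
    "write_manifest",
]

#: Elements handled by dedicated atomic networks.
ORGANIC_ELEMENTS = ("H", "C", "O", "N", "S", "P", "F", "Cl", "Br", "I")

_WATER_RESNAMES = {"HOH", "WAT", "H2O", "DOD", "TIP3", "TIP", "SOL"}


class StructureError(ValueError):
    """Raised for unusable structure files or unsupported chemistry."""


@dataclass
class Atom:
    element: str
    coords: np.ndarray  # (3,) Angstrom
    role: str  # "ligand" | "protein" | "metal"
    residue_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("empty element symbol")
        self.element = self.element.strip().capitalize()
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be a finite 3-vector")
        if self.role not in ("ligand", "protein", "metal"):
            raise ValueError(f"bad role {self.role!r}")


@dataclass
class Complex:
    """One protein-ligand entry: atoms plus optional labels.

    ``pk_exp`` is the experimental affinity as pK = -log10(K / c0);
    ``baseline_score`` is an external docking score in kcal/mol.
    """

    id: str
    protein_atoms: list[Atom]
    ligand_atoms: list[Atom]
    pk_exp: Optional[float] = None
    baseline_score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.ligand_atoms:
            raise StructureError(f"complex {self.id!r}: empty ligand")


@dataclass
class AtomicSystem:
    """Mapped elements + coordinates of a binding site; model input."""

    elements: list[str]
    coords: np.ndarray  # (N, 3)
    ligand_mask: np.ndarray  # (N,) bool

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.ligand_mask = np.asarray(self.ligand_mask, dtype=bool)
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError("coords shape must be (N, 3) matching elements")
        if self.ligand_mask.shape != (n,):
            raise ValueError("ligand_mask length mismatch")
        if n and not self.ligand_mask.any():
            raise ValueError("system must contain at least one ligand atom")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicSystem":
        """Rigidly transformed copy (used by invariance checks and decoys)."""
        return AtomicSystem(
            list(self.elements),
            self.coords @ np.asarray(rotation).T + np.asarray(translation),
            self.ligand_mask.copy(),
        )


@dataclass(frozen=True)
class SpeciesMap:
    """Element -> species policy: canonical list, metal handling, hydrogens."""

    canonical_species: tuple[str, ...] = ORGANIC_ELEMENTS
    dummy_label: str = "X"
    metal_policy: str = "discard"  # "discard" | "map_to_dummy"
    keep_hydrogens: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "canonical_species", tuple(self.canonical_species))
        if len(set(self.canonical_species)) != len(self.canonical_species):
            raise ValueError("duplicate canonical species")
        if self.metal_policy not in ("discard", "map_to_dummy"):
            raise ValueError(f"bad metal_policy {self.metal_policy!r}")

    @property
    def model_species(self) -> tuple[str, ...]:
        """Species labels seen by the featurizer/model, in frozen order."""
        if self.metal_policy == "map_to_dummy":
            return self.canonical_species + (self.dummy_label,)
        return self.canonical_species

    def is_metal(self, element: str) -> bool:
        return element not in self.canonical_species and element not in ORGANIC_ELEMENTS


# ---------------------------------------------------------------------------
# Parsing


def _parse_pdb_atoms(path: Path, role: str) -> list[Atom]:
    """Fixed-column PDB ATOM/HETATM parsing; element column is mandatory."""
    atoms: list[Atom] = []
    n_water = 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec not in ("ATOM  ", "HETATM"):
                continue
            resname = line[17:20].strip()
            if resname in _WATER_RESNAMES:
                n_water += 1
                continue
            element = line[76:78].strip() if len(line) >= 77 else ""
            if not element or not element.isalpha():
                raise StructureError(
                    f"{path}: ATOM/HETATM record without element column "
                    f"(cols 77-78): {line.rstrip()!r}"
                )
            element = element.capitalize()
            try:
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except ValueError as exc:
                raise StructureError(f"{path}: bad coordinates: {line.rstrip()!r}") from exc
            chain = line[21].strip()
            resseq = line[22:27].strip()  # includes insertion code
            residue_id = f"{chain}:{resname}:{resseq}"
            atom_role = role
            if role == "protein" and element not in ORGANIC_ELEMENTS:
                atom_role = "metal"
            atoms.append(Atom(element, xyz, atom_role, residue_id))
    if n_water:
        logger.info("%s: removed %d water atoms", path, n_water)
    return atoms


def _parse_ligand_rdkit(path: Path) -> list[Atom]:
    from rdkit import Chem

    suffix = path.suffix.lower()
    if suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        mol = next(iter(supplier), None)
    elif suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=False)
    else:
        raise StructureError(f"{path}: unsupported ligand format {suffix!r}")
    if mol is None or mol.GetNumAtoms() == 0:
        raise StructureError(f"{path}: could not parse ligand (empty or malformed)")
    conf = mol.GetConformer()
    atoms = []
    for a in mol.GetAtoms():
        sym = a.GetSymbol()
        if not sym or sym == "*":
            raise StructureError(f"{path}: atom {a.GetIdx()} has no element symbol")
        pos = conf.GetAtomPosition(a.GetIdx())
        atoms.append(Atom(sym, [pos.x, pos.y, pos.z], "ligand"))
    return atoms


def load_complex(
    protein_path, ligand_path, *, id: Optional[str] = None,
    pk_exp: Optional[float] = None, baseline_score: Optional[float] = None,
) -> Complex:
    """Read a protein PDB and a ligand SDF/MOL2/PDB into a :class:`Complex`.

    Water molecules are always removed. Element symbols come exclusively
    from explicit element fields; files without them are rejected.
    """
    protein_path, ligand_path = Path(protein_path), Path(ligand_path)
    protein_atoms = _parse_pdb_atoms(protein_path, role="protein")
    if ligand_path.suffix.lower() == ".pdb":
        ligand_atoms = _parse_pdb_atoms(ligand_path, role="ligand")
        for a in ligand_atoms:
            a.role = "ligand"
            a.residue_id = None
    else:
        ligand_atoms = _parse_ligand_rdkit(ligand_path)
    if not ligand_atoms:
        raise StructureError(f"{ligand_path}: empty ligand")
    cid = id if id is not None else protein_path.stem
    return Complex(cid, protein_atoms, ligand_atoms, pk_exp, baseline_score)


# ---------------------------------------------------------------------------
# Binding-site selection


def select_binding_site(complex: Complex, d: float, species_map: SpeciesMap) -> AtomicSystem:
    """Assemble the model's input system from a complex.

    All ligand atoms are kept. A protein residue is kept iff any of its
    atoms lies within ``d`` (Angstrom) of any ligand atom; metals are kept
    or discarded per policy (a metal centre counts as its own residue).
    ``d = 0`` yields the ligand-only system. The distance test runs after
    the hydrogen policy is applied.
    """
    if d < 0:
        raise ValueError("d must be >= 0")

    def h_filter(atoms: Iterable[Atom]) -> list[Atom]:
        if species_map.keep_hydrogens:
            return list(atoms)
        return [a for a in atoms if a.element != "H"]

    ligand = h_filter(complex.ligand_atoms)
    if not ligand:
        raise StructureError(f"complex {complex.id!r}: no ligand atoms after hydrogen policy")
    protein = h_filter(complex.protein_atoms)

    for a in ligand + protein:
        if a.element == "Se":
            raise StructureError(
                f"complex {complex.id!r}: selenium-containing entry rejected"
            )

    lig_xyz = np.array([a.coords for a in ligand])

    kept: list[Atom] = []
    if protein and d > 0:
        residues: dict[str, list[Atom]] = {}
        for a in protein:
            residues.setdefault(a.residue_id or "?", []).append(a)
        for rid, atoms in residues.items():
            xyz = np.array([a.coords for a in atoms])
            dmin = np.min(
                np.linalg.norm(xyz[:, None, :] - lig_xyz[None, :, :], axis=-1)
            )
            if dmin <= d:
                kept.extend(atoms)

    elements, coords, mask = [], [], []
    n_discarded = 0
    for a in ligand + kept:
        el = a.element
        if species_map.is_metal(el):
            if species_map.metal_policy == "map_to_dummy":
                el = species_map.dummy_label
            else:
                n_discarded += 1
                continue
        elif el not in species_map.canonical_species:
            raise StructureError(
                f"complex {complex.id!r}: element {a.element!r} not in canonical "
                f"species {species_map.canonical_species}"
            )
        elements.append(el)
        coords.append(a.coords)
        mask.append(a.role == "ligand")
    if n_discarded:
        logger.info("complex %s: discarded %d metal atoms", complex.id, n_discarded)
    return AtomicSystem(elements, np.array(coords), np.array(mask))


# ---------------------------------------------------------------------------
# Dataset handling


def split_dataset(
    ids: Sequence[str], ratio: float, exclude_ids: Iterable[str] = (), seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Deterministic random train/validation partition after exclusions."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    excluded = set(exclude_ids)
    pool = [i for i in ids if i not in excluded]
    if len(pool) < 2:
        raise ValueError("fewer than 2 ids remain after exclusion")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    n_train = int(round(ratio * len(pool)))
    n_train = min(max(n_train, 1), len(pool) - 1)
    train = [pool[k] for k in sorted(order[:n_train])]
    val = [pool[k] for k in sorted(order[n_train:])]
    return train, val


_MANIFEST_COLUMNS = ["id", "protein_path", "ligand_path", "pk_exp", "baseline_score"]


def write_manifest(path, records: Sequence[dict]) -> None:
    """Write a dataset manifest CSV (id, paths, pk_exp, baseline_score)."""
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_MANIFEST_COLUMNS)
        w.writeheader()
        for rec in records:
            w.writerow({c: rec.get(c, "") for c in _MANIFEST_COLUMNS})


def read_manifest(path) -> list[dict]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rec = dict(row)
            for key in ("pk_exp", "baseline_score"):
                rec[key] = float(rec[key]) if rec.get(key) not in (None, "",) else None
            out.append(rec)
    if len({r["id"] for r in out}) != len(out):
        raise ValueError(f"{path}: duplicate ids in manifest")
    return out
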