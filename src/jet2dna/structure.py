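"""Structure model, PDB parsing and solvent accessibility.

The internal model is deliberately small: a :class:`Structure` holds chains of
:class:`Residue` objects, each a bag of heavy :class:`Atom` coordinates with
author numbering preserved. Parsing goes through Bio.PDB (first model only,
altloc resolved to highest occupancy, hydrogens and waters dropped); solvent
accessible surface areas are computed with biotite's Shrake-Rupley sampler and
converted to relative values (rASA, percent) against a shipped per-residue
reference table.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "AccessibilityRecord",
    "ResidueKey",
    "parse_structure",
    "compute_sasa",
    "surface_residues",
    "load_max_asa",
    "PDBFormatError",
]

#: (chain id, author residue number, insertion code) -- the identifier used
#: for residues everywhere in the package.
ResidueKey = Tuple[str, int, str]

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
# modified amino acids mapped to their parent residue
MODIFIED_PROTEIN = {"MSE": "MET", "SEC": "CYS", "PYL": "LYS"}
DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DU", "DI"}
RNA_RESIDUES = {"A", "C", "G", "U", "I"}
WATER_RESIDUES = {"HOH", "WAT", "DOD"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class PDBFormatError(ValueError):
    """Raised when PDB text cannot be parsed into a usable structure."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name: str
    atoms: List[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.icode)

    @property
    def molecule_class(self) -> str:
        name = self.name
        if name in PROTEIN_RESIDUES or name in MODIFIED_PROTEIN:
            return "protein"
        if name in DNA_RESIDUES:
            return "DNA"
        if name in RNA_RESIDUES:
            return "RNA"
        return "other"

    @property
    def standard_name(self) -> str:
        """Three-letter name with modified residues mapped to their parent."""
        return MODIFIED_PROTEIN.get(self.name, self.name)

    @property
    def one_letter(self) -> Optional[str]:
        return THREE_TO_ONE.get(self.standard_name)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class Structure:
    id: str
    chains: Dict[str, List[Residue]] = field(default_factory=dict)
    header: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            keys = [(r.number, r.icode) for r in residues]
            if len(keys) != len(set(keys)):
                raise ValueError(f"duplicate residue identifiers in chain {cid}")

    def residues(self, molecule_class: Optional[str] = None) -> List[Residue]:
        out: List[Residue] = []
        for residues in self.chains.values():
            for res in residues:
                if molecule_class is None or res.molecule_class == molecule_class:
                    out.append(res)
        return out

    def residue(self, key: ResidueKey) -> Residue:
        for res in self.chains[key[0]]:
            if res.number == key[1] and res.icode == key[2]:
                return res
        raise KeyError(key)

    def protein_chain_ids(self) -> Set[str]:
        return {
            cid for cid, residues in self.chains.items()
            if any(r.molecule_class == "protein" for r in residues)
        }

    def nucleic_chain_ids(self) -> Set[str]:
        return {
            cid for cid, residues in self.chains.items()
            if any(r.molecule_class in ("DNA", "RNA") for r in residues)
        }

    def subset(self, molecule_classes: Iterable[str], id_suffix: str = "") -> "Structure":
        """New structure keeping only residues of the given molecule classes."""
        wanted = set(molecule_classes)
        chains: Dict[str, List[Residue]] = {}
        for cid, residues in self.chains.items():
            kept = [r for r in residues if r.molecule_class in wanted]
            if kept:
                chains[cid] = kept
        return Structure(id=self.id + id_suffix, chains=chains, header=dict(self.header))

    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


@dataclass
class AccessibilityRecord:
    """Per-residue absolute (A^2) and relative (percent) accessible area."""

    area: float
    rasa: Optional[float]  # None when the residue type has no reference area
    context: str = "free"

    def __post_init__(self) -> None:
        if self.rasa is not None and self.rasa < 0:
            raise ValueError("rASA must be non-negative")


def load_max_asa(path: Optional[str] = None) -> Dict[str, float]:
    """Load the per-residue reference maximum ASA table (three-letter -> A^2)."""
    if path is None:
        text = (
            resources.files("jet2dna.data")
            .joinpath("max_asa_tien2013.tsv")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    table: Dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed reference-area line {lineno}: {line!r}")
        table[parts[0].upper()] = float(parts[1])
    return table


def parse_structure(pdb_text: str, structure_id: str = "structure") -> Structure:
    """Parse PDB-format text into the internal model.

    First model only; hydrogens, deuteriums and waters are excluded; altlocs
    resolve to the highest-occupancy conformer (ties: first in file).
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    if not any(line.startswith(("ATOM", "HETATM")) for line in pdb_text.splitlines()):
        raise PDBFormatError("no ATOM/HETATM records found")

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_struct = parser.get_structure(structure_id, io.StringIO(pdb_text))
    except PDBConstructionException as exc:
        raise PDBFormatError(f"unparseable PDB record: {exc}") from exc

    try:
        model = next(bio_struct.get_models())
    except StopIteration:  # pragma: no cover - guarded by the record check above
        raise PDBFormatError("structure contains no model")

    chains: Dict[str, List[Residue]] = {}
    for bio_chain in model:
        residues: List[Residue] = []
        for bio_res in bio_chain:
            resname = bio_res.get_resname().strip()
            if resname in WATER_RESIDUES or bio_res.id[0] == "W":
                continue
            atoms: List[Atom] = []
            for bio_atom in bio_res.get_atoms():
                # DisorderedAtom iteration yields the selected (highest
                # occupancy, first-in-file on ties) conformer only.
                element = (bio_atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                atoms.append(
                    Atom(
                        name=bio_atom.get_name().strip(),
                        element=element or bio_atom.get_name()[0].upper(),
                        coord=np.asarray(bio_atom.get_coord(), dtype=float),
                        occupancy=float(bio_atom.get_occupancy() or 1.0),
                        altloc=bio_atom.get_altloc().strip(),
                    )
                )
            if not atoms:
                continue
            hetflag, number, icode = bio_res.id
            residues.append(
                Residue(
                    chain_id=bio_chain.id,
                    number=int(number),
                    icode=icode.strip(),
                    name=resname,
                    atoms=atoms,
                )
            )
        if residues:
            chains[bio_chain.id] = residues

    if not chains:
        raise PDBFormatError("structure is empty after filtering")
    return Structure(id=structure_id, chains=chains)


def _build_atom_array(structure: Structure):
    import biotite.structure as bst

    records = []
    for res in structure.residues():
        for atom in res.atoms:
            records.append((res, atom))
    n = len(records)
    array = bst.AtomArray(n)
    array.coord = np.array([a.coord for _, a in records], dtype=np.float32)
    array.chain_id = np.array([r.chain_id for r, _ in records])
    array.res_id = np.array([r.number for r, _ in records])
    array.ins_code = np.array([r.icode for r, _ in records])
    array.res_name = np.array([r.name for r, _ in records])
    array.atom_name = np.array([a.name for _, a in records])
    array.element = np.array([a.element for _, a in records])
    keys = [r.key for r, _ in records]
    return array, keys


def compute_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    max_asa: Optional[Dict[str, float]] = None,
    point_number: int = 500,
    context: str = "free",
) -> Dict[ResidueKey, AccessibilityRecord]:
    """Shrake-Rupley accessible surface area per residue.

    Per-atom areas are sampled with ``point_number`` Fibonacci sphere points
    (biotite engine, element-based vdW radii) and summed per residue; rASA is
    100 x area / reference-max-area for the residue type. Residues without a
    reference entry get ``rasa=None`` and are excluded from surface sets.
    """
    import biotite.structure as bst

    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if structure.atom_count() < 2:
        raise ValueError("structure must contain at least 2 atoms")
    if max_asa is None:
        max_asa = load_max_asa()

    array, keys = _build_atom_array(structure)
    atom_sasa = bst.sasa(
        array,
        probe_radius=probe_radius,
        vdw_radii="Single",
        point_number=point_number,
    )
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)

    per_residue: Dict[ResidueKey, float] = {}
    for key, area in zip(keys, atom_sasa):
        per_residue[key] = per_residue.get(key, 0.0) + float(area)

    out: Dict[ResidueKey, AccessibilityRecord] = {}
    for res in structure.residues():
        area = per_residue.get(res.key, 0.0)
        ref = max_asa.get(res.standard_name)
        rasa = 100.0 * area / ref if ref else None
        out[res.key] = AccessibilityRecord(area=area, rasa=rasa, context=context)
    return out


def surface_residues(
    accessibility: Dict[ResidueKey, AccessibilityRecord],
    threshold: float = 5.0,
) -> Set[ResidueKey]:
    """Residues with rASA >= threshold percent (inclusive); undefined rASA excluded."""
    return {
        key
        for key, rec in accessibility.items()
        if rec.rasa is not None and rec.rasa >= threshold
    }
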