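"""Experimental protein-nucleic-acid interfaces and the support-core-rim model.

Interface residues of a bound complex are those losing accessible area when
the nucleic partner is present (delta-rASA = rasa_free - rasa_DNA > 0). Each
one falls in exactly one structural class against the 25% rASA thresholds:

* *support* -- buried with and without DNA (rasa_free < 25, rasa_DNA < 25);
* *core*    -- exposed when free, buried on binding (rasa_free >= 25, rasa_DNA < 25);
* *rim*     -- exposed in both states (rasa_free >= 25, rasa_DNA >= 25).

The fourth quadrant (buried free, exposed bound) is impossible for a residue
that loses area and raises a consistency error. Atomic contacts (< 5 A) are
partitioned into DNA backbone (phosphate + sugar atoms, C1' included by the
phosphodiester convention) versus base atoms. RNA chains are treated exactly
like DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structure import (
    ResidueKey,
    Structure,
    compute_sasa,
)

__all__ = [
    "BACKBONE_ATOMS",
    "Contact",
    "ReferenceInterface",
    "interface_residues",
    "classify_scr",
    "atomic_contacts",
    "scr_contact_profile",
    "extract_reference_interface",
]

#: Nucleic-acid atoms counted as backbone: phosphate group plus the sugar
#: ring. C1' bonds the base but belongs to the sugar by convention.
BACKBONE_ATOMS = {
    "P", "OP1", "OP2", "OP3",
    "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'",
}

#: delta-rASA below this many percent-points is treated as sampling noise.
DELTA_RASA_TOLERANCE = 1e-3

SCR_THRESHOLD = 25.0


@dataclass
class Contact:
    protein_residue: ResidueKey
    nucleic_residue: ResidueKey
    protein_atom: str
    nucleic_atom: str
    distance: float
    dna_part: str  # "backbone" | "base"


@dataclass
class ReferenceInterface:
    """Interface residues with SCR labels, rASA bookkeeping and contacts."""

    residues: Set[ResidueKey]
    scr_labels: Dict[ResidueKey, str]
    rasa_free: Dict[ResidueKey, float]
    rasa_dna: Dict[ResidueKey, float]
    contacts: List[Contact] = field(default_factory=list)

    def delta_rasa(self, key: ResidueKey) -> float:
        return self.rasa_free[key] - self.rasa_dna[key]


def interface_residues(
    bound: Structure,
    probe_radius: float = 1.4,
    point_number: int = 500,
) -> Tuple[Set[ResidueKey], Dict[ResidueKey, float], Dict[ResidueKey, float]]:
    """Protein residues buried by the nucleic partner (delta-rASA > 0).

    rASA is computed twice: in the full complex context (``rasa_DNA``) and
    after deleting all nucleic atoms (``rasa_free``). Differences below the
    sampling-noise tolerance are discarded. Returns the interface set plus
    both rASA maps for all protein residues.
    """
    if not bound.protein_chain_ids():
        raise ValueError("bound structure has no protein chain")
    if not bound.nucleic_chain_ids():
        raise ValueError("bound structure has no nucleic chain")

    complex_struct = bound.subset(["protein", "DNA", "RNA"])
    free_struct = bound.subset(["protein"], id_suffix="_free")

    acc_complex = compute_sasa(
        complex_struct, probe_radius, point_number=point_number, context="complex"
    )
    acc_free = compute_sasa(
        free_struct, probe_radius, point_number=point_number, context="free"
    )

    rasa_dna: Dict[ResidueKey, float] = {}
    rasa_free: Dict[ResidueKey, float] = {}
    interface: Set[ResidueKey] = set()
    for res in free_struct.residues("protein"):
        rec_free = acc_free[res.key]
        rec_complex = acc_complex[res.key]
        if rec_free.rasa is None or rec_complex.rasa is None:
            continue
        rasa_free[res.key] = rec_free.rasa
        rasa_dna[res.key] = rec_complex.rasa
        if rec_free.rasa - rec_complex.rasa > DELTA_RASA_TOLERANCE:
            interface.add(res.key)
    return interface, rasa_free, rasa_dna


def classify_scr(rasa_free: float, rasa_dna: float) -> str:
    """Support / core / rim label from the two rASA values (thresholds at 25%)."""
    free_buried = rasa_free < SCR_THRESHOLD
    dna_buried = rasa_dna < SCR_THRESHOLD
    if free_buried and dna_buried:
        return "support"
    if not free_buried and dna_buried:
        return "core"
    if not free_buried and not dna_buried:
        return "rim"
    raise ValueError(
        f"inconsistent interface residue: rasa_free={rasa_free} < 25 but "
        f"rasa_DNA={rasa_dna} >= 25 (cannot lose area and gain exposure)"
    )


def atomic_contacts(
    structure: Structure,
    cutoff: float = 5.0,
    protein_keys: Optional[Set[ResidueKey]] = None,
) -> List[Contact]:
    """All protein-atom / nucleic-atom pairs strictly closer than ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    prot_coords, prot_meta = [], []
    for res in structure.residues("protein"):
        if protein_keys is not None and res.key not in protein_keys:
            continue
        for atom in res.atoms:
            prot_coords.append(atom.coord)
            prot_meta.append((res.key, atom.name))
    nuc_coords, nuc_meta = [], []
    for mol in ("DNA", "RNA"):
        for res in structure.residues(mol):
            for atom in res.atoms:
                nuc_coords.append(atom.coord)
                nuc_meta.append((res.key, atom.name))
    if not prot_coords or not nuc_coords:
        return []

    prot_tree = cKDTree(np.asarray(prot_coords))
    nuc_tree = cKDTree(np.asarray(nuc_coords))
    contacts: List[Contact] = []
    for pi, neighbors in enumerate(prot_tree.query_ball_tree(nuc_tree, cutoff)):
        for ni in neighbors:
            dist = float(
                np.linalg.norm(np.asarray(prot_coords[pi]) - np.asarray(nuc_coords[ni]))
            )
            if dist >= cutoff:  # strict < cutoff
                continue
            pkey, pname = prot_meta[pi]
            nkey, nname = nuc_meta[ni]
            part = "backbone" if nname in BACKBONE_ATOMS else "base"
            contacts.append(
                Contact(
                    protein_residue=pkey,
                    nucleic_residue=nkey,
                    protein_atom=pname,
                    nucleic_atom=nname,
                    distance=dist,
                    dna_part=part,
                )
            )
    contacts.sort(key=lambda c: (c.protein_residue, c.nucleic_residue, c.distance))
    return contacts


def scr_contact_profile(reference: ReferenceInterface) -> Dict[str, Dict[str, float]]:
    """Per-SCR-class residue counts, contact counts and backbone/base split."""
    profile: Dict[str, Dict[str, float]] = {}
    for cls in ("support", "core", "rim"):
        keys = {k for k, v in reference.scr_labels.items() if v == cls}
        cls_contacts = [c for c in reference.contacts if c.protein_residue in keys]
        backbone = sum(1 for c in cls_contacts if c.dna_part == "backbone")
        base = len(cls_contacts) - backbone
        profile[cls] = {
            "residues": len(keys),
            "contacts": len(cls_contacts),
            "contacts_per_residue": len(cls_contacts) / len(keys) if keys else 0.0,
            "backbone_fraction": backbone / len(cls_contacts) if cls_contacts else 0.0,
            "base_fraction": base / len(cls_contacts) if cls_contacts else 0.0,
        }
    profile["total_contacts"] = sum(profile[c]["contacts"] for c in ("support", "core", "rim"))
    return profile


def extract_reference_interface(
    bound: Structure,
    probe_radius: float = 1.4,
    contact_cutoff: float = 5.0,
    point_number: int = 500,
) -> ReferenceInterface:
    """Full reference extraction: interface set, SCR labels and contacts."""
    interface, rasa_free, rasa_dna = interface_residues(
        bound, probe_radius, point_number=point_number
    )
    labels = {
        key: classify_scr(rasa_free[key], rasa_dna[key]) for key in sorted(interface)
    }
    contacts = atomic_contacts(bound, contact_cutoff)
    return ReferenceInterface(
        residues=interface,
        scr_labels=labels,
        rasa_free={k: rasa_free[k] for k in interface},
        rasa_dna={k: rasa_dna[k] for k in interface},
        contacts=contacts,
    )
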