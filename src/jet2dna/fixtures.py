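"""Seeded synthetic inputs: pseudo-proteins, bound pairs and alignments.

Every generator is deterministic given its seed and emits machine-readable
truth next to the data, so each stage of the predictor can be tested closed
loop without external downloads:

* ``make_pseudo_protein`` -- residues realised as small rigid atom clusters on
  a spherical shell (optionally with buried interior residues, a planted
  high-signal surface patch, a deep conserved pocket, or a concave funnel
  whose lining is globally buried);
* ``make_bound_pair`` -- the same protein with a pseudo-DNA duplex hovering
  over the planted patch, so interface extraction has a known answer;
* ``make_alignment`` -- an alignment evolved over a random tree with chosen
  conserved columns, for the conservation descriptor.

The pseudo-residues carry real amino-acid names so the propensity scale
applies: planted patches are arginine/lysine-rich (DNA interfaces are
enriched in positively charged and polar residues), concave-funnel linings
use mid-propensity polar types, and the background is hydrophobic/acidic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .structure import ResidueKey

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "make_pseudo_protein",
    "make_bound_pair",
    "make_alignment",
    "write_fasta",
]

PATCH_TYPES = ("ARG", "LYS")  # scaled PC_DNA 1.0 / 0.90
CLEFT_TYPES = ("SER", "THR", "ASN", "HIS")  # scaled PC_DNA ~ 0.5
BACKGROUND_TYPES = ("LEU", "VAL", "ILE", "PHE", "ALA", "MET", "GLU", "ASP")

# compact rigid body of 5 heavy atoms per pseudo-residue (local frame, A)
_RESIDUE_OFFSETS = (
    ("N", "N", (1.40, 0.20, 0.10)),
    ("CA", "C", (0.00, 0.00, 0.00)),
    ("C", "C", (-0.75, 1.20, 0.15)),
    ("O", "O", (-1.90, 1.30, 0.45)),
    ("CB", "C", (0.10, -0.90, 1.20)),
)

_NUCLEOTIDE_OFFSETS = (
    # backbone (phosphate + sugar), local z points away from the protein
    ("P", "P", (0.0, 0.0, 2.2)),
    ("OP1", "O", (1.2, 0.0, 2.8)),
    ("OP2", "O", (-1.2, 0.0, 2.8)),
    ("O5'", "O", (0.0, 1.2, 2.0)),
    ("C5'", "C", (0.8, -0.8, 1.6)),
    ("C4'", "C", (0.0, -1.2, 1.2)),
    ("O4'", "O", (1.0, 0.8, 1.0)),
    ("C3'", "C", (-1.0, 0.6, 1.0)),
    ("O3'", "O", (-0.6, -1.2, 1.4)),
    ("C2'", "C", (0.8, -0.2, 0.6)),
    ("C1'", "C", (0.0, 0.6, 0.4)),
    # base atoms, facing the protein
    ("N1", "N", (0.0, 0.0, -0.6)),
    ("C2", "C", (1.1, 0.0, -1.0)),
    ("N3", "N", (0.9, 1.1, -1.4)),
    ("C4", "C", (-0.4, 0.9, -1.2)),
)


@dataclass
class FixtureSpec:
    seed: int
    n_residues: int = 150
    geometry: str = "sphere"  # sphere | helix-bundle | concave-envelope
    # center spacing chosen so geometric neighbors fall reliably within the
    # 5 A heavy-atom contact cutoff, as neighboring residues do on real
    # protein surfaces
    spacing: float = 4.5
    n_buried: int = 0
    patch_size: int = 12
    contrast: float = 0.4
    background_t_jet: Tuple[float, float] = (0.10, 0.45)
    pocket: bool = False
    pocket_size: int = 6
    cleft_half_angle: float = 0.8  # radians, concave-envelope only
    cleft_depth_frac: float = 0.9
    dna_length: int = 9
    dna_height: float = 3.8

    def __post_init__(self) -> None:
        if self.n_residues < 20:
            raise ValueError("need at least 20 residues")
        if self.geometry not in ("sphere", "helix-bundle", "concave-envelope"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.n_buried >= self.n_residues:
            raise ValueError("n_buried must leave surface residues")


@dataclass
class FixtureTruth:
    """Machine-readable construction truth emitted with every fixture."""

    planted: List[ResidueKey] = field(default_factory=list)
    pocket: List[ResidueKey] = field(default_factory=list)
    buried: List[ResidueKey] = field(default_factory=list)
    cleft: List[ResidueKey] = field(default_factory=list)
    conservation: Dict[ResidueKey, float] = field(default_factory=dict)

    def conservation_tsv(self) -> str:
        lines = ["# chain\tresnum\tscore"]
        for (chain, num, icode), score in sorted(self.conservation.items()):
            lines.append(f"{chain}\t{num}{icode}\t{score:.6f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# geometry helpers


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistant unit vectors."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _frame_along(direction: np.ndarray) -> np.ndarray:
    """Orthonormal frame whose third column is the given unit direction."""
    z = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(z @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    x = np.cross(helper, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def _residue_atoms(
    center: np.ndarray, frame: np.ndarray
) -> List[Tuple[str, str, np.ndarray]]:
    return [
        (name, element, center + frame @ np.asarray(offset))
        for name, element, offset in _RESIDUE_OFFSETS
    ]


# ---------------------------------------------------------------------------
# PDB emission


def _pdb_atom_line(
    serial: int, name: str, resname: str, chain: str, resnum: int,
    coord: np.ndarray, element: str, record: str = "ATOM",
) -> str:
    name_field = name if len(name) == 4 else f" {name:<3}"
    return (
        f"{record:<6}{serial:5d} {name_field} {resname:>3} {chain}{resnum:4d}    "
        f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )


def _emit_pdb(
    residues: Sequence[Tuple[str, str, int, List[Tuple[str, str, np.ndarray]]]]
) -> str:
    """residues: (resname, chain, resnum, atoms); atoms: (name, element, coord)."""
    lines: List[str] = []
    serial = 1
    last_chain: Optional[str] = None
    for resname, chain, resnum, atoms in residues:
        if last_chain is not None and chain != last_chain:
            lines.append("TER")
        last_chain = chain
        for name, element, coord in atoms:
            lines.append(
                _pdb_atom_line(serial, name, resname, chain, resnum, coord, element)
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pseudo-protein generator


def _sphere_layout(spec: FixtureSpec, rng: np.random.Generator):
    """Residue centers/directions for the sphere geometries."""
    n_surface = spec.n_residues - spec.n_buried
    radius = spec.spacing * np.sqrt(n_surface / (4.0 * np.pi))
    rotation = _random_rotation(rng)
    directions = _fibonacci_sphere(n_surface) @ rotation.T
    centers = directions * radius
    return radius, directions, centers


def _buried_centers(spec: FixtureSpec, radius: float) -> np.ndarray:
    """Interior residues packed on concentric shells (tight enough to bury)."""
    remaining = spec.n_buried
    centers: List[np.ndarray] = []
    shell_r = radius - 4.0
    while remaining > 0 and shell_r > 1.0:
        capacity = max(1, int(4.0 * np.pi * shell_r**2 / 16.0))
        take = min(remaining, capacity)
        centers.append(_fibonacci_sphere(take) * shell_r)
        remaining -= take
        shell_r -= 4.0
    if remaining > 0:
        centers.append(np.zeros((remaining, 3)))
    return np.concatenate(centers) if centers else np.zeros((0, 3))


def make_pseudo_protein(spec: FixtureSpec) -> Tuple[str, FixtureTruth]:
    """Generate a pseudo-protein as PDB text plus its construction truth."""
    rng = np.random.default_rng(spec.seed)
    truth = FixtureTruth()
    residues: List[Tuple[str, str, int, List]] = []

    if spec.geometry == "helix-bundle":
        _build_helix_bundle(spec, rng, residues, truth)
    elif spec.geometry == "concave-envelope":
        _build_concave_envelope(spec, rng, residues, truth)
    else:
        _build_sphere(spec, rng, residues, truth)

    return _emit_pdb(residues), truth


def _assign_t_jet(
    rng: np.random.Generator, spec: FixtureSpec, elevated: bool
) -> float:
    low, high = spec.background_t_jet
    if elevated:
        floor = high + spec.contrast
        return float(rng.uniform(floor, min(floor + 0.1, 1.0)))
    return float(rng.uniform(low, high))


def _build_sphere(spec, rng, residues, truth) -> None:
    radius, directions, centers = _sphere_layout(spec, rng)

    # planted patch: the patch_size surface residues nearest a random direction
    patch_dir = directions[int(rng.integers(len(directions)))]
    order = np.argsort(-directions @ patch_dir)
    plant = set(order[: spec.patch_size].tolist())

    pocket_keys: List[ResidueKey] = []
    pocket_atoms: List[Tuple[str, str, int, List]] = []
    hole: Set[int] = set()
    if spec.pocket:
        pocket_dir = -patch_dir  # far side of the sphere
        hole = set(np.where(directions @ pocket_dir > np.cos(0.65))[0].tolist())
        plant -= hole

    resnum = 0
    for i, center in enumerate(centers):
        if i in hole:
            continue
        resnum += 1
        is_plant = i in plant
        name = (
            PATCH_TYPES[resnum % len(PATCH_TYPES)]
            if is_plant
            else BACKGROUND_TYPES[resnum % len(BACKGROUND_TYPES)]
        )
        frame = _frame_along(directions[i])
        atoms = _residue_atoms(center, frame)
        residues.append((name, "A", resnum, atoms))
        key = ("A", resnum, "")
        truth.conservation[key] = _assign_t_jet(rng, spec, is_plant)
        if is_plant:
            truth.planted.append(key)

    if spec.pocket:
        resnum = _build_pocket(spec, rng, residues, truth, radius,
                               -patch_dir, resnum)

    for center in _buried_centers(spec, radius):
        resnum += 1
        frame = _frame_along(center if np.linalg.norm(center) > 0 else np.array([0, 0, 1.0]))
        residues.append(
            (BACKGROUND_TYPES[resnum % len(BACKGROUND_TYPES)], "A", resnum,
             _residue_atoms(center, frame))
        )
        key = ("A", resnum, "")
        truth.conservation[key] = _assign_t_jet(rng, spec, False)
        truth.buried.append(key)


def _build_pocket(spec, rng, residues, truth, radius, pocket_dir, resnum) -> int:
    """A deep, conserved, high-propensity pocket buried in a solid blob.

    Pocket residues (single heavy atoms, so they fit the cavity) sit on a
    small ring inside a spherical void carved out of a dense atom grid; a
    narrow mouth channel connects the void to the protein surface. The grid
    encloses the pocket residues almost isotropically (CV_local > 0.9) while
    the void is wide enough for the 1.4 A solvent probe, keeping them on the
    accessible surface.
    """
    cavity_center = pocket_dir * 7.0
    void_radius = 7.2
    blob_radius = 10.5
    mouth_radius = 3.0
    grid_step = 2.2

    # conserved pocket residues on a ring at the cavity floor
    frame = _frame_along(pocket_dir)
    for j in range(spec.pocket_size):
        angle = 2.0 * np.pi * j / spec.pocket_size
        local = np.array([3.6 * np.cos(angle), 3.6 * np.sin(angle), 0.0])
        center = cavity_center + frame @ local
        resnum += 1
        name = PATCH_TYPES[j % len(PATCH_TYPES)]
        residues.append((name, "A", resnum, [("CB", "C", center)]))
        key = ("A", resnum, "")
        floor = spec.background_t_jet[1] + spec.contrast
        truth.conservation[key] = float(rng.uniform(min(floor + 0.08, 0.97), 0.99))
        truth.pocket.append(key)

    # dense filler grid: solid blob minus the void and the mouth channel
    span = np.arange(-blob_radius, blob_radius + grid_step / 2, grid_step)
    for x in span:
        for y in span:
            for z in span:
                point = np.array([x, y, z])
                r = np.linalg.norm(point)
                if r > blob_radius or r <= void_radius:
                    continue
                # mouth channel: a cylinder along the pocket axis, outward
                axial = point @ pocket_dir
                lateral = np.linalg.norm(point - axial * pocket_dir)
                if axial > 0 and lateral < mouth_radius:
                    continue
                resnum += 1
                residues.append(
                    ("GLY", "A", resnum, [("CA", "C", cavity_center + point)])
                )
                truth.conservation[("A", resnum, "")] = _assign_t_jet(rng, spec, False)
    return resnum


def _build_concave_envelope(spec, rng, residues, truth) -> None:
    """Sphere with a deep conical funnel; the funnel lining is the plant."""
    radius, directions, _ = _sphere_layout(spec, rng)
    rotation = _random_rotation(rng)
    axis = rotation @ np.array([0.0, 0.0, 1.0])
    depth = spec.cleft_depth_frac * radius

    resnum = 0
    for direction in directions:
        resnum += 1
        angle = float(np.arccos(np.clip(direction @ axis, -1.0, 1.0)))
        in_cleft = angle < spec.cleft_half_angle
        # quadratic funnel profile: the lining plunges quickly, so the
        # conserved deep lining sits well inside the globally concave region
        pull = (
            depth * (1.0 - (angle / spec.cleft_half_angle) ** 2)
            if in_cleft else 0.0
        )
        deep = in_cleft and pull > 0.7 * depth
        center = direction * (radius - pull)
        name = (
            CLEFT_TYPES[resnum % len(CLEFT_TYPES)]
            if deep
            else BACKGROUND_TYPES[resnum % len(BACKGROUND_TYPES)]
        )
        residues.append((name, "A", resnum, _residue_atoms(center, _frame_along(direction))))
        key = ("A", resnum, "")
        truth.conservation[key] = _assign_t_jet(rng, spec, deep)
        if in_cleft:
            truth.cleft.append(key)
        if deep:
            truth.planted.append(key)


def _build_helix_bundle(spec, rng, residues, truth) -> None:
    """Four parallel idealised helices; a mid-bundle window is the plant."""
    per_helix = spec.n_residues // 4
    offsets = [(-5.5, -5.5), (-5.5, 5.5), (5.5, -5.5), (5.5, 5.5)]
    resnum = 0
    plant_lo = per_helix // 2 - spec.patch_size // 8
    plant_hi = plant_lo + max(1, spec.patch_size // 4)
    for hx, (ox, oy) in enumerate(offsets):
        for i in range(per_helix):
            resnum += 1
            theta = np.deg2rad(100.0 * i)
            center = np.array(
                [ox + 2.3 * np.cos(theta), oy + 2.3 * np.sin(theta), 1.5 * i]
            )
            outward = np.array([np.cos(theta), np.sin(theta), 0.0])
            is_plant = hx < 2 and plant_lo <= i < plant_hi
            name = (
                PATCH_TYPES[resnum % len(PATCH_TYPES)]
                if is_plant
                else BACKGROUND_TYPES[resnum % len(BACKGROUND_TYPES)]
            )
            residues.append((name, "A", resnum, _residue_atoms(center, _frame_along(outward))))
            key = ("A", resnum, "")
            truth.conservation[key] = _assign_t_jet(rng, spec, is_plant)
            if is_plant:
                truth.planted.append(key)
    # remainder residues extend the last helix
    for i in range(spec.n_residues - 4 * per_helix):
        resnum += 1
        theta = np.deg2rad(100.0 * (per_helix + i))
        center = np.array(
            [5.5 + 2.3 * np.cos(theta), 5.5 + 2.3 * np.sin(theta), 1.5 * (per_helix + i)]
        )
        residues.append(
            (BACKGROUND_TYPES[resnum % len(BACKGROUND_TYPES)], "A", resnum,
             _residue_atoms(center, _frame_along(np.array([np.cos(theta), np.sin(theta), 0.0]))))
        )
        truth.conservation[("A", resnum, "")] = _assign_t_jet(rng, spec, False)


# ---------------------------------------------------------------------------
# bound pair


def make_bound_pair(spec: FixtureSpec) -> Tuple[str, str, FixtureTruth]:
    """Bound (with pseudo-DNA duplex over the plant) and free PDB texts.

    The duplex hovers ``dna_height`` A above the planted cap with base atoms
    facing the protein, so the planted residues lose accessible area in the
    bound context while the far side of the sphere is untouched.
    """
    rng = np.random.default_rng(spec.seed)
    truth = FixtureTruth()
    residues: List[Tuple[str, str, int, List]] = []
    _build_sphere(spec, rng, residues, truth)
    free_pdb = _emit_pdb(residues)

    radius = spec.spacing * np.sqrt(
        (spec.n_residues - spec.n_buried) / (4.0 * np.pi)
    )
    index = {("A", num, ""): atoms for _, _, num, atoms in residues}
    planted_centers = [
        np.mean([a[2] for a in index[key]], axis=0) for key in truth.planted
    ]
    cap_center = np.mean(planted_centers, axis=0)
    u = cap_center / np.linalg.norm(cap_center)
    frame = _frame_along(u)
    t1, t2 = frame[:, 0], frame[:, 1]

    cap_extent = max(
        float(np.linalg.norm(c - cap_center)) for c in planted_centers
    )
    half_len = max(cap_extent, 3.0)
    strand_frame = np.column_stack([t1, t2, u])  # local z points outward

    dna: List[Tuple[str, str, int, List]] = []
    names = ("DA", "DT")
    for strand, (chain, side) in enumerate((("B", -1.0), ("C", 1.0))):
        for i in range(spec.dna_length):
            s = -half_len + 2.0 * half_len * i / max(1, spec.dna_length - 1)
            base_point = (
                u * (radius + spec.dna_height) + t1 * s + t2 * (side * 2.6)
            )
            atoms = [
                (name, element, base_point + strand_frame @ np.asarray(offset))
                for name, element, offset in _NUCLEOTIDE_OFFSETS
            ]
            dna.append((names[i % 2], chain, i + 1, atoms))

    bound_pdb = _emit_pdb(list(residues) + dna)
    return bound_pdb, free_pdb, truth


# ---------------------------------------------------------------------------
# alignment generator


def _random_tree(names: List[str], rng: np.random.Generator):
    from Bio.Phylo.BaseTree import Clade, Tree

    def split(group: List[str]) -> "Clade":
        if len(group) == 1:
            return Clade(name=group[0], branch_length=float(rng.uniform(0.05, 0.3)))
        cut = int(rng.integers(1, len(group)))
        clade = Clade(branch_length=float(rng.uniform(0.05, 0.3)))
        clade.clades = [split(group[:cut]), split(group[cut:])]
        return clade

    shuffled = list(names)
    rng.shuffle(shuffled)
    root = split(shuffled)
    root.branch_length = None
    return Tree(root=root, rooted=True)


AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def make_alignment(
    n_sequences: int,
    length: int,
    conserved_columns,
    noise: float,
    seed: int,
):
    """Alignment + tree + per-column truth, evolved along a random tree.

    Conserved columns are identical in every sequence; the others mutate with
    probability ``noise`` per branch. Returns (MultipleSeqAlignment, Bio.Phylo
    tree, truth dict with the conserved column indices and per-column
    conservation fractions).
    """
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if n_sequences < 3:
        raise ValueError("need at least 3 sequences")
    rng = np.random.default_rng(seed)
    names = ["query"] + [f"s{i:03d}" for i in range(1, n_sequences)]
    tree = _random_tree(names, rng)

    if isinstance(conserved_columns, int):
        if not 0 <= conserved_columns <= length:
            raise ValueError("conserved_columns out of range")
        conserved = set(
            rng.choice(length, size=conserved_columns, replace=False).tolist()
        )
    else:
        conserved = {int(c) for c in conserved_columns}
        if conserved and (min(conserved) < 0 or max(conserved) >= length):
            raise ValueError("conserved column index out of range")
    root_seq = [AA_ALPHABET[int(i)] for i in rng.integers(0, 20, size=length)]

    sequences: Dict[str, List[str]] = {}

    def evolve(clade, seq: List[str]) -> None:
        seq = list(seq)
        for col in range(length):
            if col in conserved:
                continue
            if rng.random() < noise:
                current = seq[col]
                choices = AA_ALPHABET.replace(current, "")
                seq[col] = choices[int(rng.integers(len(choices)))]
        if clade.name:
            sequences[clade.name] = seq
        for child in clade.clades:
            evolve(child, seq)

    for child in tree.root.clades:
        evolve(child, root_seq)
    if "query" not in sequences:  # root itself may carry a name
        sequences["query"] = root_seq

    records = [
        SeqRecord(Seq("".join(sequences[name])), id=name, description="")
        for name in names
    ]
    alignment = MultipleSeqAlignment(records)

    query = sequences["query"]
    truth = {
        "conserved_columns": sorted(conserved),
        "conservation_fraction": [
            float(np.mean([sequences[n][c] == query[c] for n in names]))
            for c in range(length)
        ],
    }
    return alignment, tree, truth


def write_fasta(alignment) -> str:
    lines = []
    for record in alignment:
        lines.append(f">{record.id}")
        lines.append(str(record.seq))
    return "\n".join(lines) + "\n"
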