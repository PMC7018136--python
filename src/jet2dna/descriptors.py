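"""Per-residue descriptors: circular variance, DNA-interface propensity,
evolutionary conservation.

Four signals drive the predictor, each scaled to [0, 1]:

* ``CV_local`` / ``CV_global`` -- circular variance of the atomic environment
  within r_c = 12 A (local shape: ~0 protruding, ~1 buried) and r_c = 100 A
  (position relative to the whole protein: high values mark globally concave
  regions).
* ``PC_DNA`` -- per-amino-acid propensity to occur at protein-DNA interfaces,
  scaled by its maximum.
* ``T_JET`` -- evolutionary conservation, either read from a per-residue score
  file or computed as tree traces averaged over phylogenetic trees built from
  subsampled alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structure import ResidueKey, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "CV_LOCAL_RADIUS",
    "CV_GLOBAL_RADIUS",
    "PropensityTable",
    "ResidueDescriptors",
    "DescriptorSet",
    "circular_variance",
    "residue_cv",
    "structure_cv",
    "load_propensities",
    "scale_propensities",
    "conservation_from_file",
    "tree_trace_conservation",
    "map_scores_to_chain",
    "compute_descriptors",
]

CV_LOCAL_RADIUS = 12.0
CV_GLOBAL_RADIUS = 100.0


# ---------------------------------------------------------------------------
# circular variance


def circular_variance(
    center: np.ndarray, coords: np.ndarray, r_c: float
) -> Optional[float]:
    """Circular variance of one atom: 1 - |mean unit vector to neighbors|.

    Neighbors are the atoms within ``r_c`` of ``center`` (the center itself,
    i.e. any zero-distance point, is excluded). Returns ``None`` when no
    neighbor lies within the cutoff.
    """
    if r_c <= 0:
        raise ValueError("r_c must be positive")
    center = np.asarray(center, dtype=float)
    diff = np.asarray(coords, dtype=float) - center
    dist = np.linalg.norm(diff, axis=1)
    mask = (dist > 0) & (dist <= r_c)
    n = int(mask.sum())
    if n == 0:
        return None
    units = diff[mask] / dist[mask, None]
    return float(1.0 - np.linalg.norm(units.sum(axis=0)) / n)


def _atomic_cv(coords: np.ndarray, r_c: float) -> np.ndarray:
    """Vectorised atomic CV over a full coordinate set (NaN = undefined)."""
    tree = cKDTree(coords)
    neighbor_lists = tree.query_ball_point(coords, r_c)
    out = np.full(len(coords), np.nan)
    for i, nbrs in enumerate(neighbor_lists):
        diff = coords[nbrs] - coords[i]
        dist = np.linalg.norm(diff, axis=1)
        keep = dist > 0
        n = int(keep.sum())
        if n == 0:
            continue
        units = diff[keep] / dist[keep, None]
        out[i] = 1.0 - np.linalg.norm(units.sum(axis=0)) / n
    return np.clip(out, 0.0, 1.0, out=out)


def residue_cv(
    residue_coords: np.ndarray, all_coords: np.ndarray, r_c: float
) -> Optional[float]:
    """Unweighted mean of atomic CVs over a residue's atoms."""
    values = [circular_variance(c, all_coords, r_c) for c in residue_coords]
    defined = [v for v in values if v is not None]
    if not defined:
        return None
    return float(np.mean(defined))


def structure_cv(
    structure: Structure, r_c: float, molecule_class: str = "protein"
) -> Dict[ResidueKey, Optional[float]]:
    """Per-residue CV for every residue of the given molecule class."""
    residues = structure.residues(molecule_class)
    coords = np.concatenate([r.coords() for r in residues])
    atom_cv = _atomic_cv(coords, r_c)
    out: Dict[ResidueKey, Optional[float]] = {}
    i = 0
    for res in residues:
        n = len(res.atoms)
        vals = atom_cv[i : i + n]
        i += n
        defined = vals[~np.isnan(vals)]
        out[res.key] = float(defined.mean()) if defined.size else None
    return out


# ---------------------------------------------------------------------------
# DNA-interface propensities


@dataclass
class PropensityTable:
    """Raw and [0,1]-scaled per-amino-acid DNA-interface propensities."""

    raw: Dict[str, float]
    scaled: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.raw) != 20:
            raise ValueError(f"expected 20 amino-acid entries, got {len(self.raw)}")
        if any(v < 0 for v in self.raw.values()):
            raise ValueError("propensities must be non-negative")
        if not self.scaled:
            self.scaled = scale_propensities(self.raw)

    def value(self, one_letter: str) -> float:
        return self.scaled[one_letter]


def scale_propensities(raw: Dict[str, float]) -> Dict[str, float]:
    """Linear scaling raw / max(raw) so the maximum maps to 1 and 0 to 0."""
    peak = max(raw.values())
    if peak <= 0:
        raise ValueError("all-zero propensity table cannot be scaled")
    return {aa: v / peak for aa, v in raw.items()}


def load_propensities(path: Optional[str] = None) -> PropensityTable:
    if path is None:
        text = (
            resources.files("jet2dna.data")
            .joinpath("pc_dna_propensities_synthetic.tsv")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw: Dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed propensity line {lineno}: {line!r}")
        raw[parts[0].upper()] = float(parts[1])
    return PropensityTable(raw=raw)


# ---------------------------------------------------------------------------
# conservation providers


def conservation_from_file(path: str) -> Dict[ResidueKey, float]:
    """Read per-residue conservation from TSV (chain, resnum[+icode], score).

    Scores are clamped to [0, 1]; clamping is logged. Residues absent from the
    file default to 0 at lookup time (see :func:`DescriptorSet` assembly).
    """
    scores: Dict[ResidueKey, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"malformed conservation line {lineno}: {line!r}")
            chain, resspec, raw_score = parts
            try:
                if resspec[-1].isalpha():
                    number, icode = int(resspec[:-1]), resspec[-1]
                else:
                    number, icode = int(resspec), ""
                score = float(raw_score)
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"malformed conservation line {lineno}: {line!r}"
                ) from exc
            if score < 0.0 or score > 1.0:
                logger.warning(
                    "conservation score %.3f at %s%s clamped to [0,1]",
                    score, chain, resspec,
                )
                score = min(max(score, 0.0), 1.0)
            scores[(chain, number, icode)] = score
    return scores


def _query_columns(alignment, query_id: str) -> Tuple[str, List[int]]:
    """Query sequence row and the alignment columns where it is ungapped."""
    query_row = None
    for record in alignment:
        if record.id == query_id:
            query_row = str(record.seq)
            break
    if query_row is None:
        raise ValueError(f"query {query_id!r} absent from alignment")
    columns = [i for i, aa in enumerate(query_row) if aa not in "-."]
    return query_row, columns


def _build_nj_tree(alignment, rng: np.random.Generator, sample_size: int):
    """Neighbor-joining tree from a uniform random subsample of sequences.

    The query (first use site guarantees it is present) is always retained.
    """
    from Bio.Align import MultipleSeqAlignment
    from Bio.Phylo.TreeConstruction import DistanceCalculator, DistanceTreeConstructor

    n = len(alignment)
    take = min(sample_size, n)
    idx = rng.choice(n, size=take, replace=False)
    sub = MultipleSeqAlignment([alignment[int(i)] for i in sorted(idx)])
    calculator = DistanceCalculator("identity")
    dm = calculator.get_distance(sub)
    tree = DistanceTreeConstructor().nj(dm)
    return tree


def _tree_traces(tree, alignment_map: Dict[str, str], query_id: str,
                 columns: Sequence[int]) -> Optional[np.ndarray]:
    """Trace level per query position for one tree, normalised to [0,1].

    The trace of a position is the topological level (leaf = 0, root = path
    length) of the highest ancestor of the query leaf whose entire subtree
    carries the query's amino acid at that column, divided by the query
    leaf's root distance.
    """
    leaves = {leaf.name: leaf for leaf in tree.get_terminals()}
    if query_id not in leaves:
        return None
    path = tree.get_path(leaves[query_id])  # root-exclusive, leaf-inclusive
    depth = len(path)
    if depth == 0:
        return None
    # ancestors ordered leaf -> root; level i = i steps above the leaf
    ancestors = [path[-1 - i] for i in range(depth)] + [tree.root]
    ancestor_leaf_names = [
        [t.name for t in clade.get_terminals()] for clade in ancestors
    ]
    query_seq = alignment_map[query_id]
    traces = np.zeros(len(columns))
    for pos, col in enumerate(columns):
        aa = query_seq[col]
        level = 0
        for lvl in range(1, depth + 1):
            names = ancestor_leaf_names[lvl]
            if all(alignment_map[n][col] == aa for n in names if n in alignment_map):
                level = lvl
            else:
                break
        traces[pos] = level / depth
    return traces


def tree_trace_conservation(
    alignment,
    query_id: str,
    trees: Optional[Sequence] = None,
    n_samples: int = 10,
    sample_size: Optional[int] = None,
    seed: int = 0,
) -> np.ndarray:
    """Conservation per query position as tree traces averaged over trees.

    When no trees are supplied, ``n_samples`` neighbor-joining trees are built
    from percent-identity distances on uniformly subsampled sequence sets
    (seeded). Values lie in [0, 1]; a column identical across all sequences
    scores 1, one conserved only in the query leaf scores 0.
    """
    if len(alignment) < 3:
        raise ValueError("alignment must contain at least 3 sequences")
    query_row, columns = _query_columns(alignment, query_id)
    alignment_map = {record.id: str(record.seq) for record in alignment}

    if trees is None:
        rng = np.random.default_rng(seed)
        if sample_size is None:
            sample_size = min(50, len(alignment))
        built = []
        for _ in range(n_samples):
            # always include the query row in the subsample
            tree = None
            while tree is None:
                candidate = _build_nj_tree(alignment, rng, sample_size)
                if query_id in {t.name for t in candidate.get_terminals()}:
                    tree = candidate
            built.append(tree)
        trees = built

    all_traces = []
    for tree in trees:
        traces = _tree_traces(tree, alignment_map, query_id, columns)
        if traces is not None:
            all_traces.append(traces)
    if not all_traces:
        raise ValueError("no usable tree contained the query leaf")
    mean = np.mean(all_traces, axis=0)
    return np.clip(mean, 0.0, 1.0)


def map_scores_to_chain(
    scores: np.ndarray, structure: Structure, chain_id: str
) -> Dict[ResidueKey, float]:
    """Assign sequential per-position scores to the protein residues of a chain."""
    residues = [r for r in structure.chains[chain_id] if r.molecule_class == "protein"]
    if len(scores) != len(residues):
        raise ValueError(
            f"{len(scores)} scores for {len(residues)} protein residues in chain {chain_id}"
        )
    return {res.key: float(s) for res, s in zip(residues, scores)}


# ---------------------------------------------------------------------------
# descriptor assembly


@dataclass
class ResidueDescriptors:
    t_jet: float
    pc_dna: float
    cv_local: Optional[float]
    cv_global: Optional[float]


@dataclass
class DescriptorSet:
    """T_JET, PC_DNA, CV_local and CV_global for every surface residue."""

    values: Dict[ResidueKey, ResidueDescriptors]
    r_local: float = CV_LOCAL_RADIUS
    r_global: float = CV_GLOBAL_RADIUS

    def __getitem__(self, key: ResidueKey) -> ResidueDescriptors:
        return self.values[key]

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self.values

    def keys(self):
        return self.values.keys()


def compute_descriptors(
    structure: Structure,
    surface: set,
    conservation: Dict[ResidueKey, float],
    propensities: Optional[PropensityTable] = None,
    r_local: float = CV_LOCAL_RADIUS,
    r_global: float = CV_GLOBAL_RADIUS,
) -> DescriptorSet:
    """Assemble the descriptor set for the surface residues of a structure.

    Conservation defaults to 0 (with a warning) for surface residues missing
    from the provided score map; residues whose type has no propensity entry
    are dropped from the set.
    """
    if propensities is None:
        propensities = load_propensities()
    cv_local = structure_cv(structure, r_local)
    cv_global = structure_cv(structure, r_global)

    values: Dict[ResidueKey, ResidueDescriptors] = {}
    missing_conservation = 0
    for res in structure.residues("protein"):
        if res.key not in surface:
            continue
        one = res.one_letter
        if one is None:
            logger.warning("no propensity for residue type %s at %s", res.name, res.key)
            continue
        if res.key not in conservation:
            missing_conservation += 1
        values[res.key] = ResidueDescriptors(
            t_jet=float(np.clip(conservation.get(res.key, 0.0), 0.0, 1.0)),
            pc_dna=propensities.value(one),
            cv_local=cv_local.get(res.key),
            cv_global=cv_global.get(res.key),
        )
    if missing_conservation:
        logger.warning(
            "%d surface residues had no conservation score; defaulted to 0",
            missing_conservation,
        )
    return DescriptorSet(values=values, r_local=r_local, r_global=r_global)
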