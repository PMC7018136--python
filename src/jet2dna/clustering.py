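"""Seed -> extension -> outer-layer clustering of high-scoring surface residues.

The predictor grows patches in three steps that mirror the three structural
layers of experimental interfaces:

1. *seeds*: connected components of the top-ranked residues (pool sized to
   about a third of the expected interface);
2. *extension*: the seeds absorb, one at a time, the best-scoring unassigned
   neighbor that stays within the extension candidate pool and above a floor
   relative to the current patch mean; patches that come into contact merge;
3. *outer layer*: the same admission loop with the outer-layer score, until
   the total prediction reaches the expected interface size.

Seeds sitting on small-ligand pockets (too many residues with CV_local above
0.9) trigger one restart with those residues banned. If a full pass predicts
less than 70% of the expected size, all three steps rerun once with relaxed
thresholds. Finally 1-2 residue patches are dropped and, when the prediction
overshoots 70% of the expected size, small patches are filtered against the
size distribution of randomly grown connected surface patches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .descriptors import DescriptorSet
from .scoring import ExpectedSize, Layer, MissingDescriptorError, Scheme, layer_score
from .structure import ResidueKey, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringThresholds",
    "PredictedPatch",
    "ClusteringResult",
    "adjacency_graph",
    "detect_seeds",
    "restart_on_pockets",
    "extend_clusters",
    "add_outer_layer",
    "filter_patches",
    "run_scheme",
]


@dataclass(frozen=True)
class ClusteringThresholds:
    """Knobs of the clustering procedure (defaults documented in docs/methods.md).

    Candidate pools are expressed as fractions of the expected interface size
    (seed ~ a third, extension ~ two thirds, outer = all of it); cluster-growth
    floors are fractions of the current patch mean score that an admitted
    residue must reach. Relaxation enlarges pools by ``relax_factor`` and
    lowers floors by ``relax_floor_factor`` when a strict pass predicts less
    than ``relax_trigger`` of the expected size.
    """

    seed_pool_frac: float = 1.0 / 3.0
    extension_pool_frac: float = 2.0 / 3.0
    outer_pool_frac: float = 1.0
    extension_floor: float = 0.8
    outer_floor: float = 0.7
    relax_factor: float = 1.5
    relax_floor_factor: float = 0.9
    relax_trigger: float = 0.70
    cv_local_high: float = 0.9
    pocket_fraction_dsc1: float = 0.20
    pocket_fraction_dsc2: float = 0.30
    adjacency_cutoff: float = 5.0
    null_patch_count: int = 1000
    null_size_percentile: float = 95.0

    def pocket_fraction(self, scheme: Scheme) -> Optional[float]:
        if scheme is Scheme.DSC1:
            return self.pocket_fraction_dsc1
        if scheme is Scheme.DSC2:
            return self.pocket_fraction_dsc2
        return None  # pocket avoidance does not apply to DSC3

    def pool_size(self, frac: float, expected: ExpectedSize, relaxed: bool) -> int:
        factor = self.relax_factor if relaxed else 1.0
        return max(1, math.ceil(frac * expected.count * factor))

    def floor(self, base: float, relaxed: bool) -> float:
        return base * (self.relax_floor_factor if relaxed else 1.0)


@dataclass
class PredictedPatch:
    """A connected predicted patch with per-residue layer labels and scores."""

    layers: Dict[ResidueKey, str]
    scores: Dict[ResidueKey, float]
    scheme: Scheme
    provenance: str = "round1"

    @property
    def residues(self) -> Set[ResidueKey]:
        return set(self.layers)

    @property
    def size(self) -> int:
        return len(self.layers)

    def mean_score(self) -> float:
        return float(np.mean(list(self.scores.values())))

    def sort_key(self) -> Tuple:
        return (self.size, min(self.layers))


@dataclass
class ClusteringResult:
    patches: List[PredictedPatch]
    scheme: Scheme
    excluded: Set[ResidueKey] = field(default_factory=set)
    relaxed: bool = False
    restarted: bool = False

    @property
    def residues(self) -> Set[ResidueKey]:
        out: Set[ResidueKey] = set()
        for p in self.patches:
            out |= p.residues
        return out


# ---------------------------------------------------------------------------
# geometry


def adjacency_graph(
    structure: Structure, surface: Iterable[ResidueKey], cutoff: float = 5.0
) -> nx.Graph:
    """Residue adjacency: edge iff minimal heavy-atom distance <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    surface = set(surface)
    graph = nx.Graph()
    graph.add_nodes_from(sorted(surface))
    coords: List[np.ndarray] = []
    owner: List[ResidueKey] = []
    for res in structure.residues("protein"):
        if res.key not in surface:
            continue
        for atom in res.atoms:
            coords.append(atom.coord)
            owner.append(res.key)
    if not coords:
        return graph
    tree = cKDTree(np.asarray(coords))
    for i, j in tree.query_pairs(cutoff):
        if owner[i] != owner[j]:
            graph.add_edge(owner[i], owner[j])
    return graph


# ---------------------------------------------------------------------------
# ranking helpers


def _layer_scores(
    descriptors: DescriptorSet, scheme: Scheme, layer: Layer
) -> Dict[ResidueKey, float]:
    scores: Dict[ResidueKey, float] = {}
    for key in descriptors.keys():
        try:
            scores[key] = layer_score(scheme, layer, descriptors[key])
        except MissingDescriptorError:
            logger.warning("residue %s excluded from %s/%s ranking (missing descriptor)",
                           key, scheme.value, layer.value)
    return scores


def _ranked(
    scores: Dict[ResidueKey, float],
    descriptors: DescriptorSet,
    excluded: Set[ResidueKey],
) -> List[ResidueKey]:
    """Deterministic score ranking; ties broken by higher T_JET, then residue id."""
    keys = [k for k in scores if k not in excluded]
    return sorted(keys, key=lambda k: (-scores[k], -descriptors[k].t_jet, k))


# ---------------------------------------------------------------------------
# the three clustering steps


def detect_seeds(
    scores: Dict[ResidueKey, float],
    descriptors: DescriptorSet,
    graph: nx.Graph,
    expected: ExpectedSize,
    thresholds: ClusteringThresholds,
    scheme: Scheme,
    excluded: Set[ResidueKey] = frozenset(),
    relaxed: bool = False,
) -> List[PredictedPatch]:
    """Seeds = connected components of the top-ranked seed-score residues.

    Components of 1-2 residues are discarded here only when a component of
    size >= 3 exists (the unconditional 1-2 residue filter runs at the end).
    """
    pool_size = thresholds.pool_size(thresholds.seed_pool_frac, expected, relaxed)
    candidates = _ranked(scores, descriptors, set(excluded))[:pool_size]
    components = [sorted(c) for c in nx.connected_components(graph.subgraph(candidates))]
    components.sort(key=lambda c: (-len(c), c[0]))
    if any(len(c) >= 3 for c in components):
        components = [c for c in components if len(c) >= 3]
    return [
        PredictedPatch(
            layers={k: Layer.SEED.value for k in comp},
            scores={k: scores[k] for k in comp},
            scheme=scheme,
        )
        for comp in components
    ]


def restart_on_pockets(
    seeds: List[PredictedPatch],
    scheme: Scheme,
    cv_local: Dict[ResidueKey, Optional[float]],
    scores: Dict[ResidueKey, float],
    descriptors: DescriptorSet,
    graph: nx.Graph,
    expected: ExpectedSize,
    thresholds: ClusteringThresholds,
    excluded: Set[ResidueKey] = frozenset(),
    relaxed: bool = False,
) -> Tuple[List[PredictedPatch], Set[ResidueKey], bool]:
    """Redo seed detection once when seeds sit on a deeply buried pocket.

    If any seed holds more than the scheme's tolerated fraction of highly
    buried residues (CV_local > 0.9), seed detection reruns with all highly
    buried surface residues banned; the ban set is returned so later layers
    also avoid them. No-op for D-SC3.
    """
    fraction = thresholds.pocket_fraction(scheme)
    if fraction is None or not seeds:
        return seeds, set(excluded), False

    def buried_fraction(patch: PredictedPatch) -> float:
        flags = [
            1.0 if (cv_local.get(k) or 0.0) > thresholds.cv_local_high else 0.0
            for k in patch.layers
        ]
        return float(np.mean(flags)) if flags else 0.0

    if not any(buried_fraction(p) > fraction for p in seeds):
        return seeds, set(excluded), False

    buried = {
        k for k in scores
        if (cv_local.get(k) or 0.0) > thresholds.cv_local_high
    }
    new_excluded = set(excluded) | buried
    new_seeds = detect_seeds(
        scores, descriptors, graph, expected, thresholds, scheme,
        excluded=new_excluded, relaxed=relaxed,
    )
    return new_seeds, new_excluded, True


def _admission_loop(
    patches: List[PredictedPatch],
    pool: Sequence[ResidueKey],
    scores: Dict[ResidueKey, float],
    graph: nx.Graph,
    floor: float,
    layer: Layer,
    stop_at_total: Optional[int] = None,
) -> List[PredictedPatch]:
    """Iteratively admit the best pooled neighbor of any patch; merge on contact.

    The floor compares the candidate's score on the *current* layer scale with
    the patch mean recomputed on that same scale (layer formulas differ, so
    stored scores from earlier layers are not comparable).
    """
    patches = [p for p in patches]
    assigned: Dict[ResidueKey, int] = {}
    for idx, p in enumerate(patches):
        for k in p.layers:
            assigned[k] = idx

    def patch_mean(p: PredictedPatch) -> float:
        vals = [scores[k] for k in p.layers if k in scores]
        return float(np.mean(vals)) if vals else 0.0

    pool_order = [k for k in pool if k not in assigned]
    while True:
        if stop_at_total is not None and len(assigned) >= stop_at_total:
            break
        admitted = False
        for key in pool_order:
            if key in assigned:
                continue
            adjacent = sorted(
                {assigned[n] for n in graph.neighbors(key) if n in assigned}
            )
            if not adjacent:
                continue
            live = [i for i in adjacent if patches[i] is not None]
            if not live:
                continue
            passing = [
                i for i in live if scores[key] >= floor * patch_mean(patches[i])
            ]
            if not passing:
                continue
            # admit into the adjacent patch with the highest mean score
            target = max(passing, key=lambda i: patch_mean(patches[i]))
            patches[target].layers[key] = layer.value
            patches[target].scores[key] = scores[key]
            assigned[key] = target
            # contact through the admitted residue merges every adjacent patch
            for other in live:
                if other == target:
                    continue
                patches[target].layers.update(patches[other].layers)
                patches[target].scores.update(patches[other].scores)
                for k in patches[other].layers:
                    assigned[k] = target
                patches[other] = None
            admitted = True
            break
        if not admitted:
            break
    return [p for p in patches if p is not None]


def extend_clusters(
    seeds: List[PredictedPatch],
    scores: Dict[ResidueKey, float],
    descriptors: DescriptorSet,
    graph: nx.Graph,
    expected: ExpectedSize,
    thresholds: ClusteringThresholds,
    excluded: Set[ResidueKey] = frozenset(),
    relaxed: bool = False,
) -> List[PredictedPatch]:
    """Grow seeds with extension-layer residues from the top-2/3 candidate pool."""
    if not seeds:
        return []
    pool_size = thresholds.pool_size(thresholds.extension_pool_frac, expected, relaxed)
    pool = _ranked(scores, descriptors, set(excluded))[:pool_size]
    floor = thresholds.floor(thresholds.extension_floor, relaxed)
    return _admission_loop(seeds, pool, scores, graph, floor, Layer.EXTENSION)


def add_outer_layer(
    patches: List[PredictedPatch],
    scores: Dict[ResidueKey, float],
    descriptors: DescriptorSet,
    graph: nx.Graph,
    expected: ExpectedSize,
    thresholds: ClusteringThresholds,
    excluded: Set[ResidueKey] = frozenset(),
    relaxed: bool = False,
) -> List[PredictedPatch]:
    """Complete patches with outer-layer residues until the expected size."""
    if not patches:
        return []
    pool_size = thresholds.pool_size(thresholds.outer_pool_frac, expected, relaxed)
    pool = _ranked(scores, descriptors, set(excluded))[:pool_size]
    floor = thresholds.floor(thresholds.outer_floor, relaxed)
    return _admission_loop(
        patches, pool, scores, graph, floor, Layer.OUTER,
        stop_at_total=expected.count,
    )


# ---------------------------------------------------------------------------
# filtering


def _random_patch_sizes(
    graph: nx.Graph,
    expected: ExpectedSize,
    rng: np.random.Generator,
    n_patches: int,
) -> np.ndarray:
    """Null model: patch sizes produced by chance clustering of the candidate pool.

    Scores without spatial signal would scatter the candidate pool (of size
    ``expected.count``) uniformly over the surface; a chance patch grown from a
    random seed is then the connected component containing that seed. Each
    draw marks ``expected.count`` random surface residues and records the size
    of the component holding the first mark.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        return np.zeros(n_patches)
    take = min(expected.count, len(nodes))
    sizes = np.empty(n_patches, dtype=float)
    for i in range(n_patches):
        marks = rng.choice(len(nodes), size=take, replace=False)
        marked = {nodes[int(j)] for j in marks}
        seed_node = nodes[int(marks[0])]
        component = {seed_node}
        frontier = [seed_node]
        while frontier:
            node = frontier.pop()
            for nbr in graph.neighbors(node):
                if nbr in marked and nbr not in component:
                    component.add(nbr)
                    frontier.append(nbr)
        sizes[i] = len(component)
    return sizes


def filter_patches(
    patches: List[PredictedPatch],
    expected: ExpectedSize,
    graph: nx.Graph,
    rng: np.random.Generator,
    thresholds: ClusteringThresholds,
) -> List[PredictedPatch]:
    """Drop 1-2 residue patches; filter small patches on overshoot.

    When the prediction exceeds 70% of the expected size, patches are visited
    from the smallest and removed while their size falls below the 95th
    percentile of random connected-patch sizes, stopping once the total drops
    to 70% of the expected size or the remaining patches all pass.
    """
    kept = [p for p in patches if p.size >= 3]
    total = sum(p.size for p in kept)
    limit = thresholds.relax_trigger * expected.count
    if total <= limit:
        return sorted(kept, key=lambda p: p.sort_key())

    null_sizes = _random_patch_sizes(graph, expected, rng, thresholds.null_patch_count)
    percentile = float(np.percentile(null_sizes, thresholds.null_size_percentile))
    surviving: List[PredictedPatch] = []
    for patch in sorted(kept, key=lambda p: p.sort_key()):
        if total <= limit or patch.size >= percentile:
            surviving.append(patch)
        else:
            total -= patch.size
    return sorted(surviving, key=lambda p: p.sort_key())


# ---------------------------------------------------------------------------
# orchestration


def run_scheme(
    scheme: Scheme,
    descriptors: DescriptorSet,
    graph: nx.Graph,
    expected: ExpectedSize,
    thresholds: ClusteringThresholds,
    rng: np.random.Generator,
    excluded: Set[ResidueKey] = frozenset(),
    apply_filter: bool = True,
) -> ClusteringResult:
    """Full clustering for one scheme: seeds, pocket restart, extension,
    outer layer, one relaxation retry, final filtering."""
    scheme = Scheme(scheme)
    seed_scores = _layer_scores(descriptors, scheme, Layer.SEED)
    ext_scores = _layer_scores(descriptors, scheme, Layer.EXTENSION)
    outer_scores = _layer_scores(descriptors, scheme, Layer.OUTER)
    cv_local = {k: descriptors[k].cv_local for k in descriptors.keys()}

    def one_pass(relaxed: bool) -> Tuple[List[PredictedPatch], Set[ResidueKey], bool]:
        seeds = detect_seeds(
            seed_scores, descriptors, graph, expected, thresholds, scheme,
            excluded=set(excluded), relaxed=relaxed,
        )
        seeds, banned, restarted = restart_on_pockets(
            seeds, scheme, cv_local, seed_scores, descriptors, graph,
            expected, thresholds, excluded=set(excluded), relaxed=relaxed,
        )
        patches = extend_clusters(
            seeds, ext_scores, descriptors, graph, expected, thresholds,
            excluded=banned, relaxed=relaxed,
        )
        patches = add_outer_layer(
            patches, outer_scores, descriptors, graph, expected, thresholds,
            excluded=banned, relaxed=relaxed,
        )
        return patches, banned, restarted

    patches, banned, restarted = one_pass(relaxed=False)
    # 1-2 residue clusters are unconditionally discarded later, so only
    # viable patches count towards the relaxation trigger
    total = sum(p.size for p in patches if p.size >= 3)
    relaxed_used = False
    if total < thresholds.relax_trigger * expected.count:
        patches, banned, restarted = one_pass(relaxed=True)
        relaxed_used = True

    if apply_filter:
        patches = filter_patches(patches, expected, graph, rng, thresholds)
    return ClusteringResult(
        patches=patches,
        scheme=scheme,
        excluded=banned,
        relaxed=relaxed_used,
        restarted=restarted,
    )
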