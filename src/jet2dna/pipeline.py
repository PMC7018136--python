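"""Automated scheme selection, complete (two-round) and iterative prediction.

The automated decision tree first detects seeds with D-SC1 and inspects their
mean descriptors: a very low conservation signal (mean T_JET < 0.3, or no
seeds at all) routes the run to D-SC3; seeds in a globally concave region
(mean CV_global > 0.6) without overwhelming physico-chemical signal (mean
PC_DNA < 0.9) route it to D-SC2; everything else stays with D-SC1. The
*complete* mode adds a second clustering round with the complementary scheme
(D-SC3 after D-SC1/D-SC2, D-SC1 after D-SC3). The *iterative* mode repeats
the whole prediction with per-run reseeding and reports, per residue, the
fraction of runs in which it was detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Protocol, Set, Tuple

import networkx as nx
import numpy as np

from .clustering import (
    ClusteringThresholds,
    PredictedPatch,
    adjacency_graph,
    detect_seeds,
    run_scheme,
    _layer_scores,
)
from .descriptors import (
    DescriptorSet,
    PropensityTable,
    compute_descriptors,
    conservation_from_file,
    map_scores_to_chain,
    tree_trace_conservation,
)
from .scoring import ExpectedSize, Layer, Scheme, expected_interface_size
from .structure import ResidueKey, Structure, compute_sasa, surface_residues

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionConfig",
    "PredictionResult",
    "ConservationProvider",
    "FileConservation",
    "MappingConservation",
    "MsaConservation",
    "select_scheme",
    "prepare_inputs",
    "run_prediction",
    "run_complete",
    "run_iterative",
]

# decision-tree constants
T_JET_LOW = 0.3
CV_GLOBAL_CONCAVE = 0.6
PC_DNA_FAVOURABLE = 0.9

_LAYER_PRIORITY = {Layer.SEED.value: 0, Layer.EXTENSION.value: 1, Layer.OUTER.value: 2}


class ConservationProvider(Protocol):
    """Anything that yields per-residue conservation for a structure."""

    def scores(self, structure: Structure, seed: int) -> Dict[ResidueKey, float]:
        ...  # pragma: no cover


@dataclass
class FileConservation:
    """Per-residue scores read from a TSV file (deterministic)."""

    path: str

    def scores(self, structure: Structure, seed: int) -> Dict[ResidueKey, float]:
        return conservation_from_file(self.path)


@dataclass
class MappingConservation:
    """In-memory score map (fixtures, tests)."""

    mapping: Dict[ResidueKey, float]

    def scores(self, structure: Structure, seed: int) -> Dict[ResidueKey, float]:
        return dict(self.mapping)


@dataclass
class MsaConservation:
    """Tree-trace conservation from an alignment; stochastic via subsampling.

    ``chain_ids`` names the protein chains the query sequence maps onto
    (sequential protein residues per chain). Passing explicit ``trees`` makes
    the computation deterministic regardless of the seed.
    """

    alignment: object
    query_id: str
    chain_ids: Tuple[str, ...]
    trees: Optional[List] = None
    n_trees: int = 10
    sample_size: Optional[int] = None

    def scores(self, structure: Structure, seed: int) -> Dict[ResidueKey, float]:
        positional = tree_trace_conservation(
            self.alignment,
            self.query_id,
            trees=self.trees,
            n_samples=self.n_trees,
            sample_size=self.sample_size,
            seed=seed,
        )
        out: Dict[ResidueKey, float] = {}
        for chain_id in self.chain_ids:
            out.update(map_scores_to_chain(positional, structure, chain_id))
        return out


@dataclass
class PredictionConfig:
    scheme: str = "auto"  # "auto" | "dsc1" | "dsc2" | "dsc3"
    complete: bool = False
    surface_threshold: float = 5.0
    probe_radius: float = 1.4
    sasa_points: int = 500
    thresholds: ClusteringThresholds = field(default_factory=ClusteringThresholds)
    propensities: Optional[PropensityTable] = None
    conservation: Optional[ConservationProvider] = None


@dataclass
class PredictionResult:
    patches: List[PredictedPatch]
    scheme: Scheme
    trace: Dict[str, object]
    expected: ExpectedSize
    surface: Set[ResidueKey]
    probabilities: Optional[Dict[ResidueKey, float]] = None

    @property
    def residues(self) -> Set[ResidueKey]:
        out: Set[ResidueKey] = set()
        for p in self.patches:
            out |= p.residues
        return out


# ---------------------------------------------------------------------------
# scheme selection


def select_scheme(
    seed_patches: List[PredictedPatch], descriptors: DescriptorSet
) -> Tuple[Scheme, Dict[str, Optional[float]]]:
    """Decision tree over the D-SC1 seed residues; returns scheme + statistics."""
    seed_keys = sorted({k for p in seed_patches for k in p.layers})
    if not seed_keys:
        trace = {"mean_t_jet": None, "mean_cv_global": None, "mean_pc_dna": None}
        return Scheme.DSC3, trace

    t_jet = float(np.mean([descriptors[k].t_jet for k in seed_keys]))
    cv_global_vals = [
        descriptors[k].cv_global for k in seed_keys
        if descriptors[k].cv_global is not None
    ]
    cv_global = float(np.mean(cv_global_vals)) if cv_global_vals else 0.0
    pc_dna = float(np.mean([descriptors[k].pc_dna for k in seed_keys]))
    trace = {"mean_t_jet": t_jet, "mean_cv_global": cv_global, "mean_pc_dna": pc_dna}

    if t_jet < T_JET_LOW:
        return Scheme.DSC3, trace
    if cv_global > CV_GLOBAL_CONCAVE and pc_dna < PC_DNA_FAVOURABLE:
        return Scheme.DSC2, trace
    return Scheme.DSC1, trace


# ---------------------------------------------------------------------------
# input preparation


def prepare_inputs(
    structure: Structure,
    config: PredictionConfig,
    conservation: Dict[ResidueKey, float],
) -> Tuple[DescriptorSet, nx.Graph, ExpectedSize]:
    """Surface detection, descriptors, adjacency graph and expected size."""
    protein = structure.subset(["protein"])
    accessibility = compute_sasa(
        protein, config.probe_radius, point_number=config.sasa_points
    )
    surface = surface_residues(accessibility, config.surface_threshold)
    if not surface:
        raise ValueError("structure has no surface residues")
    descriptors = compute_descriptors(
        protein, surface, conservation, propensities=config.propensities
    )
    graph = adjacency_graph(protein, descriptors.keys(),
                            config.thresholds.adjacency_cutoff)
    expected = expected_interface_size(len(descriptors.values))
    return descriptors, graph, expected


# ---------------------------------------------------------------------------
# prediction entry points


def run_prediction(
    structure: Structure,
    descriptors: DescriptorSet,
    config: PredictionConfig,
    rng: np.random.Generator,
    graph: Optional[nx.Graph] = None,
    expected: Optional[ExpectedSize] = None,
) -> PredictionResult:
    """One full prediction: D-SC1 seeds, scheme choice, clustering."""
    if not descriptors.values:
        raise ValueError("no surface residues to predict on")
    if graph is None:
        graph = adjacency_graph(
            structure.subset(["protein"]), descriptors.keys(),
            config.thresholds.adjacency_cutoff,
        )
    if expected is None:
        expected = expected_interface_size(len(descriptors.values))

    if config.scheme != "auto":
        scheme = Scheme(config.scheme)
        trace: Dict[str, object] = {"mode": "manual", "mean_t_jet": None,
                                    "mean_cv_global": None, "mean_pc_dna": None}
    else:
        dsc1_scores = _layer_scores(descriptors, Scheme.DSC1, Layer.SEED)
        dsc1_seeds = detect_seeds(
            dsc1_scores, descriptors, graph, expected, config.thresholds, Scheme.DSC1
        )
        scheme, stats = select_scheme(dsc1_seeds, descriptors)
        trace = {"mode": "auto", **stats}
    trace["scheme"] = scheme.value

    result = run_scheme(
        scheme, descriptors, graph, expected, config.thresholds, rng
    )
    trace["relaxed"] = result.relaxed
    trace["pocket_restart"] = result.restarted
    return PredictionResult(
        patches=result.patches,
        scheme=scheme,
        trace=trace,
        expected=expected,
        surface=set(descriptors.keys()),
    )


def complementary_scheme(scheme: Scheme) -> Scheme:
    return Scheme.DSC1 if scheme is Scheme.DSC3 else Scheme.DSC3


def run_complete(
    structure: Structure,
    descriptors: DescriptorSet,
    config: PredictionConfig,
    rng: np.random.Generator,
    graph: Optional[nx.Graph] = None,
    expected: Optional[ExpectedSize] = None,
) -> PredictionResult:
    """Two-round prediction: the main scheme complemented by its partner.

    Round-2 residues already predicted in round 1 are reported once: the
    round-1 patch gains dual provenance, and a round-2 patch reduced to
    duplicates only is dropped.
    """
    if graph is None:
        graph = adjacency_graph(
            structure.subset(["protein"]), descriptors.keys(),
            config.thresholds.adjacency_cutoff,
        )
    if expected is None:
        expected = expected_interface_size(len(descriptors.values))

    round1 = run_prediction(structure, descriptors, config, rng, graph, expected)
    comp = complementary_scheme(round1.scheme)
    round2 = run_scheme(comp, descriptors, graph, expected, config.thresholds, rng)

    round1_residues = round1.residues
    patches = list(round1.patches)
    for patch in round2.patches:
        overlap = patch.residues & round1_residues
        if overlap:
            for p in patches:
                if p.residues & overlap:
                    p.provenance = "round1+round2"
        fresh = {k: v for k, v in patch.layers.items() if k not in round1_residues}
        if not fresh:
            continue
        patches.append(
            PredictedPatch(
                layers=fresh,
                scores={k: patch.scores[k] for k in fresh},
                scheme=comp,
                provenance="round2",
            )
        )
    trace = dict(round1.trace)
    trace["complementary_scheme"] = comp.value
    return PredictionResult(
        patches=patches,
        scheme=round1.scheme,
        trace=trace,
        expected=expected,
        surface=round1.surface,
    )


def run_iterative(
    structure: Structure,
    config: PredictionConfig,
    n_runs: int = 10,
    consensus_k: int = 2,
    seed: int = 0,
) -> PredictionResult:
    """Consensus over repeated runs (run r reseeded with ``seed + r``).

    Per-residue probability = detections / n_runs; the consensus prediction
    keeps residues detected in at least ``consensus_k`` runs, rebuilt into
    connected patches with layer labels set by majority vote across runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not 1 <= consensus_k <= n_runs:
        raise ValueError("consensus_k must lie in [1, n_runs]")
    if config.conservation is None:
        raise ValueError("iterative mode needs a conservation provider")

    detections: Dict[ResidueKey, int] = {}
    layer_votes: Dict[ResidueKey, Dict[str, int]] = {}
    scheme_history: List[str] = []
    graph: Optional[nx.Graph] = None
    surface: Set[ResidueKey] = set()
    expected: Optional[ExpectedSize] = None

    for run_index in range(n_runs):
        run_seed = seed + run_index
        conservation = config.conservation.scores(structure, run_seed)
        descriptors, graph, expected = prepare_inputs(structure, config, conservation)
        rng = np.random.default_rng(run_seed)
        runner = run_complete if config.complete else run_prediction
        result = runner(structure, descriptors, config, rng, graph, expected)
        scheme_history.append(result.scheme.value)
        surface = result.surface
        for patch in result.patches:
            for key, layer in patch.layers.items():
                detections[key] = detections.get(key, 0) + 1
                layer_votes.setdefault(key, {}).setdefault(layer, 0)
                layer_votes[key][layer] += 1

    probabilities = {k: detections[k] / n_runs for k in detections}
    consensus = {k for k, n in detections.items() if n >= consensus_k}

    patches: List[PredictedPatch] = []
    for component in nx.connected_components(graph.subgraph(sorted(consensus))):
        layers = {}
        for key in sorted(component):
            votes = layer_votes[key]
            layers[key] = min(
                votes, key=lambda lab: (-votes[lab], _LAYER_PRIORITY[lab])
            )
        patches.append(
            PredictedPatch(
                layers=layers,
                scores={k: probabilities[k] for k in layers},
                scheme=Scheme(scheme_history[-1]),
                provenance="consensus",
            )
        )
    patches.sort(key=lambda p: p.sort_key())

    majority_scheme = max(set(scheme_history), key=scheme_history.count)
    trace = {
        "mode": "iterative",
        "n_runs": n_runs,
        "consensus_k": consensus_k,
        "schemes": scheme_history,
    }
    return PredictionResult(
        patches=patches,
        scheme=Scheme(majority_scheme),
        trace=trace,
        expected=expected,
        surface=surface,
        probabilities=probabilities,
    )
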