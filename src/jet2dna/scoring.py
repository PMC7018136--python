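"""The three scoring schemes and the expected interface size.

Each scheme sums two [0,1] descriptors, so layer scores lie in [0,2]. Seed
and extension always share the same combination (the innermost interface
layers may swap their spatial positions, so they must be scored alike):

========  =====================  =====================
scheme    seed / extension       outer layer
========  =====================  =====================
D-SC1     T_JET + PC_DNA         T_JET + (1 - CV_local)
D-SC2     T_JET + CV_global      T_JET + PC_DNA
D-SC3     PC_DNA + (1-CV_local)  PC_DNA + (1 - CV_local)
========  =====================  =====================

D-SC1 targets generic conserved binding sites, D-SC2 the "enveloping"
(globally concave) sites typical of polymerases, D-SC3 sites without a usable
conservation signal (locally protruding, DNA-favourable chemistry).

The anticipated interface fraction for a protein with x surface residues is
f(x) = 2.66/x + 0.03, decreasing towards the 3% asymptote for large proteins.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .descriptors import ResidueDescriptors

__all__ = ["Scheme", "Layer", "ExpectedSize", "layer_score", "expected_interface_size"]


class Scheme(str, enum.Enum):
    DSC1 = "dsc1"
    DSC2 = "dsc2"
    DSC3 = "dsc3"


class Layer(str, enum.Enum):
    SEED = "seed"
    EXTENSION = "extension"
    OUTER = "outer"


class MissingDescriptorError(ValueError):
    """A descriptor needed by the requested scheme/layer is undefined."""


def layer_score(scheme: Scheme, layer: Layer, d: ResidueDescriptors) -> float:
    """Score of one residue for a (scheme, layer) pair; range [0, 2]."""
    scheme = Scheme(scheme)
    layer = Layer(layer)
    if scheme is Scheme.DSC1:
        if layer in (Layer.SEED, Layer.EXTENSION):
            return d.t_jet + d.pc_dna
        return d.t_jet + (1.0 - _require(d.cv_local, "CV_local"))
    if scheme is Scheme.DSC2:
        if layer in (Layer.SEED, Layer.EXTENSION):
            return d.t_jet + _require(d.cv_global, "CV_global")
        return d.t_jet + d.pc_dna
    # DSC3: one combination for all three layers
    return d.pc_dna + (1.0 - _require(d.cv_local, "CV_local"))


def _require(value, name: str) -> float:
    if value is None:
        raise MissingDescriptorError(f"{name} undefined for residue")
    return value


@dataclass
class ExpectedSize:
    """Expected interface size given the number of surface residues."""

    n_surface: int
    fraction: float
    count: int


def expected_interface_size(n_surface: int) -> ExpectedSize:
    """f(x) = 2.66/x + 0.03; count = round-half-up(f * x), at least 3."""
    if n_surface < 1:
        raise ValueError("n_surface must be >= 1")
    fraction = 2.66 / n_surface + 0.03
    count = max(3, math.floor(fraction * n_surface + 0.5))
    return ExpectedSize(n_surface=n_surface, fraction=fraction, count=count)
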