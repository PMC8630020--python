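"""Vertical grid for the finite-volume diagenetic solver.

Nodes sit on cell interfaces, including z = 0 (the sediment-water
interface) and z = L.  Each node owns a control volume bounded by the
midpoints to its neighbours; the two boundary nodes own half cells.  Cell
widths can be geometrically refined toward the surface, where porewater
gradients are steepest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Raised for invalid model configuration."""


@dataclass(frozen=True)
class Grid:
    """Node depths (m, increasing, 0 .. L) plus derived control volumes."""

    node_depths: np.ndarray
    porosity: np.ndarray | None = None

    # derived, filled in __post_init__
    cell_widths: np.ndarray = field(init=False, repr=False)
    control_volumes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        z = np.asarray(self.node_depths, dtype=float)
        if z.ndim != 1 or z.size < 2:
            raise ConfigurationError("grid needs at least 2 nodes")
        if z[0] != 0.0:
            raise ConfigurationError("first node must sit at z = 0")
        dz = np.diff(z)
        if np.any(dz <= 0):
            raise ConfigurationError("node depths must be strictly increasing")
        object.__setattr__(self, "node_depths", z)
        object.__setattr__(self, "cell_widths", dz)
        # control volume of node i spans the midpoints to its neighbours
        cv = np.empty_like(z)
        cv[0] = dz[0] / 2.0
        cv[-1] = dz[-1] / 2.0
        cv[1:-1] = (z[2:] - z[:-2]) / 2.0
        object.__setattr__(self, "control_volumes", cv)

    @property
    def n_nodes(self) -> int:
        return self.node_depths.size

    @property
    def length(self) -> float:
        return float(self.node_depths[-1])


def build_grid(L: float, n_nodes: int, refinement_factor: float = 1.0) -> Grid:
    """Build a grid over [0, L] with ``n_nodes`` nodes.

    ``refinement_factor`` is the geometric growth ratio between successive
    cell widths (>= 1); cells are finest at the surface.  With ratio 1 the
    grid is uniform.  For ratio g and m = n_nodes - 1 cells the first cell
    width is L (g - 1) / (g^m - 1).
    """
    if not L > 0:
        raise ConfigurationError(f"domain length must be positive, got {L}")
    if n_nodes < 10:
        raise ConfigurationError(f"need at least 10 nodes, got {n_nodes}")
    if not refinement_factor >= 1.0:
        raise ConfigurationError("refinement_factor must be >= 1")
    m = n_nodes - 1
    if refinement_factor == 1.0:
        z = np.linspace(0.0, L, n_nodes)
    else:
        g = float(refinement_factor)
        w0 = L * (g - 1.0) / (g**m - 1.0)
        widths = w0 * g ** np.arange(m)
        z = np.concatenate([[0.0], np.cumsum(widths)])
        z[-1] = L  # kill accumulated round-off
    return Grid(node_depths=z)
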