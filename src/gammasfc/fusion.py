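"""Gamma fusion of binarized population structural and functional matrices.

A single parameter gamma in [0, 1] interpolates between pure structure and
pure function::

    gammaSFC = gamma * FC_p + (1 - gamma) * SC_p

applied to the binary, density-matched population pair, so every off-diagonal
entry is one of {0, gamma, 1 - gamma, 1}: a link in neither matrix, in FC
only, in SC only, or in both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError
from .population import PopulationPair

#: gamma values swept by default: 0.0, 0.1, ..., 1.0
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))

__all__ = ["FusedMatrix", "fuse", "gamma_grid", "DEFAULT_GAMMA_GRID"]


@dataclass
class FusedMatrix:
    """gamma-fused structure-function matrix over an ordered node list."""

    gamma: float
    node_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.node_ids)
        if v.shape != (n, n):
            raise ValidationError(f"fused matrix shape {v.shape} for {n} nodes")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


def fuse(pair: PopulationPair, gamma: float) -> FusedMatrix:
    """Fuse a binary population pair at one gamma.

    gamma = 0 returns the structural matrix exactly, gamma = 1 the functional
    one; intermediate values weight FC-only links by gamma and SC-only links
    by 1 - gamma (links in both stay 1).
    """
    if not (0.0 <= gamma <= 1.0):
        raise ParameterError(f"gamma={gamma} outside [0, 1]")
    values = gamma * pair.fc_bin.values + (1.0 - gamma) * pair.sc_bin.values
    return FusedMatrix(gamma=float(gamma), node_ids=list(pair.node_ids), values=values)


def gamma_grid(
    pair: PopulationPair, gammas: list[float] | tuple[float, ...] = DEFAULT_GAMMA_GRID
) -> list[FusedMatrix]:
    """One fused matrix per gamma, in input order."""
    gammas = list(gammas)
    if not gammas:
        raise ParameterError("empty gamma grid")
    for g in gammas:
        if not (0.0 <= g <= 1.0):
            raise ParameterError(f"gamma={g} outside [0, 1]")
    return [fuse(pair, g) for g in gammas]
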