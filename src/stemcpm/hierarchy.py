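"""Cell-fate rules of the cancer-stem-cell hierarchy.

The tumor is driven by three cell types:

* CSC — cancer stem cell; divides indefinitely, self-renews with
  probability ``psi`` (two CSCs) or divides asymmetrically with
  probability ``1 - psi`` (the original CSC plus a fresh TAC).
  Symmetric differentiation (CSC -> two TACs) never occurs: there is
  no homeostatic pressure in a tumor.
* TAC — transit amplifying cell; divides at most ``G`` times. Each TAC
  division yields two TACs with the generation counter incremented;
  a TAC reaching counter ``G`` becomes a DC.
* DC — differentiated cell; quiescent, occupies space, may die by
  apoptosis, never grows or divides.

Setting ``psi = 1`` recovers the classical, non-hierarchical model in
which every cell is clonogenic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = ["CellType", "FateRule", "daughter_fates", "is_quiescent", "csc_fraction"]


class CellType(IntEnum):
    CSC = 0
    TAC = 1
    DC = 2


@dataclass(frozen=True)
class FateRule:
    """Parameters of the hierarchy: self-renewal probability and TAC depth."""

    psi: float = 0.1
    max_tac_divisions: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError(f"psi must lie in [0, 1], got {self.psi}")
        if self.max_tac_divisions < 0:
            raise ValueError("max_tac_divisions must be >= 0")


@dataclass(frozen=True)
class Fate:
    """Cell type plus TAC generation counter assigned at a division."""

    cell_type: CellType
    divisions_used: int = 0


def daughter_fates(
    parent_type: CellType,
    divisions_used: int,
    rule: FateRule,
    rng: np.random.Generator,
) -> tuple[Fate, Fate]:
    """Assign fates to the two offspring of one division.

    Returns ``(fate_mother, fate_daughter)``. A CSC parent self-renews
    into (CSC, CSC) with probability ``psi``, else spins off a TAC with
    counter 0. A TAC parent yields two TACs with counter ``g + 1``;
    a counter reaching ``G`` makes the cell a quiescent DC. DC parents
    cannot divide.
    """
    if parent_type == CellType.DC:
        raise ValueError("quiescent (DC) cells cannot divide")
    if parent_type == CellType.CSC:
        if rng.random() < rule.psi:
            return Fate(CellType.CSC), Fate(CellType.CSC)
        # G = 0 means a spun-off TAC is born already quiescent
        kind = CellType.DC if rule.max_tac_divisions == 0 else CellType.TAC
        return Fate(CellType.CSC), Fate(kind, 0)
    # TAC parent
    g = divisions_used + 1
    if g > rule.max_tac_divisions:
        raise ValueError("TAC has exhausted its divisions")
    kind = CellType.DC if g == rule.max_tac_divisions else CellType.TAC
    return Fate(kind, g), Fate(kind, g)


def is_quiescent(cell_type: CellType, divisions_used: int, rule: FateRule) -> bool:
    """True iff the cell can no longer divide (DC, i.e. TAC at counter G)."""
    return cell_type == CellType.DC or (
        cell_type == CellType.TAC and divisions_used >= rule.max_tac_divisions
    )


def csc_fraction(state) -> float:
    """CSC count over total live-cell count, in (0, 1].

    The observable that summarizes the effective population size of the
    hierarchy; identically 1 in the classical model (``psi = 1``).
    """
    n_live = state.n_live_cells()
    if n_live == 0:
        raise ValueError("empty tumor has no CSC fraction")
    return state.count_type(CellType.CSC) / n_live
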