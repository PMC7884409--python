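"""Shared container for bundled simulations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..equation_space import EquationSpaceField, TermSpec, assemble_equation_space

__all__ = ["SimulationResult"]


@dataclass
class SimulationResult:
    """Raw trajectory/field plus per-term arrays aligned with the equation.

    ``term_arrays`` maps term name -> (array, sign_convention, label); signs
    canonicalise the equation to implicit form, so the signed arrays sum to ~0
    at every point up to solver tolerance.
    """

    coords: np.ndarray  # (N, d) point locations (time, or space-time)
    states: dict  # raw state arrays keyed by variable name
    term_arrays: dict  # name -> (length-N array, sign, label)
    metadata: dict = field(default_factory=dict)

    def to_equation_space(self, term_names: list[str] | None = None) -> EquationSpaceField:
        """Assemble an :class:`EquationSpaceField` from (a subset of) the terms."""
        names = list(self.term_arrays) if term_names is None else list(term_names)
        arrays, specs = [], []
        for name in names:
            arr, sign, label = self.term_arrays[name]
            arrays.append(arr)
            specs.append(TermSpec(name=name, label=label, sign_convention=sign))
        return assemble_equation_space(arrays, specs, self.coords)
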