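"""Exactly solvable singular-perturbation fixture.

The two-point boundary-value problem

    eps * y'' + y' - 1 = 0,   y(0) = y(1) = 0,   0 < eps << 1

has the closed form  y = x - (1 - exp(-x/eps)) / (1 - exp(-1/eps))  and a
textbook inner/outer structure: a boundary layer of width O(eps) at x = 0
where the second-derivative term balances y', and an outer region where
y' balances the constant forcing.  The three terms are evaluated from the
closed-form solution, so the implicit form closes to floating-point error,
making this a deterministic end-to-end fixture with analytic ground truth.
"""

from __future__ import annotations

import numpy as np

from ..equation_space import EquationSpaceField, TermSpec

__all__ = ["analytic_boundary_layer_fixture", "INNER", "OUTER"]

#: truth labels
OUTER, INNER = 0, 1


def analytic_boundary_layer_fixture(
    epsilon: float,
    n_points: int = 400,
) -> tuple[EquationSpaceField, np.ndarray]:
    """Equation-space data for the analytic layer problem with truth labels.

    Points are log-spaced toward x = 0 so the thin layer is resolved.  A point
    is labelled INNER when the magnitude of the eps*y'' term exceeds 10% of the
    largest term magnitude at that point, OUTER otherwise.
    """
    if not (0 < epsilon < 0.1):
        raise ValueError("epsilon must lie in (0, 0.1)")
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    x = np.geomspace(epsilon * 1e-2, 1.0, n_points)
    denom = 1.0 - np.exp(-1.0 / epsilon)
    expf = np.exp(-x / epsilon)
    # y = x - (1 - e^{-x/eps}) / denom
    yp = 1.0 - expf / (epsilon * denom)
    ypp = expf / (epsilon**2 * denom)
    terms = (
        TermSpec("eps_ypp", "ε y''"),
        TermSpec("yp", "y'"),
        TermSpec("const", "-1"),
    )
    arrays = np.column_stack([epsilon * ypp, yp, -np.ones_like(x)])
    field = EquationSpaceField(terms=terms, values=arrays, coords=x[:, None])
    scale = np.abs(arrays).max(axis=1)
    labels = np.where(np.abs(arrays[:, 0]) > 0.1 * scale, INNER, OUTER)
    return field, labels
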