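"""Equation-space representation of a governing equation.

A governing equation written in implicit form, ``sum_i f_i(u, u_x, ..., u_t, ...) = 0``,
maps every discretisation point of the domain to a K-vector whose coordinates are
the pointwise term evaluations.  A dominant balance is then a cluster of points
lying near an axis-aligned subspace: near-zero coordinates mark negligible terms.

This module builds and validates that representation: term specifications with a
sign convention that canonicalises the equation to implicit form, finite-difference
evaluation of derivative terms from raw gridded states, residual (closure) checks,
and row masking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import ConfigurationError, DimensionError, EmptyInputError

logger = logging.getLogger(__name__)

__all__ = [
    "TermSpec",
    "EquationSpaceField",
    "ResidualReport",
    "assemble_equation_space",
    "finite_difference",
    "residual_report",
    "apply_mask",
    "magnitude_mask",
    "db_mask",
    "reduce_complex_rows",
]


@dataclass(frozen=True)
class TermSpec:
    """One term of a governing equation.

    Parameters
    ----------
    name :
        Short unique identifier, e.g. ``"u_t"`` or ``"I_Na"``.
    label :
        Human-readable label; may contain math notation, e.g. ``"u u_x"``.
    sign_convention :
        +1 or -1 multiplier applied when the equation is moved to implicit form
        (all terms on one side, summing to ~0).
    """

    name: str
    label: str = ""
    sign_convention: int = 1

    def __post_init__(self) -> None:
        if self.sign_convention not in (+1, -1):
            raise ConfigurationError(
                f"sign_convention must be +1 or -1, got {self.sign_convention}"
            )
        if not self.label:
            object.__setattr__(self, "label", self.name)


@dataclass
class EquationSpaceField:
    """N points of a domain represented as K-vectors of term evaluations.

    ``values[j, i]`` is term i evaluated at point j, already multiplied by the
    term's sign convention so that each row sums to ~0 when the discretisation
    is consistent.  ``coords`` holds the space/time location of each point and
    ``mask`` flags points eligible for clustering.
    """

    terms: tuple[TermSpec, ...]
    values: np.ndarray  # (N, K) float64
    coords: np.ndarray  # (N, d) float64
    mask: np.ndarray = field(default=None)  # (N,) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 1:
            self.coords = self.coords[:, None]
        self.terms = tuple(self.terms)
        if self.values.ndim != 2:
            raise DimensionError("values must be a 2-D (N, K) array")
        n, k = self.values.shape
        if k < 2:
            raise ConfigurationError("a balance needs at least K = 2 terms")
        if len(self.terms) != k:
            raise DimensionError(
                f"{len(self.terms)} TermSpecs for {k} value columns"
            )
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"term names must be unique, got {names}")
        if self.coords.shape[0] != n:
            raise DimensionError("coords row count must equal values row count")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (n,):
            raise DimensionError("mask must be a length-N boolean array")

    # ---------------------------------------------------------------- helpers
    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @property
    def n_terms(self) -> int:
        return self.values.shape[1]

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    @property
    def term_labels(self) -> list[str]:
        return [t.label for t in self.terms]

    def masked_values(self) -> np.ndarray:
        """Rows eligible for clustering."""
        return self.values[self.mask]

    def masked_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def copy(self) -> "EquationSpaceField":
        return EquationSpaceField(
            terms=self.terms,
            values=self.values.copy(),
            coords=self.coords.copy(),
            mask=self.mask.copy(),
        )


@dataclass(frozen=True)
class ResidualReport:
    """Closure check of the implicit form: how far rows are from summing to zero."""

    per_point_residual: np.ndarray  # |sum_i f_i| on masked-in points
    normalized_residual: np.ndarray  # residual / max_i |f_i|, 0 where row is 0
    max_normalized: float


def assemble_equation_space(
    term_arrays: Sequence[np.ndarray],
    term_specs: Sequence[TermSpec],
    coords: np.ndarray,
    mask: np.ndarray | None = None,
) -> EquationSpaceField:
    """Stack per-term arrays into an :class:`EquationSpaceField`.

    Each array is multiplied by its term's ``sign_convention`` so the result is
    in implicit form.  Rows containing non-finite entries are masked out (with a
    logged warning) rather than rejected: boundary stencil artifacts are an
    expected nuisance in practice.
    """
    if len(term_arrays) != len(term_specs):
        raise DimensionError(
            f"{len(term_arrays)} term arrays but {len(term_specs)} term specs"
        )
    if len(term_arrays) < 2:
        raise ConfigurationError("a balance needs at least 2 terms")
    cols = [np.ravel(np.asarray(a, dtype=float)) for a in term_arrays]
    n = cols[0].size
    for spec, c in zip(term_specs, cols):
        if c.size != n:
            raise DimensionError(
                f"term '{spec.name}' has length {c.size}, expected {n}"
            )
    values = np.column_stack(
        [spec.sign_convention * c for spec, c in zip(term_specs, cols)]
    )
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    if mask is None:
        mask = np.ones(n, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool).copy()
        if mask.shape != (n,):
            raise DimensionError("mask length must match term array length")
    finite = np.isfinite(values).all(axis=1)
    n_bad = int((~finite & mask).sum())
    if n_bad:
        logger.warning("masking out %d rows with non-finite term values", n_bad)
    mask &= finite
    return EquationSpaceField(terms=tuple(term_specs), values=values, coords=coords, mask=mask)


# --------------------------------------------------------------------------- #
# finite differences
# --------------------------------------------------------------------------- #
def finite_difference(
    field_values: np.ndarray,
    axis: int,
    spacing: float,
    order: int = 1,
    periodic: bool = False,
) -> np.ndarray:
    """Second-order finite-difference derivative along one axis of a uniform grid.

    Interior points use central stencils; boundaries use one-sided
    second-order stencils, unless ``periodic`` wraps the axis so central
    stencils apply everywhere.

    Parameters
    ----------
    field_values : gridded array
    axis : axis along which to differentiate
    spacing : positive grid step
    order : derivative order, 1 or 2
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if order not in (1, 2):
        raise ValueError(f"derivative order must be 1 or 2, got {order}")
    f = np.asarray(field_values, dtype=float)
    n = f.shape[axis]
    if n < 5:
        raise DimensionError(f"axis length {n} < 5 is too short for the stencils")
    f = np.moveaxis(f, axis, 0)
    out = np.empty_like(f)
    h = float(spacing)

    if periodic:
        fp1, fm1 = np.roll(f, -1, axis=0), np.roll(f, 1, axis=0)
        if order == 1:
            out = (fp1 - fm1) / (2 * h)
        else:
            out = (fp1 - 2 * f + fm1) / h**2
        return np.moveaxis(out, 0, axis)

    if order == 1:
        out[1:-1] = (f[2:] - f[:-2]) / (2 * h)
        out[0] = (-3 * f[0] + 4 * f[1] - f[2]) / (2 * h)
        out[-1] = (3 * f[-1] - 4 * f[-2] + f[-3]) / (2 * h)
    else:
        out[1:-1] = (f[2:] - 2 * f[1:-1] + f[:-2]) / h**2
        out[0] = (2 * f[0] - 5 * f[1] + 4 * f[2] - f[3]) / h**2
        out[-1] = (2 * f[-1] - 5 * f[-2] + 4 * f[-3] - f[-4]) / h**2
    return np.moveaxis(out, 0, axis)


# --------------------------------------------------------------------------- #
# residuals and masking
# --------------------------------------------------------------------------- #
def residual_report(esf: EquationSpaceField) -> ResidualReport:
    """Check closure of the implicit form on masked-in points.

    The per-point residual is ``|sum_i f_i|``; the normalised residual divides
    by the row's max |f_i| (0 for all-zero rows), so it measures imbalance
    relative to the locally dominant term.
    """
    if not esf.mask.any():
        raise EmptyInputError("all points are masked out; nothing to report")
    v = esf.masked_values()
    res = np.abs(v.sum(axis=1))
    scale = np.abs(v).max(axis=1)
    norm = np.divide(res, scale, out=np.zeros_like(res), where=scale > 0)
    report = ResidualReport(
        per_point_residual=res,
        normalized_residual=norm,
        max_normalized=float(norm.max()),
    )
    logger.info(
        "residual closure: max normalized %.3e over %d points",
        report.max_normalized,
        v.shape[0],
    )
    return report


def apply_mask(
    esf: EquationSpaceField,
    predicate: Callable[[np.ndarray, np.ndarray], np.ndarray],
) -> EquationSpaceField:
    """Return a copy of ``esf`` with the mask ANDed with ``predicate(coords, values)``.

    The predicate receives the full coords and values arrays and must return a
    length-N boolean array.  The input field is untouched.
    """
    keep = np.asarray(predicate(esf.coords, esf.values))
    if keep.dtype != np.bool_:
        raise TypeError(
            f"mask predicate must return a boolean array, got dtype {keep.dtype}"
        )
    if keep.shape != (esf.n_points,):
        raise DimensionError("predicate must return one boolean per point")
    out = esf.copy()
    out.mask &= keep
    return out


def magnitude_mask(threshold: float) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Predicate keeping rows whose max |f_i| is at least ``threshold``."""

    def predicate(coords: np.ndarray, values: np.ndarray) -> np.ndarray:
        return np.abs(values).max(axis=1) >= threshold

    return predicate


def db_mask(db_below_peak: float) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Predicate keeping rows within ``db_below_peak`` dB of the peak row amplitude.

    Row amplitude is max |f_i|; a row passes when
    ``20 log10(amplitude / peak) >= -db_below_peak``.
    """

    def predicate(coords: np.ndarray, values: np.ndarray) -> np.ndarray:
        amp = np.abs(values).max(axis=1)
        peak = amp.max()
        if peak == 0:
            return np.zeros(values.shape[0], dtype=bool)
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(amp / peak)
        return db >= -db_below_peak

    return predicate


def reduce_complex_rows(complex_values: np.ndarray) -> np.ndarray:
    """Reduce complex term rows to real coordinates (experimental).

    Each row is multiplied by the unit conjugate phase of its largest-magnitude
    term and the real part is taken, preserving the dominant term's magnitude.
    Off by default everywhere; phase information orthogonal to the dominant
    term is discarded, which can distort clustering.
    """
    z = np.asarray(complex_values, dtype=complex)
    if z.ndim != 2:
        raise DimensionError("expected a 2-D complex array")
    idx = np.abs(z).argmax(axis=1)
    lead = z[np.arange(z.shape[0]), idx]
    mag = np.abs(lead)
    phase = np.divide(np.conj(lead), mag, out=np.ones_like(lead), where=mag > 0)
    return np.real(z * phase[:, None])
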