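"""Planted-balance generator: ground-truth subspace clusters in equation space.

Emulates the geometric premise of balance identification: each regime is a
point cloud concentrated on an axis-aligned subspace of equation space whose
active coordinates nearly cancel (implicit form), with near-zero variance in
the negligible directions plus small isotropic noise.
"""

from __future__ import annotations

import numpy as np

from ..equation_space import EquationSpaceField, TermSpec

__all__ = ["generate_planted_balance"]


def generate_planted_balance(
    patterns: list[set | tuple | list],
    points_per_pattern: int,
    K: int,
    noise_sigma: float,
    seed: int = 0,
) -> tuple[EquationSpaceField, np.ndarray]:
    """Sample labelled equation-space points lying on planted balance subspaces.

    For each pattern (a set of >= 2 term indices), the active coordinates are
    drawn from a zero-mean anisotropic Gaussian of unit overall scale with the
    last active coordinate set to minus the sum of the others, so every sample
    satisfies the implicit form exactly before noise.  Independent Gaussian
    noise of standard deviation ``noise_sigma`` is then added to ALL K
    coordinates, filling the negligible directions with small variance.

    Returns
    -------
    (field, labels) :
        ``field.coords`` is simply the sample index; ``labels[j]`` is the index
        into ``patterns`` that generated point j.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    norm_patterns = []
    for p in patterns:
        p = tuple(sorted(int(i) for i in p))
        if len(p) < 2:
            raise ValueError(f"pattern {p} has fewer than 2 terms")
        if p[-1] >= K or p[0] < 0:
            raise ValueError(f"pattern {p} has indices outside 0..{K - 1}")
        norm_patterns.append(p)

    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for li, pat in enumerate(norm_patterns):
        p = len(pat)
        block = np.zeros((points_per_pattern, K))
        # anisotropic spread across the free active coordinates, unit scale
        stds = np.linspace(1.25, 0.75, p - 1)
        free = rng.normal(scale=stds, size=(points_per_pattern, p - 1))
        block[:, pat[:-1]] = free
        block[:, pat[-1]] = -free.sum(axis=1)
        blocks.append(block)
        labels.append(np.full(points_per_pattern, li))
    values = np.vstack(blocks)
    if noise_sigma > 0:
        values = values + rng.normal(scale=noise_sigma, size=values.shape)
    labels = np.concatenate(labels)
    terms = tuple(TermSpec(name=f"f{i}", label=f"f_{i}") for i in range(K))
    coords = np.arange(values.shape[0], dtype=float)[:, None]
    field = EquationSpaceField(terms=terms, values=values, coords=coords)
    return field, labels
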