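"""Independent verification of identified balances.

The pipeline's output can be checked against definitions that do not share any
machinery with it: a brute-force enumeration of minimal term subsets whose
complement is negligible, neglected-term magnitude ratios against random sets
of equal size, planted-truth recovery metrics, and a spurious-term probe that
augments the equation space with a noise column and checks it is never
selected as active.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .equation_space import EquationSpaceField, TermSpec
from .exceptions import DimensionError, SizeError
from .pipeline import BalanceModel, BalanceSegmentation

logger = logging.getLogger(__name__)

__all__ = [
    "OracleResult",
    "BalanceQuality",
    "RecoveryReport",
    "brute_force_oracle",
    "oracle_active_sets",
    "balance_quality",
    "recovery_metrics",
    "spurious_term_probe",
]


@dataclass(frozen=True)
class OracleResult:
    """All minimal term subsets that balance one equation-space row."""

    point_index: int
    minimal_sets: tuple[tuple[int, ...], ...]
    tolerance: float
    degenerate: bool = False


@dataclass(frozen=True)
class BalanceQuality:
    """Per-model neglected-term ratios and retained-magnitude fractions."""

    per_model_neglected_ratio: dict  # label -> mean |sum of neglected| / max|f|
    per_model_neglected_magnitude: dict  # label -> mean sum|neglected| / max|f|
    per_model_retained_fraction: dict  # label -> mean sum|active| / sum|all|
    per_model_random_median: dict  # label -> median magnitude ratio, random sets
    beats_random: dict  # label -> bool


@dataclass(frozen=True)
class RecoveryReport:
    """Agreement between a planted ground truth and a recovered segmentation."""

    exact_pattern_match: bool
    label_accuracy: float  # under optimal pattern matching
    ari: float
    matched_pairs: tuple  # ((truth_pattern, recovered_pattern), ...)


# --------------------------------------------------------------------------- #
# brute-force minimal-subset oracle
# --------------------------------------------------------------------------- #
def brute_force_oracle(
    row: np.ndarray,
    delta: float,
    point_index: int = -1,
    min_terms: int = 2,
) -> OracleResult:
    """Enumerate the minimal term subsets that balance one row.

    A subset S (|S| >= ``min_terms``) is accepted when (a) the neglected
    terms nearly cancel: ``|sum_{i not in S} row_i| <= delta * max_i
    |row_i|``, and (b) S contains the row's dominant (largest-magnitude)
    term — a set of tiny terms whose large complement happens to cancel is
    not a *dominant* balance.  All accepted sets of the minimal accepted
    cardinality are returned.  Cost is 2^K, so K is capped at 16.
    """
    row = np.asarray(row, dtype=float).ravel()
    k = row.size
    if k > 16:
        raise SizeError(f"K = {k} > 16: subset enumeration is 2^K")
    if not (0 < delta <= 1):
        raise ValueError(f"delta must lie in (0, 1], got {delta}")
    scale = np.abs(row).max()
    if scale == 0:
        return OracleResult(
            point_index=point_index,
            minimal_sets=(tuple(range(k)),),
            tolerance=delta,
            degenerate=True,
        )
    dominant = set(np.flatnonzero(np.abs(row) == scale).tolist())
    total = row.sum()
    accepted: list[tuple[int, ...]] = []
    for size in range(min_terms, k + 1):
        for s in combinations(range(k), size):
            if not dominant.intersection(s):
                continue
            neglected = total - row[list(s)].sum()
            if abs(neglected) <= delta * scale:
                accepted.append(s)
        if accepted:
            break
    if not accepted:  # only the full set remains (its complement sums to 0)
        accepted = [tuple(range(k))]
    return OracleResult(
        point_index=point_index,
        minimal_sets=tuple(accepted),
        tolerance=delta,
    )


def oracle_active_sets(values: np.ndarray, delta: float = 0.1) -> list[OracleResult]:
    """Row-wise brute-force oracle over an (N, K) matrix."""
    return [brute_force_oracle(r, delta, point_index=i) for i, r in enumerate(values)]


# --------------------------------------------------------------------------- #
# quality of identified balances
# --------------------------------------------------------------------------- #
def balance_quality(
    esf: EquationSpaceField,
    segmentation: BalanceSegmentation,
    balance_models: list[BalanceModel],
    n_random: int = 100,
    seed: int = 0,
) -> BalanceQuality:
    """Neglected-term ratio per model, benchmarked against random term sets.

    Two neglected-term statistics are reported per model with active set S,
    both averaged over the model's member points and normalised by the row's
    dominant magnitude: the *residual* ratio ``|sum_{i not in S} f_i| /
    max_i |f_i|`` (how much dropping the complement perturbs the equation)
    and the *magnitude* ratio ``sum_{i not in S} |f_i| / max_i |f_i|`` (how
    big the dropped terms are individually — immune to accidental
    cancellation inside the complement).  An informative balance must at
    least beat the median magnitude ratio of random active sets of equal
    size.
    """
    if segmentation.labels.shape[0] != esf.n_points:
        raise DimensionError("segmentation and field have different N")
    rng = np.random.default_rng(seed)
    k = esf.n_terms
    neg_ratio, neg_mag, retained, rand_median, beats = {}, {}, {}, {}, {}
    for m in balance_models:
        pts = esf.values[m.member_points]
        if pts.shape[0] == 0:
            logger.warning("balance model %d has no member points; skipped", m.label)
            continue
        scale = np.abs(pts).max(axis=1)
        scale[scale == 0] = 1.0

        def ratio_for(active: tuple[int, ...]) -> float:
            inactive = [i for i in range(k) if i not in active]
            if not inactive:
                return 0.0
            return float(np.mean(np.abs(pts[:, inactive].sum(axis=1)) / scale))

        def magnitude_for(active: tuple[int, ...]) -> float:
            inactive = [i for i in range(k) if i not in active]
            if not inactive:
                return 0.0
            return float(np.mean(np.abs(pts[:, inactive]).sum(axis=1) / scale))

        neg_ratio[m.label] = ratio_for(m.active_terms)
        neg_mag[m.label] = magnitude_for(m.active_terms)
        retained[m.label] = float(
            np.mean(
                np.abs(pts[:, list(m.active_terms)]).sum(axis=1)
                / np.abs(pts).sum(axis=1).clip(min=1e-300)
            )
        )
        p = len(m.active_terms)
        rand = [
            magnitude_for(tuple(rng.choice(k, size=p, replace=False)))
            for _ in range(n_random)
        ]
        rand_median[m.label] = float(np.median(rand))
        beats[m.label] = neg_mag[m.label] <= rand_median[m.label]
    return BalanceQuality(
        per_model_neglected_ratio=neg_ratio,
        per_model_neglected_magnitude=neg_mag,
        per_model_retained_fraction=retained,
        per_model_random_median=rand_median,
        beats_random=beats,
    )


# --------------------------------------------------------------------------- #
# planted-truth recovery
# --------------------------------------------------------------------------- #
def recovery_metrics(
    truth_labels: np.ndarray,
    truth_patterns: list,
    segmentation: BalanceSegmentation,
    balance_models: list[BalanceModel],
) -> RecoveryReport:
    """Compare a recovered segmentation with planted ground truth.

    Pattern labels are matched by maximising label agreement (Hungarian
    assignment on the confusion matrix), so the report is invariant to label
    permutations.
    """
    truth_labels = np.asarray(truth_labels)
    if truth_labels.shape[0] != segmentation.labels.shape[0]:
        raise DimensionError("truth and segmentation label lengths differ")
    truth_patterns = [tuple(sorted(int(i) for i in p)) for p in truth_patterns]
    found_patterns = [m.active_terms for m in balance_models]
    exact = set(truth_patterns) == set(found_patterns)

    keep = segmentation.labels >= 0
    t, r = truth_labels[keep], segmentation.labels[keep]
    n_t, n_r = len(truth_patterns), len(balance_models)
    conf = np.zeros((n_t, max(n_r, n_t)))
    for ti in range(n_t):
        for ri in range(n_r):
            conf[ti, ri] = np.sum((t == ti) & (r == ri))
    rows, cols = linear_sum_assignment(-conf)
    accuracy = float(conf[rows, cols].sum() / max(len(t), 1))
    pairs = tuple(
        (truth_patterns[ti], found_patterns[ci])
        for ti, ci in zip(rows, cols)
        if ci < n_r
    )
    return RecoveryReport(
        exact_pattern_match=bool(exact),
        label_accuracy=accuracy,
        ari=float(adjusted_rand_score(t, r)),
        matched_pairs=pairs,
    )


# --------------------------------------------------------------------------- #
# spurious-term detection
# --------------------------------------------------------------------------- #
def spurious_term_probe(
    esf: EquationSpaceField,
    seed: int = 0,
    spurious_column: np.ndarray | None = None,
    **fit_kwargs,
) -> dict:
    """Check that an irrelevant extra term is rejected by the pipeline.

    Augments the equation space with one extra column — seeded Gaussian noise
    scaled to the median term magnitude unless ``spurious_column`` is supplied
    — reruns the full identification, and reports whether the extra column
    enters any active set and how the residual closure changes.  A column that
    never enters an active set is "detected as spurious".  A supplied column
    that duplicates an existing active term will legitimately be selected;
    that collinearity caveat is logged rather than hidden.
    """
    from .model import DominantBalance  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    n, k = esf.values.shape
    if spurious_column is None:
        scale = np.median(np.abs(esf.values[esf.mask]))
        col = rng.normal(scale=scale if scale > 0 else 1.0, size=n)
    else:
        col = np.asarray(spurious_column, dtype=float).ravel()
        if col.size != n:
            raise DimensionError("spurious column length must be N")
    terms = esf.terms + (TermSpec("spurious", "spurious probe"),)
    values = np.column_stack([esf.values, col])
    aug = EquationSpaceField(terms=terms, values=values, coords=esf.coords, mask=esf.mask.copy())

    base_res = np.abs(esf.masked_values().sum(axis=1))
    aug_res = np.abs(aug.masked_values().sum(axis=1))

    res = DominantBalance(aug, **fit_kwargs).fit(seed=seed)
    spurious_idx = k
    entered = [m.label for m in res.balances if spurious_idx in m.active_terms]
    detected = len(entered) == 0
    if not detected:
        logger.warning(
            "probe column entered active sets of balance model(s) %s — likely "
            "collinear with a genuine term, not an independent spurious term",
            entered,
        )
    return {
        "detected_as_spurious": detected,
        "entered_balance_labels": entered,
        "active_sets": [m.active_terms for m in res.balances],
        "residual_change": float(np.mean(aug_res) - np.mean(base_res)),
    }
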