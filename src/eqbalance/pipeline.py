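"""Core balance-identification pipeline: GMM -> sparse PCA -> merge -> segment.

Points in equation space that share a dominant balance concentrate near an
axis-aligned subspace: large covariance along the active terms, near-zero
variance along the negligible ones.  A Gaussian mixture model clusters the
point cloud; each cluster's leading principal component is then sparsified
with an l1 penalty so that its nonzero loadings name the cluster's active
terms.  Clusters sharing a sparsity pattern belong to the same balance regime
and are merged, and the domain is segmented by those merged models, with
1 - (posterior membership of the assigned regime) as a pointwise uncertainty.

Feature columns are deliberately NOT standardised by default: the method is
premised on the local, relative magnitudes of the terms, which per-column
scaling would erase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import SparsePCA
from sklearn.mixture import GaussianMixture

from .equation_space import EquationSpaceField
from .exceptions import (
    EqBalanceError,
    InsufficientDataError,
    SchemaError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterModel",
    "SparseDirection",
    "BalanceModel",
    "BalanceSegmentation",
    "fit_gmm",
    "select_n_clusters",
    "sparse_leading_component",
    "select_alpha",
    "extract_active_terms",
    "merge_balance_models",
    "segment_domain",
    "assign_new_points",
]

#: absolute tolerance below which a unit-normalised loading counts as zero
ZERO_TOL = 1e-8
#: diagonal regularisation of GMM covariances
REG_COVAR = 1e-6


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #
@dataclass
class ClusterModel:
    """A fitted Gaussian mixture over the masked-in equation-space points."""

    n_clusters: int
    weights: np.ndarray  # (n_clusters,), on the simplex
    means: np.ndarray  # (n_clusters, K)
    covariances: np.ndarray  # (n_clusters, K, K)
    responsibilities: np.ndarray  # (n_masked, n_clusters), row-stochastic
    point_indices: np.ndarray  # original row index of each masked-in point
    seed: int
    log_likelihood: float
    estimator: GaussianMixture = field(repr=False)

    def hard_assignment(self) -> np.ndarray:
        """Most-responsible cluster per masked-in point (ties -> lower index)."""
        return self.responsibilities.argmax(axis=1)


@dataclass
class SparseDirection:
    """Sparse approximation to one cluster's leading principal component."""

    cluster_id: int
    loadings: np.ndarray  # (K,), unit Euclidean norm when nonzero
    active_set: tuple[int, ...]  # sorted indices with |loading| > ZERO_TOL
    alpha: float


@dataclass
class BalanceModel:
    """One dominant-balance regime: an active-term set and its members."""

    active_terms: tuple[int, ...]  # sorted, 2 <= p <= K
    member_clusters: list[int]
    member_points: np.ndarray  # original row indices
    label: int

    @property
    def n_points(self) -> int:
        return int(self.member_points.size)


@dataclass
class BalanceSegmentation:
    """Per-point balance label (-1 for masked-out points) plus uncertainty.

    ``uncertainty = 1 - (summed posterior responsibility of the assigned
    balance model's clusters)``; masked-out points get 1.0.
    """

    labels: np.ndarray  # (N,) int
    uncertainty: np.ndarray  # (N,) float in [0, 1]


# --------------------------------------------------------------------------- #
# clustering
# --------------------------------------------------------------------------- #
def fit_gmm(
    esf: EquationSpaceField,
    n_clusters: int,
    seed: int = 0,
    n_init: int = 5,
) -> ClusterModel:
    """Fit a full-covariance Gaussian mixture to the masked-in points.

    Best of ``n_init`` EM restarts by log-likelihood; deterministic given
    ``seed``.  Rank-deficient clusters (the signature of a balance) are
    handled by diagonal covariance regularisation, never by failure.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    idx = esf.masked_indices()
    x = esf.values[idx]
    if x.shape[0] < 10 * n_clusters:
        raise InsufficientDataError(
            f"{x.shape[0]} masked-in points < 10 x {n_clusters} clusters"
        )
    gm = GaussianMixture(
        n_components=n_clusters,
        covariance_type="full",
        reg_covar=REG_COVAR,
        n_init=n_init,
        max_iter=500,
        random_state=seed,
    )
    gm.fit(x)
    resp = gm.predict_proba(x)
    return ClusterModel(
        n_clusters=n_clusters,
        weights=gm.weights_,
        means=gm.means_,
        covariances=gm.covariances_,
        responsibilities=resp,
        point_indices=idx,
        seed=seed,
        log_likelihood=float(gm.score(x) * x.shape[0]),
        estimator=gm,
    )


def select_n_clusters(
    esf: EquationSpaceField,
    candidate_range=range(1, 13),
    seed: int = 0,
    n_init: int = 5,
) -> int:
    """Pick the mixture size minimising BIC; ties break toward fewer clusters.

    Overestimating is benign — redundant clusters sharing a sparsity pattern
    are merged downstream — so BIC's mild preference for larger models is
    acceptable.
    """
    candidates = list(candidate_range)
    if not candidates:
        raise ValueError("candidate_range must be nonempty")
    x = esf.masked_values()
    table = []
    for k in candidates:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            reg_covar=REG_COVAR,
            n_init=n_init,
            max_iter=500,
            random_state=seed,
        )
        gm.fit(x)
        table.append((k, float(gm.bic(x))))
    for k, bic in table:
        logger.info("BIC(n_clusters=%d) = %.2f", k, bic)
    best_bic = min(b for _, b in table)
    # ties (within floating noise) resolve toward the smaller candidate
    for k, bic in sorted(table):
        if bic <= best_bic + 1e-9 * abs(best_bic):
            return k
    return min(table, key=lambda kb: kb[1])[0]  # pragma: no cover


# --------------------------------------------------------------------------- #
# sparse principal directions
# --------------------------------------------------------------------------- #
def _dense_leading_component(x: np.ndarray) -> np.ndarray:
    # uncentered second moment: balance subspaces pass through the origin
    moment = x.T @ x / max(x.shape[0], 1)
    w, v = np.linalg.eigh(moment)
    return v[:, -1]


def _normalise_sign(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    if norm == 0:
        return v
    v = v / norm
    lead = np.abs(v).argmax()
    return v if v[lead] > 0 else -v


def sparse_leading_component(
    cluster_points: np.ndarray,
    alpha: float,
    cluster_id: int = -1,
    seed: int = 0,
) -> SparseDirection:
    """l1-sparsified leading principal component of one cluster's points.

    The leading direction is taken of the *uncentered* second moment rather
    than the covariance: a dominant-balance cluster lies near an axis-aligned
    subspace through the origin, so a negligible term is one with small
    values, not merely small variance (a large constant term is very much
    active).  For zero-mean clusters the two notions coincide.  At
    ``alpha = 0`` this is an ordinary dense eigendecomposition (the iterative
    l1 solver is not meaningful without a penalty); for ``alpha > 0`` the
    cloud is symmetrised with its negation — which zeroes the mean while
    preserving second moments — and passed to the l1-penalised solver.
    Loadings are unit-normalised with the largest-magnitude entry made
    positive.

    ``alpha`` is a *per-sample* penalty: the cluster is pre-scaled by a single
    scalar (its overall RMS) and the solver's l1 weight is ``alpha`` times the
    sample count, so one value of ``alpha`` means the same degree of sparsity
    for clusters of very different sizes and magnitudes.  Scalar rescaling
    leaves directions unchanged.
    """
    x = np.asarray(cluster_points, dtype=float)
    m, k = x.shape
    if m < k:
        raise InsufficientDataError(f"{m} points < {k} terms: cannot fit SPCA")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    scale = float(np.sqrt(np.mean(x**2)))
    xs = x / scale if scale > 0 else x
    if alpha == 0 or scale == 0:
        v = _normalise_sign(_dense_leading_component(xs))
    else:
        z = np.vstack([xs, -xs])
        spca = SparsePCA(
            n_components=1,
            alpha=alpha * z.shape[0],
            ridge_alpha=0.01,
            method="lars",
            max_iter=2000,
            random_state=seed,
        )
        spca.fit(z)
        v = _normalise_sign(spca.components_[0])
    active = tuple(int(i) for i in np.flatnonzero(np.abs(v) > ZERO_TOL))
    return SparseDirection(cluster_id=cluster_id, loadings=v, active_set=active, alpha=float(alpha))


def _variance_along(x: np.ndarray, direction: np.ndarray) -> float:
    """Uncentered second moment of the projections onto ``direction``."""
    if np.linalg.norm(direction) == 0:
        return 0.0
    proj = x @ (direction / np.linalg.norm(direction))
    return float(np.mean(proj**2))


def select_alpha(
    cluster_points: np.ndarray,
    alpha_grid,
    eta: float = 0.05,
    cluster_id: int = -1,
    seed: int = 0,
) -> float:
    """Largest penalty whose sparse component still explains the variance.

    Returns the largest ``alpha`` in the grid whose sparse direction retains at
    least ``1 - eta`` of the variance explained by the dense leading component;
    if none qualifies (isotropic noise, say — no sparse direction captures the
    variance), the smallest alpha is returned and the cluster is flagged as
    having no dominant balance.
    """
    grid = sorted(float(a) for a in alpha_grid)
    if not grid:
        raise ValueError("alpha_grid must be nonempty")
    x = np.asarray(cluster_points, dtype=float)
    dense = sparse_leading_component(x, 0.0, cluster_id=cluster_id, seed=seed)
    var_dense = _variance_along(x, dense.loadings)
    trade_off = []
    chosen = None
    for a in reversed(grid):
        d = sparse_leading_component(x, a, cluster_id=cluster_id, seed=seed)
        var_a = _variance_along(x, d.loadings)
        frac = var_a / var_dense if var_dense > 0 else 0.0
        trade_off.append((a, len(d.active_set), frac))
        if chosen is None and frac >= 1.0 - eta:
            chosen = a
            break
    for a, nact, frac in trade_off:
        logger.info(
            "alpha=%.4g: %d active terms, variance fraction %.4f", a, nact, frac
        )
    if chosen is None:
        logger.info(
            "cluster %d: no sparse direction retains %.0f%% of leading variance; "
            "no dominant balance — falling back to smallest alpha",
            cluster_id,
            100 * (1 - eta),
        )
        chosen = grid[0]
    return float(chosen)


def extract_active_terms(
    direction: SparseDirection,
    zero_tol: float = ZERO_TOL,
    min_terms: int = 2,
    cluster_points: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[int, ...]:
    """Indices with |loading| > zero_tol, enforcing a minimum balance size.

    A single nonzero term cannot satisfy an implicit-form equation unless that
    term is itself ~0, so fewer than ``min_terms`` survivors trigger automatic
    halving of the l1 penalty and a re-fit (requires ``cluster_points``) until
    the active set is large enough.  The dense (alpha = 0) component of any
    full-rank cluster has K nonzero entries, so the loop terminates.
    """
    if zero_tol < 0:
        raise ValueError("zero_tol must be >= 0")
    active = tuple(int(i) for i in np.flatnonzero(np.abs(direction.loadings) > zero_tol))
    if len(active) >= min_terms:
        return active
    if cluster_points is None:
        raise InsufficientDataError(
            f"active set {active} smaller than min_terms={min_terms} and no "
            "cluster points supplied for an alpha-reduction re-fit"
        )
    alpha = direction.alpha
    while len(active) < min_terms:
        alpha = 0.0 if alpha < 1e-10 else alpha / 2.0
        logger.info(
            "cluster %d: %d active terms < %d, reducing alpha to %.3g and re-fitting",
            direction.cluster_id,
            len(active),
            min_terms,
            alpha,
        )
        refit = sparse_leading_component(
            cluster_points, alpha, cluster_id=direction.cluster_id, seed=seed
        )
        active = tuple(
            int(i) for i in np.flatnonzero(np.abs(refit.loadings) > zero_tol)
        )
        if alpha == 0.0:
            break
    if len(active) < min_terms:
        # dense component too sparse (data exactly on < min_terms axes):
        # keep the largest-magnitude loadings so a balance is still reported
        order = np.argsort(-np.abs(refit.loadings))
        active = tuple(sorted(int(i) for i in order[:min_terms]))
        logger.warning(
            "cluster %d: dense component has < %d nonzero loadings; "
            "falling back to the %d largest-magnitude terms",
            direction.cluster_id,
            min_terms,
            min_terms,
        )
    return tuple(sorted(active))


def direction_with_min_terms(
    cluster_points: np.ndarray,
    alpha: float,
    cluster_id: int,
    zero_tol: float = ZERO_TOL,
    min_terms: int = 2,
    seed: int = 0,
) -> SparseDirection:
    """Fit a sparse direction and enforce the minimum active-set size.

    Convenience wrapper combining :func:`sparse_leading_component` and
    :func:`extract_active_terms`; returns a direction whose ``active_set``
    honours ``min_terms``.
    """
    d = sparse_leading_component(cluster_points, alpha, cluster_id=cluster_id, seed=seed)
    active = extract_active_terms(
        d, zero_tol=zero_tol, min_terms=min_terms, cluster_points=cluster_points, seed=seed
    )
    if active != d.active_set:
        d = SparseDirection(
            cluster_id=cluster_id,
            loadings=d.loadings,
            active_set=tuple(sorted(active)),
            alpha=d.alpha,
        )
    return d


# --------------------------------------------------------------------------- #
# merging and segmentation
# --------------------------------------------------------------------------- #
def merge_balance_models(
    directions: list[SparseDirection],
    cluster_model: ClusterModel,
) -> list[BalanceModel]:
    """Group clusters sharing a sparsity pattern into single balance regimes.

    A mixture routinely needs more components than there are distinct balance
    regimes (the data are not actually Gaussian), so several clusters with the
    same active-term set are one physical regime.  Balance labels follow the
    lexicographic order of the active sets for reproducibility.
    """
    if len(directions) != cluster_model.n_clusters:
        raise EqBalanceError(
            f"{len(directions)} directions for {cluster_model.n_clusters} clusters"
        )
    assign = cluster_model.hard_assignment()
    groups: dict[tuple[int, ...], list[int]] = {}
    for d in directions:
        groups.setdefault(tuple(sorted(d.active_set)), []).append(d.cluster_id)
    models = []
    for label, pattern in enumerate(sorted(groups)):
        clusters = sorted(groups[pattern])
        member = np.isin(assign, clusters)
        models.append(
            BalanceModel(
                active_terms=pattern,
                member_clusters=clusters,
                member_points=cluster_model.point_indices[member],
                label=label,
            )
        )
    return models


def _segment(
    n_points: int,
    point_indices: np.ndarray,
    responsibilities: np.ndarray,
    balance_models: list[BalanceModel],
) -> BalanceSegmentation:
    n_clusters = responsibilities.shape[1]
    cluster_to_label = np.full(n_clusters, -1, dtype=int)
    for m in balance_models:
        for c in m.member_clusters:
            cluster_to_label[c] = m.label
    if (cluster_to_label < 0).any():
        missing = np.flatnonzero(cluster_to_label < 0).tolist()
        raise EqBalanceError(f"clusters {missing} not covered by any balance model")
    balance_resp = np.zeros((responsibilities.shape[0], len(balance_models)))
    for m in balance_models:
        balance_resp[:, m.label] = responsibilities[:, m.member_clusters].sum(axis=1)
    assign = responsibilities.argmax(axis=1)
    point_labels = cluster_to_label[assign]
    unc = 1.0 - balance_resp[np.arange(len(point_labels)), point_labels]
    labels = np.full(n_points, -1, dtype=int)
    uncertainty = np.ones(n_points, dtype=float)
    labels[point_indices] = point_labels
    uncertainty[point_indices] = np.clip(unc, 0.0, 1.0)
    return BalanceSegmentation(labels=labels, uncertainty=uncertainty)


def segment_domain(
    esf: EquationSpaceField,
    balance_models: list[BalanceModel],
    cluster_model: ClusterModel,
) -> BalanceSegmentation:
    """Label every point with the balance regime of its most-responsible cluster.

    Uncertainty is one minus the posterior probability (summed over the
    assigned regime's clusters) that the point belongs to that regime.
    Masked-out points get label -1 and uncertainty 1.
    """
    return _segment(
        esf.n_points,
        cluster_model.point_indices,
        cluster_model.responsibilities,
        balance_models,
    )


def assign_new_points(
    cluster_model: ClusterModel,
    balance_models: list[BalanceModel],
    new_esf: EquationSpaceField,
    term_names: list[str] | None = None,
) -> BalanceSegmentation:
    """Assign unseen points to existing balance regimes via GMM posteriors.

    A posterior evaluation only — no re-fit.  The new field must present the
    same terms in the same order (checked by name when ``term_names`` given).
    """
    if term_names is not None and new_esf.term_names != list(term_names):
        raise SchemaError(
            f"term mismatch: expected {list(term_names)}, got {new_esf.term_names}"
        )
    if new_esf.n_terms != cluster_model.means.shape[1]:
        raise SchemaError(
            f"new field has {new_esf.n_terms} terms, model expects "
            f"{cluster_model.means.shape[1]}"
        )
    idx = new_esf.masked_indices()
    x = new_esf.values[idx]
    degenerate = ~np.abs(x).max(axis=1).astype(bool)
    if degenerate.any():
        logger.warning(
            "%d near-degenerate (all-zero) rows assigned with full uncertainty "
            "caveat",
            int(degenerate.sum()),
        )
    resp = cluster_model.estimator.predict_proba(x)
    return _segment(new_esf.n_points, idx, resp, balance_models)
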