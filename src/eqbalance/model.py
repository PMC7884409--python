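"""Model/Results interface to dominant-balance identification.

:class:`DominantBalance` is built from an :class:`~eqbalance.equation_space.
EquationSpaceField` (or a DataFrame) and holds the hyperparameters;
:meth:`DominantBalance.fit` runs clustering, sparsification, merging and
segmentation and returns a :class:`DominantBalanceResults` carrying the
fitted mixture, the per-cluster sparse directions, the merged balance models,
the per-point segmentation with uncertainties, and a ``summary()`` table.

Example
-------
>>> field, truth = generate_planted_balance([{0, 1}, {2, 3}], 500, K=4,
...                                         noise_sigma=0.01, seed=0)
>>> res = DominantBalance(field).fit(seed=0)
>>> print(res.summary())
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from . import pipeline
from .equation_space import EquationSpaceField, TermSpec
from .exceptions import ConfigurationError
from .pipeline import (
    BalanceSegmentation,
    assign_new_points,
    fit_gmm,
    merge_balance_models,
    segment_domain,
    select_alpha,
    select_n_clusters,
)

logger = logging.getLogger(__name__)

__all__ = ["DominantBalance", "DominantBalanceResults"]

DEFAULT_ALPHA_GRID = tuple(float(a) for a in np.logspace(-5, -1, 9))


class DominantBalance:
    """Unsupervised identification of dominant-balance regimes.

    Parameters
    ----------
    field :
        Equation-space data (N points x K terms, in implicit form).
    n_clusters :
        Mixture size; ``None`` selects it by BIC over ``cluster_range``.
    cluster_range :
        Candidate mixture sizes for BIC selection (default 1..12).
    alpha :
        l1 penalty of the sparse principal component.  ``None`` selects a
        per-cluster value from ``alpha_grid`` (largest penalty retaining
        ``1 - eta`` of the dense leading variance).
    eta :
        Variance-loss budget for automatic alpha selection (default 0.05).
    zero_tol :
        |loading| threshold below which a term counts as inactive.
    min_terms :
        Minimum balance size; an implicit-form equation cannot be satisfied
        by a single non-negligible term, so the default is 2.
    scale_columns :
        If True, standardise term columns before clustering.  Off by default:
        the method is premised on the local *relative* magnitude of terms,
        which global standardisation erases.  Turning this on changes the
        semantics of the analysis.
    """

    def __init__(
        self,
        field: EquationSpaceField,
        n_clusters: int | None = None,
        cluster_range=range(1, 13),
        alpha: float | None = None,
        alpha_grid=DEFAULT_ALPHA_GRID,
        eta: float = 0.05,
        zero_tol: float = pipeline.ZERO_TOL,
        min_terms: int = 2,
        scale_columns: bool = False,
    ) -> None:
        self.field = field
        self.n_clusters = n_clusters
        self.cluster_range = list(cluster_range)
        self.alpha = alpha
        self.alpha_grid = list(alpha_grid)
        self.eta = eta
        self.zero_tol = zero_tol
        self.min_terms = min_terms
        self.scale_columns = scale_columns
        if min_terms < 2:
            raise ConfigurationError("min_terms must be >= 2")

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        term_columns: list[str],
        coord_columns: list[str] | None = None,
        signs: list[int] | None = None,
        **kwargs,
    ) -> "DominantBalance":
        """Build the model from a tidy DataFrame of term evaluations."""
        signs = signs or [1] * len(term_columns)
        terms = tuple(
            TermSpec(name=c, sign_convention=s) for c, s in zip(term_columns, signs)
        )
        values = df[term_columns].to_numpy(dtype=float) * np.asarray(signs)
        if coord_columns:
            coords = df[coord_columns].to_numpy(dtype=float)
        else:
            coords = np.arange(len(df), dtype=float)[:, None]
        field = EquationSpaceField(terms=terms, values=values, coords=coords)
        return cls(field, **kwargs)

    # ------------------------------------------------------------------- fit
    def _working_field(self) -> tuple[EquationSpaceField, np.ndarray]:
        scale = np.ones(self.field.n_terms)
        if self.scale_columns:
            scale = self.field.masked_values().std(axis=0)
            scale[scale == 0] = 1.0
            logger.info("standardising term columns (semantics-altering option)")
            scaled = self.field.copy()
            scaled.values = scaled.values / scale
            return scaled, scale
        return self.field, scale

    def fit(self, seed: int = 0, n_init: int = 5) -> "DominantBalanceResults":
        """Run GMM -> sparse PCA -> merge -> segment; deterministic given seed."""
        work, col_scale = self._working_field()

        bic_table = None
        k = self.n_clusters
        if k is None:
            # reuse select_n_clusters but keep the score table for the results
            x = work.masked_values()
            from sklearn.mixture import GaussianMixture

            bic_table = {}
            for cand in self.cluster_range:
                gm = GaussianMixture(
                    n_components=cand,
                    covariance_type="full",
                    reg_covar=pipeline.REG_COVAR,
                    n_init=n_init,
                    max_iter=500,
                    random_state=seed,
                )
                gm.fit(x)
                bic_table[cand] = float(gm.bic(x))
            best = min(bic_table.values())
            k = min(c for c, b in bic_table.items() if b <= best + 1e-9 * abs(best))
            logger.info("BIC selected n_clusters = %d", k)

        cm = fit_gmm(work, k, seed=seed, n_init=n_init)
        assign = cm.hard_assignment()
        x = work.masked_values()

        directions, alphas = [], {}
        for c in range(cm.n_clusters):
            pts = x[assign == c]
            if pts.shape[0] < max(work.n_terms, 10):
                # tiny cluster: take its most-responsible points so SPCA is posed
                top = np.argsort(-cm.responsibilities[:, c])[: max(work.n_terms, 10)]
                pts = x[top]
                logger.info(
                    "cluster %d has few hard-assigned points; using top "
                    "responsibilities for SPCA",
                    c,
                )
            a = self.alpha
            if a is None:
                a = select_alpha(pts, self.alpha_grid, eta=self.eta, cluster_id=c, seed=seed)
            alphas[c] = float(a)
            directions.append(
                pipeline.direction_with_min_terms(
                    pts, a, cluster_id=c,
                    zero_tol=self.zero_tol, min_terms=self.min_terms, seed=seed,
                )
            )

        balances = merge_balance_models(directions, cm)
        seg = segment_domain(work, balances, cm)
        return DominantBalanceResults(
            model=self,
            cluster_model=cm,
            directions=directions,
            balances=balances,
            segmentation=seg,
            alphas=alphas,
            bic_table=bic_table,
            seed=seed,
            column_scale=col_scale,
        )


class DominantBalanceResults:
    """Fitted dominant-balance decomposition of an equation-space field."""

    def __init__(
        self,
        model: DominantBalance,
        cluster_model,
        directions,
        balances,
        segmentation: BalanceSegmentation,
        alphas: dict,
        bic_table: dict | None,
        seed: int,
        column_scale: np.ndarray,
    ) -> None:
        self.model = model
        self.field = model.field
        self.cluster_model = cluster_model
        self.directions = directions
        self.balances = balances
        self.segmentation = segmentation
        self.alphas = alphas
        self.bic_table = bic_table
        self.seed = seed
        self.column_scale = column_scale

    # ------------------------------------------------------------- reporting
    @property
    def labels(self) -> np.ndarray:
        return self.segmentation.labels

    @property
    def uncertainty(self) -> np.ndarray:
        return self.segmentation.uncertainty

    @property
    def active_sets(self) -> list[tuple[int, ...]]:
        return [m.active_terms for m in self.balances]

    def active_term_names(self, label: int) -> list[str]:
        names = self.field.term_names
        return [names[i] for i in self.balances[label].active_terms]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        n_in = int(self.field.mask.sum())
        for m in self.balances:
            sel = self.segmentation.labels == m.label
            rows.append(
                {
                    "balance": m.label,
                    "active_terms": " + ".join(self.active_term_names(m.label)),
                    "n_points": m.n_points,
                    "fraction": m.n_points / max(n_in, 1),
                    "n_clusters": len(m.member_clusters),
                    "mean_uncertainty": float(self.segmentation.uncertainty[sel].mean())
                    if sel.any()
                    else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("balance")

    def summary(self) -> str:
        """Human-readable fit summary."""
        df = self.summary_frame()
        lines = [
            "Dominant balance identification",
            "=" * 64,
            f"points: {int(self.field.mask.sum())} masked-in of {self.field.n_points}"
            f" | terms (K): {self.field.n_terms}",
            f"GMM clusters: {self.cluster_model.n_clusters}"
            f" (seed {self.seed}, log-likelihood {self.cluster_model.log_likelihood:.1f})",
            f"balance models: {len(self.balances)}",
            "-" * 64,
            df.to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------ prediction
    def predict(self, new_field: EquationSpaceField) -> BalanceSegmentation:
        """Assign unseen equation-space points to the fitted balance regimes."""
        work = new_field
        if self.model.scale_columns:
            work = new_field.copy()
            work.values = work.values / self.column_scale
        return assign_new_points(
            self.cluster_model, self.balances, work, term_names=self.field.term_names
        )

    # --------------------------------------------------------------- exports
    def to_json_dict(self) -> dict:
        return {
            "balance_models": [
                {
                    "label": m.label,
                    "active_term_names": self.active_term_names(m.label),
                    "active_terms": list(m.active_terms),
                    "n_points": m.n_points,
                    "member_clusters": list(m.member_clusters),
                }
                for m in self.balances
            ],
            "gmm": {
                "n_clusters": self.cluster_model.n_clusters,
                "seed": self.seed,
                "log_likelihood": self.cluster_model.log_likelihood,
                "bic_table": self.bic_table,
            },
            "spca_alphas": self.alphas,
            "term_names": self.field.term_names,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)

    def save_segmentation_csv(self, path) -> None:
        d = self.field.coords.shape[1]
        df = pd.DataFrame(
            {
                "point": np.arange(self.field.n_points),
                **{f"coord_{i}": self.field.coords[:, i] for i in range(d)},
                "label": self.segmentation.labels,
                "uncertainty": self.segmentation.uncertainty,
            }
        )
        df.to_csv(path, index=False)

    def save_segmentation_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("labels", data=self.segmentation.labels)
            fh.create_dataset("uncertainty", data=self.segmentation.uncertainty)
            fh.create_dataset("coords", data=self.field.coords)

    def plot(self, ax=None, **kwargs):
        """Render the segmentation (1-D trace or 2-D map)."""
        from .plotting import render_segmentation

        return render_segmentation(
            self.segmentation,
            self.field.coords,
            legend_names=[" + ".join(self.active_term_names(m.label)) for m in self.balances],
            ax=ax,
            **kwargs,
        )
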