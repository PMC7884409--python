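"""Segmentation figures: domain coloured by local dominant balance."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # noqa: E402 — headless rendering
import matplotlib.pyplot as plt
import numpy as np

from .exceptions import EmptyInputError
from .pipeline import BalanceSegmentation

__all__ = ["render_segmentation"]


def render_segmentation(
    segmentation: BalanceSegmentation,
    coords: np.ndarray,
    legend_names: list[str] | None = None,
    values: np.ndarray | None = None,
    ax=None,
    cmap: str = "tab10",
    point_size: float = 4.0,
):
    """Colour the domain by balance label.

    1-D coords: a trace (of ``values`` if given, else the label itself)
    coloured per-point by balance.  2-D coords: a coloured scatter over
    (coord_0, coord_1).  Higher-dimensional coords are not supported — slice
    the data first.
    """
    labels = segmentation.labels
    keep = labels >= 0
    if not keep.any():
        raise EmptyInputError("segmentation has no labelled points to render")
    coords = np.asarray(coords)
    if coords.ndim == 1:
        coords = coords[:, None]
    d = coords.shape[1]
    if d > 2:
        raise ValueError(
            f"coords have d = {d} > 2; slice to 1-D or 2-D before rendering"
        )
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    colors = plt.get_cmap(cmap)
    uniq = np.unique(labels[keep])
    for lab in uniq:
        sel = labels == lab
        name = (
            legend_names[lab]
            if legend_names is not None and lab < len(legend_names)
            else f"balance {lab}"
        )
        c = colors(int(lab) % 10)
        if d == 1:
            y = values[sel] if values is not None else np.zeros(sel.sum()) + lab
            ax.scatter(coords[sel, 0], y, s=point_size, color=c, label=name)
        else:
            ax.scatter(coords[sel, 0], coords[sel, 1], s=point_size, color=c, label=name)
    ax.legend(loc="best", fontsize=8, markerscale=3)
    ax.set_xlabel("coord_0")
    ax.set_ylabel("value" if (d == 1 and values is not None) else ("balance" if d == 1 else "coord_1"))
    return ax
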