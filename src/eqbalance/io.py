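"""Reading and writing equation-space fields.

HDF5 layout: datasets ``/values`` (N x K float64), ``/coords`` (N x d),
``/mask`` (N uint8); attributes ``term_names`` (ordered strings) and
``term_signs`` (ints).  CSV fallback: one row per point with columns
``coord_0..coord_{d-1}`` followed by one column per term name; the mask is
implicit (all rows kept).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .equation_space import EquationSpaceField, TermSpec
from .exceptions import SchemaError

__all__ = ["save_field_hdf5", "load_field_hdf5", "save_field_csv", "load_field_csv", "load_field"]


def save_field_hdf5(esf: EquationSpaceField, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=esf.values.astype(np.float64))
        fh.create_dataset("coords", data=esf.coords.astype(np.float64))
        fh.create_dataset("mask", data=esf.mask.astype(np.uint8))
        fh.attrs["term_names"] = esf.term_names
        fh.attrs["term_labels"] = esf.term_labels
        fh.attrs["term_signs"] = [t.sign_convention for t in esf.terms]


def load_field_hdf5(path) -> EquationSpaceField:
    with h5py.File(path, "r") as fh:
        for key in ("values", "coords", "mask"):
            if key not in fh:
                raise SchemaError(f"missing dataset '/{key}' in {path}")
        if "term_names" not in fh.attrs:
            raise SchemaError(f"missing attribute 'term_names' in {path}")
        values = fh["values"][...]
        coords = fh["coords"][...]
        mask = fh["mask"][...].astype(bool)
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in fh.attrs["term_names"]]
        signs = [int(s) for s in fh.attrs.get("term_signs", [1] * len(names))]
        labels = fh.attrs.get("term_labels", names)
        labels = [l.decode() if isinstance(l, bytes) else str(l) for l in labels]
    terms = tuple(
        TermSpec(name=n, label=l, sign_convention=s)
        for n, l, s in zip(names, labels, signs)
    )
    # values on disk are already in implicit form; sign conventions are metadata
    return EquationSpaceField(terms=terms, values=values, coords=coords, mask=mask)


def save_field_csv(esf: EquationSpaceField, path) -> None:
    d = esf.coords.shape[1]
    data = {f"coord_{i}": esf.coords[:, i] for i in range(d)}
    for j, name in enumerate(esf.term_names):
        data[name] = esf.values[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def load_field_csv(path) -> EquationSpaceField:
    df = pd.read_csv(path)
    coord_cols = sorted(
        (c for c in df.columns if c.startswith("coord_")),
        key=lambda c: int(c.split("_")[1]),
    )
    term_cols = [c for c in df.columns if c not in coord_cols]
    if len(term_cols) < 2:
        raise SchemaError(f"{path}: found {len(term_cols)} term columns, need >= 2")
    coords = df[coord_cols].to_numpy(dtype=float) if coord_cols else \
        np.arange(len(df), dtype=float)[:, None]
    terms = tuple(TermSpec(name=c) for c in term_cols)
    return EquationSpaceField(
        terms=terms, values=df[term_cols].to_numpy(dtype=float), coords=coords
    )


def load_field(path) -> EquationSpaceField:
    """Dispatch on file extension (.h5/.hdf5 vs .csv)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return load_field_hdf5(path)
    if suffix == ".csv":
        return load_field_csv(path)
    raise SchemaError(f"unsupported input format '{suffix}' (expected .h5/.hdf5/.csv)")
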