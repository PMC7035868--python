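"""Minimal loom (v2/v3) reading and writing on top of h5py.

Loom files are plain HDF5 with a genes x cells main matrix at ``/matrix``,
per-gene arrays under ``/row_attrs`` and per-cell arrays under
``/col_attrs``. Only this subset is handled; graphs and layers are ignored.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError


def _decode(arr: np.ndarray) -> np.ndarray:
    if arr.dtype.kind in ("S", "O"):
        return np.array([x.decode() if isinstance(x, bytes) else str(x) for x in arr])
    return arr


def read_loom(path) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Return (matrix genes x cells, row_attrs, col_attrs)."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"{path} is not a readable HDF5/loom file: {exc}") from exc
    with f:
        if "matrix" not in f:
            raise FormatError(f"{path}: loom file without a /matrix dataset")
        matrix = f["matrix"][()]
        row_attrs = {k: _decode(f["row_attrs"][k][()]) for k in f.get("row_attrs", {})}
        col_attrs = {k: _decode(f["col_attrs"][k][()]) for k in f.get("col_attrs", {})}
    return matrix, row_attrs, col_attrs


def write_loom(path, matrix: np.ndarray, row_attrs: dict, col_attrs: dict) -> None:
    """Write a genes x cells matrix plus attributes as a loom file."""
    matrix = np.asarray(matrix)
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.attrs["LOOM_SPEC_VERSION"] = "3.0.0"
        f.create_dataset("matrix", data=matrix)
        for group, attrs, size in (
            ("row_attrs", row_attrs, matrix.shape[0]),
            ("col_attrs", col_attrs, matrix.shape[1]),
        ):
            g = f.create_group(group)
            for name, values in attrs.items():
                values = np.asarray(values)
                if len(values) != size:
                    raise ValueError(
                        f"{group}/{name}: {len(values)} values for axis of {size}"
                    )
                if values.dtype.kind in ("U", "O", "S"):
                    g.create_dataset(
                        name, data=[str(v) for v in values], dtype=str_dt
                    )
                else:
                    g.create_dataset(name, data=values)
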