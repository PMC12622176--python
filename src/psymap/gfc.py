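"""Functional connectivity and the global functional connectivity map.

From each subject's parcellated BOLD time-series we compute a parcel ×
parcel Pearson correlation (functional connectivity) matrix, reduce it to a
regional map by averaging each parcel's correlations with all *other*
parcels — global functional connectivity (GFC) — and contrast group-mean
GFC maps (drug minus placebo) to get a pharmacological connectivity-change
map.

Self-correlations are excluded from the GFC mean; including the unit
diagonal would only shift and rescale the map, but exclusion is the
standard definition. No Fisher z-transform is applied by default (an
option exists), and no denoising is performed here — time-series are taken
as preprocessed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas
from .errors import AlignmentError, ZeroVarianceError
from .expression_maps import RegionalMap


@dataclass
class ConnectivityMatrix:
    """Parcel × parcel Pearson correlation matrix."""

    values: np.ndarray
    atlas: ParcelAtlas | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if self.atlas is not None and v.shape[0] != self.atlas.n_parcels:
            raise AlignmentError("matrix size does not match atlas")


def connectivity(bold: np.ndarray,
                 atlas: ParcelAtlas | None = None) -> ConnectivityMatrix:
    """Pearson correlation of every pair of parcel time-series.

    ``bold`` is timepoints × parcels; at least 3 timepoints are required
    and every parcel must have non-zero temporal variance.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 2 or bold.shape[0] < 3:
        raise ValueError("bold must be timepoints x parcels with >= 3 timepoints")
    sd = bold.std(axis=0)
    bad = np.flatnonzero(sd <= 1e-12 * max(1.0, float(np.abs(bold).max())))
    if bad.size:
        raise ZeroVarianceError(f"zero-variance parcel(s) at column(s) {bad[:5].tolist()}")
    C = np.corrcoef(bold, rowvar=False)
    C = np.clip((C + C.T) / 2, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return ConnectivityMatrix(values=C, atlas=atlas)


def global_fc(C: ConnectivityMatrix, fisher_z: bool = False) -> RegionalMap:
    """Per-parcel mean correlation with all other parcels (units: mean r).

    With ``fisher_z=True`` correlations are arctanh-transformed before
    averaging and the mean transformed back.
    """
    V = C.values.copy()
    np.fill_diagonal(V, np.nan)
    if fisher_z:
        with np.errstate(divide="ignore"):
            V = np.arctanh(np.clip(V, -1 + 1e-15, 1 - 1e-15))
        g = np.tanh(np.nanmean(V, axis=1))
    else:
        g = np.nanmean(V, axis=1)
    atlas = C.atlas
    if atlas is None:
        # a bare frame so the map is still a RegionalMap
        n = V.shape[0]
        atlas = ParcelAtlas(parcel_id=np.arange(1, n + 1),
                            hemisphere=np.array(["L"] * n, dtype=object),
                            network=np.array(["VN"] * n, dtype=object),
                            centroids=np.zeros((n, 3)))
    return RegionalMap(atlas, g, name="GFC")


def group_difference(group_a: list[RegionalMap],
                     group_b: list[RegionalMap]) -> RegionalMap:
    """Parcelwise mean(group A) - mean(group B) of per-subject GFC maps."""
    if not group_a or not group_b:
        raise ValueError("each group needs at least one subject map")
    ref = group_a[0].atlas
    for m in group_a + group_b:
        if not ref.same_frame(m.atlas):
            raise AlignmentError("all maps must share one atlas")
    ma = np.mean([m.values for m in group_a], axis=0)
    mb = np.mean([m.values for m in group_b], axis=0)
    return RegionalMap(ref, ma - mb, name="GFC difference")


def read_bold(path) -> np.ndarray:
    """Read one subject's time-series CSV (rows = timepoints, header = parcel ids)."""
    return pd.read_csv(path).to_numpy(dtype=float)


def write_bold(bold: np.ndarray, path, atlas: ParcelAtlas | None = None) -> None:
    cols = ([str(int(p)) for p in atlas.parcel_id] if atlas is not None
            else [str(i + 1) for i in range(bold.shape[1])])
    pd.DataFrame(np.asarray(bold), columns=cols).to_csv(
        path, index=False, float_format="%.17g")
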