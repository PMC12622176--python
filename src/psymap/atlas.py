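"""Cortical parcellation atlas.

A :class:`ParcelAtlas` is the spatial frame every map in the package lives
on: integer parcel labels, a hemisphere per parcel, one of the seven
canonical intrinsic networks, a 3-D centroid, and a flag for parcels that
lack expression data (in the human atlas 11 of the 200 Schaefer parcels
have no usable microarray samples and are excluded from every statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

#: Canonical seven intrinsic networks, fixed reporting order:
#: visual, somatomotor, dorsal attention, ventral attention, limbic,
#: frontoparietal, default mode.
NETWORKS: tuple[str, ...] = ("VN", "SMN", "DAN", "VAN", "LiN", "FPN", "DMN")


@dataclass
class ParcelAtlas:
    """Parcellation with hemisphere, network, centroid and missing flag.

    Parameters
    ----------
    parcel_id : (P,) int array of unique labels.
    hemisphere : (P,) array of ``"L"``/``"R"``.
    network : (P,) array of network labels (normally drawn from NETWORKS).
    centroids : (P, 3) float array of parcel centre coordinates. Units are
        arbitrary but must be consistent within the atlas; distances between
        centroids drive the spatial-null machinery.
    missing : (P,) bool array; True marks parcels without expression data.
    """

    parcel_id: np.ndarray
    hemisphere: np.ndarray
    network: np.ndarray
    centroids: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.parcel_id = np.asarray(self.parcel_id, dtype=int)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        self.network = np.asarray(self.network, dtype=object)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.parcel_id.size, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        p = self.parcel_id.size
        if np.unique(self.parcel_id).size != p:
            raise ValueError("parcel ids must be unique")
        if self.centroids.shape != (p, 3):
            raise ValueError(f"centroids must have shape ({p}, 3)")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        for arr, what in ((self.hemisphere, "hemisphere"), (self.network, "network"),
                          (self.missing, "missing")):
            if arr.shape != (p,):
                raise ValueError(f"{what} must have length {p}")
        if int((~self.missing).sum()) < 2:
            raise ValueError("need at least 2 non-missing parcels")

    @property
    def n_parcels(self) -> int:
        return int(self.parcel_id.size)

    @property
    def nonmissing(self) -> np.ndarray:
        """Boolean mask of parcels that carry data."""
        return ~self.missing

    def index_of(self, parcel_ids: np.ndarray) -> np.ndarray:
        """Row positions of the given parcel ids (raises KeyError if unknown)."""
        lookup = {int(p): i for i, p in enumerate(self.parcel_id)}
        try:
            return np.array([lookup[int(p)] for p in parcel_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"unknown parcel id {exc.args[0]}") from None

    def same_frame(self, other: "ParcelAtlas") -> bool:
        """True when both atlases index the same parcels in the same order."""
        return (self.n_parcels == other.n_parcels
                and bool(np.array_equal(self.parcel_id, other.parcel_id)))

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parcel_id": self.parcel_id,
            "hemisphere": self.hemisphere,
            "network": self.network,
            "x": self.centroids[:, 0],
            "y": self.centroids[:, 1],
            "z": self.centroids[:, 2],
            "missing": self.missing.astype(int),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ParcelAtlas":
        df = pd.read_csv(path)
        required = {"parcel_id", "hemisphere", "network", "x", "y", "z"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise SchemaError(f"atlas file missing columns: {sorted(missing_cols)}")
        miss = df["missing"].to_numpy(dtype=bool) if "missing" in df else None
        return cls(
            parcel_id=df["parcel_id"].to_numpy(),
            hemisphere=df["hemisphere"].to_numpy(),
            network=df["network"].to_numpy(),
            centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
            missing=miss,
        )
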