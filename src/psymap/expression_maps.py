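"""Parcellated gene expression matrices and regional maps.

The spatial substrate of the whole analysis is a parcels × genes matrix of
regional expression (the human atlas version is the abagen-processed Allen
Human Brain Atlas on the 200-parcel Schaefer parcellation: 15,634 genes on
189 of 200 parcels). Every gene column is standardised to z-scores over the
non-missing parcels, so gene maps, set-average maps and receptor maps all
share units and missing parcels are excluded from every statistic rather
than imputed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import NETWORKS, ParcelAtlas
from .errors import AlignmentError, SchemaError, ZeroVarianceError
from .gene_sets import GeneSet

log = logging.getLogger(__name__)

# z-scoring uses the sample SD (ddof=1), the convention of the upstream
# atlas-processing toolchain; the contract everywhere is mean 0, sd 1 over
# non-missing parcels.
_DDOF = 1


def _zscore_columns(values: np.ndarray, mask: np.ndarray,
                    genes) -> np.ndarray:
    sub = values[mask]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=_DDOF)
    bad = np.flatnonzero(~(sd > 0))
    if bad.size:
        raise ZeroVarianceError(
            f"zero-variance gene column(s): {[genes[i] for i in bad[:5]]}")
    out = np.full_like(values, np.nan, dtype=float)
    out[mask] = (sub - mean) / sd
    return out


@dataclass
class RegionalMap:
    """One value per parcel, aligned to an atlas.

    Units are inherited from the source: z-scores for expression maps,
    mean Pearson r for global-connectivity maps. Missing parcels hold NaN.
    """

    atlas: ParcelAtlas
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.atlas.n_parcels,):
            raise ValueError("map length must match atlas")

    @property
    def finite(self) -> np.ndarray:
        return np.isfinite(self.values)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["parcel_id", "value"])
            for pid, v in zip(self.atlas.parcel_id, self.values):
                w.writerow([int(pid), "" if not np.isfinite(v) else repr(float(v))])

    @classmethod
    def from_csv(cls, path, atlas: ParcelAtlas, name: str | None = None) -> "RegionalMap":
        df = pd.read_csv(path)
        if not {"parcel_id", "value"} <= set(df.columns):
            raise SchemaError("regional map file needs parcel_id,value columns")
        vals = np.full(atlas.n_parcels, np.nan)
        idx = atlas.index_of(df["parcel_id"].to_numpy())
        vals[idx] = df["value"].to_numpy(dtype=float)
        return cls(atlas, vals, name or str(path))


@dataclass
class ExpressionMatrix:
    """Parcels × genes z-scored expression, with a per-parcel missing mask."""

    atlas: ParcelAtlas
    genes: tuple[str, ...]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genes = tuple(str(g).strip().upper() for g in self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise SchemaError("duplicate gene symbols in expression matrix")
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = self.atlas.missing.copy()
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        P, G = self.atlas.n_parcels, len(self.genes)
        if self.values.shape != (P, G):
            raise ValueError(f"values must have shape ({P}, {G})")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValueError("non-missing rows contain non-finite values")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_parcels(self) -> int:
        return self.atlas.n_parcels

    @property
    def nonmissing(self) -> np.ndarray:
        return ~self.missing_mask

    def column(self, symbol: str) -> np.ndarray:
        sym = str(symbol).strip().upper()
        if sym not in self._index:
            near = [g for g in self.genes if g.startswith(sym[:3])][:5]
            raise KeyError(f"gene {sym!r} not in matrix; near matches: {near}")
        return self.values[:, self._index[sym]]

    def columns(self, symbols) -> np.ndarray:
        return np.column_stack([self.column(s) for s in symbols])

    def gene_set(self, name: str = "all") -> GeneSet:
        return GeneSet(name, self.genes)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        """Write `parcel_id,<gene>,<gene>,...`; missing parcels as empty fields."""
        df = pd.DataFrame(self.values, columns=list(self.genes))
        df.insert(0, "parcel_id", self.atlas.parcel_id)
        df.to_csv(path, index=False, float_format="%.17g")


def load_expression(path, atlas: ParcelAtlas) -> ExpressionMatrix:
    """Load a parcels × genes CSV and align it to the atlas.

    The first column must be ``parcel_id``; the remaining header fields are
    gene symbols. Rows are aligned by id (file row order is irrelevant);
    parcels absent from the file, or present with all-empty values, are
    marked missing. Columns are re-standardised to z-scores over the
    non-missing parcels, so the matrix has z-score semantics regardless of
    upstream scaling.
    """
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    if not header or header[0] != "parcel_id":
        raise SchemaError("expression file must start with a parcel_id column")
    genes = [g.strip().upper() for g in header[1:]]
    dupes = {g for g in genes if genes.count(g) > 1}
    if dupes:
        raise SchemaError(f"duplicate gene column(s): {sorted(dupes)}")

    df = pd.read_csv(path)
    df.columns = ["parcel_id"] + genes
    known = set(int(p) for p in atlas.parcel_id)
    unknown = [int(p) for p in df["parcel_id"] if int(p) not in known]
    if unknown:
        raise AlignmentError(f"expression file has unknown parcel ids: {unknown[:5]}")

    P = atlas.n_parcels
    values = np.full((P, len(genes)), np.nan)
    idx = atlas.index_of(df["parcel_id"].to_numpy())
    values[idx] = df[genes].to_numpy(dtype=float)
    present = np.zeros(P, dtype=bool)
    present[idx] = True
    # a row that is present but entirely empty also counts as missing
    mask = present & np.isfinite(values).all(axis=1)
    n_missing = int((~mask).sum())
    if n_missing:
        log.info("load_expression: %d of %d parcels missing expression", n_missing, P)
    values = _zscore_columns(values, mask, genes)
    return ExpressionMatrix(atlas=atlas, genes=tuple(genes), values=values,
                            missing_mask=~mask)


def gene_map(E: ExpressionMatrix, symbol: str) -> RegionalMap:
    """A single gene's z-scored regional expression as a map."""
    return RegionalMap(E.atlas, E.column(symbol).copy(), name=str(symbol).upper())


def set_average_map(E: ExpressionMatrix, s: GeneSet) -> RegionalMap:
    """Parcelwise arithmetic mean of the member genes' z-scored maps.

    Genes in ``s`` absent from the matrix are skipped (and logged); an
    empty intersection is an error.
    """
    present = [g for g in s if g in E._index]
    skipped = len(s) - len(present)
    if not present:
        raise KeyError(f"no gene of set {s.name!r} is in the expression matrix")
    if skipped:
        log.info("set_average_map(%s): skipped %d genes absent from matrix",
                 s.name, skipped)
    return RegionalMap(E.atlas, E.columns(present).mean(axis=1), name=s.name)


def network_profile(m: RegionalMap) -> dict[str, float]:
    """Mean map value per canonical network, in fixed network order.

    A network with no non-missing parcel is reported as NaN.
    """
    out: dict[str, float] = {}
    ok = m.finite
    for net in NETWORKS:
        sel = ok & (m.atlas.network == net)
        out[net] = float(m.values[sel].mean()) if sel.any() else float("nan")
    return out
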