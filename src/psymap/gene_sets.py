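"""Literature gene tables and gene-set algebra.

The unit of evidence is one reported expression change: a gene symbol, the
drug, the species and tissue it was measured in, the direction of change,
and the time from dosing to sampling in hours. The analysis keeps only
*acute* findings — changes reported within a few hours of a single dose —
then reduces the surviving records to a unique symbol set and intersects it
with the genes actually quantified in the human expression atlas.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass

from .errors import RowError, SchemaError

log = logging.getLogger(__name__)

DRUGS = ("LSD", "Psi", "Psn", "Doi", "Dob", "other")
DIRECTIONS = ("+", "-", "-/+", "na")

#: Default acute window: a finding counts as acute when sampled within
#: this many hours of dosing (inclusive).
ACUTE_MAX_HOURS = 5.0


@dataclass(frozen=True)
class GeneRecord:
    """One literature finding for one gene."""

    symbol: str
    drug: str = "other"
    species: str = ""
    tissue: str = ""
    direction: str = "na"
    time_hours: float | None = None
    study_id: str = ""

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.time_hours is not None and not self.time_hours > 0:
            raise ValueError("time_hours must be positive when present")


class GeneSet:
    """Named, ordered set of gene symbols (unique after uppercasing)."""

    def __init__(self, name: str, symbols) -> None:
        self.name = name
        seen: dict[str, None] = {}
        for s in symbols:
            s = str(s).strip().upper()
            if not s:
                raise ValueError("empty gene symbol")
            seen.setdefault(s, None)
        self.symbols: tuple[str, ...] = tuple(seen)
        self._set = frozenset(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return str(symbol).strip().upper() in self._set

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSet) and self.symbols == other.symbols

    def __repr__(self) -> str:
        return f"GeneSet({self.name!r}, n={len(self)})"

    def to_txt(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.name}\n")
            fh.writelines(s + "\n" for s in self.symbols)

    @classmethod
    def from_txt(cls, path, name: str | None = None) -> "GeneSet":
        """Read a one-symbol-per-line list; ``#`` starts a comment."""
        symbols = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    symbols.append(line)
        return cls(name or str(path), symbols)


GENE_TABLE_COLUMNS = ("symbol", "drug", "species", "tissue", "direction",
                      "time_hours", "study_id")


def read_gene_table(path) -> list[GeneRecord]:
    """Parse a literature gene table CSV into records.

    Required columns are ``symbol`` and ``time_hours``; the remaining
    metadata columns are optional and default to empty. Symbols are
    uppercased and stripped; an empty ``time_hours`` field is kept as
    missing (the record then never passes the acute filter).
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in ("symbol", "time_hours"):
            if col not in header:
                raise SchemaError(f"gene table is missing required column {col!r}")
        records: list[GeneRecord] = []
        for lineno, row in enumerate(reader, start=2):
            raw_sym = (row.get("symbol") or "").strip()
            if not raw_sym:
                raise RowError(f"line {lineno}: empty gene symbol")
            raw_t = (row.get("time_hours") or "").strip()
            if raw_t == "":
                t: float | None = None
            else:
                try:
                    t = float(raw_t)
                except ValueError:
                    raise RowError(
                        f"line {lineno}: unparseable time_hours {raw_t!r}") from None
            try:
                records.append(GeneRecord(
                    symbol=raw_sym.upper(),
                    drug=(row.get("drug") or "other").strip() or "other",
                    species=(row.get("species") or "").strip(),
                    tissue=(row.get("tissue") or "").strip(),
                    direction=(row.get("direction") or "na").strip() or "na",
                    time_hours=t,
                    study_id=(row.get("study_id") or "").strip(),
                ))
            except ValueError as exc:
                raise RowError(f"line {lineno}: {exc}") from None
    return records


def write_gene_table(records: list[GeneRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GENE_TABLE_COLUMNS)
        for r in records:
            t = "" if r.time_hours is None else repr(float(r.time_hours))
            writer.writerow([r.symbol, r.drug, r.species, r.tissue,
                             r.direction, t, r.study_id])


def filter_acute(records: list[GeneRecord],
                 max_hours: float = ACUTE_MAX_HOURS,
                 inclusive: bool = True,
                 name: str = "acute") -> GeneSet:
    """Unique symbols sampled within ``max_hours`` of dosing.

    A gene passes if *any* of its records is acute. The boundary is
    inclusive by default ("within 5 h" includes findings at exactly 5 h;
    the acute set's reported maximum sits on the boundary). Records with a
    missing time are excluded and counted in the log.
    """
    if not max_hours > 0:
        raise ValueError("max_hours must be positive")
    no_time = 0
    keep: list[str] = []
    for r in records:
        if r.time_hours is None:
            no_time += 1
            continue
        ok = r.time_hours <= max_hours if inclusive else r.time_hours < max_hours
        if ok:
            keep.append(r.symbol)
    if no_time:
        log.info("filter_acute: %d records had no reported time and were excluded",
                 no_time)
    return GeneSet(name, keep)


def summarize_times(records: list[GeneRecord]) -> dict[str, float]:
    """Mean, sample SD (n-1), min and max of the reported times, in hours.

    A single usable time yields sd = 0 by convention.
    """
    times = [r.time_hours for r in records if r.time_hours is not None]
    if not times:
        raise ValueError("no records with a reported time")
    n = len(times)
    mean = sum(times) / n
    sd = 0.0 if n == 1 else math.sqrt(sum((t - mean) ** 2 for t in times) / (n - 1))
    return {"mean": mean, "sd": sd, "min": min(times), "max": max(times), "n": n}


def intersect(a: GeneSet, b: GeneSet, name: str | None = None) -> GeneSet:
    """Case-normalised intersection, ordered as in ``a``."""
    return GeneSet(name or f"{a.name}&{b.name}", (s for s in a if s in b))
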