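"""End-to-end analysis pipeline.

``run_all`` drives the full study from one configuration: literature gene
filtering → expression maps → overlap test → receptor colocalization →
signed co-expression communities → global functional connectivity →
spatial surrogate nulls. Every stage writes its tables under the output
directory and the numeric results are collected into one ``summary.json``.

All study constants (acute window, permutation count, binarization
threshold, Louvain resolution, seed) live in :class:`RunConfig`; a single
top-level seed fans out to deterministic per-stage seeds so any stage can
be rerun in isolation.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .atlas import ParcelAtlas
from .colocalization import (anova_posthoc, geneset_correlations, map_correlation,
                             resampling_null, two_sample_t)
from .coexpression_network import (binarized_degree, cluster_maps, gce_matrix,
                                   louvain_signed)
from .errors import ConfigError
from .expression_maps import (RegionalMap, gene_map, load_expression,
                              network_profile, set_average_map)
from .gene_sets import GeneSet, filter_acute, intersect, read_gene_table, summarize_times
from .gfc import connectivity, global_fc, group_difference, read_bold
from .overlap_stats import fisher_overlap
from .spatial_nulls import distance_matrix, surrogate_maps, surrogate_p

log = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed (< 2^31)."""
    return zlib.crc32(f"{stage}:{seed}".encode()) % (2 ** 31)


@dataclass
class RunConfig:
    """Paths and constants for one full run."""

    gene_table: str
    expression: str
    atlas: str
    har_genes: str
    out_dir: str
    bold_group_a: str | None = None
    bold_group_b: str | None = None
    background_genes: str | None = None   # default: all genes in the matrix
    coloc_targets: list[str] = field(
        default_factory=lambda: ["HTR2A", "HTR1A", "HTR2C", "DRD1", "SLC6A4"])
    acute_max_hours: float = 5.0
    n_perm: int = 5000
    gce_threshold: float = 0.3
    gamma: float = 0.5
    n_restarts: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        for name in ("gene_table", "expression", "atlas", "har_genes",
                     "bold_group_a", "bold_group_b", "background_genes"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"config field {name!r}: path does not exist: {p}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        missing = {f for f in ("gene_table", "expression", "atlas", "har_genes",
                               "out_dir")} - set(data)
        if missing:
            raise ConfigError(f"missing required config fields: {sorted(missing)}")
        return cls(**data)


def _round_floats(obj, ndigits: int = 12):
    """Round floats recursively so the summary JSON is stable to write."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the summary dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {k: getattr(config, k) for k in
                                ("acute_max_hours", "n_perm", "gce_threshold",
                                 "gamma", "n_restarts", "seed")},
                     "version": __version__}

    def _stage(name):
        log.info("stage: %s", name)

    # ---------------------------------------------------------- gene table
    _stage("genes")
    records = read_gene_table(config.gene_table)
    acute = filter_acute(records, config.acute_max_hours)
    acute_records = [r for r in records
                     if r.time_hours is not None
                     and r.time_hours <= config.acute_max_hours]
    summary["genes"] = {
        "n_records": len(records),
        "n_acute_unique": len(acute),
        "acute_time_summary": summarize_times(acute_records),
    }

    # ------------------------------------------------------- expression map
    _stage("maps")
    atlas = ParcelAtlas.from_csv(config.atlas)
    E = load_expression(config.expression, atlas)
    gcep = intersect(acute, E.gene_set(), name="GCEP_AHBA")
    gcep.to_txt(out / "gcep_ahba.txt")
    summary["maps"] = {
        "n_genes": len(E.genes),
        "n_parcels": atlas.n_parcels,
        "n_missing_parcels": int(E.missing_mask.sum()),
        "n_gcep_ahba": len(gcep),
    }

    # ------------------------------------------------------------- overlap
    _stage("overlap")
    har = GeneSet.from_txt(config.har_genes, name="HAR_AHBA")
    background = (GeneSet.from_txt(config.background_genes, name="background")
                  if config.background_genes else E.gene_set("background"))
    ov = fisher_overlap(gcep, har, background)
    har_gcep = intersect(gcep, har, name="GCEP_AHBA&HAR_AHBA")
    overlap_block = {"fisher": ov.to_dict()}
    if len(har_gcep):
        m = set_average_map(E, har_gcep)
        m.to_csv(out / "har_gcep_map.csv")
        overlap_block["har_gcep_network_profile"] = network_profile(m)
    summary["overlap"] = overlap_block

    # ------------------------------------------------------ colocalization
    _stage("coloc")
    coloc: dict = {}
    per_target_r: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(stage_seed(config.seed, "coloc"))
    for i, target_sym in enumerate(config.coloc_targets):
        tmap = gene_map(E, target_sym)
        rs = geneset_correlations(E, gcep, tmap)
        per_target_r[target_sym] = rs
        null = resampling_null(E, len(gcep), tmap, n_perm=config.n_perm,
                               seed=stage_seed(config.seed, f"coloc:{target_sym}"),
                               exclude=gcep)
        # one same-sized random non-query draw for the two-sample contrast
        pool = [g for g in E.genes if g not in gcep]
        draw = GeneSet("random", rng.choice(pool, size=len(gcep), replace=False))
        tt = two_sample_t(rs[np.isfinite(rs)],
                          geneset_correlations(E, draw, tmap))
        coloc[target_sym] = {"mean_r": float(np.nanmean(rs)),
                             "p_perm": null.p, "t_test": tt}
    if len(per_target_r) >= 2:
        an = anova_posthoc({k: v[np.isfinite(v)] for k, v in per_target_r.items()})
        coloc["anova"] = {"F": an.F, "df1": an.df1, "df2": an.df2, "p": an.p,
                          "pairwise": an.pairwise}
    summary["coloc"] = coloc

    # ------------------------------------------------------------- network
    _stage("network")
    C = gce_matrix(E, gcep)
    degrees = binarized_degree(C, config.gce_threshold)
    part = louvain_signed(C, gamma=config.gamma,
                          seed=stage_seed(config.seed, "network"),
                          n_restarts=config.n_restarts)
    part.to_csv(out / "partition.csv")
    C.to_edge_csv(out / "gce_edges.csv")
    cmaps = cluster_maps(E, part)
    for m in cmaps:
        m.to_csv(out / f"{m.name.replace(' ', '_').lower()}_map.csv")
    summary["network"] = {
        "n_genes": len(C.genes),
        "modularity": part.modularity,
        "n_communities": part.n_communities,
        "community_sizes": sorted(
            (sum(1 for v in part.communities.values() if v == c)
             for c in set(part.communities.values())), reverse=True),
        "mean_degree": float(np.mean(degrees)),
        "cluster_network_profiles": {m.name: network_profile(m) for m in cmaps},
    }

    # ----------------------------------------------------------------- gfc
    diff = None
    if config.bold_group_a and config.bold_group_b:
        _stage("gfc")
        groups = []
        for d in (config.bold_group_a, config.bold_group_b):
            maps = []
            for f in sorted(Path(d).glob("*.csv")):
                maps.append(global_fc(connectivity(read_bold(f), atlas)))
            if not maps:
                raise ConfigError(f"no subject CSVs found in {d}")
            groups.append(maps)
        diff = group_difference(groups[0], groups[1])
        # analysis frame: parcels with expression data only
        vals = diff.values.copy()
        vals[E.missing_mask] = np.nan
        diff = RegionalMap(atlas, vals, name="GFC difference")
        diff.to_csv(out / "gfc_difference.csv")
        summary["gfc"] = {
            "n_subjects": [len(g) for g in groups],
            "mean_gfc_a": float(np.nanmean([m.values for m in groups[0]])),
            "mean_gfc_b": float(np.nanmean([m.values for m in groups[1]])),
            "diff_mean": float(np.nanmean(diff.values)),
        }

        # --------------------------------------------------- spatial nulls
        _stage("nulls")
        D = distance_matrix(atlas)
        ens = surrogate_maps(diff, D, n=config.n_perm,
                             seed=stage_seed(config.seed, "nulls"))
        nulls_block = {}
        for m in cmaps:
            nd = surrogate_p(diff, m, ens)
            nulls_block[m.name] = {"r": nd.observed, "p_perm": nd.p}
        summary["nulls"] = nulls_block

    summary = _round_floats(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
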