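"""Synthetic study generator.

Everything downstream of raw data acquisition can be exercised on
synthetic inputs with planted, known truth: a spherical two-hemisphere
parcel atlas; a z-scored parcels × genes expression matrix whose genes
fall into spatially coherent co-expression clusters plus spatially
autocorrelated noise; a literature gene table with a planted acute subset;
and two-group BOLD time-series with a planted regional connectivity
effect.

The default study emulates the real analysis frame: 200 parcels with 11
missing expression (189 usable), a 51-gene query set in 3 co-expression
clusters, a 156-row gene table with 56 unique acute genes sampled within
0.75-5 h of dosing, and 15 subjects per BOLD group. The gene universe is
scaled down (hundreds rather than ~15k genes) — resampling statistics are
insensitive to universe size once it is much larger than the query set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atlas import NETWORKS, ParcelAtlas
from .errors import PsymapError
from .expression_maps import ExpressionMatrix, RegionalMap, _DDOF
from .gene_sets import GeneRecord, GeneSet, write_gene_table

SPHERE_RADIUS = 50.0  # centroid units; distances therefore span ~0-100


@dataclass
class SyntheticSpec:
    """Controls for the expression generator.

    Each gene map is built as

        cluster network-profile map
        + smooth noise   (white noise smoothed at ``spatial_scale``, sd = noise_sd)
        + white noise    (sd = noise_sd)

    and then z-scored over non-missing parcels. ``n_background`` extra
    genes carry noise only (planted cluster label 0), emulating the bulk of
    the transcriptome that has no relation to the query set.
    """

    n_parcels: int
    n_genes: int
    n_clusters: int
    cluster_profiles: np.ndarray | None = None  # (n_clusters, 7) network weights
    spatial_scale: float = 15.0
    noise_sd: float = 0.3
    n_background: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_genes:
            raise ValueError("n_clusters cannot exceed n_genes")
        if self.spatial_scale < 0 or self.noise_sd < 0:
            raise ValueError("spatial_scale and noise_sd must be >= 0")


def gen_parcel_atlas(n_parcels: int, seed: int = 0,
                     n_missing: int = 0) -> ParcelAtlas:
    """Random spherical atlas: two hemispheric caps, 7 contiguous networks.

    Centroids are sampled uniformly on a sphere of radius 50; parcels are
    sorted along x, the lower-x half labelled L and the rest R, and each
    hemisphere is split into 7 contiguous blocks of network labels.
    Optionally ``n_missing`` random parcels are flagged as lacking data.
    """
    if n_parcels < 2:
        raise ValueError("need at least 2 parcels")
    if not 0 <= n_missing <= n_parcels - 2:
        raise ValueError("n_missing must leave >= 2 usable parcels")
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n_parcels, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= SPHERE_RADIUS
    order = np.argsort(pts[:, 0], kind="stable")
    pts = pts[order]
    n_left = n_parcels // 2
    hemi = np.array(["L"] * n_left + ["R"] * (n_parcels - n_left), dtype=object)
    network = np.empty(n_parcels, dtype=object)
    for lo, hi in ((0, n_left), (n_left, n_parcels)):
        blocks = np.array_split(np.arange(lo, hi), len(NETWORKS))
        for net, idx in zip(NETWORKS, blocks):
            network[idx] = net
    missing = np.zeros(n_parcels, dtype=bool)
    if n_missing:
        missing[rng.choice(n_parcels, size=n_missing, replace=False)] = True
    return ParcelAtlas(parcel_id=np.arange(1, n_parcels + 1), hemisphere=hemi,
                       network=network, centroids=pts, missing=missing)


def _distances(atlas: ParcelAtlas) -> np.ndarray:
    diff = atlas.centroids[:, None, :] - atlas.centroids[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))


def _smoother(atlas: ParcelAtlas, scale: float) -> np.ndarray:
    """Row-normalised Gaussian distance kernel; identity at scale 0."""
    if scale == 0:
        return np.eye(atlas.n_parcels)
    K = np.exp(-_distances(atlas) ** 2 / (2.0 * scale ** 2))
    return K / K.sum(axis=1, keepdims=True)


def _standardize(v: np.ndarray, ok: np.ndarray) -> np.ndarray:
    sd = v[ok].std(ddof=_DDOF)
    return (v - v[ok].mean()) / sd if sd > 0 else v - v[ok].mean()


def gen_random_map(atlas: ParcelAtlas, spatial_scale: float, seed: int = 0,
                   nugget: float = 0.0, name: str = "random") -> RegionalMap:
    """One z-scored random map: smoothed white noise plus an optional white
    nugget (relative amplitude), NaN on missing parcels."""
    rng = np.random.default_rng(seed)
    S = _smoother(atlas, spatial_scale)
    ok = atlas.nonmissing
    v = _standardize(S @ rng.standard_normal(atlas.n_parcels), ok)
    if nugget > 0:
        v = v + nugget * rng.standard_normal(atlas.n_parcels)
    v = _standardize(v, ok)
    v[~ok] = np.nan
    return RegionalMap(atlas, v, name=name)


def _default_profiles(n_clusters: int, net_idx: np.ndarray, ok: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Network-weight profiles whose *maps* are orthogonal over the
    non-missing parcels, so planted clusters are spatially uncorrelated
    rather than accidentally collinear."""
    if n_clusters > len(NETWORKS):
        return rng.standard_normal((n_clusters, len(NETWORKS)))
    sub = net_idx[ok]
    M = np.zeros((sub.size, len(NETWORKS)))
    M[np.arange(sub.size), sub] = 1.0
    X = M @ rng.standard_normal((len(NETWORKS), n_clusters))
    X = X - X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    # Q columns stay network-wise constant (combinations of indicators)
    profiles = np.zeros((n_clusters, len(NETWORKS)))
    for n in range(len(NETWORKS)):
        members = sub == n
        if members.any():
            profiles[:, n] = Q[members].mean(axis=0)
    return profiles


def gen_expression(atlas: ParcelAtlas,
                   spec: SyntheticSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Synthetic z-scored expression with planted co-expression clusters.

    Returns the matrix and the planted gene→cluster labels (1..k for the
    structured genes, 0 for background-noise genes).
    """
    if atlas.n_parcels != spec.n_parcels:
        raise ValueError("atlas size does not match spec.n_parcels")
    rng = np.random.default_rng(spec.seed)
    ok = atlas.nonmissing
    P = atlas.n_parcels

    net_idx = np.array([NETWORKS.index(n) for n in atlas.network])
    profiles = (np.asarray(spec.cluster_profiles, dtype=float)
                if spec.cluster_profiles is not None
                else _default_profiles(spec.n_clusters, net_idx, ok, rng))
    if profiles.shape != (spec.n_clusters, len(NETWORKS)):
        raise ValueError(f"cluster_profiles must be ({spec.n_clusters}, 7)")
    profile_maps = np.column_stack(
        [_standardize(profiles[c][net_idx].astype(float), ok)
         for c in range(spec.n_clusters)])

    S = _smoother(atlas, spec.spatial_scale)
    labels = np.zeros(spec.n_genes + spec.n_background, dtype=int)
    blocks = np.array_split(np.arange(spec.n_genes), spec.n_clusters)
    for c, idx in enumerate(blocks, start=1):
        labels[idx] = c

    n_total = labels.size
    values = np.empty((P, n_total))
    for g in range(n_total):
        base = profile_maps[:, labels[g] - 1] if labels[g] > 0 else 0.0
        smooth = _standardize(S @ rng.standard_normal(P), ok) if spec.noise_sd > 0 else 0.0
        white = rng.standard_normal(P) if spec.noise_sd > 0 else 0.0
        col = base + spec.noise_sd * (smooth + white)
        if labels[g] == 0 and spec.noise_sd == 0:
            col = rng.standard_normal(P)  # background genes always need variance
        while col[ok].std() == 0:  # degenerate column: jitter, never emit flat
            col = col + 1e-6 * rng.standard_normal(P)
        values[:, g] = _standardize(col, ok)
    values[~ok] = np.nan

    genes = tuple(f"G{i + 1:04d}" for i in range(n_total))
    E = ExpressionMatrix(atlas=atlas, genes=genes, values=values,
                         missing_mask=~ok)
    return E, labels


def compound_cov(n_parcels: int, rho: float = 0.3) -> np.ndarray:
    """Compound-symmetry covariance: unit variance, constant correlation."""
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    C = np.full((n_parcels, n_parcels), rho)
    np.fill_diagonal(C, 1.0)
    return C


def smooth_cov(atlas: ParcelAtlas, scale: float = 20.0, amplitude: float = 0.3,
               nugget: float = 0.7) -> np.ndarray:
    """Distance-decaying covariance (Gaussian kernel + white nugget); PSD by
    construction."""
    C = amplitude * np.exp(-_distances(atlas) ** 2 / (2.0 * scale ** 2))
    C[np.diag_indices_from(C)] += nugget
    return C


def gen_bold(atlas: ParcelAtlas, base_cov: np.ndarray, effect,
             n_subjects: int = 15, n_timepoints: int = 220,
             seed: int = 0) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Two-group BOLD simulation with a planted connectivity effect.

    Group A subjects are Gaussian with covariance ``base_cov``; group B
    uses a covariance whose off-diagonal entries are scaled by
    sqrt((1+e_i)(1+e_j)) — i.e. each row/column i scaled by sqrt(1+e_i) —
    with the diagonal restored, so the planted global-connectivity
    difference follows the effect map. The modified covariance is clipped
    to PSD with an eigenvalue floor of 1e-8.
    """
    cov = np.asarray(base_cov, dtype=float)
    P = atlas.n_parcels
    if cov.shape != (P, P) or not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("base_cov must be a symmetric (P, P) matrix")
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("base_cov must be positive semidefinite")
    e = effect.values if isinstance(effect, RegionalMap) else np.asarray(effect, float)
    e = np.nan_to_num(e, nan=0.0)
    if e.shape != (P,):
        raise ValueError("effect must have one value per parcel")
    if np.any(e <= -1):
        raise ValueError("effect values must be > -1")

    d = np.sqrt(1.0 + e)
    cov_b = cov * np.outer(d, d)
    np.fill_diagonal(cov_b, np.diag(cov))

    def _floor(C: np.ndarray) -> np.ndarray:
        w, V = np.linalg.eigh(C)
        return (V * np.clip(w, 1e-8, None)) @ V.T

    rng = np.random.default_rng(seed)
    out: list[list[np.ndarray]] = []
    for C in (cov, cov_b):
        L = np.linalg.cholesky(_floor(C))
        out.append([rng.standard_normal((n_timepoints, P)) @ L.T
                    for _ in range(n_subjects)])
    return out[0], out[1]


def gen_gene_table(n_entries: int, acute_fraction: float, universe,
                   seed: int = 0) -> tuple[list[GeneRecord], GeneSet]:
    """Literature-style gene table with a planted acute subset.

    round(n_entries * acute_fraction) entries are acute: each gets a
    distinct symbol and a time drawn from a normal centred at 1.5 h
    (sd 0.5) truncated to [0.75, 5] h — the acute window the analysis
    targets. Remaining entries reuse the leftover universe (duplicates
    allowed) with times beyond 5 h, or no time at all for a minority.
    Returns the records and the planted acute gene set.
    """
    symbols = [str(s).strip().upper() for s in universe]
    if not symbols:
        raise ValueError("gene universe is empty")
    if not 0 <= acute_fraction <= 1:
        raise ValueError("acute_fraction must lie in [0, 1]")
    n_acute = round(n_entries * acute_fraction)
    if n_acute > len(symbols):
        raise ValueError("universe too small for the requested acute set")
    rng = np.random.default_rng(seed)
    drugs = ("LSD", "Psi", "Psn", "Doi", "Dob")
    species = ("Rattus norvegicus", "Mus musculus", "Homo sapiens")
    tissues = ("prefrontal cortex", "sensory cortex", "hippocampus", "subcortex")
    directions = ("+", "+", "+", "-", "-/+", "na")

    acute_syms = list(rng.choice(symbols, size=n_acute, replace=False))
    rest = [s for s in symbols if s not in set(acute_syms)] or acute_syms

    def _acute_time(i: int) -> float:
        # the acute window's boundaries are part of the emulated table:
        # one finding right after dosing onset, one exactly at the cutoff
        if n_acute >= 2 and i == 0:
            return 0.75
        if n_acute >= 2 and i == 1:
            return 5.0
        while True:
            t = rng.normal(1.5, 0.5)
            if 0.75 <= t <= 5.0:
                return round(float(t), 2)

    records: list[GeneRecord] = []
    for i in range(n_entries):
        if i < n_acute:
            sym, t = acute_syms[i], _acute_time(i)
        else:
            sym = str(rng.choice(rest))
            t = None if rng.random() < 0.15 else round(float(rng.uniform(5.5, 336.0)), 1)
        records.append(GeneRecord(
            symbol=sym,
            drug=str(rng.choice(drugs)),
            species=str(rng.choice(species)),
            tissue=str(rng.choice(tissues)),
            direction=str(rng.choice(directions)),
            time_hours=t,
            study_id=f"S{int(rng.integers(1, 18)):02d}",
        ))
    return records, GeneSet("planted_acute", acute_syms)


def make_overlapping_sets(universe, n_a: int, n_b: int, n_overlap: int,
                          seed: int = 0, names=("A", "B")) -> tuple[GeneSet, GeneSet]:
    """Two gene sets from a universe with an exact planted overlap."""
    symbols = [str(s).strip().upper() for s in universe]
    if n_overlap > min(n_a, n_b) or n_a + n_b - n_overlap > len(symbols):
        raise ValueError("inconsistent set sizes for the given universe")
    rng = np.random.default_rng(seed)
    picked = list(rng.choice(symbols, size=n_a + n_b - n_overlap, replace=False))
    a = picked[:n_a]
    b = picked[n_a - n_overlap:n_a] + picked[n_a:]
    return GeneSet(names[0], a), GeneSet(names[1], b)


# --------------------------------------------------------------------------
# full synthetic study
# --------------------------------------------------------------------------

RECEPTOR_NAMES = ("HTR2A", "HTR1A", "HTR2C", "DRD1", "SLC6A4")


@dataclass
class SyntheticStudy:
    """In-memory bundle of one simulated study plus its planted truth."""

    atlas: ParcelAtlas
    expression: ExpressionMatrix
    cluster_labels: np.ndarray
    records: list[GeneRecord]
    acute_truth: GeneSet
    query_set: GeneSet            # planted analysis gene set (within atlas)
    har_set: GeneSet
    effect: RegionalMap
    bold_a: list[np.ndarray]
    bold_b: list[np.ndarray]
    coloc_targets: tuple[str, ...] = RECEPTOR_NAMES
    params: dict = field(default_factory=dict)


def build_study(seed: int = 0, n_parcels: int = 200, n_missing: int = 11,
                n_set: int = 51, n_clusters: int = 3, n_background: int = 549,
                n_har: int = 50, n_har_overlap: int = 9, n_entries: int = 156,
                n_acute: int = 56, spatial_scale: float = 15.0,
                noise_sd: float = 0.3, n_subjects: int = 15,
                n_timepoints: int = 220, bold_rho: float = 0.3,
                effect_amplitude: float = -0.3) -> SyntheticStudy:
    """Simulate a complete study mirroring the real analysis frame.

    The query set (default 51 genes, in 3 planted co-expression clusters)
    sits inside a larger gene universe; the acute gene table plants
    ``n_acute`` unique acute genes of which exactly ``n_set`` are in the
    universe; the HAR-like list shares ``n_har_overlap`` genes with the
    query set; the BOLD effect map is proportional to the first planted
    cluster's profile (amplitude -0.3), so the connectivity-change map
    truly couples to Cluster 1 and to no other cluster.
    """
    if n_acute < n_set:
        raise ValueError("n_acute must be >= n_set (acute genes outside the "
                         "universe make up the difference)")
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(6)]

    atlas = gen_parcel_atlas(n_parcels, seed=seeds[0], n_missing=n_missing)
    spec = SyntheticSpec(n_parcels=n_parcels, n_genes=n_set,
                         n_clusters=n_clusters, spatial_scale=spatial_scale,
                         noise_sd=noise_sd, n_background=n_background,
                         seed=seeds[1])
    E, labels = gen_expression(atlas, spec)

    # name the query genes: receptors first, then GCEP-style symbols
    names = list(RECEPTOR_NAMES)[:n_set]
    names += [f"GCEP{i + 1:03d}" for i in range(len(names), n_set)]
    names += [f"BG{i + 1:04d}" for i in range(n_background)]
    E = ExpressionMatrix(atlas=atlas, genes=tuple(names), values=E.values,
                         missing_mask=E.missing_mask)
    query = GeneSet("GCEP_AHBA", names[:n_set])

    rng = np.random.default_rng(seeds[2])
    extra = [f"EXTRA{i + 1}" for i in range(n_acute - n_set)]
    acute_syms = list(query) + extra
    table_records, _ = gen_gene_table(
        n_entries=n_entries, acute_fraction=len(acute_syms) / n_entries,
        universe=acute_syms + [f"NONACUTE{i + 1}" for i in range(200)],
        seed=seeds[2])
    # gen_gene_table draws its own acute subset; rebuild with the exact
    # planted symbols so the acute truth is the query set plus the extras
    records: list[GeneRecord] = []
    k = 0
    for r in table_records:
        if r.time_hours is not None and r.time_hours <= 5.0 and k < len(acute_syms):
            records.append(GeneRecord(acute_syms[k], r.drug, r.species, r.tissue,
                                      r.direction, r.time_hours, r.study_id))
            k += 1
        else:
            sym = f"NONACUTE{int(rng.integers(1, 60)):02d}"
            t = r.time_hours if (r.time_hours is None or r.time_hours > 5.0) \
                else round(float(rng.uniform(5.5, 336.0)), 1)
            records.append(GeneRecord(sym, r.drug, r.species, r.tissue,
                                      r.direction, t, r.study_id))
    if k != len(acute_syms):
        raise PsymapError("internal: planted acute entries did not fit the table")

    har_from_query = list(rng.choice(list(query), size=n_har_overlap, replace=False))
    bg_pool = [g for g in names[n_set:]]
    har_rest = list(rng.choice(bg_pool, size=n_har - n_har_overlap, replace=False))
    har = GeneSet("HAR_AHBA", har_from_query + har_rest)

    # connectivity effect proportional to cluster 1's average map
    n_c1 = max(1, math.ceil(n_set / n_clusters))
    c1 = np.zeros(n_parcels)
    ok = atlas.nonmissing
    c1[ok] = E.values[np.ix_(ok, np.arange(n_c1))].mean(axis=1)
    c1 = np.nan_to_num(_standardize(c1, ok), nan=0.0)
    effect = RegionalMap(atlas, np.clip(effect_amplitude * c1, -0.8, 0.8),
                         name="planted effect")
    cov = smooth_cov(atlas, scale=spatial_scale, amplitude=bold_rho,
                     nugget=1.0 - bold_rho)
    # group A is the drug condition (carries the planted effect), group B
    # the control, so the pipeline's A-minus-B difference is drug-placebo
    bold_b, bold_a = gen_bold(atlas, cov, effect, n_subjects=n_subjects,
                              n_timepoints=n_timepoints, seed=seeds[3])

    return SyntheticStudy(
        atlas=atlas, expression=E, cluster_labels=labels, records=records,
        acute_truth=GeneSet("planted_acute", acute_syms), query_set=query,
        har_set=har, effect=effect, bold_a=bold_a, bold_b=bold_b,
        params={"seed": seed, "n_parcels": n_parcels, "n_missing": n_missing,
                "n_set": n_set, "n_clusters": n_clusters,
                "n_background": n_background, "n_har": n_har,
                "n_har_overlap": n_har_overlap, "n_entries": n_entries,
                "n_acute": n_acute, "noise_sd": noise_sd,
                "spatial_scale": spatial_scale, "n_subjects": n_subjects,
                "n_timepoints": n_timepoints})


def write_study(study: SyntheticStudy, outdir) -> dict:
    """Write a study directory: atlas.csv, expression.csv, genes.csv, gene
    lists, bold_groupA/-B subject CSVs and truth.json. Returns the file map."""
    from .gfc import write_bold  # local import avoids a cycle

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.atlas.to_csv(out / "atlas.csv")
    study.expression.to_csv(out / "expression.csv")
    write_gene_table(study.records, out / "genes.csv")
    study.har_set.to_txt(out / "har_genes.txt")
    study.query_set.to_txt(out / "query_genes.txt")
    for group, data in (("A", study.bold_a), ("B", study.bold_b)):
        gdir = out / f"bold_group{group}"
        gdir.mkdir(exist_ok=True)
        for i, bold in enumerate(data, start=1):
            write_bold(bold, gdir / f"sub-{i:02d}.csv", study.atlas)
    truth = {
        "params": study.params,
        "acute_genes": list(study.acute_truth),
        "query_genes": list(study.query_set),
        "har_genes": list(study.har_set),
        "cluster_labels": study.cluster_labels.tolist(),
        "effect": study.effect.values.tolist(),
        "coloc_targets": list(study.coloc_targets),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return {"dir": str(out)}
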