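"""Spatial colocalization of gene maps with receptor maps.

A gene set "colocalizes" with a receptor when its members' regional
expression maps correlate with the receptor's map more strongly than maps
of randomly chosen genes do. The null is built by resampling same-sized
random gene sets from the atlas (excluding the query set) and recording the
mean map correlation of each draw; the permutation p counts how often the
null mean is at least as large as the observed mean. Distributions of
per-gene correlations across several receptors are compared with a pooled
two-sample t-test and a one-way ANOVA with Tukey-Kramer post-hocs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import UndefinedCorrelationError
from .expression_maps import ExpressionMatrix, RegionalMap
from .gene_sets import GeneSet
from .overlap_stats import bh_adjust

log = logging.getLogger(__name__)


def permutation_pvalue(samples: np.ndarray, observed: float,
                       tail: str = "greater", smoothed: bool = False) -> float:
    """Permutation p from null samples by the counting rule.

    The literal rule p = #{null meets tail}/n_perm can return exactly 0;
    ``smoothed`` switches to (1 + #)/(1 + n_perm), which cannot.

    tail:
      - "greater": count samples >= observed
      - "less": count samples <= observed
      - "two_sided": count |samples| >= |observed|
      - "directed": one-sided in the direction of the observed statistic,
        i.e. count sign(observed) * samples >= |observed|.
    """
    s = np.asarray(samples, dtype=float)
    if tail == "greater":
        count = int(np.sum(s >= observed))
    elif tail == "less":
        count = int(np.sum(s <= observed))
    elif tail == "two_sided":
        count = int(np.sum(np.abs(s) >= abs(observed)))
    elif tail == "directed":
        sign = 1.0 if observed >= 0 else -1.0
        count = int(np.sum(sign * s >= abs(observed)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    if smoothed:
        return (1 + count) / (1 + s.size)
    return count / s.size


@dataclass
class NullDistribution:
    """Resampling/permutation null with its observed statistic and p-value."""

    samples: np.ndarray
    observed: float
    p: float
    tail: str
    seed: int | None = None
    smoothed: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def n_perm(self) -> int:
        return int(self.samples.size)


def map_correlation(a: RegionalMap, b: RegionalMap) -> float:
    """Pearson r of two maps over their mutually non-missing parcels."""
    if not a.atlas.same_frame(b.atlas):
        raise UndefinedCorrelationError("maps are on different atlases")
    ok = a.finite & b.finite
    if int(ok.sum()) < 3:
        raise UndefinedCorrelationError("fewer than 3 mutually non-missing parcels")
    x, y = a.values[ok], b.values[ok]
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("zero-variance map")
    return float(stats.pearsonr(x, y)[0])


def _gene_target_correlations(E: ExpressionMatrix, target: RegionalMap) -> np.ndarray:
    """Pearson r of every gene column with the target map (vectorised)."""
    ok = E.nonmissing & target.finite
    if int(ok.sum()) < 3:
        raise UndefinedCorrelationError("fewer than 3 usable parcels")
    X = E.values[ok]                       # (p, G)
    y = target.values[ok]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=0)) * np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / denom
    return r


def geneset_correlations(E: ExpressionMatrix, s: GeneSet,
                         target: RegionalMap) -> np.ndarray:
    """Per-gene map correlation with the target, ordered as in ``s``.

    Genes absent from the matrix, or with an undefined correlation, are
    reported as NaN and logged.
    """
    all_r = _gene_target_correlations(E, target)
    out = np.full(len(s), np.nan)
    skipped = 0
    for i, g in enumerate(s):
        j = E._index.get(g)
        if j is None:
            skipped += 1
            continue
        out[i] = all_r[j]
    if skipped or np.isnan(out).any():
        log.info("geneset_correlations(%s): %d absent genes, %d undefined r",
                 s.name, skipped, int(np.isnan(out).sum()) - skipped)
    return out


def resampling_null(E: ExpressionMatrix, set_size: int, target: RegionalMap,
                    n_perm: int = 5000, seed: int | None = None,
                    exclude: GeneSet | None = None,
                    smoothed: bool = False) -> NullDistribution:
    """Random-gene-set null for the mean map correlation with a target.

    Each permutation draws ``set_size`` genes uniformly without replacement
    from the matrix excluding the query set, and records the mean Pearson r
    of their maps with the target. The observed statistic is the mean r of
    the query (= excluded) set; p counts null means >= observed.
    """
    exclude = exclude or GeneSet("none", [])
    all_r = _gene_target_correlations(E, target)
    candidates = np.array([i for g, i in E._index.items() if g not in exclude])
    if candidates.size < set_size:
        raise ValueError(
            f"only {candidates.size} genes available outside the query set, "
            f"need {set_size}")
    query_idx = [E._index[g] for g in exclude if g in E._index]
    observed = float(np.nanmean(all_r[query_idx])) if query_idx else float("nan")

    rng = np.random.default_rng(seed)
    samples = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(candidates, size=set_size, replace=False)
        samples[i] = np.nanmean(all_r[draw])
    p = permutation_pvalue(samples, observed, tail="greater", smoothed=smoothed)
    return NullDistribution(samples=samples, observed=observed, p=p,
                            tail="greater", seed=seed, smoothed=smoothed,
                            name=f"resampling({target.name})")


def two_sample_t(x, y) -> dict[str, float]:
    """Pooled-variance two-sample Student t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 values per group")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return {"t": float(t), "df": int(x.size + y.size - 2), "p": float(p)}


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    pairwise: list[dict] = field(default_factory=list)  # group_a, group_b, diff, p_adj


def anova_posthoc(groups: dict[str, np.ndarray],
                  posthoc: str = "tukey") -> AnovaResult:
    """One-way fixed-effects ANOVA with all-pairs post-hoc comparisons.

    ``posthoc="tukey"`` uses the Tukey-Kramer studentized-range adjustment
    (valid for unequal group sizes); ``posthoc="fdr"`` runs all pairwise
    pooled t-tests and Benjamini-Hochberg adjusts their p-values.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    F, p = stats.f_oneway(*arrays)
    df1 = len(arrays) - 1
    df2 = sum(a.size for a in arrays) - len(arrays)

    pairwise: list[dict] = []
    if posthoc == "tukey":
        res = stats.tukey_hsd(*arrays)
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                pairwise.append({
                    "group_a": names[i], "group_b": names[j],
                    "diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                })
    elif posthoc == "fdr":
        raw = []
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                tt = two_sample_t(arrays[i], arrays[j])
                raw.append(tt["p"])
                pairwise.append({
                    "group_a": names[i], "group_b": names[j],
                    "diff": float(arrays[i].mean() - arrays[j].mean()),
                })
        for entry, q in zip(pairwise, bh_adjust(raw)):
            entry["p_adj"] = float(q)
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=float(p), pairwise=pairwise)
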