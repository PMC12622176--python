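"""Regional co-expression networks and signed community detection.

Genes whose regional expression profiles rise and fall together across the
cortex form a co-expression network: nodes are genes, edge weights are the
Pearson correlation of their parcelwise maps. Communities in this signed,
weighted network are found with a Louvain algorithm maximising signed
modularity with *symmetric* treatment of negative weights,

    Q = Q+/v+ - Q-/v-,

where Q+ and Q- are the usual modularity sums (with resolution gamma) over
the positive- and negative-edge sub-networks and v+/v- their total weights.
Positive within-community correlation is rewarded and negative
within-community correlation penalised on an equal footing, so communities
are sets of genes that co-vary positively with each other and negatively
with the rest. A resolution below 1 (the default gamma = 0.5) favours
larger, coarser communities.

Louvain is greedy and order-dependent; determinism comes from a fixed
number of seeded restarts, keeping the best-modularity partition with
deterministic tie-breaking.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import ZeroVarianceError
from .expression_maps import ExpressionMatrix, RegionalMap, set_average_map
from .gene_sets import GeneSet


@dataclass
class CoexpressionMatrix:
    """Symmetric gene × gene Pearson r matrix with unit diagonal."""

    genes: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match gene count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("co-expression matrix must be symmetric")

    def to_edge_csv(self, path, threshold: float | None = None) -> None:
        """Weighted edge list ``gene_a,gene_b,r`` (upper triangle)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["gene_a", "gene_b", "r"])
            n = len(self.genes)
            for i in range(n):
                for j in range(i + 1, n):
                    r = self.values[i, j]
                    if threshold is None or r > threshold:
                        w.writerow([self.genes[i], self.genes[j], repr(float(r))])

    def to_graphml(self, path, partition: "Partition | None" = None) -> None:
        import networkx as nx

        g = nx.Graph()
        for i, gene in enumerate(self.genes):
            attrs = {}
            if partition is not None:
                attrs["community"] = partition.communities[gene]
            g.add_node(gene, **attrs)
        n = len(self.genes)
        for i in range(n):
            for j in range(i + 1, n):
                g.add_edge(self.genes[i], self.genes[j],
                           r=float(self.values[i, j]))
        nx.write_graphml(g, path)


def gce_matrix(E: ExpressionMatrix, s: GeneSet) -> CoexpressionMatrix:
    """Gene-to-gene regional co-expression matrix for a gene set.

    Pairwise Pearson correlation of the member genes' maps over the
    non-missing parcels; diagonal fixed at 1.
    """
    present = [g for g in s if g in E._index]
    if len(present) < 3:
        raise ValueError("need at least 3 genes present in the matrix")
    X = E.columns(present)[E.nonmissing]
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ZeroVarianceError(f"zero-variance gene(s): {[present[i] for i in bad]}")
    C = np.corrcoef(X, rowvar=False)
    C = np.clip((C + C.T) / 2, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CoexpressionMatrix(genes=tuple(present), values=C)


def binarized_degree(C: CoexpressionMatrix, threshold: float = 0.3,
                     absolute: bool = False) -> np.ndarray:
    """Nodal degree after binarizing edges at a correlation threshold.

    An edge survives when r > threshold (signed rule, the default) or
    |r| > threshold with ``absolute=True``; the diagonal never counts.
    """
    if not -1 < threshold < 1:
        raise ValueError("threshold must lie in (-1, 1)")
    W = np.abs(C.values) if absolute else C.values
    A = W > threshold
    np.fill_diagonal(A, False)
    return A.sum(axis=1).astype(int)


# --------------------------------------------------------------------------
# signed modularity + Louvain
# --------------------------------------------------------------------------

def _norm_coeffs(vp: float, vn: float, negative: str) -> tuple[float, float]:
    """Per-subnetwork coefficients so Q = ap*S+ - an*S-."""
    ap = 1.0 / vp if vp > 0 else 0.0
    if negative == "sym":
        an = 1.0 / vn if vn > 0 else 0.0
    elif negative == "asym":
        an = 1.0 / (vp + vn) if vn > 0 else 0.0
    else:
        raise ValueError(f"negative must be 'sym' or 'asym', got {negative!r}")
    return ap, an


def signed_modularity(W: np.ndarray, labels: np.ndarray, gamma: float = 0.5,
                      negative: str = "sym") -> float:
    """Signed modularity of a partition of a signed weight matrix."""
    W = np.asarray(W, dtype=float)
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    Wp = np.clip(W, 0, None)
    Wn = np.clip(-W, 0, None)
    ap, an = _norm_coeffs(Wp.sum(), Wn.sum(), negative)
    q = 0.0
    for Wx, coeff in ((Wp, ap), (Wn, -an)):
        v = Wx.sum()
        if v > 0:
            k = Wx.sum(axis=1)
            B = Wx - gamma * np.outer(k, k) / v
            q += coeff * float(B[same].sum())
    return q


def _move_nodes(Wp: np.ndarray, Wn: np.ndarray, gamma: float, negative: str,
                rng: np.random.Generator,
                init: np.ndarray | None = None) -> np.ndarray:
    """One Louvain level: greedy local moving until no gain.

    The positive and negative sub-networks are passed separately (both
    non-negative); diagonals may carry self-loops on aggregated graphs.
    ``init`` seeds the starting partition (default: all singletons).
    """
    n = Wp.shape[0]
    vp, vn = Wp.sum(), Wn.sum()
    ap, an = _norm_coeffs(vp, vn, negative)
    kp, kn = Wp.sum(axis=1), Wn.sum(axis=1)
    # self-loops move with the node: constant across targets, excluded from links
    Wp_nd, Wn_nd = Wp.copy(), Wn.copy()
    np.fill_diagonal(Wp_nd, 0.0)
    np.fill_diagonal(Wn_nd, 0.0)

    labels = np.arange(n) if init is None else np.asarray(init, dtype=int).copy()
    sig_p = np.bincount(labels, weights=kp, minlength=n)
    sig_n = np.bincount(labels, weights=kn, minlength=n)
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            c0 = labels[i]
            lp = np.bincount(labels, weights=Wp_nd[i], minlength=n)
            ln = np.bincount(labels, weights=Wn_nd[i], minlength=n)
            sig_p[c0] -= kp[i]
            sig_n[c0] -= kn[i]
            gain = np.zeros(n)
            if vp > 0:
                gain += ap * (lp - gamma * kp[i] * sig_p / vp)
            if vn > 0:
                gain -= an * (ln - gamma * kn[i] * sig_n / vn)
            best = int(np.argmax(gain))
            if gain[best] <= gain[c0] + 1e-13:
                best = c0
            if best != c0:
                improved = True
            labels[i] = best
            sig_p[best] += kp[i]
            sig_n[best] += kn[i]
    return labels


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel communities 0..k-1 in order of first occurrence."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, c in enumerate(labels):
        out[i] = mapping.setdefault(int(c), len(mapping))
    return out


def _aggregate(Wx: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    C = np.zeros((Wx.shape[0], k))
    C[np.arange(Wx.shape[0]), labels] = 1.0
    return C.T @ Wx @ C  # within-community weights become self-loops


def _louvain_pass(Wp0: np.ndarray, Wn0: np.ndarray, gamma: float, negative: str,
                  rng: np.random.Generator, init: np.ndarray) -> np.ndarray:
    """One full multi-level Louvain pass starting from ``init``."""
    labels = _relabel(_move_nodes(Wp0, Wn0, gamma, negative, rng, init=init))
    node_labels = labels
    k = int(labels.max()) + 1
    # the ± sub-networks are aggregated separately: re-splitting a net
    # weight by sign would change v± and the degree sequences
    Wp, Wn = _aggregate(Wp0, labels, k), _aggregate(Wn0, labels, k)
    while k > 1:
        labels = _relabel(_move_nodes(Wp, Wn, gamma, negative, rng))
        node_labels = labels[node_labels]
        k2 = int(labels.max()) + 1
        if k2 == k:  # no merges at this level: converged
            break
        k = k2
        Wp, Wn = _aggregate(Wp, labels, k), _aggregate(Wn, labels, k)
    return _relabel(node_labels)


def _louvain_run(W: np.ndarray, gamma: float, negative: str,
                 rng: np.random.Generator) -> np.ndarray:
    """Iterated Louvain: full passes re-seeded from the current partition
    (single-node refinement on the original graph) until Q stops rising."""
    n = W.shape[0]
    Wp0 = np.clip(W, 0, None)
    Wn0 = np.clip(-W, 0, None)
    # singleton start on the first pass of half the restarts; random initial
    # partitions otherwise — greedy moving from singletons alone can be
    # unable to reach optima that need coordinated multi-node moves
    if rng.random() < 0.5:
        labels = np.arange(n)
    else:
        labels = rng.integers(0, int(rng.integers(1, n + 1)), size=n)
    q = -np.inf
    while True:
        new = _louvain_pass(Wp0, Wn0, gamma, negative, rng, init=labels)
        new_q = signed_modularity(W, new, gamma, negative)
        if new_q <= q + 1e-12:
            break
        labels, q = new, new_q
    return labels


class SignedLouvain(ClusterMixin, BaseEstimator):
    """Louvain community detection on a signed similarity matrix.

    scikit-learn-style clusterer: ``X`` passed to :meth:`fit` is the square
    symmetric signed weight matrix itself (e.g. a gene × gene correlation
    matrix); the diagonal is ignored.

    Parameters
    ----------
    gamma : float, default 0.5
        Resolution of the modularity null model; values below 1 favour
        larger communities.
    n_restarts : int, default 100
        Seeded restarts with random node orders; the best-modularity
        partition is kept. Ties go to the partition with fewer communities,
        then to the lexicographically smallest canonical labelling, so the
        result is deterministic given ``random_state``.
    random_state : int, default 0
    negative : {"sym", "asym"}, default "sym"
        Symmetric treatment weighs negative edges as heavily as positive
        ones (Q+/v+ - Q-/v-); the asymmetric variant down-weights the
        negative term by v-/(v+ + v-).

    Attributes
    ----------
    labels_ : (n,) int array of community labels, 0-based, first-occurrence
        ordered.
    modularity_ : float, signed modularity of ``labels_``.
    n_communities_ : int
    """

    def __init__(self, gamma: float = 0.5, n_restarts: int = 100,
                 random_state: int = 0, negative: str = "sym"):
        self.gamma = gamma
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.negative = negative

    def fit(self, X, y=None):
        W = check_array(X, dtype=float)
        if W.shape[0] != W.shape[1]:
            raise ValueError("X must be a square weight matrix")
        if not np.allclose(W, W.T, atol=1e-8):
            raise ValueError("X must be symmetric")
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        n = W.shape[0]

        if not np.any(W):
            self.labels_ = np.zeros(n, dtype=int)
            self.modularity_ = 0.0
            self.n_communities_ = 1
            return self

        ss = np.random.SeedSequence(self.random_state)
        best: tuple | None = None
        for child in ss.spawn(self.n_restarts):
            rng = np.random.default_rng(child)
            labels = _louvain_run(W, self.gamma, self.negative, rng)
            q = signed_modularity(W, labels, self.gamma, self.negative)
            key = (-q, int(labels.max()) + 1, tuple(labels))
            if best is None or key < best[0]:
                best = (key, labels, q)
        _, labels, q = best
        self.labels_ = labels
        self.modularity_ = float(q)
        self.n_communities_ = int(labels.max()) + 1
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class Partition:
    """Community assignment of a gene set, ids contiguous from 1."""

    genes: tuple[str, ...]
    communities: dict[str, int]
    modularity: float
    gamma: float
    seed: int
    n_restarts: int

    @property
    def n_communities(self) -> int:
        return len(set(self.communities.values()))

    def members(self, community: int) -> list[str]:
        return [g for g in self.genes if self.communities[g] == community]

    def labels(self) -> np.ndarray:
        return np.array([self.communities[g] for g in self.genes])

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["symbol", "community"])
            for g in self.genes:
                w.writerow([g, self.communities[g]])


def louvain_signed(C: CoexpressionMatrix, gamma: float = 0.5, seed: int = 0,
                   n_restarts: int = 100, negative: str = "sym") -> Partition:
    """Community detection on a co-expression matrix (functional wrapper)."""
    est = SignedLouvain(gamma=gamma, n_restarts=n_restarts,
                        random_state=seed, negative=negative)
    labels = est.fit_predict(C.values) + 1  # 1-based ids
    return Partition(
        genes=C.genes,
        communities={g: int(c) for g, c in zip(C.genes, labels)},
        modularity=est.modularity_,
        gamma=gamma, seed=seed, n_restarts=n_restarts,
    )


def cluster_maps(E: ExpressionMatrix, part: Partition) -> list[RegionalMap]:
    """Average expression map per community, named Cluster 1..k by
    descending community size (ties by community id)."""
    comms = sorted(set(part.communities.values()),
                   key=lambda c: (-len(part.members(c)), c))
    maps = []
    for rank, c in enumerate(comms, start=1):
        s = GeneSet(f"Cluster {rank}", part.members(c))
        m = set_average_map(E, s)
        m.name = f"Cluster {rank}"
        maps.append(m)
    return maps
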