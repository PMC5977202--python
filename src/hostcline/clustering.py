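"""Population clustering: Nei distances, neighbor-joining networks with
locus bootstrap, DAPC with a-score PC selection and permutation
significance, and Mantel tests for isolation by distance / ecology.

Nei's standard genetic distance between populations X and Y over biallelic
loci uses the gene identities

    J_X  = mean_l (p_x^2 + q_x^2),   J_XY = mean_l (p_x p_y + q_x q_y)
    D    = -ln( J_XY / sqrt(J_X * J_Y) )

DAPC (discriminant analysis of principal components) reduces the centred
dosage matrix to m principal components and runs a linear discriminant
analysis with equal group priors and pooled within-group covariance on
the PC scores, which makes it robust to strong LD among loci.  The
a-score picks m: observed self-reassignment success minus the mean
success over label-randomized runs, maximised over the m grid (smallest
m on ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "NjTree",
    "DapcModel",
    "MantelResult",
    "nei_distance",
    "nj_tree",
    "bootstrap_support",
    "dapc_fit",
    "optimize_a_score",
    "cluster_significance",
    "build_predictor_matrices",
    "mantel_test",
]


# ---------------------------------------------------------------------------
# Nei distance


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal; np.inf flagged
    infinite: np.ndarray  # bool mask of pairs with undefined (infinite) D

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def nei_distance(freqs: pd.DataFrame) -> DistanceMatrix:
    """Nei standard genetic distance between all population pairs.

    ``freqs``: populations x SNPs alternate-allele frequencies; loci with
    NA in either member of a pair are dropped pairwise.  A zero between-
    population identity yields an infinite, flagged distance.
    """
    labels = list(freqs.index)
    P = freqs.to_numpy(dtype=float)
    k = len(labels)
    D = np.zeros((k, k))
    inf = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            x, y = P[i], P[j]
            ok = np.isfinite(x) & np.isfinite(y)
            if not ok.any():
                D[i, j] = D[j, i] = np.inf
                inf[i, j] = inf[j, i] = True
                continue
            xi, yi = x[ok], y[ok]
            jx = np.mean(xi**2 + (1 - xi) ** 2)
            jy = np.mean(yi**2 + (1 - yi) ** 2)
            jxy = np.mean(xi * yi + (1 - xi) * (1 - yi))
            if jxy <= 0:
                D[i, j] = D[j, i] = np.inf
                inf[i, j] = inf[j, i] = True
            else:
                d = -math.log(jxy / math.sqrt(jx * jy))
                D[i, j] = D[j, i] = max(d, 0.0) if d > -1e-12 else d
    return DistanceMatrix(labels, D, inf)


# ---------------------------------------------------------------------------
# Neighbor joining


@dataclass
class NjTree:
    """Unrooted tree as an adjacency map; leaves carry population labels."""

    adjacency: dict  # node -> list[(neighbor, branch_length)]
    leaves: list[str]
    supports: dict | None = None  # frozenset(split side) -> percent

    def splits(self) -> set:
        """Non-trivial bipartitions, each canonicalised as the side that
        excludes the alphabetically first leaf."""
        ref = min(self.leaves)
        n = len(self.leaves)
        out: set = set()
        seen: set = set()
        for a in self.adjacency:
            for b, _ in self.adjacency[a]:
                edge = frozenset((a, b))
                if edge in seen:
                    continue
                seen.add(edge)
                side = self._leafset(a, b)
                if not 2 <= len(side) <= n - 2:
                    continue
                if ref in side:
                    side = frozenset(set(self.leaves) - side)
                out.add(side)
        return out

    def canonical_split(self, side) -> frozenset:
        """Canonical form of a bipartition: the side excluding the
        alphabetically first leaf."""
        side = frozenset(side)
        if min(self.leaves) in side:
            side = frozenset(set(self.leaves) - side)
        return side

    def has_split(self, side) -> bool:
        return self.canonical_split(side) in self.splits()

    def support(self, side) -> float | None:
        """Bootstrap support (%) for a bipartition, or None if absent."""
        if self.supports is None:
            return None
        return self.supports.get(self.canonical_split(side))

    def _leafset(self, a, b) -> frozenset:
        """Leaves on b's side of the edge (a, b)."""
        stack, seen, found = [b], {a, b}, set()
        while stack:
            u = stack.pop()
            if isinstance(u, str):
                found.add(u)
            for v, _ in self.adjacency[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return frozenset(found)

    def branch_length(self, a, b) -> float:
        for v, ln in self.adjacency[a]:
            if v == b:
                return ln
        raise KeyError((a, b))

    def newick(self, with_support: bool = False) -> str:
        root = next(n for n in self.adjacency if not isinstance(n, str))
        ref = min(self.leaves)

        def fmt(node, parent, length):
            if isinstance(node, str):
                return f"{node}:{length:.6g}"
            kids = [fmt(v, node, ln) for v, ln in self.adjacency[node] if v != parent]
            label = ""
            if with_support and self.supports is not None and parent is not None:
                side = self._leafset(parent, node)
                if ref in side:
                    side = frozenset(set(self.leaves) - side)
                if side in self.supports:
                    label = f"{self.supports[side]:.0f}"
            inner = "(" + ",".join(kids) + ")" + label
            return inner if parent is None else f"{inner}:{length:.6g}"

        return fmt(root, None, 0.0) + ";"


def nj_tree(dist: DistanceMatrix) -> NjTree:
    """Saitou-Nei neighbor joining.

    Branch lengths from the standard two-leaf update; a negative branch
    length is clamped to zero with the deficit shifted onto its sister
    branch so path lengths between the joined pair are preserved.  Q-matrix
    ties break on the first (row-major) minimal entry, which makes the
    resolution of ultrametric ties deterministic.
    """
    if len(dist.labels) < 3:
        raise ValueError("need at least 3 populations")
    if not np.all(np.isfinite(dist.values)):
        raise ValueError("distance matrix contains infinite entries")

    nodes: list = list(dist.labels)
    d = {
        (a, b): float(dist.values[i, j])
        for i, a in enumerate(dist.labels)
        for j, b in enumerate(dist.labels)
    }
    adjacency: dict = {leaf: [] for leaf in dist.labels}
    next_id = 0

    def dd(a, b):
        return d[(a, b)] if (a, b) in d else d[(b, a)]

    while len(nodes) > 2:
        m = len(nodes)
        r = {a: sum(dd(a, b) for b in nodes if b is not a) for a in nodes}
        best, pair = None, None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = nodes[i], nodes[j]
                q = (m - 2) * dd(a, b) - r[a] - r[b]
                if best is None or q < best - 1e-15:
                    best, pair = q, (a, b)
        a, b = pair
        u = ("internal", next_id)
        next_id += 1
        la = dd(a, b) / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dd(a, b) - la
        if la < 0:
            lb += -la
            la = 0.0
        if lb < 0:
            la += -lb
            lb = 0.0
        adjacency.setdefault(u, [])
        adjacency[u].append((a, la))
        adjacency[u].append((b, lb))
        adjacency[a].append((u, la))
        adjacency[b].append((u, lb))
        for c in nodes:
            if c is a or c is b:
                continue
            d[(u, c)] = (dd(a, c) + dd(b, c) - dd(a, b)) / 2.0
        nodes = [c for c in nodes if c is not a and c is not b] + [u]

    a, b = nodes
    ln = max(dd(a, b), 0.0)
    adjacency[a].append((b, ln))
    adjacency[b].append((a, ln))
    return NjTree(adjacency, list(dist.labels))


def bootstrap_support(
    freqs: pd.DataFrame, n_reps: int = 10000, seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Locus-bootstrap support for the observed NJ topology.

    Loci are resampled with replacement, Nei distances and NJ recomputed,
    and each observed bipartition's recovery percentage recorded.
    Replicates whose resampled distance matrix is not finite are skipped
    (their count is returned).  Returns ``(NjTree with supports, skipped)``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    obs = nj_tree(nei_distance(freqs))
    target = obs.splits()
    counts = {s: 0 for s in target}
    L = freqs.shape[1]
    valid = 0
    skipped = 0
    for _ in range(n_reps):
        idx = rng.integers(0, L, L)
        dm = nei_distance(freqs.iloc[:, idx])
        if dm.infinite.any():
            skipped += 1
            continue
        rep = nj_tree(dm)
        valid += 1
        for s in rep.splits():
            if s in counts:
                counts[s] += 1
    supports = {
        s: (100.0 * c / valid if valid else np.nan) for s, c in counts.items()
    }
    obs.supports = supports
    return obs, skipped


# ---------------------------------------------------------------------------
# DAPC


@dataclass
class DapcModel:
    n_pcs: int
    groups: list[str]
    pc_scores: np.ndarray  # (n, n_pcs)
    pc_var_ratio: np.ndarray
    disc_eigvals: np.ndarray  # <= k-1 discriminant eigenvalues
    disc_shares: np.ndarray  # eigenvalue shares
    coords: np.ndarray  # (n, n_disc) discriminant coordinates
    memberships: pd.DataFrame  # n x k posterior membership probabilities
    labels: np.ndarray
    mean_correct_prob: float
    reassignment_prop: float


def _pca_scores(dosages: np.ndarray, scale: bool = False):
    X = np.asarray(dosages, dtype=float).copy()
    col_mean = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    X[nan] = np.take(col_mean, np.where(nan)[1])
    X -= X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        X /= np.where(sd == 0, 1.0, sd)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    scores = U[:, :rank] * s[:rank]
    var_ratio = (s[:rank] ** 2) / np.sum(s**2)
    return scores, var_ratio, rank


def _lda(scores: np.ndarray, labels: np.ndarray):
    """Equal-prior LDA with pooled within-group covariance in PC space.

    Returns (memberships (n, k), group order, disc eigvals, disc vectors).
    """
    from scipy.linalg import eigh, solve

    groups = list(dict.fromkeys(labels))
    k = len(groups)
    n, m = scores.shape
    means = np.stack([scores[labels == g].mean(axis=0) for g in groups])
    W = np.zeros((m, m))
    for gi, g in enumerate(groups):
        resid = scores[labels == g] - means[gi]
        W += resid.T @ resid
    W /= max(n - k, 1)
    W += np.eye(m) * 1e-9 * max(np.trace(W) / m, 1e-12)
    grand = scores.mean(axis=0)
    B = np.zeros((m, m))
    for gi, g in enumerate(groups):
        ng = np.sum(labels == g)
        diff = (means[gi] - grand)[:, None]
        B += ng * (diff @ diff.T)
    B /= n

    n_disc = min(k - 1, m)
    vals, vecs = eigh(B, W)
    idx = np.argsort(vals)[::-1][:n_disc]
    disc_vals = np.clip(vals[idx], 0.0, None)
    disc_vecs = vecs[:, idx]

    # Gaussian posteriors, pooled covariance, equal priors
    Winv_mu = solve(W, means.T, assume_a="pos")  # (m, k)
    lin = scores @ Winv_mu - 0.5 * np.sum(means.T * Winv_mu, axis=0)[None, :]
    lin -= lin.max(axis=1, keepdims=True)
    post = np.exp(lin)
    post /= post.sum(axis=1, keepdims=True)
    return post, groups, disc_vals, disc_vecs


def _assignment_stats(post: np.ndarray, groups: list, labels: np.ndarray):
    gi = np.array([groups.index(l) for l in labels])
    correct_prob = post[np.arange(len(labels)), gi]
    prop = float(np.mean(np.argmax(post, axis=1) == gi))
    return float(correct_prob.mean()), prop


def dapc_fit(dosages: np.ndarray, labels, n_pcs: int, scale: bool = False) -> DapcModel:
    """Fit DAPC with ``n_pcs`` retained principal components.

    Missing dosages are imputed with the per-SNP mean; columns are centred
    (unit-variance scaling optional).  Membership probabilities come from
    the pooled-covariance Gaussian model with equal priors.
    """
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 individuals")
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    scores, var_ratio, rank = _pca_scores(dosages, scale=scale)
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds rank {rank}")
    S = scores[:, :n_pcs]
    post, group_order, disc_vals, disc_vecs = _lda(S, labels)
    mean_prob, prop = _assignment_stats(post, group_order, labels)
    shares = disc_vals / disc_vals.sum() if disc_vals.sum() > 0 else disc_vals
    return DapcModel(
        n_pcs=n_pcs,
        groups=group_order,
        pc_scores=S,
        pc_var_ratio=var_ratio[:n_pcs],
        disc_eigvals=disc_vals,
        disc_shares=shares,
        coords=S @ disc_vecs,
        memberships=pd.DataFrame(post, columns=group_order),
        labels=labels,
        mean_correct_prob=mean_prob,
        reassignment_prop=prop,
    )


def optimize_a_score(
    dosages: np.ndarray, labels, m_grid, n_rand: int = 10,
    seed: int | None = None, rng: np.random.Generator | None = None,
    scale: bool = False,
):
    """Pick the number of retained PCs by a-score.

    a(m) = observed correct-reassignment proportion minus its mean over
    ``n_rand`` label-randomized refits; returns ``(best_m, curve)`` with
    the smallest m among ties.
    """
    m_grid = list(m_grid)
    if not m_grid:
        raise ValueError("empty m grid")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed) if rng is None else rng
    scores, _, rank = _pca_scores(dosages, scale=scale)
    if max(m_grid) > rank:
        raise ValueError("m grid exceeds PCA rank")
    curve = {}
    for m in sorted(m_grid):
        S = scores[:, :m]
        post, groups, _, _ = _lda(S, labels)
        _, obs_prop = _assignment_stats(post, groups, labels)
        rand = []
        for _ in range(n_rand):
            perm = rng.permutation(labels)
            post_r, groups_r, _, _ = _lda(S, perm)
            _, prop_r = _assignment_stats(post_r, groups_r, perm)
            rand.append(prop_r)
        curve[m] = obs_prop - float(np.mean(rand))
    best = max(curve, key=lambda m: (curve[m], -m))
    return best, curve


def cluster_significance(
    dosages: np.ndarray, labels, n_pcs: int, n_reps: int = 10000,
    seed: int | None = None, rng: np.random.Generator | None = None,
    scale: bool = False,
):
    """Permutation p-value for genetic clustering.

    Labels are permuted (group sizes preserved), the discriminant analysis
    refit on the same retained PCs, and the mean correct-assignment
    probability recorded; p = (1 + #{null >= observed}) / (n_reps + 1).
    Returns ``(observed, p, null draws)``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed) if rng is None else rng
    scores, _, rank = _pca_scores(dosages, scale=scale)
    if n_pcs > rank:
        raise ValueError("n_pcs exceeds rank")
    S = scores[:, :n_pcs]
    post, groups, _, _ = _lda(S, labels)
    obs, _ = _assignment_stats(post, groups, labels)
    null = np.empty(n_reps)
    for i in range(n_reps):
        perm = rng.permutation(labels)
        post_r, groups_r, _, _ = _lda(S, perm)
        null[i], _ = _assignment_stats(post_r, groups_r, perm)
    p = float((1.0 + np.sum(null >= obs)) / (n_reps + 1.0))
    return obs, p, null


# ---------------------------------------------------------------------------
# Mantel


def build_predictor_matrices(pop_meta: pd.DataFrame):
    """Geographic and ecological predictor matrices between populations.

    ``pop_meta``: indexed by population label with ``site_order`` and
    ``host`` columns.  Geographic entry = |order_i - order_j|; host entry
    is 0 for same host, 1 for different.
    """
    if pop_meta["site_order"].isna().any():
        raise ValueError("site_order missing for some population")
    labels = list(pop_meta.index)
    order = pop_meta["site_order"].to_numpy(dtype=float)
    host = pop_meta["host"].to_numpy()
    geo = np.abs(order[:, None] - order[None, :])
    eco = (host[:, None] != host[None, :]).astype(float)
    return (
        pd.DataFrame(geo, index=labels, columns=labels),
        pd.DataFrame(eco, index=labels, columns=labels),
    )


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def mantel_test(
    genetic: pd.DataFrame, predictor: pd.DataFrame, n_perm: int = 10000,
    seed: int | None = None, rng: np.random.Generator | None = None,
) -> MantelResult:
    """One-tailed Mantel test (positive association).

    r is the Pearson correlation of upper-triangle entries; permutations
    jointly shuffle rows and columns of the genetic matrix while the
    predictor stays fixed; p = (1 + #{r_perm >= r_obs}) / (n_perm + 1).
    """
    if list(genetic.index) != list(predictor.index):
        raise ValueError("matrices must share label order")
    k = genetic.shape[0]
    if k < 4:
        raise ValueError("need at least 4 populations")
    G = genetic.to_numpy(dtype=float)
    X = predictor.to_numpy(dtype=float)
    iu = np.triu_indices(k, 1)
    xv = X[iu]
    if xv.std() == 0:
        raise ValueError("constant predictor matrix")
    r_obs = float(np.corrcoef(G[iu], xv)[0, 1])
    rng = np.random.default_rng(seed) if rng is None else rng
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        Gp = G[np.ix_(perm, perm)]
        if np.corrcoef(Gp[iu], xv)[0, 1] >= r_obs:
            count += 1
    return MantelResult(r_obs, float((1.0 + count) / (n_perm + 1.0)), n_perm)
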