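"""Composite linkage disequilibrium (Burrows/Weir) and LD-class structure.

Composite LD is estimable from unphased genotypes: for loci A and B with
alternate-allele dosages X, Y in {0, 1, 2} (or posterior-mean dosages for
low-coverage data),

    Delta_hat = (1/2n) * sum X_i Y_i - 2 * p_A * p_B
    r_hat     = Delta_hat / sqrt((p_A q_A + D_A)(p_B q_B + D_B))

where D_A = P_AA - p_A^2 is the within-locus Hardy-Weinberg
disequilibrium.  With population (1/n) moments these identities reduce to
half the dosage covariance and the dosage Pearson correlation, which is
how the vectorised routines compute them.

Within-chromosome r^2 drives a threshold-graph classification into high,
intermediate and low LD classes - proxies for how tightly SNPs track
inversion polymorphisms: a SNP is *high* iff it has r^2 > 0.6 with at
least one other SNP on its chromosome, *low* iff every within-chromosome
r^2 is < 0.15, and *intermediate* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "LdPair",
    "LdClassAssignment",
    "composite_ld",
    "pairwise_composite_ld",
    "classify_ld_network",
    "assign_ld_classes",
    "mean_linked_ld",
    "select_strong_diapause_snps",
    "interchromosomal_ld_distributions",
]

HIGH_R2 = 0.6
LOW_R2 = 0.15


@dataclass
class LdPair:
    snp_a: str
    snp_b: str
    delta: float
    r: float
    r2: float
    n: int
    reason: str | None = None  # set when the pair is NA


def composite_ld(x, y, snp_a: str = "A", snp_b: str = "B") -> LdPair:
    """Composite LD for one locus pair from dosage vectors.

    Missing entries are dropped pairwise.  Returns an NA pair (NaN
    statistics with a reason) when fewer than two complete individuals
    remain or either locus is monomorphic in the sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < 2:
        return LdPair(snp_a, snp_b, np.nan, np.nan, np.nan, n, "fewer than 2 complete individuals")
    x, y = x[ok], y[ok]
    vx = x.var()  # population (1/n) moments throughout
    vy = y.var()
    if vx == 0 or vy == 0:
        return LdPair(snp_a, snp_b, np.nan, np.nan, np.nan, n, "monomorphic locus")
    delta = (x * y).mean() / 2.0 - 2.0 * (x.mean() / 2.0) * (y.mean() / 2.0)
    r = delta / np.sqrt((vx / 2.0) * (vy / 2.0))
    return LdPair(snp_a, snp_b, float(delta), float(r), float(r * r), n)


def composite_ld_bruteforce(gx, gy) -> float:
    """Genotype-count form of Delta_hat (hard genotypes only); test oracle.

    Delta = (2 n_AABB + n_AABb + n_AaBB + n_AaBb / 2) / n - 2 p_A p_B
    """
    gx = np.asarray(gx, dtype=int)
    gy = np.asarray(gy, dtype=int)
    n = gx.size
    n_AABB = np.sum((gx == 2) & (gy == 2))
    n_AABb = np.sum((gx == 2) & (gy == 1))
    n_AaBB = np.sum((gx == 1) & (gy == 2))
    n_AaBb = np.sum((gx == 1) & (gy == 1))
    pA = gx.mean() / 2.0
    pB = gy.mean() / 2.0
    return (2 * n_AABB + n_AABb + n_AaBB + 0.5 * n_AaBb) / n - 2 * pA * pB


def _pairwise_moments(D: np.ndarray):
    """NaN-aware pairwise first/second moments via masked matmuls."""
    M = (~np.isnan(D)).astype(float)
    D0 = np.nan_to_num(D)
    n = M.T @ M
    Sx = D0.T @ M  # sum of x over joint support, per (i, j)
    Sxy = D0.T @ D0
    Sxx = (D0 * D0).T @ M
    return n, Sx, Sxy, Sxx


def pairwise_composite_ld(D: np.ndarray):
    """Delta and r matrices for all column pairs of a dosage matrix.

    Pairwise-complete over missing entries; diagonal is NaN.  Pairs with
    fewer than two shared individuals or a monomorphic locus are NaN.
    """
    D = np.asarray(D, dtype=float)
    n, Sx, Sxy, Sxx = _pairwise_moments(D)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = Sx / n
        my = Sx.T / n
        cov = Sxy / n - mx * my
        vx = Sxx / n - mx**2
        vy = Sxx.T / n - my**2
        bad = (n < 2) | (vx <= 0) | (vy <= 0)
        delta = np.where(bad, np.nan, cov / 2.0)
        r = np.where(bad, np.nan, cov / np.sqrt(np.where(bad, 1.0, vx * vy)))
    np.fill_diagonal(delta, np.nan)
    np.fill_diagonal(r, np.nan)
    return delta, r, n


@dataclass
class LdClassAssignment:
    snp_ids: list[str]
    classes: np.ndarray  # per-SNP {high, intermediate, low, unassigned}
    max_r2: np.ndarray
    components: dict  # component id -> list of snp ids (high-LD graph)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "ld_class": self.classes, "max_r2": self.max_r2}
        )


def classify_ld_network(r2: np.ndarray, snp_ids, high: float = HIGH_R2,
                        low: float = LOW_R2) -> LdClassAssignment:
    """Classify SNPs of one chromosome from their within-chromosome r^2 matrix.

    Strict thresholds: high iff max off-diagonal r^2 > ``high``; low iff
    max < ``low`` (a SNP alone on its chromosome vacuously satisfies this);
    r^2 exactly in [low, high] is intermediate.  SNPs whose row is all-NA
    against a non-trivial chromosome are left unassigned.  High-class SNPs
    are additionally grouped into connected components of the > ``high``
    graph.
    """
    r2 = np.asarray(r2, dtype=float)
    m = r2.shape[0]
    if r2.shape != (m, m):
        raise ValueError("r2 matrix must be square")
    snp_ids = list(snp_ids)
    if len(snp_ids) != m:
        raise ValueError("snp_ids length mismatch")

    classes = np.full(m, "low", dtype=object)
    if m == 1:
        return LdClassAssignment(snp_ids, classes, np.full(1, np.nan), {})
    work = r2.copy()
    np.fill_diagonal(work, np.nan)
    all_na = np.all(np.isnan(work), axis=1)
    with np.errstate(invalid="ignore"):
        max_r2 = np.where(all_na, np.nan, np.nanmax(np.where(np.isnan(work), -np.inf, work), axis=1))
    classes[all_na] = "unassigned"
    hi = ~all_na & (max_r2 > high)
    mid = ~all_na & ~hi & (max_r2 >= low)
    classes[hi] = "high"
    classes[mid] = "intermediate"

    components: dict = {}
    if hi.any():
        adj = np.where(np.isnan(work), 0.0, work) > high
        idx = np.where(hi)[0]
        sub = adj[np.ix_(idx, idx)]
        n_comp, labels = connected_components(csr_matrix(sub), directed=False)
        for cid in range(n_comp):
            components[cid] = [snp_ids[idx[k]] for k in np.where(labels == cid)[0]]
    return LdClassAssignment(snp_ids, classes, max_r2, components)


def assign_ld_classes(dosages: np.ndarray, snp_map: pd.DataFrame, high: float = HIGH_R2,
                      low: float = LOW_R2) -> pd.DataFrame:
    """Per-SNP LD class over all mapped chromosomes; unmapped SNPs unassigned."""
    out = pd.DataFrame(
        {"snp_id": snp_map["snp_id"], "ld_class": "unassigned", "max_r2": np.nan}
    ).set_index("snp_id")
    for chrom, grp in snp_map.groupby("chrom"):
        if str(chrom) == "un":
            continue
        idx = grp.index.to_numpy()
        _, r, _ = pairwise_composite_ld(dosages[:, idx])
        assign = classify_ld_network(r**2, grp["snp_id"].tolist(), high, low)
        out.loc[assign.snp_ids, "ld_class"] = assign.classes
        out.loc[assign.snp_ids, "max_r2"] = assign.max_r2
    return out.reset_index()


def mean_linked_ld(dosages: np.ndarray, snp_map: pd.DataFrame, stat: str = "r2") -> pd.Series:
    """Per mapped SNP, mean LD (r^2 by default, |r| optional) to every other
    SNP on the same chromosome; NaN for unmapped or singleton SNPs."""
    if stat not in ("r2", "abs_r"):
        raise ValueError("stat must be 'r2' or 'abs_r'")
    out = pd.Series(np.nan, index=snp_map["snp_id"], name="mean_linked_ld")
    for chrom, grp in snp_map.groupby("chrom"):
        if str(chrom) == "un" or len(grp) < 2:
            continue
        idx = grp.index.to_numpy()
        _, r, _ = pairwise_composite_ld(dosages[:, idx])
        vals = r**2 if stat == "r2" else np.abs(r)
        cnt = (~np.isnan(vals)).sum(axis=1)
        means = np.where(cnt > 0, np.nansum(vals, axis=1) / np.maximum(cnt, 1), np.nan)
        out.loc[grp["snp_id"].to_numpy()] = means
    return out


def select_strong_diapause_snps(study_results: dict, min_diff: float = 0.2) -> np.ndarray:
    """SNPs under strong diapause-related selection.

    ``study_results`` maps study name -> DataFrame with columns
    ``significant`` (bool) and ``abs_diff``, indexed consistently.  A SNP
    is kept iff it is significant in at least one study AND shows an
    absolute frequency response of at least ``min_diff`` in at least one
    study.  Returns the boolean keep mask (aligned to the shared index).
    """
    if not study_results:
        raise ValueError("no study results supplied")
    frames = list(study_results.values())
    idx = frames[0].index
    for f in frames[1:]:
        if not f.index.equals(idx):
            raise ValueError("study results are not aligned")
        if "significant" not in f or "abs_diff" not in f:
            raise ValueError("study results need 'significant' and 'abs_diff' columns")
    any_sig = np.zeros(len(idx), dtype=bool)
    any_big = np.zeros(len(idx), dtype=bool)
    for f in frames:
        any_sig |= f["significant"].fillna(False).to_numpy(dtype=bool)
        any_big |= (f["abs_diff"].to_numpy(dtype=float) >= min_diff)
    return any_sig & any_big


def _pool_delta(dosage_blocks: list[np.ndarray], idx: np.ndarray) -> np.ndarray:
    D = np.concatenate([d[:, idx] for d in dosage_blocks], axis=0)
    delta, _, _ = pairwise_composite_ld(D)
    return delta


def interchromosomal_ld_distributions(
    dosages_by_pop: dict, snp_map: pd.DataFrame, snp_subset, groupings: dict
) -> dict:
    """Composite-LD distributions among unlinked (different-chromosome) SNPs.

    ``groupings`` maps a mode name (e.g. ``within_population``,
    ``pooled_hosts_per_site``, ``pooled_geographic_extremes``) to a list of
    pools, each pool being a list of population labels whose individuals
    are concatenated before LD is computed.  For every mode the per-pair
    Delta is averaged across its pools, and the distribution over
    different-chromosome pairs is returned with summary statistics.
    """
    keep = snp_map["snp_id"].isin(set(snp_subset)) & (snp_map["chrom"].astype(str) != "un")
    idx = snp_map.index.to_numpy()[keep.to_numpy()]
    chroms = snp_map.loc[keep, "chrom"].astype(str).to_numpy()
    if len(set(chroms)) < 2:
        raise ValueError("need SNPs on at least two chromosomes")
    inter = chroms[:, None] != chroms[None, :]
    iu = np.triu_indices(len(idx), k=1)
    pair_mask = inter[iu]
    if not pair_mask.any():
        raise ValueError("empty interchromosomal pair set")

    out = {}
    for mode, pools in groupings.items():
        stack = []
        for pool in pools:
            delta = _pool_delta([dosages_by_pop[p] for p in pool], idx)
            stack.append(delta[iu][pair_mask])
        arr = np.stack(stack, axis=0)
        cnt = (~np.isnan(arr)).sum(axis=0)
        vals = np.where(cnt > 0, np.nansum(arr, axis=0) / np.maximum(cnt, 1), np.nan)
        vals = vals[~np.isnan(vals)]
        out[mode] = {
            "values": vals,
            "mean": float(np.mean(vals)) if vals.size else np.nan,
            "quantiles": {
                q: float(np.quantile(vals, q)) for q in (0.05, 0.25, 0.5, 0.75, 0.95)
            } if vals.size else {},
            "n_pairs": int(vals.size),
        }
    return out
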