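"""Whole-genotype Monte Carlo resampling tests.

The null model for a two-group frequency comparison is built by drawing,
with replacement from the pooled individuals of both groups, randomized
samples of the original group sizes and recomputing per-SNP allele
frequency differences.  Resampling whole individuals (their entire
multi-locus genotype, missingness pattern included) preserves LD among
loci in the null, which per-SNP binomial shuffles would destroy.

A SNP is significant when its observed |dp| strictly exceeds the 95th
percentile (linear interpolation) of its own null |dp| draws - a
two-sided test at overall alpha.  The table-wise excess test asks whether
the *percentage* of significant SNPs is itself larger than expected:
each replicate is scored against the same per-SNP critical values and the
observed percentage is compared to the replicate distribution.

Within replicates, per-individual genotype posteriors are computed once
from the pooled sample and group frequencies re-estimated as mean
posterior dosage / 2 over the resampled individuals; the observed
statistic uses the same estimator so that observed and null are exactly
comparable.  Monte Carlo p-values use the add-one convention
(1 + #{null >= obs}) / (n_reps + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeData, allele_frequencies, posterior_dosages, _check_groups

__all__ = [
    "NullDistribution",
    "McTestResult",
    "mc_difference_test",
    "tablewise_excess_test",
    "mc_regression_significance",
]

MIN_NULL_DRAWS = 100


@dataclass
class NullDistribution:
    null_abs: np.ndarray | None  # (n_reps, n_snps) float32, NaN where undefined
    crit: np.ndarray  # per-SNP (1 - alpha) null quantile of |dp|
    n_draws: np.ndarray  # valid draws per SNP
    null_percent: np.ndarray | None  # per-replicate % of SNPs beyond their crit
    n_reps: int
    alpha: float
    seed: int | None


@dataclass
class McTestResult:
    snp_ids: list[str]
    obs_diff: np.ndarray  # signed, group1 - group2
    obs_abs: np.ndarray
    crit: np.ndarray
    significant: np.ndarray  # bool; False where crit undefined
    testable: np.ndarray  # bool; SNP had >= MIN_NULL_DRAWS null draws and finite obs
    observed_percent: float  # % significant among testable SNPs
    tablewise_p: float | None
    tablewise_excess: bool | None
    null: NullDistribution | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "obs_diff": self.obs_diff,
                "abs_diff": self.obs_abs,
                "crit": self.crit,
                "significant": self.significant,
            }
        )


def _group_freqs_from_dosages(dos: np.ndarray, rows: np.ndarray) -> np.ndarray:
    sub = dos[rows]
    cnt = (~np.isnan(sub)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.nansum(sub, axis=0) / (2.0 * cnt)
    return np.where(cnt > 0, f, np.nan)


def _null_freq_matrix(dos0, info, counts):
    """Frequencies for resampled groups via multinomial count matmuls.

    counts: (n_reps, n_pool) how many times each pooled individual is drawn.
    """
    sums = counts @ dos0  # (n_reps, n_snps)
    ns = counts @ info
    with np.errstate(invalid="ignore", divide="ignore"):
        f = sums / (2.0 * ns)
    return np.where(ns > 0, f, np.nan)


def mc_difference_test(
    data: GenotypeData,
    group1,
    group2,
    n_reps: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    keep_null: bool = True,
    resample: str = "bootstrap",
) -> McTestResult:
    """Per-SNP Monte Carlo frequency-difference test with table-wise excess.

    ``resample="bootstrap"`` draws both null groups with replacement from
    the pooled individuals (the default procedure).  ``"permutation"``
    splits the pool without replacement instead; the per-SNP test behaves
    the same but the table-wise p-value is exactly calibrated under the
    null, which the bootstrap's is not (see the methods note).
    Deterministic given ``seed`` (or a supplied generator).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if resample not in ("bootstrap", "permutation"):
        raise ValueError("resample must be 'bootstrap' or 'permutation'")
    g1, g2 = _check_groups(group1, group2)
    rng = np.random.default_rng(seed) if rng is None else rng

    pooled = g1 + g2
    pool = data.subset(pooled)
    freqs = allele_frequencies(pool)
    dos = posterior_dosages(pool, freqs)  # (n_pool, n_snps), NaN at missing
    n1, n2 = len(g1), len(g2)
    rows1 = np.arange(n1)
    rows2 = np.arange(n1, n1 + n2)

    p1 = _group_freqs_from_dosages(dos, rows1)
    p2 = _group_freqs_from_dosages(dos, rows2)
    obs_diff = p1 - p2
    obs_abs = np.abs(obs_diff)

    info = (~np.isnan(dos)).astype(np.float32)
    dos0 = np.nan_to_num(dos).astype(np.float32)
    n_pool = n1 + n2
    if resample == "bootstrap":
        probs = np.full(n_pool, 1.0 / n_pool)
        c1 = rng.multinomial(n1, probs, size=n_reps).astype(np.float32)
        c2 = rng.multinomial(n2, probs, size=n_reps).astype(np.float32)
    else:
        base = np.r_[np.ones(n1, np.float32), np.zeros(n2, np.float32)]
        c1 = rng.permuted(np.tile(base, (n_reps, 1)), axis=1)
        c2 = 1.0 - c1
    null_abs = np.abs(
        _null_freq_matrix(dos0, info, c1) - _null_freq_matrix(dos0, info, c2)
    ).astype(np.float32)

    n_draws = (~np.isnan(null_abs)).sum(axis=0)
    crit = np.full(data.n_snps, np.nan)
    has = n_draws > 0
    if has.any():
        crit[has] = np.nanquantile(null_abs[:, has], 1.0 - alpha, axis=0)
    testable = (n_draws >= MIN_NULL_DRAWS) & np.isfinite(obs_abs)
    significant = testable & (obs_abs > crit)
    observed_percent = (
        100.0 * significant[testable].mean() if testable.any() else np.nan
    )

    null = NullDistribution(
        null_abs if keep_null else None, crit, n_draws, None, n_reps, alpha, seed
    )
    result = McTestResult(
        list(data.snp_ids), obs_diff, obs_abs, crit, significant, testable,
        observed_percent, None, None, null,
    )
    if keep_null:
        tablewise_excess_test(result, null, _null_abs=null_abs, _testable=testable)
    return result


def tablewise_excess_test(
    result: McTestResult,
    null: NullDistribution | None = None,
    _null_abs: np.ndarray | None = None,
    _testable: np.ndarray | None = None,
) -> float:
    """Table-wise excess of significant SNPs.

    Per replicate, the percentage of SNPs whose null |dp| exceeds their own
    critical value; the observed percentage is in excess iff it exceeds the
    95th percentile of replicate percentages.  Updates ``result`` in place
    and returns the Monte Carlo p-value.
    """
    null = result.null if null is None else null
    null_abs = _null_abs if _null_abs is not None else (null.null_abs if null else None)
    if null_abs is None:
        raise ValueError("per-SNP null draws were not retained")
    testable = _testable if _testable is not None else result.testable
    cols = np.where(testable)[0]
    beyond = null_abs[:, cols] > null.crit[cols][None, :]
    valid = ~np.isnan(null_abs[:, cols])
    with np.errstate(invalid="ignore", divide="ignore"):
        perc = 100.0 * beyond.sum(axis=1) / np.maximum(valid.sum(axis=1), 1)
    obs = result.observed_percent
    p = (1.0 + np.sum(perc >= obs)) / (null.n_reps + 1.0)
    excess = obs > np.quantile(perc, 0.95)
    null.null_percent = perc
    result.tablewise_p = float(p)
    result.tablewise_excess = bool(excess)
    return float(p)


def mc_regression_significance(
    data: GenotypeData,
    group1,
    group2,
    predictor: np.ndarray,
    n_reps: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    resample_predictor: bool = False,
):
    """Monte Carlo significance for a cross-experiment regression.

    The observed r^2 regresses the group1-minus-group2 frequency response
    on the (fixed) predictor across SNPs; null replicates rebuild the
    response from individuals resampled out of the pooled groups.  The
    predictor is held fixed by default (it comes from an independent
    experiment); ``resample_predictor`` additionally permutes it per
    replicate.  Returns ``(r2_obs, p, null_r2)``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    g1, g2 = _check_groups(group1, group2)
    rng = np.random.default_rng(seed) if rng is None else rng
    x = np.asarray(predictor, dtype=float)
    if x.shape[0] != data.n_snps:
        raise ValueError("predictor not aligned to SNP panel")

    pool = data.subset(g1 + g2)
    freqs = allele_frequencies(pool)
    dos = posterior_dosages(pool, freqs)
    n1, n2 = len(g1), len(g2)
    p1 = _group_freqs_from_dosages(dos, np.arange(n1))
    p2 = _group_freqs_from_dosages(dos, np.arange(n1, n1 + n2))
    y = p1 - p2

    keep = np.isfinite(y) & np.isfinite(x)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 SNPs with complete data")
    r_obs = np.corrcoef(x[keep], y[keep])[0, 1]
    r2_obs = float(r_obs**2)

    info = (~np.isnan(dos)).astype(np.float32)[:, keep]
    dos0 = np.nan_to_num(dos).astype(np.float32)[:, keep]
    xk = x[keep]
    n_pool = n1 + n2
    probs = np.full(n_pool, 1.0 / n_pool)
    c1 = rng.multinomial(n1, probs, size=n_reps).astype(np.float32)
    c2 = rng.multinomial(n2, probs, size=n_reps).astype(np.float32)
    V = _null_freq_matrix(dos0, info, c1) - _null_freq_matrix(dos0, info, c2)
    if resample_predictor:
        perm = rng.permuted(np.tile(xk, (n_reps, 1)), axis=1)
        null_r2 = _rowwise_r2_matrix(V, perm)
    else:
        null_r2 = _rowwise_r2(V, xk)
    p = float((1.0 + np.sum(null_r2 >= r2_obs)) / (n_reps + 1.0))
    return r2_obs, p, null_r2


def _rowwise_r2(V: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of each row of V with x, NaN-aware."""
    M = ~np.isnan(V)
    V0 = np.nan_to_num(V)
    n = M.sum(axis=1)
    Sx = M @ x
    Sxx = M @ (x * x)
    Sv = V0.sum(axis=1)
    Svv = (V0 * V0).sum(axis=1)
    Svx = V0 @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = Svx / n - (Sv / n) * (Sx / n)
        vv = Svv / n - (Sv / n) ** 2
        vx = Sxx / n - (Sx / n) ** 2
        r2 = cov**2 / (vv * vx)
    return np.where((n >= 3) & (vv > 0) & (vx > 0), r2, np.nan)


def _rowwise_r2_matrix(V: np.ndarray, X: np.ndarray) -> np.ndarray:
    out = np.empty(V.shape[0])
    for i in range(V.shape[0]):
        row = V[i]
        ok = ~np.isnan(row)
        if ok.sum() < 3 or row[ok].std() == 0 or X[i, ok].std() == 0:
            out[i] = np.nan
            continue
        out[i] = np.corrcoef(row[ok], X[i, ok])[0, 1] ** 2
    return out
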