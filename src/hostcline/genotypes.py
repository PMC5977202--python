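"""Genotype-likelihood data and allele-frequency estimation.

Low-coverage GBS data (~3-6x mean depth) does not support hard genotype
calls, so every downstream statistic here is computed from per-individual
genotype likelihoods.  Allele frequencies are estimated by an EM algorithm
that places a Hardy-Weinberg prior on the three diploid genotypes and
iterates posterior genotype weights against the frequency estimate.
Expected allele dosages (posterior-mean alternate-allele copy numbers)
are the working currency for LD, resampling tests and clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "GenotypeData",
    "AlleleFrequencies",
    "FrequencyDifference",
    "read_genotype_data",
    "read_sample_metadata",
    "read_snp_map",
    "estimate_allele_freq_em",
    "allele_frequencies",
    "posterior_dosages",
    "frequency_difference",
    "mean_eclosion_response",
    "polarize_to_reference",
]

_FLAT_TOL = 1e-12


@dataclass
class GenotypeData:
    """Genotype likelihoods for a sample x SNP panel.

    ``likelihoods`` holds linear-scale likelihoods, normalised to sum to 1
    over the three genotypes (0, 1, 2 alternate-allele copies); missing
    entries (zero sequencing depth) are NaN and mirrored in ``missing``.
    """

    likelihoods: np.ndarray  # (n_samples, n_snps, 3)
    missing: np.ndarray  # (n_samples, n_snps) bool
    samples: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        n, s, g = self.likelihoods.shape
        if g != 3:
            raise ValueError("likelihoods must have 3 genotype columns")
        if self.missing.shape != (n, s):
            raise ValueError("missing mask shape mismatch")
        if len(self.samples) != n or len(self.snp_ids) != s:
            raise ValueError("sample/SNP label lengths inconsistent with matrix")
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.likelihoods.shape[0]

    @property
    def n_snps(self) -> int:
        return self.likelihoods.shape[1]

    def sample_indices(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.asarray([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise KeyError(f"sample {exc.args[0]!r} not present in genotype data") from None

    def subset(self, sample_ids) -> "GenotypeData":
        idx = self.sample_indices(sample_ids)
        return GenotypeData(
            self.likelihoods[idx],
            self.missing[idx],
            [self.samples[i] for i in idx],
            list(self.snp_ids),
        )

    def informative_mask(self) -> np.ndarray:
        """True where an entry is non-missing and not genotype-flat."""
        L = self.likelihoods
        with np.errstate(invalid="ignore"):
            flat = (np.abs(L[..., 0] - L[..., 1]) < _FLAT_TOL) & (
                np.abs(L[..., 1] - L[..., 2]) < _FLAT_TOL
            )
        return ~self.missing & ~flat


@dataclass
class AlleleFrequencies:
    """Per-SNP alternate-allele frequency estimates with effective n."""

    freqs: np.ndarray  # (n_snps,), NaN where no informative individual
    n_eff: np.ndarray  # (n_snps,) informative individuals used
    snp_ids: list[str]
    posteriors: np.ndarray | None = None  # (n, n_snps, 3) on request

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.snp_ids, "p_hat": self.freqs, "n_eff": self.n_eff})


@dataclass
class FrequencyDifference:
    """Signed per-SNP frequency difference, group1 minus group2."""

    values: np.ndarray
    snp_ids: list[str]
    group1: str
    group2: str
    orientation: str = ""

    def swapped(self) -> "FrequencyDifference":
        return FrequencyDifference(
            -self.values, self.snp_ids, self.group2, self.group1, self.orientation
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.snp_ids, "delta_p": self.values})


# ---------------------------------------------------------------------------
# Readers


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id in metadata: {dup!r}")
    return meta


def read_snp_map(path) -> pd.DataFrame:
    snpmap = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    if snpmap["snp_id"].duplicated().any():
        raise ValueError("duplicate snp id in map")
    return snpmap


def read_genotype_data(vcf_path, metadata_path, snpmap_path):
    """Read a biallelic-SNP VCF with GL or PL plus metadata and map tables.

    Returns ``(GenotypeData, metadata, snp_map)`` with rows of the
    likelihood matrix in VCF sample order and metadata aligned to it.
    SNPs absent from the map table are marked chromosome ``un`` with LD
    class ``unassigned``.
    """
    meta = read_sample_metadata(metadata_path)
    snpmap = read_snp_map(snpmap_path)

    vcf = pysam.VariantFile(str(vcf_path))
    samples = list(vcf.header.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample id in VCF")
    known = set(meta["sample_id"])
    for s in samples:
        if s not in known:
            raise ValueError(f"sample {s!r} in VCF is missing from metadata")

    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(f"record {rec.id or rec.pos} is not biallelic")
        gl = np.full((len(samples), 3), np.nan)
        for i, s in enumerate(samples):
            fmt = rec.samples[s]
            vals = None
            if "GL" in fmt and fmt.get("GL") is not None:
                v = fmt["GL"]
                if v is not None and None not in v:
                    vals = np.power(10.0, np.asarray(v, dtype=float))
            if vals is None and "PL" in fmt and fmt.get("PL") is not None:
                v = fmt["PL"]
                if v is not None and None not in v:
                    vals = np.power(10.0, -np.asarray(v, dtype=float) / 10.0)
            if vals is not None:
                if len(vals) != 3:
                    raise ValueError("expected 3 GL/PL values per biallelic genotype")
                gl[i] = vals
        if np.all(np.isnan(gl)):
            has_fields = {"GL", "PL"} & set(rec.format.keys())
            if not has_fields:
                raise ValueError(f"record {rec.id or rec.pos} has no GL or PL field")
        snp_ids.append(rec.id if rec.id else f"{rec.chrom}:{rec.pos}")
        rows.append(gl)
    vcf.close()

    L = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0, 3))
    missing = np.isnan(L[..., 0])
    with np.errstate(invalid="ignore"):
        tot = L.sum(axis=-1, keepdims=True)
    L = np.where(missing[..., None], np.nan, L / np.where(tot == 0, 1.0, tot))
    data = GenotypeData(L, missing, samples, snp_ids)

    snpmap = snpmap.set_index("snp_id").reindex(snp_ids)
    snpmap["chrom"] = snpmap["chrom"].fillna("un")
    if "ld_class" in snpmap.columns:
        snpmap["ld_class"] = snpmap["ld_class"].fillna("unassigned")
    else:
        snpmap["ld_class"] = "unassigned"
    snpmap = snpmap.reset_index()

    meta = meta.set_index("sample_id").loc[samples].reset_index()
    return data, meta, snpmap


# ---------------------------------------------------------------------------
# EM allele frequencies


def _em_frequencies(L, informative, tol, max_iter, return_posteriors, init=0.5):
    """Vectorised EM over SNP columns.

    L: (n, S, 3) linear likelihoods with NaN at missing entries;
    informative: (n, S) bool.  Uninformative individuals are excluded:
    they do not move the fixed point and only dilute convergence.
    """
    n, S, _ = L.shape
    n_inf = informative.sum(axis=0)
    Lw = np.where(informative[..., None], np.nan_to_num(L, nan=1.0 / 3.0), 1.0 / 3.0)

    p = np.full(S, init, dtype=float)
    for _ in range(max_iter):
        pc = np.clip(p, 1e-9, 1 - 1e-9)
        prior = np.stack(((1 - pc) ** 2, 2 * pc * (1 - pc), pc**2), axis=-1)  # (S, 3)
        w = Lw * prior[None]
        w /= w.sum(axis=-1, keepdims=True)
        dos = w[..., 1] + 2.0 * w[..., 2]
        num = np.where(informative, dos, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_new = num / (2.0 * n_inf)
        p_new = np.where(n_inf > 0, p_new, np.nan)
        delta = np.nanmax(np.abs(p_new - p)) if np.any(n_inf > 0) else 0.0
        p = p_new
        if delta < tol:
            break
    post = None
    if return_posteriors:
        pc = np.clip(np.where(np.isnan(p), 0.5, p), 1e-9, 1 - 1e-9)
        prior = np.stack(((1 - pc) ** 2, 2 * pc * (1 - pc), pc**2), axis=-1)
        post = np.nan_to_num(L, nan=1.0 / 3.0) * prior[None]
        post /= post.sum(axis=-1, keepdims=True)
        post = np.where(np.isnan(L[..., :1]), np.nan, post)
    return p, n_inf, post


def allele_frequencies(
    data: GenotypeData,
    sample_ids=None,
    tol: float = 1e-6,
    max_iter: int = 100,
    keep_posteriors: bool = False,
) -> AlleleFrequencies:
    """EM allele frequencies over a sample subset (all samples by default)."""
    sub = data if sample_ids is None else data.subset(sample_ids)
    p, n_inf, post = _em_frequencies(
        sub.likelihoods, sub.informative_mask(), tol, max_iter, keep_posteriors
    )
    return AlleleFrequencies(p, n_inf, list(sub.snp_ids), post)


def estimate_allele_freq_em(likelihoods, tol: float = 1e-6, max_iter: int = 100):
    """EM frequency for one SNP from an (n, 3) likelihood array.

    Returns ``(p_hat, posteriors)``; ``p_hat`` is NaN when no individual is
    informative (all entries missing or genotype-flat).
    """
    L = np.asarray(likelihoods, dtype=float)[:, None, :]
    missing = np.isnan(L[..., 0])
    flat = (np.abs(L[..., 0] - L[..., 1]) < _FLAT_TOL) & (
        np.abs(L[..., 1] - L[..., 2]) < _FLAT_TOL
    )
    informative = ~missing & ~flat
    p, _, post = _em_frequencies(L, informative, tol, max_iter, True)
    return float(p[0]), post[:, 0, :]


def posterior_dosages(data: GenotypeData, freqs: AlleleFrequencies | np.ndarray) -> np.ndarray:
    """Expected alternate-allele dosage per entry under an HWE prior.

    Missing entries stay NaN; genotype-flat entries fall back on the prior
    mean 2p.  SNPs whose frequency is NA yield NaN dosages throughout.
    """
    p = freqs.freqs if isinstance(freqs, AlleleFrequencies) else np.asarray(freqs, dtype=float)
    if p.shape[0] != data.n_snps:
        raise ValueError("frequency vector length does not match SNP panel")
    na = np.isnan(p)
    pc = np.clip(np.where(na, 0.5, p), 1e-9, 1 - 1e-9)
    prior = np.stack(((1 - pc) ** 2, 2 * pc * (1 - pc), pc**2), axis=-1)
    w = np.nan_to_num(data.likelihoods, nan=1.0 / 3.0) * prior[None]
    w /= w.sum(axis=-1, keepdims=True)
    dos = w[..., 1] + 2.0 * w[..., 2]
    dos = np.where(data.missing | na[None, :], np.nan, dos)
    return dos


def _check_groups(group1, group2):
    g1, g2 = list(group1), list(group2)
    if not g1 or not g2:
        raise ValueError("groups must be non-empty")
    if set(g1) & set(g2):
        raise ValueError("groups overlap")
    return g1, g2


def frequency_difference(
    data: GenotypeData,
    group1,
    group2,
    names: tuple[str, str] = ("group1", "group2"),
    orientation: str = "",
    tol: float = 1e-6,
    max_iter: int = 100,
) -> FrequencyDifference:
    """Per-SNP EM frequency difference, group1 minus group2 (NA propagates)."""
    g1, g2 = _check_groups(group1, group2)
    f1 = allele_frequencies(data, g1, tol=tol, max_iter=max_iter)
    f2 = allele_frequencies(data, g2, tol=tol, max_iter=max_iter)
    return FrequencyDifference(
        f1.freqs - f2.freqs, list(data.snp_ids), names[0], names[1], orientation
    )


def mean_eclosion_response(
    diff_apple: FrequencyDifference, diff_haw: FrequencyDifference
) -> FrequencyDifference:
    """Average the early-minus-late eclosion response across the host races."""
    if diff_apple.snp_ids != diff_haw.snp_ids:
        raise ValueError("responses are on different SNP panels")
    return FrequencyDifference(
        (diff_apple.values + diff_haw.values) / 2.0,
        list(diff_apple.snp_ids),
        "early",
        "late",
        "mean of apple and hawthorn eclosion responses",
    )


@dataclass
class PolarizedValues:
    values: np.ndarray
    flipped: np.ndarray  # bool mask of SNPs whose counted allele was swapped
    reference_freqs: np.ndarray  # reference frequencies after polarization


def polarize_to_reference(values, reference_freqs, mode: str = "difference") -> PolarizedValues:
    """Re-sign values so the reference population's major allele is counted.

    SNPs where the reference alternate-allele frequency is below 0.5 are
    flipped: differences negate, frequencies become 1-p.  An exact 0.5
    reference frequency is deterministically left unflipped.  Applying the
    function to its own output (values plus polarized reference) is the
    identity.
    """
    values = np.asarray(values, dtype=float)
    ref = np.asarray(reference_freqs, dtype=float)
    if values.shape[-1] != ref.shape[0]:
        raise ValueError("values and reference frequencies differ in length")
    flip = ref < 0.5
    flip = np.where(np.isnan(ref), False, flip)
    if mode == "difference":
        out = np.where(flip, -values, values)
    elif mode == "frequency":
        out = np.where(flip, 1.0 - values, values)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PolarizedValues(out, flip, np.where(flip, 1.0 - ref, ref))
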