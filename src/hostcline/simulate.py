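"""Synthetic GBS cline simulator.

Generates datasets with the architecture the analysis assumes: two host
races (apple and hawthorn) sampled at four latitudinally ordered sympatric
sites, biallelic SNPs on five chromosomes plus an unmapped bin, clinal and
host-associated allele-frequency structure on the logit scale, and
inversion-like blocks that tie member SNPs to a latent chromosomal
orientation to produce high / intermediate / low within-chromosome LD
strata.  Individuals are "sequenced" at Poisson read depth with a symmetric
base-calling error, yielding genotype likelihoods and missing data like a
real reduced-representation panel.  Paired experiment samples (early vs
late eclosion; 7-day vs 32-day prewinter survivors) are drawn from
frequency-shifted copies of a base population, with the planned shifts
recorded in a truth set for recovery tests.

The model:

* non-block SNP, population (site s, host h):
  ``p = logistic(alpha + beta * s + gamma * [h == apple])``
* block SNPs: the block's latent orientation frequency follows its own
  (alpha, beta, gamma) cline; each gamete's allele matches the orientation
  with probability ``1 - m`` (``m`` is the per-SNP mismatch probability
  controlling how tightly members track the inversion).
* reads: depth ``d ~ Poisson(depth_mean)``; alternate-read count
  ``~ Binomial(d, e_g)`` with ``e_g in {eps, 1/2, 1 - eps}`` for genotypes
  0/1/2; genotype likelihoods are the binomial read likelihoods; ``d = 0``
  is a missing entry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .genotypes import GenotypeData

__all__ = [
    "Block",
    "SimConfig",
    "TruthSet",
    "SimulatedDataset",
    "simulate_truth",
    "simulate_genotypes_reads",
    "simulate_experiment_groups",
    "simulate_dataset",
    "write_vcf",
    "write_metadata",
    "write_snp_map",
    "write_truth_json",
]

SITE_NAMES = ["Grant", "Fennville", "Dowagiac", "Urbana"]
EXPERIMENTS = ("eclosion", "prewinter_apple", "prewinter_hawthorn")


@dataclass
class Block:
    """An inversion-like LD block: member SNPs track a latent orientation."""

    chrom: int
    start: int  # SNP index within the chromosome, half-open [start, stop)
    stop: int
    ld_class: str  # "high" or "intermediate"
    mismatch: float  # m: per-gamete probability a member allele disagrees
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    gamma_site: tuple | None = None  # per-site host effect on top of gamma
    alpha_site: tuple | None = None  # per-site offset shared by both hosts

    def __post_init__(self) -> None:
        if not 0.0 <= self.mismatch <= 0.5:
            raise ValueError("block mismatch probability must lie in [0, 0.5]")
        if self.ld_class not in ("high", "intermediate"):
            raise ValueError("block ld_class must be 'high' or 'intermediate'")
        if self.stop <= self.start:
            raise ValueError("empty block range")


@dataclass
class SimConfig:
    """Study design and generative parameters for one synthetic dataset."""

    n_sites: int = 4
    hosts: tuple[str, str] = ("apple", "hawthorn")
    n_per_pop: int = 50
    chrom_lengths: dict = field(default_factory=dict)  # {"1":..,..,"5":..,"un":..}
    blocks: list[Block] = field(default_factory=list)
    alpha: np.ndarray | None = None  # per-SNP logit intercept
    beta: np.ndarray | None = None  # per-SNP logit slope in site order
    gamma: np.ndarray | None = None  # per-SNP logit host (apple) effect
    gamma_site: np.ndarray | None = None  # optional (n_sites, n_snps) site-local host effect
    alpha_site: np.ndarray | None = None  # optional (n_sites, n_snps) shared site effect
    coupling_fraction: float = 0.7
    effect_deltas: dict = field(default_factory=dict)  # experiment -> (n_snps,) shift
    experiment_sizes: dict = field(default_factory=dict)  # experiment -> (n1, n2)
    depth_mean: float = 4.0
    base_error: float = 0.01
    seed: int = 0

    @property
    def n_snps(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    @property
    def n_pops(self) -> int:
        return self.n_sites * len(self.hosts)

    def chrom_of(self) -> np.ndarray:
        out = []
        for chrom, ln in self.chrom_lengths.items():
            out.extend([str(chrom)] * int(ln))
        return np.asarray(out)

    def chrom_offsets(self) -> dict:
        off, total = {}, 0
        for chrom, ln in self.chrom_lengths.items():
            off[str(chrom)] = total
            total += int(ln)
        return off

    def block_members(self, block: Block) -> np.ndarray:
        base = self.chrom_offsets()[str(block.chrom)]
        return np.arange(base + block.start, base + block.stop)

    def validate(self) -> None:
        if self.alpha is None or self.beta is None or self.gamma is None:
            raise ValueError("cline parameters (alpha, beta, gamma) are required")
        n = self.n_snps
        for name, arr in (("alpha", self.alpha), ("beta", self.beta), ("gamma", self.gamma)):
            if np.asarray(arr).shape != (n,):
                raise ValueError(f"{name} must have length n_snps={n}")
        for name, arr in (("gamma_site", self.gamma_site), ("alpha_site", self.alpha_site)):
            if arr is not None and np.asarray(arr).shape != (self.n_sites, n):
                raise ValueError(f"{name} must have shape (n_sites, n_snps)")
        per_chrom: dict = {}
        for b in self.blocks:
            if str(b.chrom) not in self.chrom_lengths:
                raise ValueError(f"block on unknown chromosome {b.chrom}")
            if b.stop > self.chrom_lengths[str(b.chrom)]:
                raise ValueError("block range exceeds chromosome length")
            for s, e in per_chrom.get(b.chrom, []):
                if b.start < e and s < b.stop:
                    raise ValueError(f"overlapping blocks on chromosome {b.chrom}")
            per_chrom.setdefault(b.chrom, []).append((b.start, b.stop))
        for name, delta in self.effect_deltas.items():
            d = np.asarray(delta)
            if d.shape != (n,):
                raise ValueError(f"effect delta {name!r} must have length n_snps")
            if np.any(np.abs(d) > 1):
                raise ValueError("effect deltas must lie in [-1, 1]")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        if not 0.0 <= self.base_error < 0.5:
            raise ValueError("base_error must lie in [0, 0.5)")

    def population_labels(self) -> list[str]:
        return [
            f"{host}_{self.site_names()[s]}" for s in range(self.n_sites) for host in self.hosts
        ]

    def site_names(self) -> list[str]:
        if self.n_sites == len(SITE_NAMES):
            return list(SITE_NAMES)
        return [f"site{k + 1}" for k in range(self.n_sites)]

    @classmethod
    def default(
        cls,
        seed: int = 0,
        n_snps: int = 2000,
        n_per_pop: int = 50,
        depth_mean: float = 4.0,
        base_error: float = 0.01,
        coupling_fraction: float = 0.7,
        geo_host_ratio: float = 2.5,
        site_effect_sd: float = 0.25,
    ) -> "SimConfig":
        """Default study-scale configuration.

        Chromosome sizes mirror the study panel's mapped/unmapped split
        (~41% of SNPs mapped to chromosomes 1-5); each chromosome carries
        one high-LD (m = 0.02) and one intermediate-LD (m = 0.12)
        inversion-like block spanning ~30% and ~25% of its SNPs.  The
        geographic logit slope is ~``geo_host_ratio`` times the host
        effect, reproducing the within-race-cline-dominates-host-contrast
        regime.  Experiment effects are concentrated on chromosomes 1-3
        (eclosion) and 2-3 (prewinter), with shared SNPs linking the
        prewinter response to the clinal architecture.
        """
        rng = np.random.default_rng(seed)
        mapped = int(round(n_snps * 4244 / 10241))
        shares = np.array([949, 675, 996, 812, 812], dtype=float)
        per = np.floor(shares / shares.sum() * mapped).astype(int)
        per[0] += mapped - per.sum()
        chrom_lengths = {str(c + 1): int(per[c]) for c in range(5)}
        chrom_lengths["un"] = n_snps - mapped

        n_sites = 4
        blocks = []
        for c in range(1, 6):
            ln = chrom_lengths[str(c)]
            if ln < 4:
                continue
            hi = min(max(2, int(0.30 * ln)), ln // 2)
            mid = min(max(2, int(0.25 * ln)), ln - min(max(2, int(0.30 * ln)), ln // 2))
            for start, stop, cls_name, m in ((0, hi, "high", 0.02),
                                             (hi, hi + mid, "intermediate", 0.12)):
                sb = 1 if rng.random() < 0.5 else -1
                blocks.append(
                    Block(c, start, stop, cls_name, m, float(rng.uniform(-0.8, 0.8)),
                          sb * float(rng.uniform(0.09, 0.21)),
                          sb * float(rng.uniform(0.06, 0.12)) * 2.5 / geo_host_ratio,
                          tuple(rng.normal(0.0, 0.10, n_sites)),
                          tuple(rng.normal(0.0, site_effect_sd, n_sites)))
                )

        alpha = np.log(1.0 / rng.uniform(0.15, 0.85, n_snps) - 1.0) * -1.0
        beta = np.zeros(n_snps)
        gamma = np.zeros(n_snps)
        clinal = rng.random(n_snps) < 0.35
        sgn = np.where(rng.random(n_snps) < 0.5, 1.0, -1.0)
        beta[clinal] = (sgn * rng.uniform(0.06, 0.24, n_snps))[clinal]
        coupled = clinal & (rng.random(n_snps) < coupling_fraction)
        gamma[coupled] = np.sign(beta[coupled]) * rng.uniform(0.04, 0.16, n_snps)[coupled]
        loose = clinal & ~coupled & (rng.random(n_snps) < 0.5)
        gamma[loose] = (sgn * rng.uniform(0.04, 0.16, n_snps))[loose]
        # drawn magnitudes correspond to a ~2.5x geographic:host logit ratio
        gamma *= 2.5 / geo_host_ratio
        # site-local host divergence (direction varies by site): the
        # generator analogue of the crossing patterns between the races
        gamma_site = rng.normal(0.0, 0.08, (n_sites, n_snps))
        # drift-like site effects shared by both races at a site
        alpha_site = rng.normal(0.0, site_effect_sd, (n_sites, n_snps))

        chroms = np.concatenate(
            [np.repeat(str(c), ln) for c, ln in chrom_lengths.items()]
        )

        def implied_freq(site_idx: int, is_apple: bool) -> np.ndarray:
            lg = alpha + beta * site_idx + gamma * float(is_apple) + alpha_site[site_idx]
            if is_apple:
                lg = lg + gamma_site[site_idx]
            p = expit(lg)
            off = 0
            offsets = {}
            for c, ln in chrom_lengths.items():
                offsets[str(c)] = off
                off += int(ln)
            for b in blocks:
                blg = b.alpha + b.beta * site_idx + b.gamma * float(is_apple)
                if is_apple and b.gamma_site is not None:
                    blg += b.gamma_site[site_idx]
                if b.alpha_site is not None:
                    blg += b.alpha_site[site_idx]
                f = expit(blg)
                members = np.arange(offsets[str(b.chrom)] + b.start,
                                    offsets[str(b.chrom)] + b.stop)
                p[members] = f * (1 - b.mismatch) + (1 - f) * b.mismatch
            return p

        deltas = {}
        targets = {
            "eclosion": (("1", "2", "3"), [(1, True), (1, False)]),
            "prewinter_apple": (("2", "3"), [(0, True)]),
            "prewinter_hawthorn": (("3", "4", "5"), [(0, False)]),
        }
        for name, (chrs, base_pops) in targets.items():
            d = np.zeros(n_snps)
            eligible = np.isin(chroms, chrs) | (chroms == "un")
            hit = eligible & (rng.random(n_snps) < 0.15)
            mag = rng.uniform(0.1, 0.3, n_snps)
            share = rng.random(n_snps) < coupling_fraction
            sign = np.where(share & (beta != 0), np.sign(beta),
                            np.where(rng.random(n_snps) < 0.5, 1.0, -1.0))
            # planned shifts cannot exceed the base population's headroom
            head = np.full(n_snps, np.inf)
            for s, ap in base_pops:
                p = implied_freq(s, ap)
                head = np.minimum(head, 1.8 * np.minimum(p, 1 - p))
            d[hit] = (sign * np.minimum(mag, head))[hit]
            deltas[name] = d
        sizes = {"eclosion": (50, 50), "prewinter_apple": (48, 41),
                 "prewinter_hawthorn": (48, 41)}

        return cls(
            n_sites=n_sites,
            n_per_pop=n_per_pop,
            chrom_lengths=chrom_lengths,
            blocks=blocks,
            alpha=alpha,
            beta=beta,
            gamma=gamma,
            gamma_site=gamma_site,
            alpha_site=alpha_site,
            coupling_fraction=coupling_fraction,
            effect_deltas=deltas,
            experiment_sizes=sizes,
            depth_mean=depth_mean,
            base_error=base_error,
            seed=seed,
        )


@dataclass
class TruthSet:
    """Ground truth for recovery tests."""

    pop_labels: list[str]
    freqs: np.ndarray  # (n_pops, n_snps) true allele frequencies
    block_orientation_freqs: np.ndarray  # (n_blocks, n_pops)
    deltas: dict  # experiment -> (n_snps,) planned response
    ld_class: np.ndarray  # (n_snps,) true class label
    snp_ids: list[str]


def _snp_ids(config: SimConfig) -> list[str]:
    return [f"snp{i:05d}" for i in range(config.n_snps)]


def simulate_truth(config: SimConfig) -> TruthSet:
    """Population allele frequencies implied by the clinal model.

    Deterministic given the configuration (all randomness lives in the
    parameter arrays, which carry the seed that generated them).
    """
    config.validate()
    n_snps = config.n_snps
    pops = config.population_labels()
    site_of = np.repeat(np.arange(config.n_sites), len(config.hosts))
    apple = np.tile(np.array([h == "apple" for h in config.hosts]), config.n_sites)

    logit = (
        config.alpha[None, :]
        + np.outer(site_of, config.beta)
        + np.outer(apple.astype(float), config.gamma)
    )
    if config.gamma_site is not None:
        # site-local host divergence: direction varies across sites, emulating
        # the crossing patterns real host races show along the transect
        logit += apple.astype(float)[:, None] * config.gamma_site[site_of, :]
    if config.alpha_site is not None:
        # drift-like site effects shared by the sympatric pair: geographic
        # differentiation accumulates in independent directions per site
        # rather than along one straight line in frequency space
        logit += config.alpha_site[site_of, :]
    freqs = expit(logit)

    block_f = np.zeros((len(config.blocks), len(pops)))
    ld_class = np.full(n_snps, "low", dtype=object)
    chroms = config.chrom_of()
    ld_class[chroms == "un"] = "unassigned"
    for bi, b in enumerate(config.blocks):
        lg = b.alpha + b.beta * site_of + b.gamma * apple.astype(float)
        if b.gamma_site is not None:
            lg = lg + np.asarray(b.gamma_site)[site_of] * apple.astype(float)
        if b.alpha_site is not None:
            lg = lg + np.asarray(b.alpha_site)[site_of]
        f = expit(lg)
        block_f[bi] = f
        members = config.block_members(b)
        ld_class[members] = b.ld_class
        # marginal SNP frequency: orientation frequency passed through the
        # mismatch channel
        freqs[:, members] = (f * (1 - b.mismatch))[:, None] + ((1 - f) * b.mismatch)[:, None]

    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("cline parameters imply frequencies outside (0, 1)")
    return TruthSet(pops, freqs, block_f, dict(config.effect_deltas), ld_class, _snp_ids(config))


def _draw_genotypes(config: SimConfig, truth: TruthSet, pop_idx: int, n: int, rng) -> np.ndarray:
    """Diploid genotypes for one population: HWE draws for independent SNPs,
    latent-orientation gamete pairs for block members."""
    n_snps = config.n_snps
    g = rng.binomial(2, truth.freqs[pop_idx][None, :], size=(n, n_snps))
    for bi, b in enumerate(config.blocks):
        members = config.block_members(b)
        f = truth.block_orientation_freqs[bi, pop_idx]
        ori = rng.random((n, 2)) < f  # two latent gametes per individual
        match = rng.random((n, 2, members.size)) >= b.mismatch
        alleles = np.where(match, ori[:, :, None], ~ori[:, :, None])
        g[:, members] = alleles.sum(axis=1)
    return g


def _reads_to_likelihoods(g: np.ndarray, config: SimConfig, rng):
    """Sequence genotypes: Poisson depth, binomial alt reads, binomial GLs."""
    from scipy.stats import binom

    eps = config.base_error
    depth = rng.poisson(config.depth_mean, size=g.shape)
    p_alt = np.array([eps, 0.5, 1.0 - eps])[g]
    alt = rng.binomial(depth, p_alt)
    L = np.empty(g.shape + (3,), dtype=float)
    for gt, e in enumerate((eps, 0.5, 1.0 - eps)):
        L[..., gt] = binom.pmf(alt, depth, e)
    missing = depth == 0
    tot = L.sum(axis=-1, keepdims=True)
    L = np.where(missing[..., None], np.nan, L / np.where(tot == 0, 1.0, tot))
    return L, missing


@dataclass
class SimulatedDataset:
    data: GenotypeData
    metadata: "pd.DataFrame"
    snp_map: "pd.DataFrame"
    true_genotypes: np.ndarray


def _make_snp_map(config: SimConfig, truth: TruthSet):
    import pandas as pd

    rows = []
    chroms = config.chrom_of()
    within: dict = {}
    for i, snp in enumerate(truth.snp_ids):
        c = chroms[i]
        k = within.get(c, 0)
        within[c] = k + 1
        rows.append((snp, c, (k + 1) * 1000, truth.ld_class[i]))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "true_ld_class"])


def simulate_genotypes_reads(truth: TruthSet, config: SimConfig, rng=None) -> SimulatedDataset:
    """Survey dataset: every host x site population, sequenced.

    Returns the likelihood matrix, sample metadata, SNP map and the true
    genotype matrix (for recovery tests).
    """
    import pandas as pd

    config.validate()
    if truth.freqs.shape != (config.n_pops, config.n_snps):
        raise ValueError("truth dimensions do not match config")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    sites = config.site_names()
    genos, meta_rows, sample_ids = [], [], []
    for p, pop in enumerate(truth.pop_labels):
        host, site = pop.split("_", 1)
        order = sites.index(site) + 1
        g = _draw_genotypes(config, truth, p, config.n_per_pop, rng)
        genos.append(g)
        for i in range(config.n_per_pop):
            sid = f"{pop}_{i:03d}"
            sample_ids.append(sid)
            meta_rows.append((sid, host, site, order, pop))
    G = np.concatenate(genos, axis=0)
    L, missing = _reads_to_likelihoods(G, config, rng)
    data = GenotypeData(L, missing, sample_ids, truth.snp_ids)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "host", "site", "site_order", "group"])
    return SimulatedDataset(data, meta, _make_snp_map(config, truth), G)


def simulate_experiment_groups(truth: TruthSet, config: SimConfig, rng=None, clip_tol=0.02):
    """Paired experiment samples with planned per-SNP frequency responses.

    For each experiment the two groups are drawn from frequency-shifted
    copies of a base population (eclosion: both races at the second site;
    prewinter: the named race at the first site), with group frequencies
    ``base +/- delta/2`` clipped into (0, 1).  Sign convention: first group
    minus second (early - late; 7-day - 32-day).  Individuals are sampled
    per SNP at the shifted frequencies and sequenced like the survey; the
    experiments feed only frequency contrasts downstream, so block latent
    structure is not re-imposed on experiment samples.
    """
    import pandas as pd

    config.validate()
    if not config.effect_deltas:
        raise ValueError("config.effect_deltas must be defined")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    sites = config.site_names()
    pops = truth.pop_labels

    def base_pop(host, site_idx):
        return pops.index(f"{host}_{sites[site_idx]}")

    plans = {
        "eclosion": [("apple", 1, ("early", "late")), ("hawthorn", 1, ("early", "late"))],
        "prewinter_apple": [("apple", 0, ("7d", "32d"))],
        "prewinter_hawthorn": [("hawthorn", 0, ("7d", "32d"))],
    }
    out = {}
    for exp, delta in config.effect_deltas.items():
        if exp not in plans:
            raise ValueError(f"unknown experiment {exp!r}")
        n1, n2 = config.experiment_sizes.get(exp, (50, 50))
        datasets = {}
        for host, site_idx, (lab1, lab2) in plans[exp]:
            base = truth.freqs[base_pop(host, site_idx)]
            lo, hi = 1e-4, 1 - 1e-4
            f1_raw, f2_raw = base + delta / 2.0, base - delta / 2.0
            if np.any(f1_raw > 1 + clip_tol) or np.any(f1_raw < -clip_tol) or np.any(
                f2_raw > 1 + clip_tol
            ) or np.any(f2_raw < -clip_tol):
                raise ValueError(f"experiment {exp!r} deltas push frequencies outside [0, 1]")
            f1, f2 = np.clip(f1_raw, lo, hi), np.clip(f2_raw, lo, hi)
            genos, meta_rows, ids = [], [], []
            for lab, f, n in ((lab1, f1, n1), (lab2, f2, n2)):
                g = rng.binomial(2, f[None, :], size=(n, config.n_snps))
                genos.append(g)
                for i in range(n):
                    sid = f"{exp}_{host}_{lab}_{i:03d}"
                    ids.append(sid)
                    meta_rows.append((sid, host, sites[site_idx], site_idx + 1, lab))
            G = np.concatenate(genos, axis=0)
            L, missing = _reads_to_likelihoods(G, config, rng)
            datasets[host] = SimulatedDataset(
                GenotypeData(L, missing, ids, truth.snp_ids),
                pd.DataFrame(
                    meta_rows, columns=["sample_id", "host", "site", "site_order", "group"]
                ),
                _make_snp_map(config, truth),
                G,
            )
        out[exp] = datasets
    return out


# ---------------------------------------------------------------------------
# Writers


def write_vcf(dataset: SimulatedDataset, path) -> None:
    """Write a VCF 4.2 with GT, GL (log10) and PL, missing entries as '.'."""
    data, snpmap = dataset.data, dataset.snp_map
    lines = ["##fileformat=VCFv4.2", "##source=hostcline-simulator"]
    for chrom in dict.fromkeys(snpmap["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GL,Number=G,Type=Float,Description="Log10 genotype likelihoods">',
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(data.samples),
    ]
    G = dataset.true_genotypes
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for j, row in snpmap.iterrows():
            fields = [str(row["chrom"]), str(int(row["pos"])), row["snp_id"],
                      "A", "T", ".", "PASS", ".", "GT:GL:PL"]
            cells = []
            for i in range(data.n_samples):
                if data.missing[i, j]:
                    cells.append("./.:.:.")
                    continue
                L = data.likelihoods[i, j]
                gl = np.log10(np.clip(L, 1e-300, None))
                gl -= gl.max()
                pl = np.round(-10.0 * gl).astype(int)
                cells.append(
                    f"{gt_str[int(G[i, j])]}:"
                    + ",".join(f"{v:.4f}" for v in gl)
                    + ":" + ",".join(str(v) for v in pl)
                )
            fh.write("\t".join(fields + cells) + "\n")


def write_metadata(dataset: SimulatedDataset, path) -> None:
    dataset.metadata.to_csv(path, sep="\t", index=False)


def write_snp_map(dataset: SimulatedDataset, path) -> None:
    m = dataset.snp_map.rename(columns={"true_ld_class": "ld_class"})
    m.to_csv(path, sep="\t", index=False)


def write_truth_json(truth: TruthSet, path) -> None:
    doc = {
        "pop_labels": truth.pop_labels,
        "freqs": truth.freqs.tolist(),
        "block_orientation_freqs": truth.block_orientation_freqs.tolist(),
        "deltas": {k: v.tolist() for k, v in truth.deltas.items()},
        "ld_class": truth.ld_class.tolist(),
        "snp_ids": truth.snp_ids,
    }
    Path(path).write_text(json.dumps(doc))


def simulate_dataset(config: SimConfig, out_dir=None):
    """Simulate the full design (survey + experiments); optionally write files."""
    truth = simulate_truth(config)
    rng = np.random.default_rng(config.seed)
    survey = simulate_genotypes_reads(truth, config, rng)
    experiments = simulate_experiment_groups(truth, config, rng)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(survey, out / "survey.vcf")
        write_metadata(survey, out / "survey_metadata.tsv")
        write_snp_map(survey, out / "snp_map.tsv")
        write_truth_json(truth, out / "truth.json")
        for exp, by_host in experiments.items():
            for host, ds in by_host.items():
                write_vcf(ds, out / f"{exp}_{host}.vcf")
                write_metadata(ds, out / f"{exp}_{host}_metadata.tsv")
    return truth, survey, experiments
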