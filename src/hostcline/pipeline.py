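"""Full-analysis orchestration.

One configuration drives the whole analysis in dependency order:
simulate (or load) -> per-population frequencies -> LD classes -> Monte
Carlo contrasts -> cross-experiment and geographic/host regressions ->
stepwise models -> distances / NJ / DAPC / Mantel -> coupling LD among
unlinked loci.  Every number in the report is written first to a stage
output file (TSV/JSON) under the output directory; the report JSON only
aggregates stage outputs.  Per-stage seeds are derived deterministically
from the master seed, so stage-level reruns reproduce pipeline results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering as cl
from . import ld as ldmod
from . import mc as mcmod
from . import regression as regmod
from .genotypes import (
    GenotypeData,
    allele_frequencies,
    mean_eclosion_response,
    posterior_dosages,
    read_genotype_data,
)
from .simulate import EXPERIMENTS, SimConfig, simulate_dataset

logger = logging.getLogger("hostcline")

ALL_STAGES = [
    "data",
    "freqs",
    "ldclass",
    "mctest",
    "regress",
    "stepwise",
    "cluster",
    "coupling",
]
STAGE_REQUIRES = {
    "freqs": ["data"],
    "ldclass": ["freqs"],
    "mctest": ["freqs"],
    "regress": ["mctest"],
    "stepwise": ["mctest", "ldclass"],
    "cluster": ["freqs", "mctest"],
    "coupling": ["mctest", "ldclass"],
}

REPORT_SECTIONS = [
    "experiment_responses",
    "cross_experiment",
    "geographic_variation",
    "host_differentiation",
    "stepwise_models",
    "distances_and_trees",
    "clustering_dapc_mantel",
    "coupling_ld",
]
STAGE_SECTIONS = {
    "mctest": ["experiment_responses", "geographic_variation", "host_differentiation"],
    "regress": ["cross_experiment", "geographic_variation", "host_differentiation"],
    "stepwise": ["stepwise_models"],
    "cluster": ["distances_and_trees", "clustering_dapc_mantel"],
    "coupling": ["coupling_ld"],
}


@dataclass
class PipelineConfig:
    out_dir: Path
    simulation: dict | None = None  # kwargs for SimConfig.default
    inputs: dict | None = None  # {survey: {vcf, metadata, snp_map}, experiments: {...}}
    n_reps: int = 10000
    alpha: float = 0.05
    seed: int = 0
    nj_boot_reps: int = 10000
    mantel_perms: int = 10000
    dapc_reps: int = 10000
    a_score_grid_max: int = 20
    a_score_n_rand: int = 10
    strong_min_diff: float = 0.2
    stages: list = field(default_factory=lambda: list(ALL_STAGES))

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.simulation is None and self.inputs is None:
            raise ValueError("config needs a 'simulation' block or 'inputs' paths")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)


@dataclass
class StudyData:
    survey: GenotypeData
    survey_meta: pd.DataFrame
    snp_map: pd.DataFrame
    experiments: dict  # name -> {host -> (GenotypeData, metadata)}


def _load_study(config: PipelineConfig) -> StudyData:
    if config.simulation is not None:
        sim_cfg = SimConfig.default(**config.simulation)
        truth, survey, exps = simulate_dataset(sim_cfg, out_dir=config.out_dir / "data")
        experiments = {
            name: {host: (ds.data, ds.metadata) for host, ds in by_host.items()}
            for name, by_host in exps.items()
        }
        snp_map = survey.snp_map.rename(columns={"true_ld_class": "ld_class"})
        return StudyData(survey.data, survey.metadata, snp_map, experiments)
    paths = config.inputs
    data, meta, snp_map = read_genotype_data(
        paths["survey"]["vcf"], paths["survey"]["metadata"], paths["survey"]["snp_map"]
    )
    experiments = {}
    for name, by_host in paths.get("experiments", {}).items():
        experiments[name] = {}
        for host, p in by_host.items():
            d, m, _ = read_genotype_data(p["vcf"], p["metadata"], paths["survey"]["snp_map"])
            experiments[name][host] = (d, m)
    return StudyData(data, meta, snp_map, experiments)


def _groups_by(meta: pd.DataFrame, col: str) -> dict:
    return {k: g["sample_id"].tolist() for k, g in meta.groupby(col)}


def summarize_by_class(results: pd.DataFrame, snp_map: pd.DataFrame) -> pd.DataFrame:
    """Percent significant per chromosome x LD-class cell.

    Unmapped SNPs are excluded from chromosome cells but included in the
    genome-wide total; empty cells are NA with count 0.
    """
    df = results.merge(snp_map[["snp_id", "chrom", "ld_class"]], on="snp_id")
    rows = []
    mapped = df[df["chrom"].astype(str) != "un"]
    chroms = sorted(mapped["chrom"].astype(str).unique(), key=str)
    classes = ["high", "intermediate", "low"]
    for chrom in chroms + ["chr_1_5"]:
        sub = mapped if chrom == "chr_1_5" else mapped[mapped["chrom"].astype(str) == chrom]
        row = {"chrom": chrom}
        for cls in classes + ["all_mapped"]:
            cell = sub if cls == "all_mapped" else sub[sub["ld_class"] == cls]
            row[f"pct_{cls}"] = (
                100.0 * cell["significant"].mean() if len(cell) else np.nan
            )
            row[f"n_{cls}"] = len(cell)
        rows.append(row)
    total = {"chrom": "genome_wide"}
    for cls in classes + ["all_mapped"]:
        cell = df if cls == "all_mapped" else df[df["ld_class"] == cls]
        total[f"pct_{cls}"] = 100.0 * cell["significant"].mean() if len(cell) else np.nan
        total[f"n_{cls}"] = len(cell)
    rows.append(total)
    return pd.DataFrame(rows)


def _jsonable(o):
    if isinstance(o, dict):
        return {str(k): _jsonable(v) for k, v in o.items()}
    if isinstance(o, (list, tuple)):
        return [_jsonable(v) for v in o]
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.bool_):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return json.loads(o.to_json(orient="records"))
    return o


class Pipeline:
    """Stateful runner; stages write files and fill report sections."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        ss = np.random.SeedSequence(config.seed)
        kids = ss.spawn(len(ALL_STAGES))
        self.rngs = {name: np.random.default_rng(k) for name, k in zip(ALL_STAGES, kids)}
        self.report: dict = {"seed": config.seed, "n_reps": config.n_reps, "skipped": []}
        self.state: dict = {}

    # -- stage implementations -------------------------------------------

    def stage_data(self):
        self.state["study"] = _load_study(self.cfg)

    def stage_freqs(self):
        study: StudyData = self.state["study"]
        pops = _groups_by(study.survey_meta, "group")
        freq_rows = {}
        for pop, ids in pops.items():
            freq_rows[pop] = allele_frequencies(study.survey, ids).freqs
        pop_freqs = pd.DataFrame(freq_rows, index=study.survey.snp_ids).T
        pop_freqs.to_csv(self.out / "population_frequencies.tsv", sep="\t")
        af = allele_frequencies(study.survey)
        dosages = posterior_dosages(study.survey, af)
        self.state.update(pop_freqs=pop_freqs, survey_dosages=dosages, pops=pops)

    def stage_ldclass(self):
        study: StudyData = self.state["study"]
        dos = self.state["survey_dosages"]
        classes = ldmod.assign_ld_classes(dos, study.snp_map)
        mld = ldmod.mean_linked_ld(dos, study.snp_map)
        classes["mean_linked_ld"] = mld.to_numpy()
        classes.to_csv(self.out / "ld_classes.tsv", sep="\t", index=False)
        self.state["ld_classes"] = classes

    def _contrast_tests(self):
        study: StudyData = self.state["study"]
        cfg = self.cfg
        rng = self.rngs["mctest"]
        tests = {}

        for exp, by_host in study.experiments.items():
            per_host = {}
            for host, (data, meta) in by_host.items():
                groups = _groups_by(meta, "group")
                labs = (
                    ("early", "late") if exp == "eclosion" else ("7d", "32d")
                )
                per_host[host] = mcmod.mc_difference_test(
                    data, groups[labs[0]], groups[labs[1]],
                    n_reps=cfg.n_reps, alpha=cfg.alpha, rng=rng,
                )
            tests[exp] = per_host

        pops = self.state["pops"]
        sites = list(dict.fromkeys(study.survey_meta["site"]))
        geo = {}
        for host in ("apple", "hawthorn"):
            geo[host] = mcmod.mc_difference_test(
                study.survey,
                pops[f"{host}_{sites[0]}"], pops[f"{host}_{sites[-1]}"],
                n_reps=cfg.n_reps, alpha=cfg.alpha, rng=rng,
            )
        host_tests = {}
        for site in sites:
            host_tests[site] = mcmod.mc_difference_test(
                study.survey, pops[f"hawthorn_{site}"], pops[f"apple_{site}"],
                n_reps=cfg.n_reps, alpha=cfg.alpha, rng=rng,
            )
        return tests, geo, host_tests, sites

    def stage_mctest(self):
        study: StudyData = self.state["study"]
        exp_tests, geo_tests, host_tests, sites = self._contrast_tests()
        snp_map = self.state["ld_classes"].merge(
            study.snp_map[["snp_id", "chrom"]], on="snp_id"
        ) if "ld_classes" in self.state else study.snp_map

        def dump(name, res):
            df = res.to_frame()
            df.to_csv(self.out / f"mctest_{name}.tsv", sep="\t", index=False)
            table = summarize_by_class(df, snp_map)
            table.to_csv(self.out / f"mctest_{name}_by_class.tsv", sep="\t", index=False)
            return {
                "percent_significant": res.observed_percent,
                "tablewise_p": res.tablewise_p,
                "tablewise_excess": res.tablewise_excess,
                "by_class": table,
            }

        section = {}
        responses = {}
        significance = {}
        for exp, per_host in exp_tests.items():
            section[exp] = {}
            sigs, absd = [], []
            for host, res in per_host.items():
                section[exp][host] = dump(f"{exp}_{host}", res)
                sigs.append(res.significant)
                absd.append(res.obs_abs)
            significance[exp] = np.any(sigs, axis=0)
            if exp == "eclosion":
                responses[exp] = np.mean([r.obs_diff for r in per_host.values()], axis=0)
            else:
                responses[exp] = list(per_host.values())[0].obs_diff
        self.report["experiment_responses"] = section

        geo_sec, host_sec = {}, {}
        for host, res in geo_tests.items():
            geo_sec[host] = dump(f"geo_{host}", res)
            responses[f"geo_{host}"] = res.obs_diff
        for site, res in host_tests.items():
            host_sec[site] = dump(f"host_{site}", res)
            responses[f"host_{site}"] = res.obs_diff
        self.report["geographic_variation"] = {"tests": geo_sec}
        self.report["host_differentiation"] = {"tests": host_sec}
        self.state.update(
            exp_tests=exp_tests, geo_tests=geo_tests, host_tests=host_tests,
            responses=responses, significance=significance, sites=sites,
        )

    def stage_regress(self):
        study: StudyData = self.state["study"]
        cfg = self.cfg
        rng = self.rngs["regress"]
        responses = self.state["responses"]
        exp_tests = self.state["exp_tests"]
        sites = self.state["sites"]
        pops = self.state["pops"]

        def mc_p(contrast_data, g1, g2, predictor):
            r2, p, _ = mcmod.mc_regression_significance(
                contrast_data, g1, g2, predictor, n_reps=cfg.n_reps, rng=rng
            )
            return r2, p

        rows = []
        pairs = [
            ("eclosion", "prewinter_apple"),
            ("eclosion", "prewinter_hawthorn"),
            ("prewinter_apple", "prewinter_hawthorn"),
        ]
        for resp_name, pred_name in pairs:
            fit = regmod.fit_simple_regression(responses[resp_name], responses[pred_name])
            host = "apple" if resp_name != "prewinter_hawthorn" else "hawthorn"
            data, meta = list(study.experiments[resp_name].values())[0] \
                if resp_name != "eclosion" else study.experiments["eclosion"][host]
            groups = _groups_by(meta, "group")
            labs = ("early", "late") if resp_name == "eclosion" else ("7d", "32d")
            r2, p = mc_p(data, groups[labs[0]], groups[labs[1]], responses[pred_name])
            rows.append({"response": resp_name, "predictor": pred_name,
                         "r": fit.r, "r2": fit.r2, "mc_p": p})
        cross = pd.DataFrame(rows)
        cross.to_csv(self.out / "cross_experiment_regressions.tsv", sep="\t", index=False)
        self.report["cross_experiment"] = cross

        geo_rows, host_rows = [], []
        for host in ("apple", "hawthorn"):
            for pred in EXPERIMENTS:
                fit = regmod.fit_simple_regression(responses[f"geo_{host}"], responses[pred])
                first, last = sites[0], sites[-1]
                r2, p = mc_p(study.survey, pops[f"{host}_{first}"], pops[f"{host}_{last}"],
                             responses[pred])
                geo_rows.append({"race": host, "predictor": pred, "r": fit.r,
                                 "r2": fit.r2, "mc_p": p})
        for site in sites:
            for pred in list(EXPERIMENTS) + ["geo_apple", "geo_hawthorn"]:
                fit = regmod.fit_simple_regression(responses[f"host_{site}"], responses[pred])
                r2, p = mc_p(study.survey, pops[f"hawthorn_{site}"], pops[f"apple_{site}"],
                             responses[pred])
                host_rows.append({"site": site, "predictor": pred, "r": fit.r,
                                  "r2": fit.r2, "mc_p": p})
        geo_df, host_df = pd.DataFrame(geo_rows), pd.DataFrame(host_rows)
        geo_df.to_csv(self.out / "geographic_regressions.tsv", sep="\t", index=False)
        host_df.to_csv(self.out / "host_regressions.tsv", sep="\t", index=False)
        self.report["geographic_variation"]["regressions"] = geo_df
        self.report["host_differentiation"]["regressions"] = host_df

    def stage_stepwise(self):
        responses = self.state["responses"]
        classes = self.state["ld_classes"]
        snp_map = self.state["study"].snp_map
        mapped = (snp_map["chrom"].astype(str) != "un").to_numpy()
        X = pd.DataFrame(
            {
                "eclosion": responses["eclosion"],
                "prewinter_apple": responses["prewinter_apple"],
                "prewinter_hawthorn": responses["prewinter_hawthorn"],
                "mean_linked_ld": classes["mean_linked_ld"].to_numpy(),
            }
        )[mapped]
        section = {}
        rows = []
        targets = {f"geo_{h}": responses[f"geo_{h}"][mapped] for h in ("apple", "hawthorn")}
        targets.update(
            {f"host_{s}": responses[f"host_{s}"][mapped] for s in self.state["sites"]}
        )
        for name, y in targets.items():
            res = regmod.stepwise_aic(y, X)
            section[name] = {
                "retained": res.retained,
                "adj_r2": res.adj_r2,
                "F": res.fvalue,
                "p": res.f_pvalue,
                "aic": res.aic,
                "coefficients": res.to_frame().reset_index(names="predictor"),
            }
            for pred in res.retained:
                rows.append({"model": name, "predictor": pred,
                             "coeff": res.params[pred], "se": res.bse[pred],
                             "t": res.tvalues[pred], "p": res.pvalues[pred],
                             "adj_r2": res.adj_r2, "F": res.fvalue})
        pd.DataFrame(rows).to_csv(self.out / "stepwise_models.tsv", sep="\t", index=False)
        self.report["stepwise_models"] = section

    def stage_cluster(self):
        cfg = self.cfg
        study: StudyData = self.state["study"]
        rng = self.rngs["cluster"]
        pop_freqs: pd.DataFrame = self.state["pop_freqs"]
        sites = self.state["sites"]
        pops = self.state["pops"]

        dm = cl.nei_distance(pop_freqs)
        dm.to_frame().to_csv(self.out / "nei_distances.tsv", sep="\t")
        tree, skipped = cl.bootstrap_support(pop_freqs, n_reps=cfg.nj_boot_reps, rng=rng)
        (self.out / "nj_tree.nwk").write_text(tree.newick(with_support=True) + "\n")
        trees = {"all_snps": {"newick": tree.newick(with_support=True),
                              "supports": {";".join(sorted(k)): v
                                           for k, v in tree.supports.items()},
                              "skipped_replicates": skipped}}

        sig = self.state.get("significance")
        if sig is not None:
            strong = np.any(list(sig.values()), axis=0)
            if strong.sum() >= 2:
                sub = pop_freqs.loc[:, strong]
                dm_s = cl.nei_distance(sub)
                tree_s, sk = cl.bootstrap_support(sub, n_reps=cfg.nj_boot_reps, rng=rng)
                trees["significant_snps"] = {
                    "newick": tree_s.newick(with_support=True),
                    "supports": {";".join(sorted(k)): v for k, v in tree_s.supports.items()},
                    "skipped_replicates": sk,
                    "nei": dm_s.to_frame(),
                }
        self.report["distances_and_trees"] = {
            "nei": dm.to_frame().reset_index(names="population"),
            "nj": trees,
        }

        # Mantel IBD / IBE
        pop_meta = (
            study.survey_meta.groupby("group")
            .agg(site_order=("site_order", "first"), host=("host", "first"))
            .loc[list(pop_freqs.index)]
        )
        geo_m, eco_m = cl.build_predictor_matrices(pop_meta)
        ibd = cl.mantel_test(dm.to_frame(), geo_m, n_perm=cfg.mantel_perms, rng=rng)
        ibe = cl.mantel_test(dm.to_frame(), eco_m, n_perm=cfg.mantel_perms, rng=rng)

        # DAPC: host pairs per site, and the two geographic extremes (hawthorn)
        dos = self.state["survey_dosages"]
        sample_pos = {s: i for i, s in enumerate(study.survey.samples)}
        dapc_sec = {}
        comparisons = {f"host_{s}": (f"apple_{s}", f"hawthorn_{s}") for s in sites}
        comparisons["geo_hawthorn"] = (
            f"hawthorn_{sites[0]}", f"hawthorn_{sites[-1]}"
        )
        for name, (pa, pb) in comparisons.items():
            ids = pops[pa] + pops[pb]
            rows = [sample_pos[s] for s in ids]
            X = dos[rows]
            labels = [pa] * len(pops[pa]) + [pb] * len(pops[pb])
            grid = range(1, min(cfg.a_score_grid_max, len(ids) - len(set(labels)) - 1) + 1)
            best_m, curve = cl.optimize_a_score(
                X, labels, grid, n_rand=cfg.a_score_n_rand, rng=rng
            )
            model = cl.dapc_fit(X, labels, best_m)
            obs, p, _ = cl.cluster_significance(
                X, labels, best_m, n_reps=cfg.dapc_reps, rng=rng
            )
            model.memberships.assign(sample_id=ids).to_csv(
                self.out / f"dapc_{name}_memberships.tsv", sep="\t", index=False
            )
            dapc_sec[name] = {
                "n_pcs": best_m,
                "a_score_curve": {int(k): v for k, v in curve.items()},
                "mean_correct_assignment": model.mean_correct_prob,
                "p": p,
                "disc_eigenvalue_shares": model.disc_shares,
            }
        self.report["clustering_dapc_mantel"] = {
            "mantel_ibd": {"r": ibd.r, "p": ibd.p},
            "mantel_ibe": {"r": ibe.r, "p": ibe.p},
            "dapc": dapc_sec,
        }
        with open(self.out / "clustering_summary.json", "w") as fh:
            json.dump(_jsonable(self.report["clustering_dapc_mantel"]), fh, indent=2)

    def stage_coupling(self):
        cfg = self.cfg
        study: StudyData = self.state["study"]
        responses = self.state["responses"]
        significance = self.state["significance"]
        snp_ids = pd.Index(study.survey.snp_ids)

        study_results = {
            exp: pd.DataFrame(
                {"significant": significance[exp], "abs_diff": np.abs(responses[exp])},
                index=snp_ids,
            )
            for exp in EXPERIMENTS
        }
        keep = ldmod.select_strong_diapause_snps(study_results, cfg.strong_min_diff)
        strong = snp_ids[keep]
        pd.Series(strong).to_csv(self.out / "strong_diapause_snps.tsv",
                                 sep="\t", index=False, header=["snp_id"])

        pops = self.state["pops"]
        sites = self.state["sites"]
        sample_pos = {s: i for i, s in enumerate(study.survey.samples)}
        dos = self.state["survey_dosages"]
        dosages_by_pop = {
            pop: dos[[sample_pos[s] for s in ids]] for pop, ids in pops.items()
        }
        groupings = {
            "within_population": [[p] for p in pops],
            "pooled_hosts_per_site": [
                [f"apple_{s}", f"hawthorn_{s}"] for s in sites
            ],
            "pooled_geographic_extremes": [
                [f"hawthorn_{sites[0]}", f"hawthorn_{sites[-1]}"]
            ],
        }
        chrom_count = study.snp_map.loc[
            study.snp_map["snp_id"].isin(strong), "chrom"
        ].astype(str).nunique()
        if len(strong) < 2 or chrom_count < 2:
            self.report["coupling_ld"] = {
                "note": "too few strong diapause SNPs for interchromosomal LD",
                "n_strong": int(len(strong)),
            }
            return
        dists = ldmod.interchromosomal_ld_distributions(
            dosages_by_pop, study.snp_map, strong, groupings
        )
        summary = {
            mode: {k: v for k, v in d.items() if k != "values"}
            for mode, d in dists.items()
        }
        summary["n_strong"] = int(len(strong))
        with open(self.out / "coupling_ld.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2)
        self.report["coupling_ld"] = summary

    # -- driver -----------------------------------------------------------

    def run(self) -> dict:
        enabled = set(self.cfg.stages)
        done = set()
        for stage in ALL_STAGES:
            deps = STAGE_REQUIRES.get(stage, [])
            if stage not in enabled:
                self.report["skipped"].append({"stage": stage, "reason": "disabled"})
                continue
            missing = [d for d in deps if d not in done]
            if missing:
                self.report["skipped"].append(
                    {"stage": stage, "reason": f"requires skipped stage(s) {missing}"}
                )
                continue
            logger.info("stage %s", stage)
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            done.add(stage)

        report = _jsonable(self.report)
        with open(self.out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        (self.out / "report.txt").write_text(self._text_report(report))
        return report

    def _text_report(self, report: dict) -> str:
        lines = [f"hostcline pipeline report (seed={report['seed']}, "
                 f"n_reps={report['n_reps']})", ""]
        for section in REPORT_SECTIONS:
            if section not in report:
                continue
            lines.append(f"== {section} ==")
            lines.append(json.dumps(report[section], indent=1, sort_keys=True)[:4000])
            lines.append("")
        if report.get("skipped"):
            lines.append("== skipped stages ==")
            for s in report["skipped"]:
                lines.append(f"{s['stage']}: {s['reason']}")
        return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the report dict."""
    return Pipeline(config).run()
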