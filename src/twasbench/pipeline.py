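"""End-to-end experiment recipes on synthetic cohorts.

``run_experiment`` wires the simulator, the per-gene trainers, the nested-CV
engine, heritability estimation and the TWAS stage into deterministic,
seed-driven experiment designs:

* ``nested_cv`` — per-gene, per-method 10-fold nested CV plus BSLMM mixing
  diagnostics;
* ``train_fraction_sweep`` — the same design at training fractions 0.1..0.9
  with one shared fold assignment per seed, so results are paired;
* ``cross_population`` — train in population A, predict population B,
  alongside within-A nested CV;
* ``mixed_population`` — composition-preserving down-sampled merged CV;
* ``cross_tissue`` — train on tissue A expression, score each fold against
  both tissue A and tissue B expression;
* ``twas`` — train on a reference subset, impute expression into a disjoint
  GWAS subset carrying a simulated binary trait, test association.

All randomness flows from one root seed through named substreams
(simulate, folds, mcmc/forest via per-fold seeds); outputs carry the config
hash and seed so identical runs are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import crossval, simdata, twas
from .genio import EmptyPanelError
from .heritability import HeritabilityError, reml_h2_from_genotypes
from .mcmc_diag import mixing_table
from .simdata import SimConfig

logger = logging.getLogger("twasbench")

DESIGNS = ("nested_cv", "train_fraction_sweep", "cross_population",
           "mixed_population", "cross_tissue", "twas", "h2")


@dataclass
class ExperimentConfig:
    sim: SimConfig
    methods: list[str]
    design: str
    seed: int
    out_dir: str | Path | None = None
    k: int = 10
    train_folds: list[int] = field(default_factory=lambda: [9])
    n_total: int | None = None           # mixed_population
    n_gwas: int = 2000                   # twas: GWAS subset size
    odds_scale: float = 0.0              # twas
    prevalence: float = 0.4              # twas
    mediating_gene: str = "gene0"        # twas
    bslmm_burnin: int = 1000
    bslmm_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; choose from {DESIGNS}")
        for m in self.methods:
            if m not in crossval.METHODS:
                raise ValueError(f"unknown method {m!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in raw.pop("sim", {}).items()})
        return cls(sim=sim, **raw)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir", None)
        return hashlib.sha1(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _substreams(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("simulate", "folds", "mcmc", "forest", "trait")
    states = ss.generate_state(len(names))
    return {n: int(s % 2**31) for n, s in zip(names, states)}


def _write(df: pd.DataFrame, path: Path, cfg: ExperimentConfig) -> None:
    with path.open("w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()}\tseed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_experiment(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Execute one experiment design; returns (and optionally writes) tidy
    result tables.  Failures at single genes are logged and skipped; the run
    fails only if every gene fails."""
    t0 = time.time()
    seeds = _substreams(config.seed)
    sim = SimConfig(**{**asdict(config.sim), "seed": seeds["simulate"]})
    expr_b = None
    if sim.tissue_sharing is not None:
        panel, expr, expr_b, truth = simdata.simulate_cohort(sim)
    else:
        panel, expr, truth = simdata.simulate_cohort(sim)

    tables: dict[str, pd.DataFrame] = {}
    cv_kw = dict(k=config.k, bslmm_burnin=config.bslmm_burnin,
                 bslmm_iter=config.bslmm_iter)

    if config.design in ("nested_cv", "cross_tissue"):
        all_results, diag = [], {}
        for method in config.methods:
            res = crossval.cv_all_genes(panel, expr, method, seed=seeds["folds"],
                                        train_folds=config.train_folds[-1],
                                        expr_secondary=expr_b, **cv_kw)
            all_results += res
            if method == "bslmm":
                for cv_res in res:
                    for f, par in enumerate(cv_res.fold_params):
                        fit = par.get("bslmm_fit")
                        if fit is not None:
                            diag[(cv_res.gene, f)] = fit.traces
        tables["cv"] = crossval.results_frame(all_results)
        if config.design == "cross_tissue":
            rows = [(r.gene, r.method, r.mean_r, r.mean_r_secondary) for r in all_results]
            tables["cross_tissue"] = pd.DataFrame(
                rows, columns=["gene", "method", "mean_R_within", "mean_R_cross"])
        summary = tables["cv"].groupby(["gene", "method"], as_index=False)["mean_R"].first()
        tables["summary"] = summary.pivot(index="gene", columns="method",
                                          values="mean_R").reset_index()
        if diag:
            tables["bslmm_diagnostics"] = mixing_table(diag)

    elif config.design == "train_fraction_sweep":
        rows = []
        for method in config.methods:
            for gene_id in expr.gene_ids:
                try:
                    cis, y = crossval.gene_design(panel, expr, gene_id)
                except EmptyPanelError:
                    continue
                folds = crossval.make_folds(len(y), config.k, seeds["folds"])
                for tf in config.train_folds:
                    res = crossval.nested_cv(method, cis.dosages, y, k=config.k,
                                             train_folds=tf, seed=seeds["folds"],
                                             gene=gene_id, folds=folds, snps=cis.snps)
                    rows.append((gene_id, method, tf / config.k, res.mean_r))
        tables["sweep"] = pd.DataFrame(
            rows, columns=["gene", "method", "train_fraction", "mean_R"])

    elif config.design in ("cross_population", "mixed_population"):
        pops = [p for p in simdata.POPULATIONS if (panel.samples["population"] == p).any()]
        if len(pops) < 2:
            raise ValueError(f"{config.design} needs two simulated populations")
        panel_a = panel.population(pops[0])
        panel_b = panel.population(pops[1])
        ia = pd.Index(expr.sample_ids).get_indexer(panel_a.sample_ids)
        ib = pd.Index(expr.sample_ids).get_indexer(panel_b.sample_ids)
        expr_a, expr_bp = expr.subset_samples(ia), expr.subset_samples(ib)
        rows = []
        if config.design == "cross_population":
            for method in config.methods:
                cross = crossval.cross_population_eval(method, panel_a, expr_a,
                                                       panel_b, expr_bp,
                                                       seed=seeds["folds"])
                within = crossval.cv_all_genes(panel_a, expr_a, method,
                                               seed=seeds["folds"], **cv_kw)
                within_r = {r.gene: r.mean_r for r in within}
                for _, rec in cross.iterrows():
                    rows.append((rec["gene"], method, within_r.get(rec["gene"], np.nan),
                                 rec["r"]))
            tables["cross_population"] = pd.DataFrame(
                rows, columns=["gene", "method", "mean_R_within", "R_cross"])
        else:
            n_total = config.n_total or panel_a.n_samples
            for method in config.methods:
                res = crossval.mixed_population_cv(panel, expr, n_total, method,
                                                   seed=seeds["folds"], k=config.k)
                rows += [(r.gene, method, r.mean_r) for r in res]
            tables["mixed_population"] = pd.DataFrame(
                rows, columns=["gene", "method", "mean_R"])

    elif config.design == "h2":
        rows = []
        for gene_id in expr.gene_ids:
            try:
                cis, y = crossval.gene_design(panel, expr, gene_id)
                fit = reml_h2_from_genotypes(cis.dosages, y)
                rows.append((gene_id, fit.h2, fit.loglik, fit.converged))
            except (EmptyPanelError, HeritabilityError) as exc:
                logger.warning("gene %s h2 failed: %s", gene_id, exc)
        tables["h2"] = pd.DataFrame(rows, columns=["gene", "h2", "loglik", "converged"])

    elif config.design == "twas":
        n_ref = panel.n_samples - config.n_gwas
        if n_ref < 30:
            raise ValueError("simulated cohort too small for the reference/GWAS split")
        ref = panel.subset_samples(np.arange(n_ref))
        gwas = panel.subset_samples(np.arange(n_ref, panel.n_samples))
        expr_ref = expr.subset_samples(np.arange(n_ref))
        status = simdata.simulate_case_control(gwas, truth, config.mediating_gene,
                                               config.odds_scale, config.prevalence,
                                               seeds["trait"])
        per_method = {}
        for method in config.methods:
            models = {}
            for gene_id in expr_ref.gene_ids:
                try:
                    cis, y = crossval.gene_design(ref, expr_ref, gene_id)
                except EmptyPanelError:
                    continue
                models[gene_id] = crossval.train_gene_model(
                    method, cis.dosages, y, snps=cis.snps, gene=gene_id,
                    seed=seeds["mcmc"], bslmm_burnin=config.bslmm_burnin,
                    bslmm_iter=config.bslmm_iter)
            imputed = twas.impute_expression(models, gwas)
            per_method[method] = twas.associate(imputed, status).assign(method=method)
        tables["twas"] = pd.concat(per_method.values(), ignore_index=True)
        if len(per_method) >= 2:
            corr = twas.compare_methods(per_method)
            tables["z_correlation"] = corr.reset_index(names="method")

    if not tables or all(df.empty for df in tables.values()):
        raise RuntimeError("experiment produced no results (all genes failed)")

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            _write(df, out / f"{name}.tsv", config)
    logger.info("design %s finished in %.1fs", config.design, time.time() - t0)
    return tables
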