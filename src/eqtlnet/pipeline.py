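"""Config-driven orchestration of the full analysis.

A :class:`PipelineConfig` names every parameter and seed; ``run_pipeline``
executes the requested stages in dependency order inside a run directory,
writing TSV outputs plus a JSON manifest recording the config hash, seeds,
and a checksum and row count for every file. Reruns with the same config and
seeds are bit-identical.

Stages: simulate -> map -> measures -> network/degree -> stability ->
popgen -> ldsc.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data as syn
from .eqtl_mapping import map_eqtls
from .heritability import compute_ld_scores, sldsc
from .network import (build_dense_adjacency, build_sparse_adjacency, degree_np,
                      degree_sparse, top_quartile_annotation)
from .popgen import DiversityTable, correlate_degree_diversity, nucleotide_diversity, \
    tajimas_d
from .significance import compute_significance
from .stability import StabilityConfig, split_sample_stability

logger = logging.getLogger("eqtlnet")

ALL_STAGES = ("simulate", "map", "measures", "network", "stability", "popgen", "ldsc")


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run (round-trips through YAML)."""

    seed: int = 0
    out_dir: str = "eqtlnet_run"
    stages: tuple[str, ...] = ALL_STAGES

    # simulation
    simulate: bool = True
    n_samples: int = 400
    n_snps: int = 300
    n_genes: int = 60
    n_cis_edges: int = 30
    n_trans_edges: int = 20
    beta_cis: float = 0.8
    beta_trans: float = 0.8
    noise_sd: float = 1.0
    n_covariates: int = 3
    covariate_effect_sd: float = 0.5

    # external inputs (used when simulate = False)
    genotype_tsv: str | None = None
    expression_tsv: str | None = None
    covariate_tsv: str | None = None
    gene_bed: str | None = None

    # mapping / measures / network
    cis_window: int = 1_000_000
    measures: tuple[str, ...] = ("BH", "QV")
    taus: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2)
    weighted: tuple[bool, ...] = (True, False)
    scope: str = "location-specific"
    include_np: bool = True
    np_min_tests: int = 10
    lfdr_min_stats: int = 50

    # stability
    n_repeats: int = 5
    inclusion: str = "shared"

    # popgen
    popgen_theta: float = 5.0
    popgen_haplotypes: int = 20
    popgen_locus_length: float = 10_000.0

    # ldsc
    gwas_n: int = 10_000
    gwas_tau: float = 5e-4
    ldsc_blocks: int = 20

    # -- (de)serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(fields)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in d.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def validate(self) -> None:
        for t in self.taus:
            if not (0 < t < 1):
                raise ValueError(f"tau {t} outside (0, 1)")
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if not self.simulate:
            for fieldname in ("genotype_tsv", "expression_tsv", "gene_bed"):
                if getattr(self, fieldname) is None:
                    raise ValueError(
                        f"simulation disabled but config field {fieldname!r} is unset")


# ---------------------------------------------------------------------------
# manifest helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _register(manifest: dict, path: Path) -> None:
    n_rows = sum(1 for _ in open(path)) if path.suffix in (".tsv", ".bed", ".vcf") else None
    manifest["outputs"][path.name] = {"sha256": _sha256(path), "n_rows": n_rows}


# ---------------------------------------------------------------------------
# input loading (external data path)
# ---------------------------------------------------------------------------

def _load_inputs(cfg: PipelineConfig):
    geno = pd.read_csv(cfg.genotype_tsv, sep="\t", index_col=0)
    bed = pd.read_csv(cfg.gene_bed, sep="\t", header=None,
                      names=["chrom", "start", "end", "gene_id"])
    # SNP ids are expected as "snp<chrom>_<pos>" as written by the simulator,
    # or any id; coordinates fall back to a sidecar parse of the id
    chrom, pos = [], []
    for sid in geno.index:
        body = sid.removeprefix("snp")
        c, _, p = body.rpartition("_")
        chrom.append(c)
        pos.append(int(p))
    dos = geno.to_numpy().T
    p_hat = dos.mean(axis=0) / 2
    G = syn.GenotypeMatrix(dos, list(geno.index), np.asarray(chrom),
                           np.asarray(pos, dtype=np.int64),
                           np.minimum(p_hat, 1 - p_hat), list(geno.columns))
    genes = syn.GeneTable(list(bed["gene_id"]), bed["chrom"].to_numpy(),
                          bed["end"].to_numpy().astype(np.int64))
    expr = pd.read_csv(cfg.expression_tsv, sep="\t", index_col=0)
    E = syn.ExpressionMatrix(expr.to_numpy().T, genes, list(expr.columns))
    X = None
    if cfg.covariate_tsv:
        cov = pd.read_csv(cfg.covariate_tsv, sep="\t", index_col=0)
        X = syn.CovariateMatrix(cov.to_numpy().T, list(cov.index))
    return G, genes, X, E


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Run the configured stages; returns the run directory.

    Per-stage seeds are derived deterministically from ``cfg.seed`` so any
    stage subset reproduces the full run's values.
    """
    cfg.validate()
    run = Path(out_dir or cfg.out_dir)
    run.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest(),
        "seed": cfg.seed,
        "stage_seeds": {},
        "outputs": {},
    }
    # fixed per-stage seed offsets keep stages independently reproducible
    stage_seed = {s: (cfg.seed * 1000 + i) % (2 ** 31) for i, s in enumerate(ALL_STAGES)}
    manifest["stage_seeds"] = stage_seed
    stages = set(cfg.stages)

    # --- inputs --------------------------------------------------------------
    arch = None
    if cfg.simulate and "simulate" in stages:
        logger.info("stage simulate")
        ss = stage_seed["simulate"]
        G = syn.simulate_genotypes(cfg.n_samples, cfg.n_snps, seed=ss)
        genes = syn.simulate_genes(cfg.n_genes, seed=ss + 1)
        X = (syn.simulate_covariates(cfg.n_samples, cfg.n_covariates, seed=ss + 2)
             if cfg.n_covariates else None)
        arch = syn.random_architecture(
            G, genes, cfg.n_cis_edges, cfg.n_trans_edges, cfg.beta_cis,
            cfg.beta_trans, cfg.noise_sd, cfg.covariate_effect_sd,
            cfg.n_covariates, cfg.cis_window, seed=ss + 3)
        E = syn.simulate_expression(G, genes, arch, X, seed=ss + 4)
        G.to_tsv(run / "dosages.tsv")
        G.to_vcf(run / "genotypes.vcf")
        E.to_tsv(run / "expression.tsv")
        genes.to_bed(run / "genes.bed")
        if X is not None:
            X.to_tsv(run / "covariates.tsv", G.sample_ids)
        arch.to_tsv(run / "planted_truth.tsv", G.snp_ids, genes.gene_ids)
        for name in ("dosages.tsv", "genotypes.vcf", "expression.tsv",
                     "genes.bed", "planted_truth.tsv"):
            _register(manifest, run / name)
        if X is not None:
            _register(manifest, run / "covariates.tsv")
    else:
        G, genes, X, E = _load_inputs(cfg)

    # --- mapping -------------------------------------------------------------
    results = None
    if stages & {"map", "measures", "network", "ldsc"}:
        logger.info("stage map")
        results = map_eqtls(G, E, X, cis_window=cfg.cis_window, store="dense")
        results.to_tsv(run / "eqtl_edges.tsv")
        _register(manifest, run / "eqtl_edges.tsv")
        manifest["n_tests_cis"] = results.n_tests_cis
        manifest["n_tests_trans"] = results.n_tests_trans

    # --- measures + network/degree --------------------------------------------
    snp_degrees = {}
    gene_degrees = {}
    if results is not None and stages & {"measures", "network", "ldsc"}:
        logger.info("stage measures/network")
        degree_rows = []
        for kind in cfg.measures:
            meas = compute_significance(results, kind=kind, stratified=True,
                                        lfdr_min_stats=cfg.lfdr_min_stats)
            out = results.entries[["snp_id", "gene_id", "p", "cis"]].copy()
            out["Y"] = meas.values
            header = (f"# measure={kind} scope={meas.scope} "
                      f"stratified={meas.stratified}\n")
            path = run / f"measure_{kind.lower()}.tsv"
            with open(path, "w") as fh:
                fh.write(header)
                out.to_csv(fh, sep="\t", index=False)
            _register(manifest, path)
            for tau in cfg.taus:
                for weighted in cfg.weighted:
                    adj = build_sparse_adjacency(results, meas, tau, weighted,
                                                 scope=cfg.scope)
                    for axis, store in (("SNP", snp_degrees), ("gene", gene_degrees)):
                        deg = degree_sparse(adj, axis)
                        store[(kind, tau, weighted)] = deg
                        for i, node in enumerate(deg.node_ids):
                            degree_rows.append({
                                "node_id": node, "axis": axis, "definition": kind,
                                "tau": tau, "weighted": weighted,
                                "total": deg.total[i],
                                "cis_part": deg.cis_part[i] if deg.cis_part is not None else np.nan,
                                "trans_part": deg.trans_part[i] if deg.trans_part is not None else np.nan,
                            })
        if cfg.include_np:
            dense = build_dense_adjacency(results)
            for axis, store in (("SNP", snp_degrees), ("gene", gene_degrees)):
                deg = degree_np(dense, axis, cfg.np_min_tests)
                store[("NP", np.nan, False)] = deg
                for i, node in enumerate(deg.node_ids):
                    degree_rows.append({
                        "node_id": node, "axis": axis, "definition": "NP",
                        "tau": np.nan, "weighted": False, "total": deg.total[i],
                        "cis_part": np.nan, "trans_part": np.nan,
                    })
        deg_df = pd.DataFrame(degree_rows)
        deg_df.to_csv(run / "degrees.tsv", sep="\t", index=False)
        _register(manifest, run / "degrees.tsv")

    # --- stability -------------------------------------------------------------
    if "stability" in stages:
        logger.info("stage stability")
        stab_cfg = StabilityConfig(
            measures=cfg.measures, taus=cfg.taus, weighted=cfg.weighted,
            cis_window=cfg.cis_window, include_np=cfg.include_np,
            np_min_tests=cfg.np_min_tests, inclusion=cfg.inclusion,
            lfdr_min_stats=cfg.lfdr_min_stats)
        report = split_sample_stability(G, E, X, stab_cfg,
                                        n_repeats=cfg.n_repeats,
                                        seed=stage_seed["stability"])
        report.records.to_csv(run / "stability.tsv", sep="\t", index=False)
        summary = {"median": report.median, "iqr": report.iqr,
                   "per_configuration": report.summary.to_dict("records")}
        (run / "stability_summary.json").write_text(
            json.dumps(summary, indent=2, default=float))
        _register(manifest, run / "stability.tsv")
        _register(manifest, run / "stability_summary.json")

    # --- popgen ----------------------------------------------------------------
    if "popgen" in stages:
        logger.info("stage popgen")
        rows = []
        base = stage_seed["popgen"]
        for i, gid in enumerate(genes.gene_ids):
            hap = syn.simulate_haplotypes(cfg.popgen_haplotypes, cfg.popgen_theta,
                                          cfg.popgen_locus_length, seed=base + i)
            rows.append({"gene_id": gid, "pi": nucleotide_diversity(hap),
                         "tajima_d": tajimas_d(hap),
                         "n_segregating": hap.n_sites})
        div = DiversityTable(pd.DataFrame(rows))
        div.to_tsv(run / "diversity.tsv")
        _register(manifest, run / "diversity.tsv")
        key = (cfg.measures[0], cfg.taus[0], True)
        if key in gene_degrees:
            per_ds, meta = correlate_degree_diversity(gene_degrees[key], [div, div])
            (run / "diversity_correlation.json").write_text(json.dumps({
                "per_dataset": per_ds, "pooled": meta.pooled,
                "ci": [meta.ci_low, meta.ci_high], "tau2": meta.tau2},
                indent=2, default=float))
            _register(manifest, run / "diversity_correlation.json")

    # --- ldsc ------------------------------------------------------------------
    if "ldsc" in stages and results is not None:
        logger.info("stage ldsc")
        key = (cfg.measures[0], cfg.taus[0], True)
        deg = snp_degrees.get(key)
        if deg is not None:
            annot = top_quartile_annotation(deg)
            A = np.column_stack([np.ones(len(annot.values)), annot.values])
            names = ["base", "top_quartile_degree"]
            ld = compute_ld_scores(A, dosages=G.dosages, pos=G.pos,
                                   chrom=G.chrom, snp_ids=list(G.snp_ids),
                                   names=names)
            gwas = syn.simulate_gwas_chisq(
                A, np.array([0.0, cfg.gwas_tau]), cfg.gwas_n,
                seed=stage_seed["ldsc"])
            res = sldsc(gwas["chisq"].to_numpy(), cfg.gwas_n, ld, A,
                        n_blocks=cfg.ldsc_blocks)
            ld.to_tsv(run / "ld_scores.tsv")
            gwas.to_csv(run / "gwas_chisq.tsv", sep="\t", index=False)
            res.to_tsv(run / "ldsc_results.tsv")
            for name in ("ld_scores.tsv", "gwas_chisq.tsv", "ldsc_results.tsv"):
                _register(manifest, run / name)

    (run / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run complete: %s", run)
    return run
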