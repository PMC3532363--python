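"""End-to-end orchestration: simulate → rescore → heritability →
permutation test → QC → association → integrative contrasts.

Each stage reads its inputs from disk, writes its outputs plus a JSON
manifest (input SHA-256 hashes, parameters, the stage seed), and can be
re-run independently. A single global seed expands deterministically to
per-stage seeds: stage k uses ``SeedSequence([global_seed, k])`` reduced
below 2^31, so re-running one stage reproduces its output byte for byte.
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

from . import io as mio
from .containers import ExpressionMatrix
from .exceptions import DependencyError, ParameterError
from .genetics import AnalysisConfig, TraitAssociation, qc_filter, snp_vs_many_traits
from .heritability import per_mirna_heritability, target_permutation_test
from .integrative import (
    individual_vs_mean_re,
    mirtron_contrast,
    mirtron_overlap_regression,
    most_variable,
    spearman,
)
from .rescore import DEFAULT_MIN_TARGETS, conventional_mean_re, re_matrix, subtracted_mean_re
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "rescore", "herit", "herit_permtest", "qc", "assoc", "integrate")


@dataclass
class PipelineConfig:
    """Paths, knobs and stage toggles for one pipeline run."""

    out_dir: str = "mirherit_out"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    min_targets: int = DEFAULT_MIN_TARGETS
    herit_method: str = "huber"
    n_perm_herit: int = 200
    n_perm_assoc: int = 1000
    alpha: float = 0.05
    candidate_genes: list = field(default_factory=list)
    simulation: SimulationConfig | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    # explicit input paths; filled from the simulate stage when it runs
    expression: str | None = None
    sample_meta: str | None = None
    trios: str | None = None
    gmt: str | None = None
    vcf: str | None = None
    mirna_expression: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        ana = raw.pop("analysis", None)
        cfg = cls(**raw)
        if sim is not None:
            if isinstance(sim.get("maf_range"), list):
                sim["maf_range"] = tuple(sim["maf_range"])
            cfg.simulation = SimulationConfig(**sim)
        if ana is not None:
            cfg.analysis = AnalysisConfig(**ana)
        return cfg


def _stage_seed(global_seed: int, stage: str) -> int:
    k = STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, k]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path, stage: str, seed: int, inputs: dict, params: dict) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "inputs": {k: _sha256(v) for k, v in inputs.items() if v and Path(v).exists()},
        "params": params,
    }
    (out_dir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def _require(path, stage: str, what: str) -> Path:
    if path is None or not Path(path).exists():
        raise DependencyError(f"stage '{stage}' is missing its {what} input: {path}")
    return Path(path)


def validate_inputs(cfg: PipelineConfig) -> list[str]:
    """Cross-check all configured inputs; returns the full violation list
    instead of failing at the first problem."""
    violations: list[str] = []
    meta = None
    expr_samples: set = set()
    if cfg.sample_meta and Path(cfg.sample_meta).exists():
        meta = mio.read_sample_meta(cfg.sample_meta)
        for col in ("population", "role"):
            if col not in meta.columns:
                violations.append(f"sample_meta: missing column '{col}'")
    elif cfg.sample_meta:
        violations.append(f"sample_meta: file not found {cfg.sample_meta}")
    if cfg.expression and Path(cfg.expression).exists():
        try:
            expr_df = mio.read_matrix(cfg.expression)
            expr_samples = set(expr_df.columns)
            if expr_df.index.has_duplicates:
                violations.append("expression: duplicate gene identifiers")
            if meta is not None:
                unknown = expr_samples - set(meta.index)
                if unknown:
                    violations.append(f"expression: samples without metadata: {sorted(unknown)[:5]}")
        except Exception as exc:  # malformed table
            violations.append(f"expression: unreadable ({exc})")
    elif cfg.expression:
        violations.append(f"expression: file not found {cfg.expression}")
    if cfg.trios and Path(cfg.trios).exists():
        try:
            trios = mio.read_trios(cfg.trios)
            if expr_samples:
                for role in ("father", "mother", "child"):
                    absent = set(trios.table[role]) - expr_samples
                    if absent:
                        violations.append(f"trios: {role} samples absent from expression: {sorted(absent)[:5]}")
        except ParameterError as exc:
            violations.append(f"trios: {exc}")
    elif cfg.trios:
        violations.append(f"trios: file not found {cfg.trios}")
    if cfg.gmt and Path(cfg.gmt).exists():
        try:
            targets = mio.read_gmt(cfg.gmt)
            if expr_samples and cfg.expression:
                universe = set(mio.read_matrix(cfg.expression).index)
                overlap = targets.gene_universe() & universe
                if not overlap:
                    violations.append("gmt: no targeted gene appears in the expression matrix")
        except ParameterError as exc:
            violations.append(f"gmt: {exc}")
    elif cfg.gmt:
        violations.append(f"gmt: file not found {cfg.gmt}")
    if cfg.vcf and Path(cfg.vcf).exists():
        try:
            geno = mio.read_vcf(cfg.vcf)
            if expr_samples:
                shared = expr_samples & set(geno.sample_ids)
                if not shared:
                    violations.append("vcf: no sample shared with the expression matrix")
        except Exception as exc:
            violations.append(f"vcf: unreadable ({exc})")
    elif cfg.vcf:
        violations.append(f"vcf: file not found {cfg.vcf}")
    return violations


class PipelineRunner:
    """Runs enabled stages in dependency order inside ``cfg.out_dir``."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)

    # -- stage implementations -------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.cfg
        if cfg.simulation is None:
            raise ParameterError("simulate stage enabled but no simulation config given")
        seed = _stage_seed(cfg.seed, "simulate")
        sim = dataclasses.replace(cfg.simulation, seed=seed)
        ds = simulate_dataset(sim)
        comments = [f"seed={seed}", "generator=mirherit.simulate"]
        cfg.expression = str(self.out / "expression.tsv")
        cfg.sample_meta = str(self.out / "sample_meta.tsv")
        cfg.trios = str(self.out / "trios.tsv")
        cfg.gmt = str(self.out / "targets.gmt")
        cfg.vcf = str(self.out / "genotypes.vcf")
        cfg.mirna_expression = str(self.out / "mirna_expression.tsv")
        mio.write_expression(ds.expression, cfg.expression, comments)
        mio.write_sample_meta(ds.expression.sample_meta, cfg.sample_meta, comments)
        mio.write_trios(ds.trios, cfg.trios, comments)
        mio.write_gmt(ds.targets, cfg.gmt, comments)
        mio.write_vcf(ds.genotypes, cfg.vcf, comments)
        mio.write_matrix(ds.mirna_expression, cfg.mirna_expression, comments, index_label="mirna_id")
        _write_manifest(self.out, "simulate", seed, {}, dataclasses.asdict(sim))

    def _load_expression(self, stage: str) -> ExpressionMatrix:
        meta = mio.read_sample_meta(_require(self.cfg.sample_meta, stage, "sample_meta"))
        return mio.read_expression(_require(self.cfg.expression, stage, "expression"), meta)

    def stage_rescore(self) -> None:
        cfg = self.cfg
        expr = self._load_expression("rescore")
        targets = mio.read_gmt(_require(cfg.gmt, "rescore", "gmt"))
        scores = re_matrix(expr, targets, min_targets=cfg.min_targets)
        mio.write_rescores(scores, self.out / "rescore", [f"seed={cfg.seed}"])
        _write_manifest(
            self.out, "rescore", cfg.seed,
            {"expression": cfg.expression, "gmt": cfg.gmt},
            {"min_targets": cfg.min_targets},
        )

    def stage_herit(self) -> None:
        cfg = self.cfg
        re_path = self.out / "rescore" / "re_scores.tsv"
        _require(re_path, "herit", "re_scores")
        re_df = mio.read_matrix(re_path)
        from .containers import REScoreMatrix

        scores = REScoreMatrix(re=re_df, n_targets_used=pd.Series(dtype=int))
        trios = mio.read_trios(_require(cfg.trios, "herit", "trios"))
        meta = mio.read_sample_meta(_require(cfg.sample_meta, "herit", "sample_meta"))
        table = per_mirna_heritability(scores, trios, meta, method=cfg.herit_method)
        comments = [
            f"seed={cfg.seed}",
            f"n_positive={table.attrs['n_positive']}",
            f"n_positive_significant={table.attrs['n_positive_significant']}",
        ]
        mio.write_matrix(table, self.out / "heritability.tsv", comments, index_label="mirna")
        _write_manifest(
            self.out, "herit", cfg.seed,
            {"re_scores": re_path, "trios": cfg.trios},
            {"method": cfg.herit_method},
        )

    def stage_herit_permtest(self) -> None:
        cfg = self.cfg
        seed = _stage_seed(cfg.seed, "herit_permtest")
        expr = self._load_expression("herit_permtest")
        targets = mio.read_gmt(_require(cfg.gmt, "herit_permtest", "gmt"))
        trios = mio.read_trios(_require(cfg.trios, "herit_permtest", "trios"))
        result = target_permutation_test(
            expr, targets, trios, n_perm=cfg.n_perm_herit, seed=seed,
            min_targets=cfg.min_targets, method=cfg.herit_method,
        )
        (self.out / "herit_permtest.json").write_text(
            json.dumps(dataclasses.asdict(result), indent=2) + "\n"
        )
        _write_manifest(
            self.out, "herit_permtest", seed,
            {"expression": cfg.expression, "gmt": cfg.gmt, "trios": cfg.trios},
            {"n_perm": cfg.n_perm_herit},
        )

    def stage_qc(self) -> None:
        cfg = self.cfg
        seed = _stage_seed(cfg.seed, "qc")
        geno = mio.read_vcf(_require(cfg.vcf, "qc", "vcf"))
        meta = mio.read_sample_meta(_require(cfg.sample_meta, "qc", "sample_meta"))
        unrelated = meta.index[meta["role"] == "unrelated"]
        keep = geno.codes.columns.intersection(unrelated)
        if len(keep):
            geno = geno.subset_samples(keep)  # drop trio offspring / relatives
        filtered, report = qc_filter(geno, cfg.analysis, seed=seed)
        mio.write_vcf(filtered, self.out / "genotypes_qc.vcf", [f"seed={seed}"])
        report_d = dataclasses.asdict(report)
        (self.out / "qc_report.json").write_text(json.dumps(report_d, indent=2) + "\n")
        _write_manifest(self.out, "qc", seed, {"vcf": cfg.vcf}, dataclasses.asdict(cfg.analysis))

    def stage_assoc(self) -> None:
        cfg = self.cfg
        seed = _stage_seed(cfg.seed, "assoc")
        vcf_qc = self.out / "genotypes_qc.vcf"
        geno = mio.read_vcf(_require(vcf_qc, "assoc", "QC'd vcf"))
        if cfg.candidate_genes:
            geno = geno.restrict_to_genes(cfg.candidate_genes)
        re_path = self.out / "rescore" / "re_scores.tsv"
        re_df = mio.read_matrix(_require(re_path, "assoc", "re_scores"))
        targets = mio.read_gmt(_require(cfg.gmt, "assoc", "gmt"))
        from .containers import REScoreMatrix

        scores = REScoreMatrix(re=re_df, n_targets_used=pd.Series(dtype=int))
        # association trait: mean RE over conventional miRNAs (mirtrons are
        # the negative-control class, kept out of the trait)
        trait = conventional_mean_re(scores, targets)
        shared = trait.index.intersection(geno.sample_ids)
        results = TraitAssociation(trait.loc[shared], geno).fit(
            n_perm=cfg.n_perm_assoc, seed=seed
        )
        mio.write_matrix(results.table, self.out / "association.tsv", [f"seed={seed}"], index_label="snp")
        _write_manifest(
            self.out, "assoc", seed,
            {"vcf": vcf_qc, "re_scores": re_path, "gmt": cfg.gmt},
            {"n_perm": cfg.n_perm_assoc, "candidate_genes": cfg.candidate_genes},
        )

    def stage_integrate(self) -> None:
        cfg = self.cfg
        assoc_path = self.out / "association.tsv"
        re_path = self.out / "rescore" / "re_scores.tsv"
        _require(assoc_path, "integrate", "association table")
        _require(re_path, "integrate", "re_scores")
        assoc = mio.read_matrix(assoc_path)
        re_df = mio.read_matrix(re_path)
        targets = mio.read_gmt(_require(cfg.gmt, "integrate", "gmt"))
        geno = mio.read_vcf(self.out / "genotypes_qc.vcf")
        expr = self._load_expression("integrate")
        top_snp = assoc["p"].idxmin()
        genotype = geno.codes.loc[top_snp]
        samples = genotype.index.intersection(re_df.columns)

        per_mirna = snp_vs_many_traits(genotype.loc[samples], re_df[samples])
        table, fisher_p = mirtron_contrast(per_mirna["p"].dropna(), targets.classes(), alpha=cfg.alpha)

        summary: dict = {
            "top_snp": str(top_snp),
            "mirtron_table": dataclasses.asdict(table),
            "mirtron_fisher_p": fisher_p,
        }

        if cfg.mirna_expression and Path(cfg.mirna_expression).exists():
            mexpr = mio.read_matrix(cfg.mirna_expression)
            shared_m = mexpr.index.intersection(re_df.index)
            rhos = []
            for m in shared_m:
                common = mexpr.columns.intersection(samples)
                try:
                    rho, _ = spearman(mexpr.loc[m, common], re_df.loc[m, common])
                    rhos.append(rho)
                except Exception:
                    continue
            summary["mean_spearman_expr_vs_re"] = float(np.mean(rhos)) if rhos else None

            # individual RE vs subtracted mean RE and own expression
            top_var = most_variable(mexpr, top=10).intersection(re_df.index)
            stronger = 0
            tested = 0
            for m in top_var:
                if m not in targets:
                    continue
                common = mexpr.columns.intersection(re_df.columns)
                sub = subtracted_mean_re(expr, targets, m, min_targets=cfg.min_targets)
                common = common.intersection(sub.index)
                if len(common) < 4:
                    continue
                mean_res, expr_res = individual_vs_mean_re(
                    re_df.loc[m, common], sub.loc[common], mexpr.loc[m, common], identifier=m
                )
                tested += 1
                stronger += mean_res.raw_p < expr_res.raw_p
            summary["subtracted_mean_stronger"] = f"{stronger}/{tested}"

        mirtrons_with_p = per_mirna["p"].dropna().index.intersection(targets.mirtrons())
        if len(mirtrons_with_p) >= 3:
            strength = -np.log10(per_mirna.loc[mirtrons_with_p, "p"].clip(lower=1e-300))
            try:
                overlap = mirtron_overlap_regression(strength, targets)
                summary["mirtron_overlap_r2"] = overlap.extra["r_squared"]
                summary["mirtron_overlap_slope"] = overlap.statistic
                summary["mirtron_overlap_p"] = overlap.raw_p
            except ParameterError:
                pass

        (self.out / "integrative_summary.json").write_text(
            json.dumps(summary, indent=2, default=str) + "\n"
        )
        mio.write_matrix(per_mirna, self.out / "per_mirna_snp_assoc.tsv", [f"top_snp={top_snp}"], index_label="mirna")
        _write_manifest(
            self.out, "integrate", cfg.seed,
            {"association": assoc_path, "re_scores": re_path, "gmt": cfg.gmt},
            {"alpha": cfg.alpha},
        )

    # -- driver -----------------------------------------------------------

    def run(self) -> dict:
        report = {}
        for stage in STAGES:
            if stage not in self.cfg.stages:
                continue
            logger.info("running stage %s", stage)
            try:
                getattr(self, f"stage_{stage}")()
                report[stage] = "ok"
            except DependencyError:
                raise
            except Exception as exc:
                raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        (self.out / "pipeline_report.json").write_text(json.dumps(report, indent=2) + "\n")
        return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the stage
    status report."""
    return PipelineRunner(cfg).run()
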