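"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a two-population cohort of lymphoblastoid-like
expression profiles in which a per-sample latent variable E — "miRNA
pathway efficiency" — depresses the expression of miRNA target genes in
proportion to how many target sets contain each gene. E is heritable
through the standard additive mid-parent construction (child genetic value
= mid-parent genetic value + segregation deviation of variance h²/2, so the
regression of child E on mid-parent E has expected slope h²), and a single
causal SNP shifts E by ``effect_beta`` per minor allele. Gene expression is
a log-normal baseline plus a uniform population offset minus the repression
term plus Gaussian noise, clipped at zero; because the downstream RE-score
is a rank statistic, the uniform population offset is deliberately
rank-neutral, standing in for technical scale differences between cohorts.

miRNA expression is generated with mixed-sign loadings on E so that some
miRNAs associate with the causal SNP in each direction, mimicking a
trans-eQTL cluster under relative (pool-normalized) quantification.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import (
    CONVENTIONAL,
    MIRTRON,
    ExpressionMatrix,
    GenotypeMatrix,
    TargetSet,
    TargetSetCollection,
    TrioTable,
)
from .exceptions import ParameterError

BASELINE_LOG_MEAN = np.log(100.0)  # median baseline expression ~100 units
BASELINE_LOG_SD = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """All generative knobs; defaults are the package's study conditions."""

    n_genes: int = 3000
    n_mirnas: int = 50
    n_mirtrons: int = 3  # ~the source data's mirtron fraction (12 of 256)
    mean_targets_per_mirna: int = 100
    mean_sets_per_gene: float = 2.5  # target pool ~75% of genes: repression stays target-specific
    n_trios: int = 56
    n_unrelated: int = 60
    n_populations: int = 2
    h2_global: float = 0.68
    effect_beta: float = 1.0
    target_repression_strength: float = 5.0
    noise_sd: float = 10.0
    population_shift: float = 10.0
    n_snps: int = 500
    causal_snp_index: int = 0
    maf_range: tuple[float, float] = (0.1, 0.5)
    causal_maf: float = 0.4  # common causal variant; association power collapses below ~0.2 at n~60
    missing_rate: float = 0.005
    segregation_sd: float | None = None  # None -> sqrt(h2/2); 0 -> deterministic
    mirtron_bypass_causal: bool = True  # mirtron target sets ignore the causal-SNP shift
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_genes": self.n_genes,
            "n_mirnas": self.n_mirnas,
            "mean_targets_per_mirna": self.mean_targets_per_mirna,
            "n_trios": self.n_trios,
            "n_populations": self.n_populations,
            "n_snps": self.n_snps,
        }
        for name, v in counts.items():
            if v < 1:
                raise ParameterError(f"{name} must be positive, got {v}")
        if self.n_mirtrons < 0 or self.n_mirtrons > self.n_mirnas:
            raise ParameterError("n_mirtrons must be in [0, n_mirnas]")
        if self.n_unrelated < 0:
            raise ParameterError("n_unrelated must be non-negative")
        if not (0 <= self.h2_global <= 1):
            raise ParameterError("h2_global must lie in [0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ParameterError("missing_rate must lie in [0, 1)")
        if self.noise_sd <= 0 or self.target_repression_strength < 0:
            raise ParameterError("noise_sd must be > 0 and repression >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 < self.causal_maf <= 0.5):
            raise ParameterError("causal_maf must lie in (0, 0.5]")
        if not (0 <= self.causal_snp_index < self.n_snps):
            raise ParameterError("causal_snp_index must index into n_snps")
        if self.mean_targets_per_mirna >= self.n_genes:
            raise ParameterError("mean_targets_per_mirna must be < n_genes")
        if self.mean_sets_per_gene < 1:
            raise ParameterError("mean_sets_per_gene must be >= 1")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _gene_ids(n: int) -> list[str]:
    return [f"gene{str(i).zfill(5)}" for i in range(n)]


def _target_pool_size(cfg: SimulationConfig) -> int:
    """Pool size such that the expected mean number of sets per *targeted*
    gene matches ``mean_sets_per_gene``.

    With A total target assignments spread over a pool of P genes, the mean
    memberships per targeted gene is (A/P) / (1 - exp(-A/P)); invert for
    A/P by root finding.
    """
    A = cfg.n_mirnas * cfg.mean_targets_per_mirna
    target = cfg.mean_sets_per_gene

    def f(x):
        return x / (1 - np.exp(-x)) - target

    if target <= 1.0 + 1e-9:
        return cfg.n_genes
    x = brentq(f, 1e-9, max(10 * target, 10.0))
    return int(np.clip(round(A / x), cfg.mean_targets_per_mirna + 1, cfg.n_genes))


def generate_target_sets(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> TargetSetCollection:
    """Draw n_mirnas target sets over the gene universe with many-to-many
    overlap; the final ``n_mirtrons`` sets are flagged mirtron."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    genes = np.array(_gene_ids(cfg.n_genes))
    pool = rng.choice(cfg.n_genes, size=_target_pool_size(cfg), replace=False)
    sets = []
    for i in range(cfg.n_mirnas):
        size = max(1, int(rng.poisson(cfg.mean_targets_per_mirna)))
        size = min(size, len(pool))
        members = rng.choice(pool, size=size, replace=False)
        mirtron = i >= cfg.n_mirnas - cfg.n_mirtrons
        name = f"mirtron-sim-{i:03d}" if mirtron else f"miR-sim-{i:03d}"
        sets.append(
            TargetSet(name, frozenset(genes[members]),
                      MIRTRON if mirtron else CONVENTIONAL, "simulated")
        )
    return TargetSetCollection(sets)


def _population_labels(n: int, cfg: SimulationConfig) -> np.ndarray:
    return np.array([f"POP{i % cfg.n_populations + 1}" for i in range(n)])


def _trio_efficiencies(cfg: SimulationConfig, rng: np.random.Generator):
    """Latent efficiency for fathers, mothers, children under the additive
    mid-parent model; each marginal has variance 1."""
    h2 = cfg.h2_global
    n = cfg.n_trios
    g_f = rng.normal(0, np.sqrt(h2), n) if h2 > 0 else np.zeros(n)
    g_m = rng.normal(0, np.sqrt(h2), n) if h2 > 0 else np.zeros(n)
    seg_sd = np.sqrt(h2 / 2) if cfg.segregation_sd is None else cfg.segregation_sd
    g_c = (g_f + g_m) / 2 + rng.normal(0, seg_sd, n)
    env_sd = np.sqrt(max(1 - h2, 0.0))
    e_f = rng.normal(0, env_sd, n) if env_sd > 0 else np.zeros(n)
    e_m = rng.normal(0, env_sd, n) if env_sd > 0 else np.zeros(n)
    e_c = rng.normal(0, env_sd, n) if env_sd > 0 else np.zeros(n)
    return g_f + e_f, g_m + e_m, g_c + e_c


def _class_memberships(cfg: SimulationConfig, targets: TargetSetCollection):
    """Per-gene counts of conventional and mirtron sets containing it."""
    genes = _gene_ids(cfg.n_genes)
    pos = {g: i for i, g in enumerate(genes)}
    m_conv = np.zeros(cfg.n_genes)
    m_mir = np.zeros(cfg.n_genes)
    for ts in targets:
        dest = m_mir if ts.mirna_class == MIRTRON else m_conv
        for g in ts.genes:
            dest[pos[g]] += 1
    return genes, m_conv, m_mir


def _expression_from_efficiency(
    cfg: SimulationConfig,
    targets: TargetSetCollection,
    efficiency: pd.Series,
    meta: pd.DataFrame,
    rng: np.random.Generator,
    baseline: np.ndarray | None = None,
    efficiency_mirtron: pd.Series | None = None,
) -> ExpressionMatrix:
    """Expression = baseline + population offset − repression + noise.

    Repression on a gene is proportional to how many target sets contain it,
    split by miRNA class: conventional memberships respond to ``efficiency``
    (which may include the causal-SNP shift) while mirtron memberships
    respond to ``efficiency_mirtron`` (defaults to the same series) —
    mirtrons bypass DROSHA, so a DROSHA-like causal variant must not act
    through them.
    """
    genes, m_conv, m_mir = _class_memberships(cfg, targets)
    if baseline is None:
        baseline = rng.lognormal(BASELINE_LOG_MEAN, BASELINE_LOG_SD, cfg.n_genes)
    pop_index = meta["population"].str.removeprefix("POP").astype(int).to_numpy() - 1
    shift = cfg.population_shift * pop_index  # uniform across genes: rank-neutral
    E = efficiency.loc[meta.index].to_numpy()
    E_mir = E if efficiency_mirtron is None else efficiency_mirtron.loc[meta.index].to_numpy()
    k = cfg.target_repression_strength
    values = (
        baseline[:, None]
        + shift[None, :]
        - k * (m_conv[:, None] * E[None, :] + m_mir[:, None] * E_mir[None, :])
        + rng.normal(0, cfg.noise_sd, (cfg.n_genes, len(meta)))
    )
    values = np.clip(values, 0.0, None)
    df = pd.DataFrame(values, index=genes, columns=meta.index)
    return ExpressionMatrix(df, meta)


def generate_trio_expression(
    cfg: SimulationConfig,
    targets: TargetSetCollection,
    rng: np.random.Generator | None = None,
    return_efficiency: bool = False,
):
    """Expression matrix and trio table for ``cfg.n_trios`` father/mother/
    child trios; offspring latent efficiency regresses on the mid-parent
    value with expected slope ``cfg.h2_global``."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_trios
    E_f, E_m, E_c = _trio_efficiencies(cfg, rng)
    fathers = [f"trio{i:03d}F" for i in range(n)]
    mothers = [f"trio{i:03d}M" for i in range(n)]
    children = [f"trio{i:03d}C" for i in range(n)]
    pops = _population_labels(n, cfg)
    meta = pd.DataFrame(
        {
            "population": np.concatenate([pops, pops, pops]),
            "role": ["father"] * n + ["mother"] * n + ["child"] * n,
        },
        index=pd.Index(fathers + mothers + children, name="sample_id"),
    )
    efficiency = pd.Series(
        np.concatenate([E_f, E_m, E_c]), index=meta.index, name="efficiency"
    )
    expr = _expression_from_efficiency(cfg, targets, efficiency, meta, rng)
    trios = TrioTable(
        pd.DataFrame(
            {
                "trio_id": [f"trio{i:03d}" for i in range(n)],
                "father": fathers,
                "mother": mothers,
                "child": children,
            }
        )
    )
    if return_efficiency:
        return expr, trios, efficiency
    return expr, trios


def generate_genotypes(
    cfg: SimulationConfig,
    samples: Sequence[str],
    efficiency: pd.Series,
    rng: np.random.Generator | None = None,
    causal_gene: str = "DROSHA",
) -> tuple[GenotypeMatrix, pd.Series]:
    """SNP genotypes in Hardy-Weinberg proportions at MAFs drawn from
    ``cfg.maf_range``.

    The causal SNP's minor-allele count c enters the latent efficiency:
    the returned Series equals the supplied base efficiency plus
    ``effect_beta * (c - mean(c))``; all other SNPs are independent of it.
    Missing genotypes (NaN) are introduced at ``cfg.missing_rate`` after the
    efficiency contribution is computed, as missingness is an assay
    property, not a biological one. SNPs within 20 loci of the causal one
    share its ``region_gene`` label so candidate-region scans can be
    exercised.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    samples = list(samples)
    n = len(samples)
    if not efficiency.index.isin(samples).all() or len(efficiency) != n:
        raise ParameterError("efficiency must be indexed exactly by samples")
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.n_snps)
    mafs[cfg.causal_snp_index] = cfg.causal_maf
    codes = rng.binomial(2, mafs[:, None], size=(cfg.n_snps, n)).astype(float)
    causal = codes[cfg.causal_snp_index].copy()
    updated = efficiency.loc[samples] + cfg.effect_beta * (causal - causal.mean())
    updated.name = "efficiency"
    if cfg.missing_rate > 0:
        mask = rng.random((cfg.n_snps, n)) < cfg.missing_rate
        codes[mask] = np.nan
    snp_ids = [f"rs{900000 + i}" for i in range(cfg.n_snps)]
    region = np.full(cfg.n_snps, None, dtype=object)
    lo = max(0, cfg.causal_snp_index - 20)
    hi = min(cfg.n_snps, cfg.causal_snp_index + 21)
    region[lo:hi] = causal_gene
    meta = pd.DataFrame(
        {
            "chrom": "chr5",
            "pos": 31_000_000 + 1000 * np.arange(cfg.n_snps),
            "ref": "A",
            "alt": "G",
            "maf": mafs,
            "region_gene": region,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    geno = GenotypeMatrix(
        pd.DataFrame(codes, index=snp_ids, columns=samples), meta
    )
    return geno, updated


def generate_mirna_expression(
    cfg: SimulationConfig,
    efficiency: pd.Series,
    rng: np.random.Generator | None = None,
    loadings: np.ndarray | None = None,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """miRNA expression = baseline + loading x efficiency + noise, with
    mixed-sign loadings drawn N(0, 1) unless supplied."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    m = cfg.n_mirnas
    if loadings is None:
        loadings = rng.normal(0, 1, m)
    loadings = np.asarray(loadings, dtype=float)
    noise_sd = cfg.noise_sd / 10.0 if noise_sd is None else noise_sd
    baseline = rng.lognormal(np.log(50.0), 0.5, m)
    E = efficiency.to_numpy()
    names = [f"miR-sim-{i:03d}" for i in range(m - cfg.n_mirtrons)] + [
        f"mirtron-sim-{i:03d}" for i in range(m - cfg.n_mirtrons, m)
    ]
    noise = rng.normal(0, noise_sd, (m, len(E))) if noise_sd > 0 else 0.0
    values = baseline[:, None] + loadings[:, None] * E[None, :] + noise
    return pd.DataFrame(values, index=names, columns=efficiency.index)


@dataclass
class SimulatedDataset:
    """Everything one study run needs, generated from a single seed."""

    config: SimulationConfig
    targets: TargetSetCollection
    expression: ExpressionMatrix  # trios + unrelated samples
    trios: TrioTable
    genotypes: GenotypeMatrix  # unrelated samples only
    mirna_expression: pd.DataFrame  # unrelated samples only
    efficiency: pd.Series  # all samples, incl. causal-SNP contribution
    causal_snp_id: str = ""
    unrelated_samples: list = field(default_factory=list)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate a full coherent study bundle.

    Trio samples get expression only (heritability stage); the unrelated
    cohort gets expression, genotypes and miRNA expression (association and
    integrative stages). The causal SNP contributes to the unrelated
    samples' latent efficiency before expression is generated from it.
    """
    root = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(5)]
    targets = generate_target_sets(cfg, rngs[0])

    expr_trio, trios, eff_trio = generate_trio_expression(
        cfg, targets, rngs[1], return_efficiency=True
    )

    n_u = cfg.n_unrelated
    unrelated = [f"unrel{i:03d}" for i in range(n_u)]
    meta_u = pd.DataFrame(
        {"population": _population_labels(n_u, cfg), "role": "unrelated"},
        index=pd.Index(unrelated, name="sample_id"),
    )
    base_eff_u = pd.Series(rngs[2].normal(0, 1, n_u), index=meta_u.index, name="efficiency")
    geno, eff_u = generate_genotypes(cfg, unrelated, base_eff_u, rngs[2])
    eff_mirtron = base_eff_u if cfg.mirtron_bypass_causal else eff_u
    expr_u = _expression_from_efficiency(
        cfg, targets, eff_u, meta_u, rngs[3], efficiency_mirtron=eff_mirtron
    )
    mirna_expr = generate_mirna_expression(cfg, eff_u, rngs[4])

    values = pd.concat([expr_trio.values, expr_u.values], axis=1)
    meta = pd.concat([expr_trio.sample_meta, meta_u])
    expression = ExpressionMatrix(values, meta)
    efficiency = pd.concat([eff_trio, eff_u])
    return SimulatedDataset(
        config=cfg,
        targets=targets,
        expression=expression,
        trios=trios,
        genotypes=geno,
        mirna_expression=mirna_expr,
        efficiency=efficiency,
        causal_snp_id=geno.snp_ids[cfg.causal_snp_index],
        unrelated_samples=unrelated,
    )
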