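"""Genotype QC and quantitative-trait association for the mean RE-score.

The association model treats the per-sample mean RE-score as a quantitative
trait and regresses it on the additive minor-allele count at each SNP
(ordinary least squares; a score-test variant is available for comparison).
Multiple testing is handled three ways, matching the columns a candidate-gene
scan reports: Bonferroni, Storey q-values, and a family-wise permutation
adjustment in which phenotype labels are permuted, the minimum p-value across
the panel is recorded for each permutation, and each SNP's adjusted p is the
proportion of permutations whose minimum p reaches its observed p (maxT
style). A per-SNP permutation mode is available behind a flag.

QC follows the usual cohort recipe, in order: sample call-rate, SNP
call-rate, minimum minor-allele copies, Hardy-Weinberg equilibrium at a
Benjamini-Hochberg FDR cut-off, and removal of cryptically related samples
by pairwise identity-by-state on a random marker subset.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .exceptions import EmptyResultError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """QC thresholds and permutation settings for the association scan."""

    alpha: float = 0.05
    min_minor_allele_copies: int = 5
    callrate_min: float = 0.95
    hwe_fdr: float = 0.2
    ibs_markers: int = 2000
    ibs_max: float = 0.95
    n_perm: int = 1000

    def __post_init__(self):
        for name in ("alpha", "callrate_min", "hwe_fdr", "ibs_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ParameterError(f"{name} must be in (0, 1], got {v}")
        if self.min_minor_allele_copies < 1 or self.ibs_markers < 1:
            raise ParameterError("counts must be positive")


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def hwe_chisq(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """Pearson chi-square test of Hardy-Weinberg proportions (1 df).

    The allele frequency is estimated from the genotype counts; expected
    counts are N(1-q)^2, 2Nq(1-q), Nq^2 for the minor-allele frequency q.
    Classes with zero expected count are excluded from the statistic; a
    fully monomorphic locus returns (0.0, 1.0).
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ParameterError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ParameterError("total genotype count must be positive")
    q = (2 * n_aa + n_Aa) / (2.0 * n)
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    keep = expected > 0
    if keep.sum() <= 1:  # monomorphic
        return 0.0, 1.0
    chi2 = float(((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(codes: np.ndarray) -> np.ndarray:
    out = np.empty(codes.shape[0])
    for i, row in enumerate(codes):
        row = row[~np.isnan(row)]
        out[i] = hwe_chisq(int((row == 0).sum()), int((row == 1).sum()), int((row == 2).sum()))[1]
    return out


def _bh_reject(ps: np.ndarray, fdr: float) -> np.ndarray:
    """Benjamini-Hochberg rejection mask at level ``fdr``."""
    m = len(ps)
    order = np.argsort(ps)
    thresh = fdr * (np.arange(1, m + 1)) / m
    below = ps[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        reject[order[: k + 1]] = True
    return reject


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_input_snps: int
    n_input_samples: int
    n_removed_samples_callrate: int = 0
    n_failed_callrate_snp: int = 0
    n_failed_mac: int = 0
    n_failed_hwe: int = 0
    n_removed_samples_ibs: int = 0
    surviving_snp_ids: list = field(default_factory=list)
    surviving_sample_ids: list = field(default_factory=list)

    @property
    def n_surviving_snps(self) -> int:
        return len(self.surviving_snp_ids)


def _ibs_matrix(codes: np.ndarray) -> np.ndarray:
    """Pairwise mean proportion of alleles shared ({0, 1/2, 1} per marker),
    over pairwise-complete markers."""
    m, n = codes.shape
    ibs = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(codes[:, i]) & ~np.isnan(codes[:, j])
            if both.sum() == 0:
                ibs[i, j] = ibs[j, i] = np.nan
                continue
            share = 1.0 - np.abs(codes[both, i] - codes[both, j]) / 2.0
            ibs[i, j] = ibs[j, i] = share.mean()
    return ibs


def qc_filter(
    geno: GenotypeMatrix, cfg: AnalysisConfig, seed: int
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the QC cascade and report what each rule removed.

    Order: sample call-rate, SNP call-rate, minor-allele copies, HWE at
    Benjamini-Hochberg FDR ``cfg.hwe_fdr``, then pairwise IBS on
    ``cfg.ibs_markers`` randomly chosen surviving markers (one member of
    each pair with IBS >= ``cfg.ibs_max`` is removed).
    """
    if geno.n_samples < 2:
        raise ParameterError("need at least 2 samples for QC")
    report = QCReport(n_input_snps=geno.n_snps, n_input_samples=geno.n_samples)
    codes = geno.codes

    # 1. sample call rate
    sample_cr = codes.notna().mean(axis=0)
    keep_samples = sample_cr >= cfg.callrate_min
    report.n_removed_samples_callrate = int((~keep_samples).sum())
    codes = codes.loc[:, keep_samples]

    # 2. SNP call rate
    snp_cr = codes.notna().mean(axis=1)
    keep = snp_cr >= cfg.callrate_min
    report.n_failed_callrate_snp = int((~keep).sum())
    codes = codes.loc[keep]

    # 3. minor-allele copies ("less than 5 copies" removed, 5 retained)
    arr = codes.to_numpy()
    alt = np.nansum(arr, axis=1)
    total = 2 * np.sum(~np.isnan(arr), axis=1)
    mac = np.minimum(alt, total - alt)
    keep = mac >= cfg.min_minor_allele_copies
    report.n_failed_mac = int((~keep).sum())
    codes = codes.loc[keep]

    # 4. HWE at BH FDR
    if len(codes):
        hwe_p = _hwe_pvalues(codes.to_numpy())
        reject = _bh_reject(hwe_p, cfg.hwe_fdr)
        report.n_failed_hwe = int(reject.sum())
        codes = codes.loc[~reject]

    if codes.empty:
        raise EmptyResultError("all SNPs removed by QC")

    # 5. pairwise IBS on a random marker subset
    rng = np.random.default_rng(seed)
    n_markers = min(cfg.ibs_markers, len(codes))
    marker_idx = rng.choice(len(codes), size=n_markers, replace=False)
    ibs = _ibs_matrix(codes.to_numpy()[np.sort(marker_idx)])
    n = ibs.shape[0]
    drop = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if not drop[i] and not drop[j] and np.isfinite(ibs[i, j]) and ibs[i, j] >= cfg.ibs_max:
                drop[j] = True
                logger.info(
                    "IBS %.3f >= %.2f: removing sample %s (kept %s)",
                    ibs[i, j], cfg.ibs_max, codes.columns[j], codes.columns[i],
                )
    report.n_removed_samples_ibs = int(drop.sum())
    codes = codes.loc[:, ~drop]

    report.surviving_snp_ids = list(codes.index)
    report.surviving_sample_ids = list(codes.columns)
    return GenotypeMatrix(codes, geno.meta), report


# ---------------------------------------------------------------------------
# Association engine (vectorized, missing-aware)
# ---------------------------------------------------------------------------

def _ls_assoc(codes: np.ndarray, Y: np.ndarray, score_test: bool = False):
    """Least-squares slope and p of each trait column on each SNP row.

    ``codes`` is SNPs x samples with NaN missing; ``Y`` is samples x B trait
    columns (no missing). Returns (beta, p, n_used), each SNPs x B except
    n_used which is per SNP. SNPs monomorphic among non-missing samples get
    NaN. Fully vectorized so the same path serves the observed scan and the
    permutation null.
    """
    M = (~np.isnan(codes)).astype(float)
    X0 = np.nan_to_num(codes)
    n = M.sum(axis=1)  # per SNP
    Sx = X0.sum(axis=1)
    Sxx = (X0**2).sum(axis=1)
    Sy = M @ Y
    Syy = M @ (Y**2)
    Sxy = X0 @ Y
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx_c = Sxx - Sx**2 / n
        sxy_c = Sxy - (Sx / n)[:, None] * Sy
        syy_c = Syy - Sy**2 / n[:, None]
        beta = sxy_c / sxx_c[:, None]
        ssr = syy_c - sxy_c**2 / sxx_c[:, None]
        df = n - 2
        if score_test:
            # score (n * r^2 ~ chi2_1) instead of the t test on the slope
            r2 = np.where(syy_c > 0, sxy_c**2 / (sxx_c[:, None] * syy_c), 0.0)
            p = stats.chi2.sf(n[:, None] * r2, df=1)
        else:
            sigma2 = np.maximum(ssr, 0.0) / df[:, None]
            se = np.sqrt(sigma2 / sxx_c[:, None])
            t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
            p = 2.0 * stats.t.sf(np.abs(t), df[:, None])
    bad = (sxx_c <= 0) | (n < 3)
    beta[bad, :] = np.nan
    p[bad, :] = np.nan
    return beta, p, n.astype(int)


def qt_association(trait: pd.Series, geno: GenotypeMatrix, score_test: bool = False) -> pd.DataFrame:
    """Per-SNP additive regression of the trait on minor-allele count.

    Returns a DataFrame indexed by SNP with columns beta, p, n. SNPs that
    are monomorphic among non-missing samples, or have fewer than 3
    non-missing samples, are omitted (logged).
    """
    codes = geno.codes[trait.index].to_numpy()
    y = trait.to_numpy(dtype=float)[:, None]
    beta, p, n = _ls_assoc(codes, y, score_test=score_test)
    out = pd.DataFrame(
        {"beta": beta[:, 0], "p": p[:, 0], "n": n}, index=geno.snp_ids
    )
    dropped = out.index[out["p"].isna()]
    for s in dropped:
        logger.info("SNP %s omitted: monomorphic or <3 non-missing samples", s)
    return out.dropna(subset=["p"])


def adjust_permutation(
    trait: pd.Series,
    geno: GenotypeMatrix,
    raw: pd.DataFrame,
    n_perm: int,
    seed: int,
    mode: str = "family-wise",
    score_test: bool = False,
) -> pd.Series:
    """Permutation-adjusted p-values by phenotype-label permutation.

    ``family-wise`` (default, maxT style): for each permutation the minimum
    p across the panel is recorded and each SNP's adjusted p is the
    proportion of permutations whose minimum p <= its observed raw p.
    ``per-snp``: each SNP is compared only against its own permutation
    distribution.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    if mode not in ("family-wise", "per-snp"):
        raise ParameterError(f"unknown permutation mode {mode!r}")
    codes = geno.codes.loc[raw.index, trait.index].to_numpy()
    y = trait.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    Y = np.empty((len(y), n_perm))
    for b in range(n_perm):
        Y[:, b] = y[rng.permutation(len(y))]
    _, p_perm, _ = _ls_assoc(codes, Y, score_test=score_test)
    raw_p = raw["p"].to_numpy()
    if mode == "family-wise":
        min_p = np.nanmin(p_perm, axis=0)  # per permutation
        adj = (min_p[None, :] <= raw_p[:, None]).mean(axis=1)
    else:
        adj = np.nanmean(p_perm <= raw_p[:, None], axis=1)
    return pd.Series(adj, index=raw.index, name="permutation_p")


def snp_vs_many_traits(genotype: pd.Series, traits: pd.DataFrame) -> pd.DataFrame:
    """Regress many traits (rows of ``traits``, samples in columns) on one
    SNP's additive allele count. Used for per-miRNA RE-score and miRNA
    expression scans against a single locus.

    Samples with missing genotype are excluded; returns beta, p and n per
    trait, omitting nothing (rows with a monomorphic genotype get NaN).
    """
    shared = traits.columns.intersection(genotype.index)
    g = genotype.loc[shared].to_numpy(dtype=float)
    ok = ~np.isnan(g)
    g = g[ok]
    Y = traits[shared].to_numpy(dtype=float)[:, ok]
    x = g - g.mean()
    sxx = (x**2).sum()
    out = pd.DataFrame(index=traits.index, columns=["beta", "p", "n"], dtype=float)
    if sxx == 0:
        out["n"] = ok.sum()
        return out
    yc = Y - Y.mean(axis=1, keepdims=True)
    b = (yc @ x) / sxx
    ssr = (yc**2).sum(axis=1) - b**2 * sxx
    df = ok.sum() - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(ssr, 0.0) / df / sxx)
        t = np.where(se > 0, b / se, np.inf * np.sign(b))
    out["beta"] = b
    out["p"] = 2.0 * stats.t.sf(np.abs(t), df)
    out["n"] = int(ok.sum())
    return out


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def estimate_pi0(ps: np.ndarray, lambdas: np.ndarray = _LAMBDA_GRID) -> float:
    """Proportion of true nulls by the smoother method: pi0(lambda) fitted
    with a cubic polynomial over the lambda grid, evaluated at max(lambda)."""
    ps = np.asarray(ps, dtype=float)
    pi0_l = np.array([np.mean(ps > lam) / (1 - lam) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    return pi0


def qvalue(raw_ps, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    pi0 is estimated by the smoother over the 0.05..0.95 grid; the estimate
    falls back to 1 (plain Benjamini-Hochberg) when it exceeds 1, is not
    positive, or the input has fewer than 100 tests.
    """
    ps = np.asarray(raw_ps, dtype=float)
    if ((ps < 0) | (ps > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    m = len(ps)
    if pi0 is None:
        if m < 100:
            pi0 = 1.0
        else:
            pi0 = estimate_pi0(ps)
            if pi0 > 1 or pi0 <= 0:
                pi0 = 1.0
    order = np.argsort(ps)
    q = np.empty(m)
    q[order] = pi0 * m * ps[order] / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = q[order]
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------

class TraitAssociation:
    """Quantitative-trait association model: trait ~ additive allele count.

    Built from a per-sample trait and a (QC'd) genotype matrix; ``fit()``
    runs the per-SNP scan and the multiple-testing adjustments and returns
    an :class:`AssociationResults`.
    """

    def __init__(self, trait: pd.Series, geno: GenotypeMatrix):
        shared = geno.codes.columns.intersection(trait.index)
        if len(shared) < 3:
            raise ParameterError("need at least 3 samples shared by trait and genotypes")
        self.trait = trait.loc[shared].astype(float)
        self.geno = geno.subset_samples(shared)

    def fit(
        self,
        n_perm: int = 0,
        seed: int = 0,
        mode: str = "family-wise",
        score_test: bool = False,
    ) -> "AssociationResults":
        raw = qt_association(self.trait, self.geno, score_test=score_test)
        if raw.empty:
            raise EmptyResultError("no testable SNP")
        m = len(raw)
        table = raw.copy()
        table["bonferroni_p"] = np.minimum(1.0, m * table["p"])
        table["q_value"] = qvalue(table["p"].to_numpy())
        if n_perm > 0:
            table["permutation_p"] = adjust_permutation(
                self.trait, self.geno, raw, n_perm, seed, mode=mode, score_test=score_test
            )
        else:
            table["permutation_p"] = np.nan
        meta = self.geno.meta.loc[table.index, ["chrom", "pos"]]
        gene = self.geno.meta.loc[table.index].get("region_gene")
        table = pd.concat([meta, table], axis=1)
        table["gene"] = gene
        cols = ["chrom", "pos", "gene", "beta", "p", "bonferroni_p", "q_value", "permutation_p", "n"]
        return AssociationResults(table[cols].sort_values("p"), n_perm=n_perm, seed=seed)


@dataclass
class AssociationResults:
    """Per-SNP association table with raw and adjusted p-values."""

    table: pd.DataFrame
    n_perm: int
    seed: int

    @property
    def top_snp(self) -> str:
        return str(self.table.index[0])

    def significant(self, alpha: float = 0.05, column: str = "permutation_p") -> pd.DataFrame:
        return self.table[self.table[column] < alpha]

    def summary(self, top: int = 10) -> str:
        head = self.table.head(top)
        lines = [
            f"Quantitative-trait association: {len(self.table)} SNPs, "
            f"{self.n_perm} permutations (seed {self.seed})",
            "",
            head.to_string(float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)
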