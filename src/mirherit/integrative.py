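"""Downstream contrasts tying the association signal to miRNA biology.

Mirtrons — intronic miRNAs spliced out of their host transcript — bypass
DROSHA processing, so a genuine DROSHA-mediated effect on global miRNA
efficiency should leave mirtron RE-scores largely unassociated with a DROSHA
variant. The mirtron contrast formalizes this as a 2x2 Fisher's exact test
of associated / not-associated counts by miRNA class. The remaining
operations relate the trait to miRNA expression (Spearman), to biogenesis
pathway gene expression (linear regression with population covariates and
Bonferroni correction), to the subtracted mean RE-score (multiple
regression), and to target-set overlap (the mirtron overlap regression).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from .containers import TargetSetCollection, CONVENTIONAL, MIRTRON
from .exceptions import ParameterError, SingularDesignError, UndefinedCorrelationError

TIE_RELTOL = 1e-7
COLLINEARITY_LIMIT = 0.999


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) in row 1 and (c, d) in row 2; rows are miRNA classes,
    columns associated / not associated at alpha."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ParameterError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ParameterError("contingency table is empty")


@dataclass
class IntegrativeResult:
    identifier: str
    statistic: float
    raw_p: float
    adjusted_p: float
    n: int
    extra: dict | None = None


def _log_hypergeom_pmf(x: np.ndarray, r1: int, c1: int, n: int) -> np.ndarray:
    """log P(X = x) for the 2x2 table's top-left cell under fixed margins."""
    r2 = n - r1
    return (
        gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
        + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p by hypergeometric enumeration.

    All tables with the observed margins are enumerated; the p-value sums
    the probabilities of tables whose point probability does not exceed the
    observed one (within relative tolerance 1e-7, the usual tie rule).
    Computed in log space so totals up to ~1e6 are safe.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0  # degenerate margin: only one table possible
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    xs = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(xs.astype(float), r1, c1, n)
    log_obs = float(logp[xs == a][0])
    include = logp <= log_obs + np.log1p(TIE_RELTOL)
    p = float(np.exp(logp[include]).sum())
    return min(p, 1.0)


def mirtron_contrast(
    per_mirna_ps: pd.Series, classes: pd.Series, alpha: float = 0.05
) -> tuple[ContingencyTable2x2, float]:
    """Fisher contrast of association rates between mirtrons and
    conventional miRNAs.

    Rows: mirtron / conventional; columns: associated (p < alpha) / not.
    """
    shared = per_mirna_ps.index.intersection(classes.index)
    ps = per_mirna_ps.loc[shared]
    cls = classes.loc[shared]
    present = set(cls)
    if MIRTRON not in present or CONVENTIONAL not in present:
        raise ParameterError("both miRNA classes must be represented")
    assoc = ps < alpha
    table = ContingencyTable2x2(
        a=int((assoc & (cls == MIRTRON)).sum()),
        b=int((~assoc & (cls == MIRTRON)).sum()),
        c=int((assoc & (cls == CONVENTIONAL)).sum()),
        d=int((~assoc & (cls == CONVENTIONAL)).sum()),
    )
    return table, fisher_exact_two_sided(table)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; p by the t
    approximation. Raises for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ParameterError("need two equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return rho, float(2 * stats.t.sf(abs(t), n - 2))


def _with_population(predictors: pd.DataFrame, population) -> pd.DataFrame:
    if population is not None:
        pop = pd.Series(list(population), index=predictors.index)
        if pop.nunique() > 1:
            dummies = pd.get_dummies(pop, prefix="pop", drop_first=True, dtype=float)
            predictors = pd.concat([predictors, dummies], axis=1)
    return sm.add_constant(predictors)


def expression_vs_trait(
    gene_expr: pd.Series,
    trait: pd.Series,
    population=None,
    m_tests: int = 1,
    identifier: str = "gene",
) -> IntegrativeResult:
    """Regress the trait on one gene's expression (plus population
    indicators) and Bonferroni-adjust the slope's p over ``m_tests``."""
    if len(gene_expr) < 3 or len(gene_expr) != len(trait):
        raise ParameterError("need >= 3 aligned samples")
    X = _with_population(pd.DataFrame({"expr": gene_expr.to_numpy()}), population)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError("singular design in expression-vs-trait fit")
    res = sm.OLS(trait.to_numpy(dtype=float), X).fit()
    raw_p = float(res.pvalues["expr"])
    return IntegrativeResult(
        identifier=identifier,
        statistic=float(res.params["expr"]),
        raw_p=raw_p,
        adjusted_p=min(1.0, m_tests * raw_p),
        n=len(trait),
    )


def individual_vs_mean_re(
    re_i: pd.Series,
    subtracted_mean: pd.Series,
    mirna_expr: pd.Series,
    identifier: str = "mirna",
) -> tuple[IntegrativeResult, IntegrativeResult]:
    """Multiple regression of one miRNA's RE-score on its own expression and
    the subtracted mean RE-score; returns (mean-RE result, expression
    result) so the two covariates' strengths can be compared.

    Near-collinear covariates (|r| > 0.999) are flagged via ``extra`` but
    both p-values are still emitted.
    """
    n = len(re_i)
    if n < 4 or not (len(subtracted_mean) == len(mirna_expr) == n):
        raise ParameterError("need >= 4 aligned samples")
    x1 = subtracted_mean.to_numpy(dtype=float)
    x2 = mirna_expr.to_numpy(dtype=float)
    collinear = False
    if np.ptp(x1) > 0 and np.ptp(x2) > 0:
        r = float(np.corrcoef(x1, x2)[0, 1])
        collinear = abs(r) > COLLINEARITY_LIMIT
    X = sm.add_constant(pd.DataFrame({"mean_re": x1, "expr": x2}))
    res = sm.OLS(re_i.to_numpy(dtype=float), X).fit()
    extra = {"collinear": True} if collinear else None
    mean_res = IntegrativeResult(
        identifier=f"{identifier}:mean_re",
        statistic=float(res.params["mean_re"]),
        raw_p=float(res.pvalues["mean_re"]),
        adjusted_p=float(res.pvalues["mean_re"]),
        n=n,
        extra=extra,
    )
    expr_res = IntegrativeResult(
        identifier=f"{identifier}:expression",
        statistic=float(res.params["expr"]),
        raw_p=float(res.pvalues["expr"]),
        adjusted_p=float(res.pvalues["expr"]),
        n=n,
        extra=extra,
    )
    return mean_res, expr_res


def mirtron_overlap_regression(
    assoc_strength: pd.Series, targets: TargetSetCollection
) -> IntegrativeResult:
    """Regress each mirtron's association strength (-log10 p scale supplied
    by the caller) on the mean number of conventional miRNAs targeting its
    target genes.

    Tests whether mirtrons that look associated owe it to target-set overlap
    with conventional miRNAs.
    """
    mirtrons = [m for m in targets.mirtrons() if m in assoc_strength.index]
    if len(mirtrons) < 3:
        raise ParameterError("need at least 3 mirtrons with association values")
    conv_counts: dict = {}
    for m in targets.conventional():
        for g in targets[m].genes:
            conv_counts[g] = conv_counts.get(g, 0) + 1
    overlap = pd.Series(
        {m: float(np.mean([conv_counts.get(g, 0) for g in targets[m].genes])) for m in mirtrons}
    )
    y = assoc_strength.loc[mirtrons].to_numpy(dtype=float)
    x = overlap.to_numpy()
    if np.ptp(x) == 0:
        raise SingularDesignError("overlap predictor is constant")
    if np.ptp(y) == 0:
        return IntegrativeResult(
            identifier="mirtron_overlap", statistic=0.0, raw_p=1.0,
            adjusted_p=1.0, n=len(mirtrons), extra={"r_squared": 0.0},
        )
    X = sm.add_constant(pd.DataFrame({"overlap": x}))
    res = sm.OLS(y, X).fit()
    return IntegrativeResult(
        identifier="mirtron_overlap",
        statistic=float(res.params["overlap"]),
        raw_p=float(res.pvalues["overlap"]),
        adjusted_p=float(res.pvalues["overlap"]),
        n=len(mirtrons),
        extra={"r_squared": float(res.rsquared)},
    )


def consistently_expressed(mirna_expr: pd.DataFrame, min_fraction: float = 0.95) -> pd.Index:
    """miRNAs with non-missing expression in at least ``min_fraction`` of
    samples."""
    frac = mirna_expr.notna().mean(axis=1)
    return mirna_expr.index[frac >= min_fraction]


def most_variable(mirna_expr: pd.DataFrame, top: int = 20) -> pd.Index:
    """The ``top`` miRNAs by expression variance across samples."""
    return mirna_expr.var(axis=1, skipna=True).nlargest(top).index
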