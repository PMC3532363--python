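"""Narrow-sense heritability of RE-scores from parent-offspring trios.

Under the standard additive quantitative-genetics model the regression of an
offspring's trait value on the mid-parent value (the average of the two
parents) has slope equal to the narrow-sense heritability h² directly — no
factor-of-two correction, because averaging the parents already halves the
variance of the predictor. The fit is robust (M-estimation with Huber
weighting, tuning constant 1.345) so a few outlying cell lines do not drive
the estimate; population of origin enters as an indicator covariate to
absorb mean differences between cohorts.

The target-set permutation test asks whether the heritability of the mean
RE-score is a property of the *specific* predicted target sets rather than a
generic consequence of heritable gene expression: each distinct targeted
gene (among genes with expression data) is remapped to a random measured
gene by a single injective map shared across all sets, which preserves every
set's size and the full per-gene membership-count structure, then the
mean-RE heritability p-value is recomputed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import ExpressionMatrix, REScoreMatrix, TargetSet, TargetSetCollection, TrioTable
from .exceptions import ParameterError, SingularDesignError
from .rescore import DEFAULT_MIN_TARGETS, re_matrix

logger = logging.getLogger(__name__)

HUBER_T = 1.345


@dataclass
class HeritabilityResult:
    """Slope (h² estimate), its standard error and two-sided p for one trait."""

    mirna_id: str
    slope: float
    stderr: float
    p_value: float
    p_one_sided: float
    n_trios: int
    population_coefficients: dict

    def as_row(self) -> dict:
        return {
            "mirna": self.mirna_id,
            "slope": self.slope,
            "stderr": self.stderr,
            "p": self.p_value,
            "p_one_sided": self.p_one_sided,
            "n": self.n_trios,
        }


class MidparentRegression:
    """Offspring-on-mid-parent regression model for one quantitative trait.

    Parameters
    ----------
    child, father, mother
        Per-trio trait values, aligned.
    population
        Optional per-trio population labels, entered as indicator covariates.

    ``fit(method="huber")`` uses an M-estimator (HuberT, c=1.345);
    ``method="ols"`` is plain least squares. Either way the slope on the
    mid-parent value estimates h² and its p-value comes from the t
    distribution with n - k degrees of freedom.
    """

    def __init__(self, child, father, mother, population=None, name: str = "trait"):
        child = np.asarray(child, dtype=float)
        father = np.asarray(father, dtype=float)
        mother = np.asarray(mother, dtype=float)
        if not (len(child) == len(father) == len(mother)):
            raise ParameterError("child/father/mother must have equal length")
        if len(child) < 3:
            raise ParameterError("need at least 3 trios")
        self.name = name
        self.child = child
        self.midparent = (father + mother) / 2.0
        if np.ptp(self.midparent) == 0:
            raise SingularDesignError("mid-parent values are constant")
        self.population = None if population is None else pd.Series(list(population))
        X = pd.DataFrame({"midparent": self.midparent})
        if self.population is not None and self.population.nunique() > 1:
            dummies = pd.get_dummies(self.population, prefix="pop", drop_first=True, dtype=float)
            dummies.index = X.index
            X = pd.concat([X, dummies], axis=1)
        self.exog = sm.add_constant(X)

    def fit(self, method: str = "huber") -> HeritabilityResult:
        n, k = self.exog.shape
        if method == "huber":
            model = sm.RLM(self.child, self.exog, M=sm.robust.norms.HuberT(t=HUBER_T))
            res = model.fit()
        elif method == "ols":
            res = sm.OLS(self.child, self.exog).fit()
        else:
            raise ParameterError(f"unknown fit method {method!r}")
        slope = float(res.params["midparent"])
        se = float(res.bse["midparent"])
        if se == 0 or not np.isfinite(se):
            p_two = 0.0 if slope != 0 else 1.0
            p_one = p_two / 2.0 if slope > 0 else 1.0 - p_two / 2.0
        else:
            t = slope / se
            df = max(n - k, 1)
            p_two = float(2.0 * stats.t.sf(abs(t), df))
            p_one = float(stats.t.sf(t, df))  # upper tail: positive correlation
        pops = {
            c: float(res.params[c]) for c in self.exog.columns if c.startswith("pop_")
        }
        return HeritabilityResult(
            mirna_id=self.name,
            slope=slope,
            stderr=se,
            p_value=p_two,
            p_one_sided=p_one,
            n_trios=n,
            population_coefficients=pops,
        )


def midparent_regression(child, father, mother, population=None, method: str = "huber",
                         name: str = "trait") -> HeritabilityResult:
    """Convenience wrapper: build the model and fit in one call."""
    return MidparentRegression(child, father, mother, population, name=name).fit(method)


def _trio_phenotypes(values: pd.Series, trios: TrioTable):
    f = values.loc[trios.fathers.to_numpy()].to_numpy()
    m = values.loc[trios.mothers.to_numpy()].to_numpy()
    c = values.loc[trios.children.to_numpy()].to_numpy()
    return c, f, m


def per_mirna_heritability(
    re: REScoreMatrix,
    trios: TrioTable,
    meta: pd.DataFrame,
    method: str = "huber",
) -> pd.DataFrame:
    """Heritability of every miRNA's RE-score plus the mean RE-score.

    Returns a DataFrame with one row per miRNA and a final ``mean`` row, and
    attributes ``n_positive`` / ``n_positive_significant`` (slope > 0, and
    slope > 0 with two-sided p < 0.05) in ``DataFrame.attrs``.
    """
    missing = set(trios.all_samples()) - set(re.sample_ids)
    if missing:
        raise ParameterError(f"trio members absent from RE matrix: {sorted(missing)[:5]}")
    pop = meta.loc[trios.children.to_numpy(), "population"].to_numpy()
    rows = []
    for mirna in list(re.mirna_ids) + ["mean"]:
        values = re.mean_re if mirna == "mean" else re.re.loc[mirna]
        c, f, m = _trio_phenotypes(values, trios)
        try:
            res = midparent_regression(c, f, m, pop, method=method, name=mirna)
        except SingularDesignError:
            logger.warning("singular design for %s; skipped", mirna)
            continue
        rows.append(res.as_row())
    out = pd.DataFrame(rows).set_index("mirna")
    per = out.drop(index="mean", errors="ignore")
    out.attrs["n_positive"] = int((per["slope"] > 0).sum())
    out.attrs["n_positive_significant"] = int(((per["slope"] > 0) & (per["p"] < 0.05)).sum())
    return out


def permute_target_sets(
    targets: TargetSetCollection,
    expressed_genes,
    seed: int,
) -> TargetSetCollection:
    """Structure-preserving randomization of the target sets.

    Targets without expression data are dropped (they cannot affect
    RE-scores), then one random injective map from the distinct expressed
    targeted genes into the expressed genes is drawn and applied to every
    set. A gene targeted by several miRNAs is therefore replaced by the same
    random gene everywhere, preserving set sizes and the per-gene
    membership-count structure exactly.
    """
    expressed = pd.Index(expressed_genes)
    restricted = targets.restrict_to(expressed)
    distinct = sorted(restricted.gene_universe())
    if len(distinct) > len(expressed):
        raise ParameterError(
            f"{len(distinct)} targeted genes cannot map injectively into "
            f"{len(expressed)} expressed genes"
        )
    rng = np.random.default_rng(seed)
    image = rng.choice(len(expressed), size=len(distinct), replace=False)
    mapping = {g: expressed[i] for g, i in zip(distinct, image)}
    return TargetSetCollection(
        TargetSet(
            ts.mirna_id,
            frozenset(mapping[g] for g in ts.genes),
            ts.mirna_class,
            ts.provenance,
        )
        for ts in restricted
    )


@dataclass
class PermutationTestResult:
    observed_p: float
    n_permutations: int
    n_as_extreme: int
    permutation_p: float
    seed: int


def _mean_re_pvalue(expr: ExpressionMatrix, targets: TargetSetCollection,
                    trios: TrioTable, min_targets: int, method: str) -> float:
    scores = re_matrix(expr, targets, min_targets=min_targets)
    pop = expr.sample_meta.loc[trios.children.to_numpy(), "population"].to_numpy()
    c, f, m = _trio_phenotypes(scores.mean_re, trios)
    return midparent_regression(c, f, m, pop, method=method, name="mean").p_value


def target_permutation_test(
    expr: ExpressionMatrix,
    targets: TargetSetCollection,
    trios: TrioTable,
    n_perm: int,
    seed: int,
    min_targets: int = DEFAULT_MIN_TARGETS,
    method: str = "huber",
    add_one: bool = False,
) -> PermutationTestResult:
    """Permutation p-value for mean RE-score heritability.

    For each of ``n_perm`` structure-preserving target-set randomizations the
    mean-RE heritability regression p-value is recomputed; the permutation p
    is the proportion of randomizations at least as extreme (p ≤ observed).
    ``add_one=True`` switches to the (b+1)/(n+1) estimator, which is never
    exactly zero and is strictly valid.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    observed = _mean_re_pvalue(expr, targets, trios, min_targets, method)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_perm) % (2**31)
    n_extreme = 0
    for s in child_seeds:
        permuted = permute_target_sets(targets, expr.gene_ids, int(s))
        p = _mean_re_pvalue(expr, permuted, trios, min_targets, method)
        if p <= observed:
            n_extreme += 1
    if add_one:
        perm_p = (n_extreme + 1) / (n_perm + 1)
    else:
        perm_p = n_extreme / n_perm
    return PermutationTestResult(
        observed_p=observed,
        n_permutations=n_perm,
        n_as_extreme=n_extreme,
        permutation_p=perm_p,
        seed=seed,
    )
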