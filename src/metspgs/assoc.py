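"""Per-variant association testing under the additive genetic model.

Each variant is tested one at a time: the effect-allele dosage (0/1/2)
enters a logistic regression of case/control status (or an ordinary
least-squares regression of a quantitative trait) together with age and
sex as covariates.  Reported per variant: the per-allele log-odds beta,
its Wald standard error and z, the odds ratio with a 95% Wald CI
(exp(beta +/- 1.96 se)), a two-sided p-value, and — after a panel-level
pass — a Benjamini-Hochberg adjusted p and a Hardy-Weinberg exact-test
p in controls.

Protective orientations are normalised by :func:`flip_if_protective`:
when the fitted OR is below 1 the dosage is recoded g -> 2 - g (the
other allele becomes the effect allele) and the model is re-fit, so
every reported OR is on the risk-allele scale.

Model fitting is delegated to statsmodels (GLM / OLS, both IRLS-based
maximum likelihood for the logistic case); separation and
non-convergence are surfaced as flagged results, never as silent
numbers.  The Hardy-Weinberg exact test and the Benjamini-Hochberg
step-up (with an explicit panel size ``m_total``, so a printed subset of
a larger genotyped panel can be adjusted exactly) are implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .cohort import GenotypeDataset

__all__ = [
    "AssociationResult",
    "fit_logistic_additive",
    "fit_linear_additive",
    "flip_if_protective",
    "hwe_exact_test",
    "bh_adjust",
    "zscore_matrix",
    "association_scan",
]

_Z95 = 1.96
_SEPARATION_BETA = 15.0


@dataclass
class AssociationResult:
    """One additive-model fit for one variant.

    ``error`` is None for a clean fit, else one of ``"separation"``,
    ``"non_convergence"`` — a flagged result carries NaN statistics.
    For linear (quantitative-trait) fits ``beta`` is in trait units per
    effect allele and the OR fields are NaN.
    """

    variant_id: str
    effect_allele_used: str
    flipped: bool
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    n_used: int
    kind: str = "logistic"  # or "linear"
    phenotype: str | None = None
    p_fdr: float | None = None
    hwe_p: float | None = None
    error: str | None = None
    covariates: tuple[str, ...] = field(default=("age", "sex"))
    loglik: float = float("nan")

    @property
    def ok(self) -> bool:
        return self.error is None


def _design(dataset: GenotypeDataset, variant_id: str, covariates: Sequence[str]):
    """Design matrix [const, dosage, covariates...] after listwise deletion."""
    g = dataset.dosage(variant_id)
    cov_cols = []
    for c in covariates:
        if c == "age":
            cov_cols.append(dataset.age)
        elif c == "sex":
            cov_cols.append(dataset.sex.astype(float))
        elif dataset.phenotypes is not None and c in dataset.phenotypes.columns:
            cov_cols.append(dataset.phenotypes[c].to_numpy(dtype=float))
        else:
            raise KeyError(f"unknown covariate {c!r}")
    keep = ~np.isnan(g)
    for col in cov_cols:
        keep &= ~np.isnan(np.asarray(col, dtype=float))
    X = np.column_stack(
        [np.ones(keep.sum()), g[keep]] + [np.asarray(c, float)[keep] for c in cov_cols]
    )
    return X, keep


def _flagged(variant_id, allele, flipped, n_used, code, kind="logistic",
             phenotype=None, covariates=("age", "sex")) -> AssociationResult:
    nan = float("nan")
    return AssociationResult(
        variant_id=variant_id, effect_allele_used=allele, flipped=flipped,
        beta=nan, se=nan, or_=nan, ci_low=nan, ci_high=nan, z=nan, p=nan,
        n_used=n_used, kind=kind, phenotype=phenotype, error=code,
        covariates=tuple(covariates),
    )


def fit_logistic_additive(
    dataset: GenotypeDataset,
    variant_id: str,
    covariates: Sequence[str] = ("age", "sex"),
    _recode: bool = False,
) -> AssociationResult:
    """Additive-model logistic regression of case/control status.

    Maximum-likelihood fit (IRLS via statsmodels GLM, relative
    log-likelihood tolerance 1e-8, max 50 iterations).  Missing dosages
    are excluded listwise.  Raises on monomorphic dosage or a group with
    fewer than two samples; separation (|beta| > 15 on the dosage term)
    and non-convergence come back as flagged results.

    ``_recode`` fits on the complementary coding g -> 2 - g (used by
    :func:`flip_if_protective`).
    """
    spec = dataset.variant(variant_id) if dataset.variants else None
    X, keep = _design(dataset, variant_id, covariates)
    y = dataset.status[keep].astype(float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError(f"{variant_id}: fewer than 2 samples in a status group")
    if _recode:
        X[:, 1] = 2.0 - X[:, 1]
    if np.var(X[:, 1]) == 0.0:
        raise ValueError(f"{variant_id}: monomorphic dosage (zero variance)")

    if _recode and spec is not None:
        allele = spec.other_allele
    elif spec is not None:
        allele = spec.effect_allele
    else:
        allele = "?"
    n_used = int(keep.sum())

    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            model = sm.GLM(y, X, family=sm.families.Binomial())
            res = model.fit(maxiter=50, tol=1e-8)
        except PerfectSeparationWarning:
            return _flagged(variant_id, allele, _recode, n_used, "separation",
                            covariates=covariates)
        except Exception:
            return _flagged(variant_id, allele, _recode, n_used, "non_convergence",
                            covariates=covariates)
    if not getattr(res, "converged", True):
        return _flagged(variant_id, allele, _recode, n_used, "non_convergence",
                        covariates=covariates)
    beta = float(res.params[1])
    se = float(res.bse[1])
    if abs(beta) > _SEPARATION_BETA or not np.isfinite(se) or se == 0.0:
        return _flagged(variant_id, allele, _recode, n_used, "separation",
                        covariates=covariates)
    z = beta / se
    from scipy.stats import norm

    p = float(2.0 * norm.sf(abs(z)))
    return AssociationResult(
        variant_id=variant_id,
        effect_allele_used=allele,
        flipped=_recode,
        beta=beta,
        se=se,
        or_=math.exp(beta),
        ci_low=math.exp(beta - _Z95 * se),
        ci_high=math.exp(beta + _Z95 * se),
        z=z,
        p=p,
        n_used=n_used,
        covariates=tuple(covariates),
        loglik=float(res.llf),
    )


def flip_if_protective(
    result: AssociationResult, dataset: GenotypeDataset, variant_id: str
) -> AssociationResult:
    """Re-orient a protective fit onto the risk-allele scale.

    If the fitted OR is below 1 the model is re-fit with the dosage
    recoded g -> 2 - g (the alternative allele becomes the effect
    allele), giving the reciprocal OR with an identical p-value.
    Applying the flip twice returns the original orientation.
    """
    if result.error is not None or result.kind != "logistic":
        return result
    if result.or_ >= 1.0:
        return result
    return fit_logistic_additive(
        dataset, variant_id, covariates=result.covariates, _recode=not result.flipped
    )


def fit_linear_additive(
    dataset: GenotypeDataset,
    variant_id: str,
    phenotype_name: str,
    covariates: Sequence[str] = ("age", "sex"),
) -> AssociationResult:
    """Additive-model OLS of a quantitative trait on effect-allele dosage.

    beta is in trait units per allele; p is the two-sided t-test on the
    dosage coefficient.
    """
    if dataset.phenotypes is None or phenotype_name not in dataset.phenotypes.columns:
        raise KeyError(f"phenotype {phenotype_name!r} not present")
    yfull = dataset.phenotypes[phenotype_name].to_numpy(dtype=float)
    X, keep = _design(dataset, variant_id, covariates)
    ykeep = yfull[keep]
    miss = np.isnan(ykeep)
    if miss.any():
        X = X[~miss]
        ykeep = ykeep[~miss]
    if np.var(ykeep) == 0.0:
        raise ValueError(f"{phenotype_name}: constant phenotype")
    if np.var(X[:, 1]) == 0.0:
        raise ValueError(f"{variant_id}: monomorphic dosage (zero variance)")
    res = sm.OLS(ykeep, X).fit()
    beta = float(res.params[1])
    se = float(res.bse[1])
    spec = dataset.variant(variant_id) if dataset.variants else None
    nan = float("nan")
    return AssociationResult(
        variant_id=variant_id,
        effect_allele_used=spec.effect_allele if spec else "?",
        flipped=False,
        beta=beta,
        se=se,
        or_=nan,
        ci_low=nan,
        ci_high=nan,
        z=beta / se,
        p=float(res.pvalues[1]),
        n_used=int(len(ykeep)),
        kind="linear",
        phenotype=phenotype_name,
        covariates=tuple(covariates),
        loglik=float(res.llf),
    )


def hwe_exact_test(genotype_counts: tuple[int, int, int]) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    ``genotype_counts`` is (hom other-allele, het, hom effect-allele).
    Conditional on the allele totals, the heterozygote count under HWE
    follows a hypergeometric-type distribution

        P(h) = 2^h N! nA! nB! / (n_homA! h! n_homB! (2N)!)

    over heterozygote counts h of the same parity as the minor-allele
    total.  The two-sided p-value sums P(h) over all h whose probability
    does not exceed that of the observed count — the standard exact
    formulation used for genotyping QC.  Monomorphic counts give p = 1
    (single attainable configuration).
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0

    lg = math.lgamma

    def logp(h: int) -> float:
        hom_a = (n_a - h) // 2
        hom_b = (n_b - h) // 2
        return (
            h * math.log(2.0)
            + lg(n + 1) - lg(hom_a + 1) - lg(h + 1) - lg(hom_b + 1)
            + lg(n_a + 1) + lg(n_b + 1) - lg(2 * n + 1)
        )

    hs = range(rare % 2, rare + 1, 2)
    logs = {h: logp(h) for h in hs}
    lp_obs = logs[n_ab]
    # sum exact probabilities not exceeding the observed configuration's
    p = sum(math.exp(lp) for lp in logs.values() if lp <= lp_obs + 1e-12)
    return min(1.0, p)


def bh_adjust(
    p_values: Sequence[float], m_total: int | None = None
) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with an explicit panel size.

    ``adjusted_(i) = min(1, min_{j >= i} m_total * p_(j) / j)`` over the
    ascending order statistics; input order is restored on return.
    ``m_total`` defaults to the number of supplied p-values but may be
    larger: a subset of a bigger multiple-testing family (e.g. the
    significant rows of a genotyped panel) is then adjusted against the
    full family size, which is valid whenever the unsupplied p-values
    all rank above the largest supplied one.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m_total is None else int(m_total)
    if m < len(p):
        raise ValueError(f"m_total={m} smaller than number of p-values {len(p)}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def zscore_matrix(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Variants x phenotypes matrix of effect-allele-aligned Wald z-scores.

    z = beta / se with the sign of the fitted effect-allele coding;
    flagged (failed) fits appear as NaN-masked cells.  Suitable input
    for clustering or heatmap display.
    """
    cells: dict[tuple[str, str], float] = {}
    rows, cols = [], []
    for r in results:
        pheno = r.phenotype if r.phenotype is not None else "status"
        if r.variant_id not in rows:
            rows.append(r.variant_id)
        if pheno not in cols:
            cols.append(pheno)
        cells[(r.variant_id, pheno)] = r.z if r.ok else float("nan")
    mat = pd.DataFrame(index=rows, columns=cols, dtype=float)
    for (vid, pheno), z in cells.items():
        mat.loc[vid, pheno] = z
    return mat


def association_scan(
    dataset: GenotypeDataset,
    covariates: Sequence[str] = ("age", "sex"),
    m_total: int | None = None,
    flip: bool = True,
    hwe_group: str = "control",
) -> list[AssociationResult]:
    """Panel-level scan: fit every variant, flip to risk orientation,
    attach BH-adjusted p-values and control-group HWE exact-test p.

    Monomorphic variants come back flagged (error ``"monomorphic"``)
    rather than raising, so one bad locus does not abort a scan.
    """
    results: list[AssociationResult] = []
    for vid in dataset.variant_ids:
        try:
            r = fit_logistic_additive(dataset, vid, covariates=covariates)
        except ValueError:
            spec = dataset.variant(vid) if dataset.variants else None
            r = _flagged(vid, spec.effect_allele if spec else "?", False, 0,
                         "monomorphic", covariates=covariates)
        if flip and r.ok:
            r = flip_if_protective(r, dataset, vid)
        if vid in dataset.dosages.columns:
            counts = dataset.genotype_counts(vid, group=hwe_group)
            if sum(counts) > 0:
                r = replace(r, hwe_p=hwe_exact_test(counts))
        results.append(r)
    fitted = [r for r in results if r.ok]
    if fitted:
        adj = bh_adjust([r.p for r in fitted], m_total=m_total)
        adj_iter = iter(adj)
        results = [
            replace(r, p_fdr=float(next(adj_iter))) if r.ok else r for r in results
        ]
    return results
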