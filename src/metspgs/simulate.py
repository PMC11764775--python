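"""Synthetic case-control genotype simulation.

Two generative modes:

* :func:`simulate_retrospective` mirrors a case-control sampling design:
  genotypes are drawn per group under Hardy-Weinberg equilibrium at that
  group's effect-allele frequency, with fixed numbers of cases and
  controls.  This is the mode that reproduces a published frequency
  table.
* :func:`simulate_prospective` draws genotypes at population frequencies
  and then assigns disease status from an additive logistic liability
  ``logit P(case) = alpha + sum_i log(OR_i) g_i``, with the intercept
  solved numerically so the population prevalence matches the target.
  It is the generative counterpart of the additive association model and
  is used for parameter-recovery checks.

Utilities add linkage disequilibrium between a chosen pair of loci
(:func:`inject_ld`, Gaussian-copula construction) and quantitative
phenotypes with a known per-allele effect
(:func:`add_quantitative_phenotype`).

All randomness flows from a single seed through
``numpy.random.Generator``; fixed seed means byte-identical output.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import CohortConfig, GenotypeDataset, VariantSpec

__all__ = [
    "simulate_retrospective",
    "simulate_prospective",
    "inject_ld",
    "add_quantitative_phenotype",
    "make_null_variants",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_covariates(cohort: CohortConfig, n: int, rng: np.random.Generator):
    lo, hi = cohort.age_range
    a = (lo - cohort.age_mean) / cohort.age_sd
    b = (hi - cohort.age_mean) / cohort.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=cohort.age_mean, scale=cohort.age_sd, size=n, random_state=rng
    )
    sex = (rng.random(n) < cohort.sex_balance).astype(int)
    return age, sex


def _hwe_dosages(p: float, n: int, rng: np.random.Generator) -> np.ndarray:
    # two independent allele draws per individual = HWE genotype frequencies
    return rng.binomial(2, p, size=n).astype(float)


def _validate_variants(variants: Sequence[VariantSpec]) -> None:
    if not variants:
        raise ValueError("no variants supplied")
    seen = set()
    for v in variants:
        if v.variant_id in seen:
            raise ValueError(f"duplicate variant id {v.variant_id!r}")
        seen.add(v.variant_id)


def simulate_retrospective(
    variants: Sequence[VariantSpec],
    cohort: CohortConfig,
    seed: int | np.random.Generator | None = None,
    missing_rate: float = 0.0,
) -> GenotypeDataset:
    """Simulate a case-control cohort at fixed group sizes.

    Within each group every locus is drawn independently under HWE at
    that group's effect-allele frequency, so ``E[dosage] = 2 * EAF`` per
    group.  Age and sex are drawn independently of status.

    Parameters
    ----------
    variants :
        Loci with group-specific effect-allele frequencies.
    cohort :
        Group sizes and covariate distributions.
    seed :
        Seed or Generator; falls back to ``cohort.seed``.
    missing_rate :
        Optional uniform dosage missingness (default 0).
    """
    _validate_variants(variants)
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate outside [0, 1)")
    rng = _as_rng(cohort.seed if seed is None else seed)

    n_case, n_ctrl = cohort.n_case, cohort.n_control
    n = n_case + n_ctrl
    status = np.concatenate([np.ones(n_case, int), np.zeros(n_ctrl, int)])

    cols = {}
    for v in variants:
        g_case = _hwe_dosages(v.eaf_case, n_case, rng)
        g_ctrl = _hwe_dosages(v.eaf_control, n_ctrl, rng)
        cols[v.variant_id] = np.concatenate([g_case, g_ctrl])
    dosages = pd.DataFrame(cols, index=[f"S{i + 1:04d}" for i in range(n)])

    if missing_rate > 0.0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages = dosages.mask(mask)

    age, sex = _draw_covariates(cohort, n, rng)
    return GenotypeDataset(
        dosages=dosages, status=status, age=age, sex=sex, variants=list(variants)
    )


def solve_intercept(
    log_or: np.ndarray, dosages: np.ndarray, prevalence: float
) -> float:
    """Intercept of the additive logistic liability hitting a target prevalence.

    Solves ``mean(expit(alpha + G @ beta)) = prevalence`` over the supplied
    population genotypes by bracketed root finding.
    """
    eta = dosages @ log_or

    def gap(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + eta))))) - prevalence

    lo, hi = -50.0, 50.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(f"prevalence {prevalence} unattainable")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def simulate_prospective(
    variants: Sequence[VariantSpec],
    cohort: CohortConfig,
    odds_ratios: Mapping[str, float],
    seed: int | np.random.Generator | None = None,
    pool_factor: int = 20,
) -> GenotypeDataset:
    """Simulate under the generative additive logistic model, then sub-sample.

    Genotypes are drawn at the population (control) effect-allele
    frequency; status follows ``logit P(case) = alpha + sum log(OR_i) g_i``
    with ``alpha`` solved so the population case fraction equals
    ``cohort.prevalence``.  The population (size ``pool_factor * n_total``)
    is then sub-sampled to the requested numbers of cases and controls.

    Raises if any OR is non-positive, the prevalence is unattainable, or
    the pool yields too few members of either group.
    """
    _validate_variants(variants)
    for vid, orv in odds_ratios.items():
        if orv <= 0:
            raise ValueError(f"odds ratio for {vid} must be > 0, got {orv}")
    rng = _as_rng(cohort.seed if seed is None else seed)

    n_pool = pool_factor * cohort.n_total
    pop = np.column_stack(
        [_hwe_dosages(v.eaf_control, n_pool, rng) for v in variants]
    )
    log_or = np.array([np.log(odds_ratios.get(v.variant_id, 1.0)) for v in variants])
    alpha = solve_intercept(log_or, pop, cohort.prevalence)
    p_case = 1.0 / (1.0 + np.exp(-(alpha + pop @ log_or)))
    status_pool = (rng.random(n_pool) < p_case).astype(int)

    case_idx = np.flatnonzero(status_pool == 1)
    ctrl_idx = np.flatnonzero(status_pool == 0)
    if len(case_idx) < cohort.n_case or len(ctrl_idx) < cohort.n_control:
        raise ValueError(
            "population pool too small for requested group sizes; "
            "increase pool_factor"
        )
    take = np.concatenate(
        [
            rng.choice(case_idx, size=cohort.n_case, replace=False),
            rng.choice(ctrl_idx, size=cohort.n_control, replace=False),
        ]
    )
    dosages = pd.DataFrame(
        pop[take],
        columns=[v.variant_id for v in variants],
        index=[f"S{i + 1:04d}" for i in range(len(take))],
    )
    age, sex = _draw_covariates(cohort, len(take), rng)
    return GenotypeDataset(
        dosages=dosages,
        status=status_pool[take],
        age=age,
        sex=sex,
        variants=list(variants),
    )


def _copula_rho(p_a: float, p_b: float, target_r: float) -> float:
    """Latent-normal correlation giving allele-level correlation target_r.

    For alleles thresholded from a bivariate normal, the Pearson
    correlation is (P11 - pa*pb) / sqrt(pa qa pb qb) with
    P11 = BVN(qa_z, qb_z; rho).  Monotone in rho, so solve by bisection.
    """
    qa = stats.norm.ppf(p_a)
    qb = stats.norm.ppf(p_b)

    def corr(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [qa, qb], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        denom = np.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b))
        return (p11 - p_a * p_b) / denom

    hi = 0.999999
    max_r = corr(hi)
    if target_r >= max_r:
        warnings.warn(
            f"target allele correlation {target_r:.3f} exceeds the maximum "
            f"{max_r:.3f} attainable at frequencies {p_a:.2f}/{p_b:.2f}; "
            "using maximal coupling",
            stacklevel=3,
        )
        return hi
    if target_r <= 0:
        return 0.0
    return float(optimize.brentq(lambda r: corr(r) - target_r, 0.0, hi, xtol=1e-8))


def inject_ld(
    dataset: GenotypeDataset,
    variant_a: str,
    variant_b: str,
    r2: float,
    seed: int | np.random.Generator | None = None,
) -> GenotypeDataset:
    """Regenerate one variant's dosages in LD with another.

    The dosages of ``variant_b`` are redrawn so that the squared Pearson
    correlation with ``variant_a`` approximates ``r2``, preserving
    ``variant_b``'s per-group allele frequency.  Construction: each of
    the two allele draws of B is thresholded from a latent normal
    correlated (Gaussian copula) with a latent consistent with the
    corresponding observed allele of A.

    ``r2 = 1`` duplicates the column exactly; ``r2 = 0`` is an
    independent redraw.  If the requested correlation is not attainable
    at the fixed allele frequencies a warning is emitted and the maximal
    coupling is used (best effort).
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 outside [0, 1]")
    for vid in (variant_a, variant_b):
        if vid not in dataset.dosages.columns:
            raise KeyError(vid)
    rng = _as_rng(seed)

    dosages = dataset.dosages.copy()
    if r2 == 1.0:
        dosages[variant_b] = dosages[variant_a]
        return dataset.with_dosages(dosages)

    spec_b = dataset.variant(variant_b) if dataset.variants else None
    g_a = dataset.dosage(variant_a)
    new_b = np.full(len(g_a), np.nan)
    target_r = float(np.sqrt(r2))

    for is_case in (True, False):
        grp = dataset.is_case == is_case
        grp &= ~np.isnan(g_a)
        if not grp.any():
            continue
        ga = g_a[grp]
        if spec_b is not None:
            p_b = spec_b.eaf_case if is_case else spec_b.eaf_control
        else:
            p_b = float(np.nanmean(dataset.dosage(variant_b)[grp]) / 2.0)
        p_a = float(np.mean(ga) / 2.0)
        if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
            new_b[grp] = rng.binomial(2, p_b, size=grp.sum()).astype(float)
            continue
        rho = _copula_rho(p_a, p_b, target_r) if target_r > 0 else 0.0
        qa = stats.norm.ppf(p_a)
        qb = stats.norm.ppf(p_b)
        gb = np.zeros(grp.sum())
        het = ga == 1
        # split each dosage into two exchangeable allele indicators; a het
        # carries one effect allele on a randomly chosen chromosome copy
        coin = rng.random(len(ga)) < 0.5
        for copy in range(2):
            a_allele = np.where(ga == 2, 1, 0).astype(float)
            a_allele[het] = (coin[het] == (copy == 0)).astype(float)
            # latent for A conditional on observed allele (truncated normal)
            u = rng.random(len(ga))
            cdf_q = stats.norm.cdf(qa)
            z_a = np.where(
                a_allele == 1,
                stats.norm.ppf(u * cdf_q),
                stats.norm.ppf(cdf_q + u * (1 - cdf_q)),
            )
            z_b = rho * z_a + np.sqrt(1 - rho**2) * rng.standard_normal(len(ga))
            gb += (z_b < qb).astype(float)
        new_b[grp] = gb

    # samples with missing A keep an independent draw
    miss = np.isnan(new_b)
    if miss.any():
        p_fill = (
            float(np.nanmean(dataset.dosage(variant_b)) / 2.0)
            if spec_b is None
            else spec_b.eaf_control
        )
        new_b[miss] = rng.binomial(2, p_fill, size=miss.sum()).astype(float)

    dosages[variant_b] = new_b
    return dataset.with_dosages(dosages)


def add_quantitative_phenotype(
    dataset: GenotypeDataset,
    name: str,
    variant_id: str,
    beta_per_allele: float,
    noise_sd: float,
    intercept: float = 0.0,
    beta_age: float = 0.0,
    beta_sex: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> GenotypeDataset:
    """Attach a quantitative trait with a known additive genetic effect.

    trait = intercept + beta_per_allele * g + beta_age * age
    + beta_sex * sex + Normal(0, noise_sd) noise.  Missing dosages
    propagate to missing trait values.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    g = dataset.dosage(variant_id)
    rng = _as_rng(seed)
    trait = (
        intercept
        + beta_per_allele * g
        + beta_age * dataset.age
        + beta_sex * dataset.sex
        + rng.normal(0.0, noise_sd, size=len(g))
    )
    pheno = (
        dataset.phenotypes.copy()
        if dataset.phenotypes is not None
        else pd.DataFrame(index=dataset.dosages.index)
    )
    pheno[name] = trait
    out = dataset.with_dosages(dataset.dosages.copy())
    out.phenotypes = pheno
    return out


def make_null_variants(
    n: int,
    seed: int | np.random.Generator | None = None,
    eaf_range: tuple[float, float] = (0.1, 0.5),
    prefix: str = "rsNULL",
) -> list[VariantSpec]:
    """Null panel-padding loci: equal frequencies in cases and controls.

    Frequencies are drawn uniformly on ``eaf_range``; used to emulate
    extending an associated-locus panel to its full genotyped size.
    """
    rng = _as_rng(seed)
    eafs = rng.uniform(*eaf_range, size=n)
    return [
        VariantSpec(
            variant_id=f"{prefix}{i + 1:03d}",
            gene="",
            chromosome=f"null{i + 1}",
            effect_allele="A",
            other_allele="G",
            eaf_control=float(p),
            eaf_case=float(p),
            is_null=True,
        )
        for i, p in enumerate(eafs)
    ]
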