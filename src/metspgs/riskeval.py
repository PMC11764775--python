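"""Risk-model discrimination and reclassification analysis.

Nested logistic risk models (covariates only; polygenic score only;
score + covariates) are compared two ways:

* discrimination — ROC analysis; the AUC is computed as the normalised
  Mann-Whitney statistic with midrank tie handling, and its 95% CI from
  the DeLong structural-components variance estimator;
* reclassification — category-free (continuous) net reclassification
  improvement: the net proportion of cases whose predicted risk rises
  plus the net proportion of controls whose predicted risk falls when
  moving from the reference model to the new one.  It depends only on
  the sign of the prediction change, so any monotone rescaling of both
  models' predictions leaves it unchanged.  Standard errors and 95%
  percentile CIs come from a bootstrap stratified by case/control
  status; the p-value uses the normal approximation z = NRI / SE.

Evaluation is in-sample (models fitted and assessed on the same cohort)
by default, mirroring single-cohort prognostic studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

from .cohort import GenotypeDataset
from .score import ScoreSet

__all__ = [
    "RiskModel",
    "RocResult",
    "NriResult",
    "fit_risk_model",
    "roc_auc",
    "continuous_nri",
    "evaluate_model_suite",
]


@dataclass
class RiskModel:
    """Fitted logistic risk model with in-sample predicted probabilities."""

    predictors: tuple[str, ...]
    coefficients: np.ndarray  # intercept first
    probabilities: np.ndarray
    converged: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if ((p <= 0) | (p >= 1)).any():
            raise ValueError("predicted probabilities must lie strictly in (0, 1)")
        if len(self.coefficients) != len(self.predictors) + 1:
            raise ValueError("coefficient count must equal predictors + intercept")


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    curve: np.ndarray = field(repr=False)  # columns: 1-specificity, sensitivity

    @property
    def auc_pct(self) -> float:
        return 100.0 * self.auc


@dataclass
class NriResult:
    """Category-free NRI decomposition: total = event + non-event (exact)."""

    nri_total: float
    nri_event: float
    nri_nonevent: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_bootstrap: int = 0

    def __post_init__(self) -> None:
        assert abs(self.nri_total - (self.nri_event + self.nri_nonevent)) < 1e-12


def _predictor_columns(
    dataset: GenotypeDataset, scores: ScoreSet | None, predictors: Sequence[str]
) -> np.ndarray:
    cols = []
    for name in predictors:
        if name == "age":
            cols.append(dataset.age)
        elif name == "sex":
            cols.append(dataset.sex.astype(float))
        elif scores is not None and name in scores.table.columns:
            cols.append(scores.table[name].to_numpy(dtype=float))
        elif dataset.phenotypes is not None and name in dataset.phenotypes.columns:
            cols.append(dataset.phenotypes[name].to_numpy(dtype=float))
        else:
            raise KeyError(f"unknown predictor {name!r}")
    n = dataset.n_samples
    if not cols:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n)] + [np.asarray(c, float) for c in cols])


def fit_risk_model(
    dataset: GenotypeDataset,
    scores: ScoreSet | None,
    predictors: Sequence[str],
    name: str = "",
) -> RiskModel:
    """Logistic regression of status on the named predictors.

    Predictors may be score columns (``weighted_score``,
    ``unweighted_score``), covariates (``age``, ``sex``) or phenotype
    columns.  An empty predictor list fits the intercept-only model
    (every prediction equals the case fraction).  Predictions are
    in-sample.  Separation or non-convergence is flagged, never silent.
    """
    X = _predictor_columns(dataset, scores, predictors)
    if np.isnan(X).any():
        raise ValueError("predictors contain missing values; complete them first")
    y = dataset.status.astype(float)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
    beta = np.asarray(res.params, dtype=float)
    converged = bool(getattr(res, "converged", True)) and bool(
        np.all(np.abs(beta[1:]) < 50)
    )
    if not converged:
        raise RuntimeError(f"risk model {name or predictors} failed to converge")
    eta = X @ beta
    prob = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    prob = np.clip(prob, eps, 1 - eps)
    return RiskModel(
        predictors=tuple(predictors),
        coefficients=beta,
        probabilities=prob,
        converged=converged,
        name=name or "+".join(predictors) or "intercept",
    )


def _auc_delong(case_scores: np.ndarray, ctrl_scores: np.ndarray):
    """Midrank AUC and DeLong variance via structural components."""
    m, n = len(case_scores), len(ctrl_scores)
    allv = np.concatenate([case_scores, ctrl_scores])
    ranks = stats.rankdata(allv, method="average")
    r_case = stats.rankdata(case_scores, method="average")
    r_ctrl = stats.rankdata(ctrl_scores, method="average")
    # placement values: fraction of the other group below each observation
    v10 = (ranks[:m] - r_case) / n          # per case
    v01 = 1.0 - (ranks[m:] - r_ctrl) / m    # per control
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    return auc, var


def roc_auc(predictions: np.ndarray, status: np.ndarray) -> RocResult:
    """ROC curve and AUC with a DeLong 95% confidence interval.

    The AUC is the probability that a random case outscores a random
    control, computed from midranks (ties count one half).  The CI is
    auc +/- 1.96 * sqrt(DeLong variance), clipped to [0, 1].
    """
    pred = np.asarray(predictions, dtype=float)
    status = np.asarray(status)
    if (status == 1).sum() == 0 or (status == 0).sum() == 0:
        raise ValueError("both classes must be present")
    case = pred[status == 1]
    ctrl = pred[status == 0]
    auc, var = _auc_delong(case, ctrl)
    se = float(np.sqrt(var))
    fpr, tpr, _ = roc_curve(status, pred)
    return RocResult(
        auc=auc,
        ci_low=max(0.0, auc - 1.96 * se),
        ci_high=min(1.0, auc + 1.96 * se),
        se=se,
        curve=np.column_stack([fpr, tpr]),
    )


def _nri_components(p_ref, p_new, is_case):
    up = p_new > p_ref
    down = p_new < p_ref
    n_case = int(is_case.sum())
    n_ctrl = int((~is_case).sum())
    event = (int(up[is_case].sum()) - int(down[is_case].sum())) / n_case
    nonevent = (int(down[~is_case].sum()) - int(up[~is_case].sum())) / n_ctrl
    return event, nonevent


def continuous_nri(
    ref_model: RiskModel | np.ndarray,
    new_model: RiskModel | np.ndarray,
    status: np.ndarray,
    bootstrap_b: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> NriResult:
    """Category-free net reclassification improvement with bootstrap CI.

    event NRI     = (#cases up   - #cases down)   / n_cases
    non-event NRI = (#controls down - #controls up) / n_controls
    total         = event + non-event

    where up/down is the sign of (new - reference) predicted risk; ties
    contribute zero.  SE is the standard deviation of the statistic over
    ``bootstrap_b`` stratified resamples (cases and controls resampled
    separately), the CI is the 2.5/97.5 percentile interval, and the
    p-value uses z = total / SE.  Identical predictions give total 0
    with p = 1.
    """
    p_ref = ref_model.probabilities if isinstance(ref_model, RiskModel) else np.asarray(ref_model, float)
    p_new = new_model.probabilities if isinstance(new_model, RiskModel) else np.asarray(new_model, float)
    status = np.asarray(status)
    if len(p_ref) != len(p_new) or len(p_ref) != len(status):
        raise ValueError("both models must predict on identical samples")
    if bootstrap_b < 100:
        warnings.warn(
            f"bootstrap_b={bootstrap_b} < 100 gives unstable standard errors",
            stacklevel=2,
        )
    is_case = status == 1
    if is_case.sum() == 0 or (~is_case).sum() == 0:
        raise ValueError("both status groups must be present")
    event, nonevent = _nri_components(p_ref, p_new, is_case)
    total = event + nonevent

    if np.array_equal(p_ref, p_new):
        return NriResult(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    case_idx = np.flatnonzero(is_case)
    ctrl_idx = np.flatnonzero(~is_case)
    totals = np.empty(bootstrap_b)
    for b in range(bootstrap_b):
        ci = rng.choice(case_idx, size=len(case_idx), replace=True)
        ki = rng.choice(ctrl_idx, size=len(ctrl_idx), replace=True)
        idx = np.concatenate([ci, ki])
        e, ne = _nri_components(
            p_ref[idx], p_new[idx], np.concatenate([np.ones(len(ci), bool), np.zeros(len(ki), bool)])
        )
        totals[b] = e + ne
    se = float(totals.std(ddof=1))
    lo, hi = np.percentile(totals, [2.5, 97.5])
    p = 1.0 if se == 0.0 else float(2.0 * stats.norm.sf(abs(total) / se))
    return NriResult(
        nri_total=total,
        nri_event=event,
        nri_nonevent=nonevent,
        se=se,
        ci_low=float(lo),
        ci_high=float(hi),
        p=p,
        n_bootstrap=bootstrap_b,
    )


def evaluate_model_suite(
    dataset: GenotypeDataset,
    scores: ScoreSet,
    scores_full: ScoreSet | None = None,
    bootstrap_b: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Fit the standard nested models and compare them.

    ROC models (in-sample AUC with DeLong CI):

    * ``unweighted`` — unweighted score only
    * ``weighted`` — weighted score only
    * ``unweighted+age+sex`` / ``weighted+age+sex``
    * ``age+sex`` — the non-genetic reference

    NRI comparisons (continuous NRI, stratified bootstrap):

    * ``pgs_vs_covariates`` — (weighted score + age + sex) vs (age + sex)
    * ``full_vs_subset`` — if ``scores_full`` is given (a score over the
      complete genotyped panel), (full score + age + sex) vs
      (subset score + age + sex)

    Returns a JSON-serialisable report dict.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    status = dataset.status

    specs = {
        "unweighted": ["unweighted_score"],
        "weighted": ["weighted_score"],
        "unweighted+age+sex": ["unweighted_score", "age", "sex"],
        "weighted+age+sex": ["weighted_score", "age", "sex"],
        "age+sex": ["age", "sex"],
    }
    models = {
        name: fit_risk_model(dataset, scores, preds, name=name)
        for name, preds in specs.items()
    }
    report: dict = {"models": {}, "comparisons": {}}
    for name, model in models.items():
        roc = roc_auc(model.probabilities, status)
        report["models"][name] = {
            "auc_pct": roc.auc_pct,
            "ci_low_pct": 100 * roc.ci_low,
            "ci_high_pct": 100 * roc.ci_high,
            "predictors": list(model.predictors),
        }

    nri = continuous_nri(
        models["age+sex"], models["weighted+age+sex"], status,
        bootstrap_b=bootstrap_b, seed=rng,
    )
    report["comparisons"]["pgs_vs_covariates"] = _nri_dict(nri)

    if scores_full is not None:
        full_model = fit_risk_model(
            dataset, scores_full, ["weighted_score", "age", "sex"],
            name="full-panel weighted+age+sex",
        )
        nri_full = continuous_nri(
            models["weighted+age+sex"], full_model, status,
            bootstrap_b=bootstrap_b, seed=rng,
        )
        roc_full = roc_auc(full_model.probabilities, status)
        report["models"]["full_weighted+age+sex"] = {
            "auc_pct": roc_full.auc_pct,
            "ci_low_pct": 100 * roc_full.ci_low,
            "ci_high_pct": 100 * roc_full.ci_high,
            "predictors": list(full_model.predictors),
        }
        report["comparisons"]["full_vs_subset"] = _nri_dict(nri_full)
    return report


def _nri_dict(nri: NriResult) -> dict:
    return {
        "total": nri.nri_total,
        "event": nri.nri_event,
        "nonevent": nri.nri_nonevent,
        "se": nri.se,
        "ci_low": nri.ci_low,
        "ci_high": nri.ci_high,
        "p": nri.p,
    }
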