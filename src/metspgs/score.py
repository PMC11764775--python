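"""Polygenic score construction from association results.

A weight table maps each risk allele to a weight — by default the
age/sex-adjusted odds ratio itself (log-OR weighting is available as the
conventional alternative).  Per-sample scores are then

    weighted score   = sum_i  w_i * g_i
    unweighted score = sum_i  g_i        (risk-allele count)

over the loci retained after exclusions.  Same-chromosome variants in
linkage disequilibrium contribute redundant information, so
:func:`ld_prune` drops the weaker-association member of any pair whose
empirical dosage r-squared reaches the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AssociationResult
from .cohort import GenotypeDataset

__all__ = [
    "WeightTable",
    "ScoreSet",
    "build_weight_table",
    "ld_prune",
    "compute_scores",
    "score_group_summary",
]


@dataclass
class WeightTable:
    """Per-variant risk-allele weights with exclusion bookkeeping.

    ``table`` columns: variant_id, risk_allele, weight, included,
    exclusion_reason (one of ld_pruned / monomorphic / failed_fit /
    none).  ``mode`` records whether weights are raw ORs (>= 1 after
    risk-allele flipping) or log-ORs.
    """

    table: pd.DataFrame
    mode: str = "or"

    def __post_init__(self) -> None:
        required = {"variant_id", "risk_allele", "weight", "included", "exclusion_reason"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"weight table missing columns {sorted(missing)}")
        inc = self.table[self.table["included"]]
        if self.mode == "or" and (inc["weight"] < 1.0 - 1e-12).any():
            raise ValueError("OR-mode weights must be >= 1 after flipping")
        if (inc["weight"] <= 0).any() and self.mode == "or":
            raise ValueError("included weights must be positive")

    @property
    def included(self) -> pd.DataFrame:
        return self.table[self.table["included"]]

    @property
    def n_included(self) -> int:
        return int(self.table["included"].sum())

    def scaled(self, factor: float) -> "WeightTable":
        t = self.table.copy()
        t["weight"] = t["weight"] * factor
        return WeightTable(table=t, mode="custom")


@dataclass
class ScoreSet:
    """Per-sample weighted and unweighted polygenic scores."""

    table: pd.DataFrame  # sample_id index; weighted_score, unweighted_score, n_loci_used
    weights: WeightTable | None = None

    @property
    def weighted(self) -> np.ndarray:
        return self.table["weighted_score"].to_numpy(dtype=float)

    @property
    def unweighted(self) -> np.ndarray:
        return self.table["unweighted_score"].to_numpy(dtype=float)


def build_weight_table(
    results: Sequence[AssociationResult],
    mode: str = "or",
    excluded: Mapping[str, str] | None = None,
) -> WeightTable:
    """Turn risk-oriented association results into score weights.

    Results must already be flipped to the risk-allele orientation
    (OR >= 1); raw ORs are the default weights, ``mode="log_or"`` takes
    the natural log.  Failed fits are carried as excluded rows with
    reason ``failed_fit``; additional exclusions (e.g. from LD pruning)
    can be injected via ``excluded`` {variant_id: reason}.
    """
    if not results:
        raise ValueError("no association results supplied")
    if mode not in ("or", "log_or"):
        raise ValueError(f"unknown weight mode {mode!r}")
    excluded = dict(excluded or {})
    rows = []
    for r in results:
        reason = "none"
        included = True
        if not r.ok:
            included = False
            reason = "monomorphic" if r.error == "monomorphic" else "failed_fit"
            weight = float("nan")
        else:
            weight = r.or_ if mode == "or" else float(np.log(r.or_))
        if r.variant_id in excluded:
            included = False
            reason = excluded[r.variant_id]
        rows.append(
            dict(
                variant_id=r.variant_id,
                risk_allele=r.effect_allele_used,
                weight=weight,
                included=included,
                exclusion_reason=reason,
            )
        )
    return WeightTable(table=pd.DataFrame(rows), mode=mode)


def pairwise_r2(dataset: GenotypeDataset, a: str, b: str) -> float:
    """Empirical squared Pearson correlation between two dosage columns."""
    ga, gb = dataset.dosage(a), dataset.dosage(b)
    keep = ~(np.isnan(ga) | np.isnan(gb))
    ga, gb = ga[keep], gb[keep]
    if np.var(ga) == 0 or np.var(gb) == 0:
        return 0.0
    return float(np.corrcoef(ga, gb)[0, 1] ** 2)


def ld_prune(
    dataset: GenotypeDataset,
    candidate_ids: Sequence[str],
    r2_threshold: float = 0.5,
    p_values: Mapping[str, float] | None = None,
) -> tuple[list[str], list[str]]:
    """Greedy LD pruning of same-chromosome variant pairs.

    Candidates are visited in ascending association p-value (ties broken
    by variant id; missing p-values sort last).  A candidate is dropped
    when its dosage r-squared with an already-kept variant on the same
    chromosome reaches ``r2_threshold``, so of any correlated pair the
    variant with the larger p is the one removed.  Deterministic.

    Returns (kept_ids, dropped_ids).
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")
    p_values = dict(p_values or {})
    chrom = {v.variant_id: v.chromosome for v in dataset.variants}

    def sort_key(vid: str):
        p = p_values.get(vid)
        return (p is None, p if p is not None else 0.0, vid)

    ordered = sorted(candidate_ids, key=sort_key)
    kept: list[str] = []
    dropped: list[str] = []
    for vid in ordered:
        clash = any(
            chrom.get(vid, "?a") == chrom.get(k, "?b")
            and pairwise_r2(dataset, vid, k) >= r2_threshold
            for k in kept
        )
        (dropped if clash else kept).append(vid)
    return kept, dropped


def compute_scores(
    dataset: GenotypeDataset,
    weights: WeightTable,
    missing: str = "impute",
) -> ScoreSet:
    """Per-sample weighted and unweighted scores over the included loci.

    Missing dosages are handled per ``missing``:

    * ``"impute"`` (default): replace with the expected dosage
      2 * overall empirical risk-allele frequency, so every sample gets
      a complete score (reclassification analysis needs complete
      predictions);
    * ``"rescale"``: drop the locus for that sample and rescale both
      sums by n_included / n_observed; a sample with no observed locus
      gets NaN scores.

    ``n_loci_used`` counts the sample's observed (non-imputed) loci;
    zero flags a sample missing every locus.
    """
    inc = weights.included
    if inc.empty:
        raise ValueError("weight table has no included loci")
    if missing not in ("impute", "rescale"):
        raise ValueError(f"unknown missing-dosage policy {missing!r}")
    ids = list(inc["variant_id"])
    unknown = [v for v in ids if v not in dataset.dosages.columns]
    if unknown:
        raise KeyError(f"weights reference absent variants: {unknown}")
    G = dataset.dosages[ids].to_numpy(dtype=float)
    w = inc["weight"].to_numpy(dtype=float)
    obs = ~np.isnan(G)
    n_obs = obs.sum(axis=1)

    if missing == "impute":
        eaf = np.nanmean(G, axis=0) / 2.0  # overall (group-free) risk-allele freq
        Gf = np.where(obs, G, 2.0 * eaf[None, :])
        weighted = Gf @ w
        unweighted = Gf.sum(axis=1)
    else:
        G0 = np.where(obs, G, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = len(ids) / n_obs
            weighted = (G0 @ w) * scale
            unweighted = G0.sum(axis=1) * scale
        none_obs = n_obs == 0
        weighted = np.where(none_obs, np.nan, weighted)
        unweighted = np.where(none_obs, np.nan, unweighted)
    n_used = n_obs
    table = pd.DataFrame(
        {
            "weighted_score": weighted,
            "unweighted_score": unweighted,
            "n_loci_used": np.asarray(n_used, dtype=int),
        },
        index=dataset.dosages.index,
    )
    return ScoreSet(table=table, weights=weights)


def score_group_summary(scores: ScoreSet, status: np.ndarray) -> pd.DataFrame:
    """Group means +/- SE and a Welch two-sample t-test per score type.

    Returns one row per score column with case/control mean, SE, the
    mean difference and the two-sided Welch p-value.
    """
    status = np.asarray(status)
    if (status == 1).sum() == 0 or (status == 0).sum() == 0:
        raise ValueError("both status groups must be non-empty")
    rows = []
    for col in ("weighted_score", "unweighted_score"):
        x = scores.table[col].to_numpy(dtype=float)
        case, ctrl = x[status == 1], x[status == 0]
        case, ctrl = case[~np.isnan(case)], ctrl[~np.isnan(ctrl)]
        if np.var(case) == 0 and np.var(ctrl) == 0:
            raise ValueError(f"{col}: degenerate (zero) variance in both groups")
        t, p = stats.ttest_ind(case, ctrl, equal_var=False)
        rows.append(
            dict(
                score=col,
                case_mean=case.mean(),
                case_se=case.std(ddof=1) / np.sqrt(len(case)),
                control_mean=ctrl.mean(),
                control_se=ctrl.std(ddof=1) / np.sqrt(len(ctrl)),
                difference=case.mean() - ctrl.mean(),
                t=float(t),
                p=float(p),
            )
        )
    return pd.DataFrame(rows).set_index("score")
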