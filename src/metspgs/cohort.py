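"""Domain containers: variant metadata, cohort configuration, genotype datasets.

The central object is :class:`GenotypeDataset`, a thin wrapper around a
pandas dosage matrix (samples x variants, effect-allele counts 0/1/2 with
NaN for missing calls) plus per-sample case/control status, age, sex and
optional quantitative phenotypes.  Variant metadata travels with the
dataset so downstream stages (LD pruning needs chromosome labels, score
construction needs risk alleles) never have to re-join it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["VariantSpec", "CohortConfig", "GenotypeDataset"]

_VALID_ALLELES = set("ACGT")


@dataclass(frozen=True)
class VariantSpec:
    """Per-locus metadata with group-specific effect-allele frequencies.

    The effect allele (EA) is the allele whose dosage 0/1/2 enters the
    additive model; it need not be the minor allele.  Frequencies are
    stored on the effect-allele scale.  Published panels usually report
    minor-allele frequencies (MAF) instead; use :meth:`from_maf` to
    convert (EAF = MAF when the effect allele *is* the minor allele,
    else EAF = 1 - MAF).

    Parameters
    ----------
    variant_id : str
        rsID or any unique label.
    gene : str
        Gene symbol, informational only.
    chromosome : str
        Chromosome label; only equality matters (LD pruning applies to
        same-chromosome pairs).
    effect_allele, other_allele : str
        Single-character alleles, must differ.
    eaf_control, eaf_case : float
        Effect-allele frequency in controls and cases, in [0, 1].
    is_null : bool
        True for loci constructed with equal frequencies in both groups
        (panel padding with no association signal).
    """

    variant_id: str
    gene: str
    chromosome: str
    effect_allele: str
    other_allele: str
    eaf_control: float
    eaf_case: float
    is_null: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.eaf_control <= 1.0:
            raise ValueError(
                f"{self.variant_id}: eaf_control={self.eaf_control} outside [0, 1]"
            )
        if not 0.0 <= self.eaf_case <= 1.0:
            raise ValueError(
                f"{self.variant_id}: eaf_case={self.eaf_case} outside [0, 1]"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"{self.variant_id}: effect allele equals other allele "
                f"({self.effect_allele})"
            )
        if self.is_null and self.eaf_case != self.eaf_control:
            raise ValueError(
                f"{self.variant_id}: null locus requires equal group frequencies"
            )

    @classmethod
    def from_maf(
        cls,
        variant_id: str,
        effect_allele: str,
        minor_allele: str,
        maf_control: float,
        maf_case: float,
        gene: str = "",
        chromosome: str = "",
    ) -> "VariantSpec":
        """Build a spec from minor-allele frequencies.

        When the effect allele coincides with the minor allele the EAF is
        the MAF itself, otherwise it is the complementary frequency.  The
        other allele is the minor allele when they differ; when they
        coincide the partner allele is not recoverable from a MAF table,
        so an arbitrary distinct placeholder base is used.
        """
        if effect_allele == minor_allele:
            eaf_control, eaf_case = maf_control, maf_case
            other = next(b for b in "ACGT" if b != effect_allele)
        else:
            eaf_control, eaf_case = 1.0 - maf_control, 1.0 - maf_case
            other = minor_allele
        return cls(
            variant_id=variant_id,
            gene=gene,
            chromosome=chromosome,
            effect_allele=effect_allele,
            other_allele=other,
            eaf_control=float(eaf_control),
            eaf_case=float(eaf_case),
        )

    @property
    def eaf_difference(self) -> float:
        """Case-minus-control effect-allele frequency difference."""
        return self.eaf_case - self.eaf_control


@dataclass(frozen=True)
class CohortConfig:
    """Sampling design for a simulated case-control cohort.

    Defaults mirror the study cohort: 279 cases, 397 controls.  Age and
    sex are drawn independently of disease status (age truncated normal,
    sex Bernoulli), so the covariates carry no information about the
    outcome unless the caller says otherwise.  ``prevalence`` is used
    only by prospective (population) simulation.
    """

    n_case: int = 279
    n_control: int = 397
    age_mean: float = 55.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (18.0, 90.0)
    sex_balance: float = 0.5
    prevalence: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("cohort sizes must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence {self.prevalence} outside (0, 1)")
        if not 0.0 <= self.sex_balance <= 1.0:
            raise ValueError("sex_balance outside [0, 1]")

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control


@dataclass
class GenotypeDataset:
    """Dosage matrix plus per-sample status, covariates and phenotypes.

    Attributes
    ----------
    dosages : pandas.DataFrame
        samples x variants effect-allele counts; entries in {0, 1, 2}
        or NaN for missing.
    status : numpy.ndarray
        1 = case, 0 = control.
    age, sex : numpy.ndarray
        Covariates; sex coded 0/1.
    variants : list of VariantSpec
        One entry per dosage column, same order.
    phenotypes : pandas.DataFrame or None
        Optional quantitative traits, same index as ``dosages``.
    """

    dosages: pd.DataFrame
    status: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    variants: list[VariantSpec] = field(default_factory=list)
    phenotypes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=int)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=int)
        n = len(self.dosages)
        for name, arr in (("status", self.status), ("age", self.age), ("sex", self.sex)):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} samples")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be coded 0 (control) / 1 (case)")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid dosage {vals[i, j]} for sample "
                f"{self.dosages.index[i]!r}, variant {self.dosages.columns[j]!r}"
            )
        if self.variants:
            if len(self.variants) != self.dosages.shape[1]:
                raise ValueError("variant metadata does not match dosage columns")
            meta_ids = [v.variant_id for v in self.variants]
            if meta_ids != list(self.dosages.columns):
                raise ValueError("variant metadata order does not match dosage columns")
        if self.phenotypes is not None and len(self.phenotypes) != n:
            raise ValueError("phenotype table length mismatch")

    # -- convenience ---------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_samples(self) -> int:
        return len(self.dosages)

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def is_case(self) -> np.ndarray:
        return self.status == 1

    def variant(self, variant_id: str) -> VariantSpec:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise KeyError(variant_id)

    def dosage(self, variant_id: str) -> np.ndarray:
        if variant_id not in self.dosages.columns:
            raise KeyError(variant_id)
        return self.dosages[variant_id].to_numpy(dtype=float)

    def genotype_counts(self, variant_id: str, group: str = "control") -> tuple[int, int, int]:
        """(hom other, het, hom effect) counts in ``group`` ∈ {control, case, all}."""
        g = self.dosage(variant_id)
        if group == "control":
            g = g[~self.is_case]
        elif group == "case":
            g = g[self.is_case]
        elif group != "all":
            raise ValueError(f"unknown group {group!r}")
        g = g[~np.isnan(g)]
        return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())

    def empirical_eaf(self, variant_id: str, group: str = "all") -> float:
        n0, n1, n2 = self.genotype_counts(variant_id, group)
        n = n0 + n1 + n2
        if n == 0:
            return float("nan")
        return (n1 + 2 * n2) / (2 * n)

    def with_dosages(self, dosages: pd.DataFrame, variants: Sequence[VariantSpec] | None = None) -> "GenotypeDataset":
        """Copy of the dataset with a replaced dosage matrix."""
        return GenotypeDataset(
            dosages=dosages,
            status=self.status.copy(),
            age=self.age.copy(),
            sex=self.sex.copy(),
            variants=list(variants) if variants is not None else list(self.variants),
            phenotypes=None if self.phenotypes is None else self.phenotypes.copy(),
        )

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeDataset":
        keep = [v for v in self.variants if v.variant_id in set(variant_ids)]
        return self.with_dosages(self.dosages[list(variant_ids)].copy(),
                                 [v for vid in variant_ids for v in keep if v.variant_id == vid])


def replace_variant(spec: VariantSpec, **kwargs) -> VariantSpec:
    """Functional update helper (frozen dataclass)."""
    return replace(spec, **kwargs)
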