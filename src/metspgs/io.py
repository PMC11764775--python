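"""Readers and writers for the pipeline's plain-text formats.

Variant metadata travels as CSV with the column layout of a published
association table (effect allele, minor allele, per-group MAF, OR,
p-values); the effect-allele frequency is derived on read via the
EA/MA/MAF convention.  Genotypes are exchanged either as a
PLINK-``.raw``-style whitespace table (header ``FID IID PAT MAT SEX
PHENOTYPE`` then one ``rsID_EA`` column per variant, dosage =
effect-allele count, PHENOTYPE 2 = case / 1 = control, missing = NA) or
as plain CSV.  Because the ``.raw`` layout has no age or phenotype
columns, the writer emits a companion ``<stem>.cov`` table that the
reader picks up automatically, making the round trip lossless.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assoc import AssociationResult
from .cohort import GenotypeDataset, VariantSpec
from .score import ScoreSet, WeightTable

__all__ = [
    "read_variant_metadata",
    "load_mets_loci",
    "load_mets_odds_ratios",
    "read_genotypes",
    "write_genotypes",
    "write_association_results",
    "write_scores",
    "write_weight_table",
]

_REQUIRED_META = [
    "variant_id",
    "effect_allele",
    "minor_allele",
    "maf_control",
    "maf_case",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending row/sample."""


def read_variant_metadata(path: str | Path) -> list[VariantSpec]:
    """Read a variant-metadata CSV into :class:`VariantSpec` records.

    Required columns: variant_id, effect_allele, minor_allele,
    maf_control, maf_case; optional: gene, chromosome (plus any
    association columns, ignored here).  EAF = MAF when the effect
    allele equals the minor allele, else 1 - MAF.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty metadata file") from None
    missing = [c for c in _REQUIRED_META if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ParseError(f"{path}: no variant rows")
    specs = []
    for i, row in df.iterrows():
        try:
            specs.append(
                VariantSpec.from_maf(
                    variant_id=str(row["variant_id"]),
                    effect_allele=str(row["effect_allele"]).strip(),
                    minor_allele=str(row["minor_allele"]).strip(),
                    maf_control=float(row["maf_control"]),
                    maf_case=float(row["maf_case"]),
                    gene=str(row.get("gene", "")),
                    chromosome=str(row.get("chromosome", "")),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from exc
    return specs


def _packaged_loci() -> pd.DataFrame:
    with importlib.resources.files("metspgs").joinpath("data/mets_loci.csv").open() as fh:
        return pd.read_csv(fh)


def load_mets_loci() -> list[VariantSpec]:
    """The packaged 18-locus metabolic-syndrome panel (variant specs)."""
    df = _packaged_loci()
    return [
        VariantSpec.from_maf(
            variant_id=r.variant_id,
            effect_allele=r.effect_allele,
            minor_allele=r.minor_allele,
            maf_control=r.maf_control,
            maf_case=r.maf_case,
            gene=r.gene,
            chromosome=str(r.chromosome),
        )
        for r in df.itertuples()
    ]


def load_mets_odds_ratios() -> dict[str, float]:
    """Published per-allele odds ratios for the packaged panel (score weights)."""
    df = _packaged_loci()
    return dict(zip(df["variant_id"], df["odds_ratio"].astype(float)))


def load_mets_table() -> pd.DataFrame:
    """The packaged association table as a raw DataFrame (incl. p, p_fdr)."""
    return _packaged_loci()


# -- genotype files ---------------------------------------------------


def write_genotypes(
    dataset: GenotypeDataset, path: str | Path, dialect: str = "plink_raw"
) -> Path:
    """Write a dataset as a PLINK-.raw-style table or plain CSV.

    plink_raw: columns FID IID PAT MAT SEX PHENOTYPE then ``rsID_EA``
    dosage columns; SEX = sex + 1, PHENOTYPE 2 = case / 1 = control,
    missing dosage = NA.  Age (and any phenotypes) go to a companion
    ``<stem>.cov`` file.  csv: a single self-contained table.
    """
    path = Path(path)
    if dialect == "plink_raw":
        cols = {}
        cols["FID"] = dataset.sample_ids
        cols["IID"] = dataset.sample_ids
        cols["PAT"] = [0] * dataset.n_samples
        cols["MAT"] = [0] * dataset.n_samples
        cols["SEX"] = dataset.sex + 1
        cols["PHENOTYPE"] = dataset.status + 1
        out = pd.DataFrame(cols)
        for v in dataset.variants or [
            VariantSpec(c, "", "", "A", "G", 0.5, 0.5) for c in dataset.variant_ids
        ]:
            out[f"{v.variant_id}_{v.effect_allele}"] = dataset.dosages[
                v.variant_id
            ].to_numpy()
        out.to_csv(path, sep=" ", index=False, na_rep="NA")
        cov = pd.DataFrame({"FID": dataset.sample_ids, "IID": dataset.sample_ids,
                            "age": dataset.age})
        if dataset.phenotypes is not None:
            for c in dataset.phenotypes.columns:
                cov[c] = dataset.phenotypes[c].to_numpy()
        cov.to_csv(path.with_suffix(".cov"), sep=" ", index=False, na_rep="NA")
    elif dialect == "csv":
        out = pd.DataFrame(
            {
                "sample_id": dataset.sample_ids,
                "status": np.where(dataset.is_case, "case", "control"),
                "age": dataset.age,
                "sex": dataset.sex,
            }
        )
        if dataset.phenotypes is not None:
            for c in dataset.phenotypes.columns:
                out[c] = dataset.phenotypes[c].to_numpy()
        for vid in dataset.variant_ids:
            out[vid] = dataset.dosages[vid].to_numpy()
        out.to_csv(path, index=False, na_rep="NA")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def _check_dosages(df: pd.DataFrame, dose_cols: Sequence[str], path: Path, ids) -> None:
    for col in dose_cols:
        vals = df[col].to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: dosage {vals[i]} outside {{0,1,2,NA}} for sample "
                f"{ids[i]!r}, variant {col!r}"
            )


def read_genotypes(
    path: str | Path,
    dialect: str = "plink_raw",
    variants: Sequence[VariantSpec] | None = None,
) -> GenotypeDataset:
    """Read a genotype table written by :func:`write_genotypes`.

    Dosages must be 0/1/2 or NA; anything else raises a
    :class:`ParseError` naming the sample and variant.  Supplying
    ``variants`` re-attaches full metadata (frequencies, chromosomes);
    otherwise minimal specs are reconstructed from the column headers.
    """
    path = Path(path)
    if dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        fixed = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        missing = [c for c in fixed if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        ids = df["IID"].astype(str).tolist()
        pheno = df["PHENOTYPE"].to_numpy()
        if not np.isin(pheno, (1, 2)).all():
            raise ParseError(f"{path}: PHENOTYPE must be 1 (control) or 2 (case)")
        status = (pheno == 2).astype(int)
        sex = (df["SEX"].to_numpy(dtype=int) - 1).clip(0, 1)
        dose_cols = [c for c in df.columns if c not in fixed]
        _check_dosages(df, dose_cols, path, ids)
        vids, alleles = [], []
        for c in dose_cols:
            vid, _, ea = c.rpartition("_")
            if not vid:
                raise ParseError(f"{path}: dosage column {c!r} not in rsID_EA form")
            vids.append(vid)
            alleles.append(ea)
        dosages = pd.DataFrame(
            {v: df[c].to_numpy(dtype=float) for v, c in zip(vids, dose_cols)},
            index=ids,
        )
        age = np.zeros(len(ids))
        phenotypes = None
        covpath = path.with_suffix(".cov")
        if covpath.exists():
            cov = pd.read_csv(covpath, sep=r"\s+", na_values=["NA"])
            if "age" in cov.columns:
                age = cov["age"].to_numpy(dtype=float)
            extra = [c for c in cov.columns if c not in ("FID", "IID", "age")]
            if extra:
                phenotypes = pd.DataFrame(
                    {c: cov[c].to_numpy(dtype=float) for c in extra}, index=ids
                )
        if variants is not None:
            vmap = {v.variant_id: v for v in variants}
            specs = [vmap[v] for v in vids if v in vmap]
            if len(specs) != len(vids):
                absent = [v for v in vids if v not in vmap]
                raise ParseError(f"{path}: no metadata for variants {absent}")
        else:
            specs = [
                VariantSpec(v, "", "", ea if ea in set("ACGT") else "A",
                            "G" if ea != "G" else "C", 0.5, 0.5)
                for v, ea in zip(vids, alleles)
            ]
        return GenotypeDataset(
            dosages=dosages, status=status, age=age, sex=sex,
            variants=specs, phenotypes=phenotypes,
        )
    if dialect == "csv":
        df = pd.read_csv(path, na_values=["NA"])
        fixed = ["sample_id", "status", "age", "sex"]
        missing = [c for c in fixed if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        ids = df["sample_id"].astype(str).tolist()
        status_raw = df["status"].astype(str)
        if not status_raw.isin(["case", "control"]).all():
            raise ParseError(f"{path}: status must be 'case' or 'control'")
        status = (status_raw == "case").astype(int).to_numpy()
        known = (
            {v.variant_id for v in variants} if variants is not None else None
        )
        dose_cols = [
            c
            for c in df.columns
            if c not in fixed and (known is None or c in known)
        ]
        pheno_cols = [c for c in df.columns if c not in fixed and c not in dose_cols]
        if known is None:
            # without metadata, every non-fixed column is a dosage column
            pheno_cols = []
        _check_dosages(df, dose_cols, path, ids)
        dosages = pd.DataFrame(
            {c: df[c].to_numpy(dtype=float) for c in dose_cols}, index=ids
        )
        phenotypes = (
            pd.DataFrame({c: df[c].to_numpy(dtype=float) for c in pheno_cols}, index=ids)
            if pheno_cols
            else None
        )
        if variants is not None:
            vmap = {v.variant_id: v for v in variants}
            specs = [vmap[c] for c in dose_cols]
        else:
            specs = [VariantSpec(c, "", "", "A", "G", 0.5, 0.5) for c in dose_cols]
        return GenotypeDataset(
            dosages=dosages,
            status=status,
            age=df["age"].to_numpy(dtype=float),
            sex=df["sex"].to_numpy(dtype=int),
            variants=specs,
            phenotypes=phenotypes,
        )
    raise ValueError(f"unknown dialect {dialect!r}")


# -- result tables ----------------------------------------------------


def write_association_results(
    results: Sequence[AssociationResult],
    path: str | Path,
    variants: Sequence[VariantSpec] | None = None,
) -> Path:
    """Association scan as TSV mirroring a published association table."""
    vmap = {v.variant_id: v for v in (variants or [])}
    rows = []
    for r in results:
        v = vmap.get(r.variant_id)
        rows.append(
            dict(
                variant_id=r.variant_id,
                gene=v.gene if v else "",
                effect_allele=r.effect_allele_used,
                flipped=r.flipped,
                beta=r.beta,
                se=r.se,
                z=r.z,
                odds_ratio=r.or_,
                ci_low=r.ci_low,
                ci_high=r.ci_high,
                p=r.p,
                p_fdr=r.p_fdr,
                hwe_p=r.hwe_p,
                n_used=r.n_used,
                error=r.error or "",
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")
    return Path(path)


def write_scores(scores: ScoreSet, status: np.ndarray, path: str | Path) -> Path:
    out = scores.table.copy()
    out.insert(0, "status", np.where(np.asarray(status) == 1, "case", "control"))
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")
    return Path(path)


def write_weight_table(weights: WeightTable, path: str | Path) -> Path:
    weights.table.to_csv(path, index=False, na_rep="NA")
    return Path(path)
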