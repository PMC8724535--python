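"""File formats: VCF, dosage TSV, summary-statistics TSV, marker TSV, JSON.

All tabular artifacts are tab-separated with a header row; the missing
token in dosage matrices is ``NA``.  VCF reading goes through cyvcf2 and
accepts only biallelic records (GT mapped to the alt-allele dosage).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .ppd import COGNITIVE_DOMAINS, MarkerProfile
from .prs import SummaryStatRecord
from .qc import GenotypeMatrix, VariantInfo

SUMSTAT_COLUMNS = ["chrom", "pos", "ref", "alt", "effect_allele", "beta", "se", "pvalue", "maf"]


# -- dosage TSV: rows = variants, columns = metadata + one column per individual

def write_dosage_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    meta = pd.DataFrame(
        {
            "chrom": [v.chrom for v in matrix.variants],
            "pos": [v.pos for v in matrix.variants],
            "ref": [v.ref_allele for v in matrix.variants],
            "alt": [v.alt_allele for v in matrix.variants],
            "info_score": [v.info_score for v in matrix.variants],
        }
    )
    dos = pd.DataFrame(matrix.dosages.T, columns=matrix.individual_ids)
    table = pd.concat([meta, dos], axis=1)
    with open(path, "w") as fh:
        fh.write("# dosage matrix: alt-allele dosage in {0,1,2}; missing = NA\n")
        table.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%g")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    meta_cols = ["chrom", "pos", "ref", "alt", "info_score"]
    missing = [c for c in meta_cols if c not in table.columns]
    if missing:
        raise ValueError(f"dosage TSV missing columns: {missing}")
    ids = [c for c in table.columns if c not in meta_cols]
    variants = [
        VariantInfo(chrom=str(r.chrom), pos=int(r.pos), ref_allele=str(r.ref), alt_allele=str(r.alt), info_score=float(r.info_score))
        for r in table.itertuples()
    ]
    dosages = table[ids].to_numpy(dtype=float).T
    matrix = GenotypeMatrix(ids, variants, dosages)
    matrix.refresh_metadata()
    return matrix


# -- VCF (unphased GT, biallelic only)

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ppdprs\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in matrix.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.individual_ids) + "\n")
        for j, v in enumerate(matrix.variants):
            gts = [_GT.get(d, "./.") if not np.isnan(d) else "./." for d in matrix.dosages[:, j]]
            fh.write(f"{v.chrom}\t{v.pos}\t{v.key}\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, int]:
    """Read a VCF into a genotype matrix; returns (matrix, n_rejected_multiallelic)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    variants: list[VariantInfo] = []
    rows: list[np.ndarray] = []
    n_rejected = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_rejected += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        g = rec.gt_types.astype(float)
        dos = np.where(g == 0, 0.0, np.where(g == 1, 1.0, np.where(g == 3, 2.0, np.nan)))
        rows.append(dos)
        variants.append(VariantInfo(chrom=str(rec.CHROM), pos=int(rec.POS), ref_allele=rec.REF, alt_allele=rec.ALT[0]))
    vcf.close()
    if not rows:
        raise ValueError(f"no biallelic records in {path}")
    matrix = GenotypeMatrix(ids, variants, np.vstack(rows).T)
    matrix.refresh_metadata()
    return matrix, n_rejected


# -- discovery summary statistics

def write_sumstats_tsv(records: Iterable[SummaryStatRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.other_allele,
            "alt": r.effect_allele,
            "effect_allele": r.effect_allele,
            "beta": r.beta,
            "se": r.se,
            "pvalue": r.pvalue,
            "maf": r.maf,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SUMSTAT_COLUMNS).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_sumstats_tsv(path: str | Path) -> list[SummaryStatRecord]:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    missing = [c for c in SUMSTAT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"summary-statistics TSV missing columns: {missing}")
    records = []
    for r in table.itertuples():
        other = r.ref if r.effect_allele == r.alt else r.alt
        records.append(
            SummaryStatRecord(
                chrom=str(r.chrom),
                pos=int(r.pos),
                effect_allele=str(r.effect_allele),
                other_allele=str(other),
                beta=float(r.beta),
                pvalue=float(r.pvalue),
                se=float(r.se),
                maf=float(r.maf),
            )
        )
    return records


# -- marker profiles

def profiles_to_frame(profiles: Iterable[MarkerProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row: dict = {
            "individual_id": p.individual_id,
            "age": p.age,
            "sex": p.sex,
            "dementia_flag": int(p.dementia_flag),
            "mci_flag": int(p.mci_flag),
            "pd_dlb_flag": int(p.pd_dlb_flag),
        }
        for name, state in p.risk_markers.items():
            row[f"risk:{name}"] = state
        for name, state in p.prodromal_markers.items():
            row[f"prodromal:{name}"] = state
        for d in COGNITIVE_DOMAINS:
            row[f"z:{d}"] = p.cognitive_z.get(d, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_markers_tsv(profiles: Iterable[MarkerProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_markers_tsv(path: str | Path) -> list[MarkerProfile]:
    table = pd.read_csv(path, sep="\t")
    required = {"individual_id", "age", "sex"}
    if not required <= set(table.columns):
        raise ValueError(f"marker TSV missing columns: {sorted(required - set(table.columns))}")
    profiles = []
    for r in table.to_dict("records"):
        risk = {k.split(":", 1)[1]: v for k, v in r.items() if isinstance(k, str) and k.startswith("risk:")}
        prod = {k.split(":", 1)[1]: v for k, v in r.items() if isinstance(k, str) and k.startswith("prodromal:")}
        cog = {
            k.split(":", 1)[1]: float(v)
            for k, v in r.items()
            if isinstance(k, str) and k.startswith("z:") and pd.notna(v)
        }
        profiles.append(
            MarkerProfile(
                individual_id=str(r["individual_id"]),
                age=float(r["age"]),
                sex=str(r["sex"]),
                risk_markers=risk,
                prodromal_markers=prod,
                cognitive_z=cog,
                dementia_flag=bool(r.get("dementia_flag", 0)),
                mci_flag=bool(r.get("mci_flag", 0)),
                pd_dlb_flag=bool(r.get("pd_dlb_flag", 0)),
            )
        )
    return profiles


# -- small JSON/YAML helpers

def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
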