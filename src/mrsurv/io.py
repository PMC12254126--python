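"""Readers and writers for the package's plain-text interchange formats.

Weights are TSV (variant_id, effect_allele, other_allele, beta,
allele_freq, trait). Dosages travel either as a variant-major TSV (one row
per variant with its coded allele, one column per individual) or as VCF
with a DS FORMAT field (the coded allele is ALT). Phenotypes and survival
outcomes are one CSV row per individual.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import GenotypeData

WEIGHTS_COLUMNS = ["variant_id", "effect_allele", "other_allele", "beta",
                   "allele_freq", "trait"]


def write_weights_tsv(panel: pd.DataFrame, path) -> None:
    out = panel.rename(columns={"weight": "beta"})[WEIGHTS_COLUMNS]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_weights_tsv(path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t")
    missing = set(WEIGHTS_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"weights file lacks columns: {sorted(missing)}")
    return panel.rename(columns={"beta": "weight"})


def write_dosages_tsv(geno: GenotypeData, path) -> None:
    """Variant-major dosage TSV: variant_id, coded_allele, other_allele,
    then one column per individual."""
    ids = geno.dosages.columns.tolist()
    meta = pd.DataFrame({
        "variant_id": ids,
        "coded_allele": [geno.coded_allele[v] for v in ids],
        "other_allele": [geno.other_allele.get(v, ".") for v in ids],
    })
    mat = pd.DataFrame(
        geno.dosages.to_numpy().T,
        columns=[str(i) for i in geno.dosages.index],
    )
    pd.concat([meta, mat.round(4)], axis=1).to_csv(path, sep="\t",
                                                   index=False)


def read_dosages_tsv(path) -> tuple[pd.DataFrame, dict, dict]:
    """Returns (individuals x variants dosage frame, coded, other)."""
    raw = pd.read_csv(path, sep="\t")
    coded = dict(zip(raw["variant_id"], raw["coded_allele"]))
    other = dict(zip(raw["variant_id"], raw["other_allele"]))
    mat = raw.drop(columns=["variant_id", "coded_allele", "other_allele"])
    dosages = pd.DataFrame(
        mat.to_numpy(float).T, columns=raw["variant_id"].tolist(),
        index=mat.columns,
    )
    dosages.index = [int(i) if str(i).isdigit() else i
                     for i in dosages.index]
    return dosages, coded, other


def write_vcf(geno: GenotypeData, path, chrom: str = "1") -> None:
    """Minimal VCF with per-sample DS (dosage of ALT = coded allele)."""
    ids = geno.dosages.columns.tolist()
    samples = [f"S{i}" for i in geno.dosages.index]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        mat = geno.dosages.to_numpy()
        for j, v in enumerate(ids):
            ref = geno.other_allele.get(v, "N")
            alt = geno.coded_allele[v]
            vals = "\t".join(f"{x:.3f}" for x in mat[:, j])
            fh.write(f"{chrom}\t{j + 1}\t{v}\t{ref}\t{alt}\t.\t.\t.\tDS\t"
                     f"{vals}\n")


def read_vcf_dosages(path) -> tuple[pd.DataFrame, dict, dict]:
    """Read DS dosages from a VCF (cyvcf2 when available, else text parse)."""
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    samples = vcf.samples
    cols, coded, other = {}, {}, {}
    for var in vcf:
        vid = var.ID
        ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        cols[vid] = ds
        coded[vid] = var.ALT[0]
        other[vid] = var.REF
    return pd.DataFrame(cols, index=samples), coded, other


def _read_vcf_text(path) -> tuple[pd.DataFrame, dict, dict]:
    cols, coded, other = {}, {}, {}
    samples = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            vid, ref, alt = parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            ds_i = fmt.index("DS")
            cols[vid] = np.array(
                [float(p.split(":")[ds_i]) for p in parts[9:]])
            coded[vid] = alt
            other[vid] = ref
    return pd.DataFrame(cols, index=samples), coded, other


PHENOTYPE_COLUMNS = {
    "individual_id": "integer identifier",
    "sex": "male/female",
    "entry_age": "age at recruitment (years)",
    "bmi_measured": "measured BMI at recruitment (kg/m2)",
    "diabetes": "none/undiagnosed/diagnosed",
    "ancestry_prop": "Indigenous-American-like admixture fraction",
    "district": "residential district A/B",
    "smoking": "never/former/current",
    "activity": "none/any leisure-time physical activity",
    "exit_age": "age at death or censoring (years)",
    "died": "death indicator",
    "cause": "leaf cause of death, or 'none'",
}


def write_phenotypes_csv(cohort: pd.DataFrame, survival: pd.DataFrame,
                         path) -> None:
    df = cohort.merge(survival.drop(columns="entry_age"), on="individual_id")
    drop = [c for c in ("bmi_true", "confounder", "liability_mu")
            if c in df.columns]
    df.drop(columns=drop).to_csv(path, index=False, float_format="%.6g")


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file lacks columns: {sorted(missing)}")
    return df
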