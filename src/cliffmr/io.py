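"""Reading and writing the package's plain-text data dialects.

Summary statistics travel as tab-separated text with the header
``snp  effect_allele  other_allele  eaf  beta  se  pval  n  info`` —
one record per variant, effect sizes on the beta / log-OR scale.
Cohorts are a genotype dosage matrix (individuals in rows, SNPs in
columns, indexed by individual id) plus a phenotype/covariate table
keyed by the same ids.  LD-score panels are TSVs with columns
``snp  l2  z1  z2  n1  n2``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

SUMMARY_COLUMNS = [
    "snp",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "info",
]

PANEL_COLUMNS = ["snp", "l2", "z1", "z2", "n1", "n2"]


def write_summary(assocs: pd.DataFrame, path: str | Path) -> None:
    """Write per-SNP association statistics as TSV in the standard dialect."""
    missing = [c for c in SUMMARY_COLUMNS if c not in assocs.columns]
    if missing:
        raise ValueError(f"summary table missing columns: {missing}")
    assocs.loc[:, SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary(path: str | Path) -> pd.DataFrame:
    """Read a summary-statistics TSV; ORs in a `beta` column are *not* auto-logged."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns and c != "info"]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "info" not in df.columns:
        df["info"] = np.nan
    return df[SUMMARY_COLUMNS]


def write_cohort(cohort, out_dir: str | Path) -> None:
    """Write a cohort as genotypes.tsv + phenotypes.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.dosages.to_csv(out / "genotypes.tsv", sep="\t", index_label="iid")
    cohort.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index_label="iid")
    alleles = pd.DataFrame({"snp": cohort.dosages.columns, "risk_allele": cohort.risk_alleles})
    if cohort.effect_alleles is not None:
        alleles["effect_allele"] = cohort.effect_alleles
    if cohort.other_alleles is not None:
        alleles["other_allele"] = cohort.other_alleles
    alleles.to_csv(out / "alleles.tsv", sep="\t", index=False)


def read_cohort(in_dir: str | Path):
    """Read a cohort written by :func:`write_cohort`."""
    from .simulate import CohortTable  # local import avoids a cycle

    d = Path(in_dir)
    dosages = pd.read_csv(d / "genotypes.tsv", sep="\t", index_col="iid")
    pheno = pd.read_csv(d / "phenotypes.tsv", sep="\t", index_col="iid")
    alleles = pd.read_csv(d / "alleles.tsv", sep="\t").set_index("snp").reindex(dosages.columns)
    return CohortTable(
        dosages=dosages,
        phenotypes=pheno,
        risk_alleles=alleles["risk_allele"].to_numpy(),
        effect_alleles=alleles["effect_allele"].to_numpy() if "effect_allele" in alleles else None,
        other_alleles=alleles["other_allele"].to_numpy() if "other_allele" in alleles else None,
    )


def write_panel(panel, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "snp": panel.snp_ids,
            "l2": panel.ld_score,
            "z1": panel.z1,
            "z2": panel.z2,
            "n1": panel.n1,
            "n2": panel.n2,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path):
    from .ldsc import LDScorePanel

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return LDScorePanel(
        snp_ids=df["snp"].to_numpy(),
        ld_score=df["l2"].to_numpy(float),
        z1=df["z1"].to_numpy(float),
        z2=df["z2"].to_numpy(float),
        n1=int(df["n1"].iloc[0]),
        n2=int(df["n2"].iloc[0]),
    )
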