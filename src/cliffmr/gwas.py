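"""Phenotype derivation, per-SNP association testing and variant filtering.

This is the outcome-GWAS side of the pipeline: from an individual-level
cohort it derives the analysis phenotypes (childlessness, the trimmed and
dichotomized sexual-partner count), runs covariate-adjusted per-SNP
regressions of each outcome on allele dosage, and applies minor-allele
frequency / imputation-quality filters to the resulting association
records.
"""

from __future__ import annotations

import logging
from dataclasses import replace as dc_replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import CohortTable

__all__ = ["derive_phenotypes", "run_association", "filter_variants"]

log = logging.getLogger(__name__)


def derive_phenotypes(raw: CohortTable) -> CohortTable:
    """Derive the analysis outcomes from the raw phenotype table.

    Adds ``childless`` (1 iff number_of_children == 0), sets sexual-partner
    counts strictly above their empirical 99th percentile to missing, and
    adds ``top_partners`` (1 iff the trimmed count is at or above the
    empirical 90th-percentile cut).  The cut actually used is recorded in
    ``phenotypes.attrs['top_partners_cut']``.
    """
    pheno = raw.phenotypes.copy()
    pheno["childless"] = (pheno["number_of_children"] == 0).astype(float)
    pheno.loc[pheno["number_of_children"].isna(), "childless"] = np.nan

    partners = pheno["n_sexual_partners"]
    nonmiss = partners.dropna()
    if len(nonmiss) == 0:
        log.warning("all sexual-partner counts missing; top_partners not derived")
        pheno = pheno.drop(columns=["n_sexual_partners"], errors="ignore")
        pheno["n_sexual_partners"] = np.nan
    else:
        p99 = nonmiss.quantile(0.99)
        trimmed = partners.where(~(partners > p99))
        pheno["n_sexual_partners"] = trimmed
        cut = trimmed.quantile(0.90)
        pheno["top_partners"] = (trimmed >= cut).astype(float)
        pheno.loc[trimmed.isna(), "top_partners"] = np.nan
        pheno.attrs["partner_trim_threshold"] = float(p99)
        pheno.attrs["top_partners_cut"] = float(cut)

    return dc_replace(raw, phenotypes=pheno)


def _linear_fit(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """OLS slope and SE for the second column of X (intercept first)."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = len(y) - X.shape[1]
    if df <= 0 or rank < X.shape[1]:
        return float("nan"), float("nan")
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    return float(coef[1]), float(np.sqrt(sigma2 * xtx_inv[1, 1]))


def run_association(
    cohort: CohortTable,
    phenotype: str,
    covariates: list[str] | None = None,
    model: str = "linear",
) -> pd.DataFrame:
    """Per-SNP covariate-adjusted association of one phenotype with dosage.

    Complete-case per analysis: individuals missing the phenotype, any
    covariate, or that SNP's dosage are dropped.  ``linear`` returns the
    OLS dosage coefficient; ``logistic`` the log-OR from a Logit fit (the
    phenotype must then be binary).  p-values are two-sided Wald/normal.
    SNPs with zero dosage variance, or non-converged logistic fits, yield
    records with missing beta/se and a logged warning.

    Returns a summary-statistics table in the standard dialect, with the
    cohort's counted allele as effect allele and ``info`` set to 1 (true
    genotypes, no imputation).
    """
    if model not in ("linear", "logistic"):
        raise ValueError(f"unknown model {model!r}")
    covariates = list(covariates or [])
    pheno = cohort.phenotypes
    missing = [c for c in [phenotype, *covariates] if c not in pheno.columns]
    if missing:
        raise KeyError(f"columns not in phenotype table: {missing}")

    y_all = pheno[phenotype].to_numpy(float)
    C_all = pheno[covariates].to_numpy(float) if covariates else np.empty((len(pheno), 0))
    base_mask = ~np.isnan(y_all)
    if covariates:
        base_mask &= ~np.isnan(C_all).any(axis=1)
    if model == "logistic":
        vals = np.unique(y_all[base_mask])
        if not np.isin(vals, [0.0, 1.0]).all():
            raise ValueError(f"logistic model needs a binary phenotype, got values {vals[:5]}")

    eff = cohort.effect_alleles if cohort.effect_alleles is not None else cohort.risk_alleles
    oth = (cohort.other_alleles if cohort.other_alleles is not None
           else np.full(len(cohort.dosages.columns), "N"))

    records = []
    dos_mat = cohort.dosages.to_numpy(float)
    for j, snp in enumerate(cohort.dosages.columns):
        d = dos_mat[:, j]
        mask = base_mask & ~np.isnan(d)
        n_used = int(mask.sum())
        dj, yj = d[mask], y_all[mask]
        eaf = float(dj.mean() / 2) if n_used else float("nan")
        beta = se = float("nan")
        if n_used > len(covariates) + 2 and np.ptp(dj) > 0:
            X = np.column_stack([np.ones(n_used), dj, C_all[mask]])
            if model == "linear":
                beta, se = _linear_fit(yj, X)
            else:
                try:
                    res = sm.Logit(yj, X).fit(disp=0, maxiter=100)
                    if res.mle_retvals.get("converged", False):
                        beta, se = float(res.params[1]), float(res.bse[1])
                    else:
                        log.warning("logistic fit did not converge for %s", snp)
                except Exception as exc:  # separation etc.
                    log.warning("logistic fit failed for %s: %s", snp, exc)
        elif np.ptp(dj) == 0:
            log.warning("zero dosage variance for %s; emitting missing effect", snp)
        pval = 2 * stats.norm.sf(abs(beta) / se) if se == se and se > 0 else float("nan")
        records.append(
            {
                "snp": snp,
                "effect_allele": eff[j],
                "other_allele": oth[j],
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pval": pval,
                "n": n_used,
                "info": 1.0,
            }
        )
    return pd.DataFrame(records)


def filter_variants(assocs: pd.DataFrame, mode: str = "flat") -> pd.DataFrame:
    """Apply MAF/imputation-quality filters to association records.

    ``flat`` keeps records with min(eaf, 1−eaf) > 0.01 and info > 0.8.
    ``graded`` applies frequency-banded info thresholds — info > 0.3 for
    MAF > 3%, > 0.6 for MAF 1–3%, > 0.8 for MAF 0.5–1%, > 0.9 for MAF
    0.1–0.5% — with MAF below 0.1% always dropped.  Records with missing
    info are dropped (conservative) and counted.  Idempotent; per-rule
    exclusion counts are logged and attached as ``.attrs['filter_counts']``.
    """
    if mode not in ("flat", "graded"):
        raise ValueError(f"unknown filter mode {mode!r}")
    maf = np.minimum(assocs["eaf"].to_numpy(float), 1 - assocs["eaf"].to_numpy(float))
    info = assocs["info"].to_numpy(float)

    counts = {"missing_info": int(np.isnan(info).sum())}
    valid = ~np.isnan(info)
    if mode == "flat":
        keep = valid & (maf > 0.01) & (info > 0.8)
        counts["maf_le_0.01"] = int((valid & ~(maf > 0.01)).sum())
        counts["info_le_0.8"] = int((valid & (maf > 0.01) & ~(info > 0.8)).sum())
    else:
        bands = [  # (maf_low, maf_high, info_threshold)
            (0.03, 0.5, 0.3),
            (0.01, 0.03, 0.6),
            (0.005, 0.01, 0.8),
            (0.001, 0.005, 0.9),
        ]
        keep = np.zeros(len(assocs), dtype=bool)
        for lo, hi, thr in bands:
            in_band = valid & (maf > lo) & (maf <= hi) if hi < 0.5 else valid & (maf > lo)
            band_keep = in_band & (info > thr)
            keep |= band_keep
            counts[f"maf_({lo},{hi}]_info_le_{thr}"] = int((in_band & ~band_keep).sum())
        counts["maf_le_0.001"] = int((valid & (maf <= 0.001)).sum())
    out = assocs.loc[keep].reset_index(drop=True)
    log.info("filter_variants(%s): kept %d / %d (%s)", mode, len(out), len(assocs), counts)
    out.attrs["filter_counts"] = counts
    return out
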