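"""Genetic-score nonlinearity analyses on individual-level data.

The MR estimators assume a linear exposure–outcome dose-response; the
cliff-edge fitness hypothesis predicts the opposite — a drop in fitness
above a liability threshold.  This module implements the sensitivity
machinery that probes for such nonlinearity with an *unweighted* additive
genetic score (a plain risk-allele count, which avoids importing
effect-size estimation error into sex-stratified analyses):

* quantile (quintile/decile) summaries of mean outcome by score bin,
* linear regressions repeated while cumulatively removing the top tail
  of the score distribution (a cliff shows up as the slope strengthening
  as the penalized tail is excluded),
* quadratic regressions, optionally sex-stratified, whose vertex locates
  a putative fitness peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CohortTable

__all__ = [
    "build_unweighted_score",
    "quantile_summary",
    "centile_removal_scan",
    "quadratic_fit",
    "ScoreScanResult",
    "QuadraticFit",
]

_Z95 = 1.96


@dataclass
class ScoreScanResult:
    """One row of the cumulative tail-removal regression scan."""

    removal_fraction: float
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n: int


@dataclass
class QuadraticFit:
    """Quadratic score–outcome regression for one analysis group.

    Coefficients are on the raw (uncentered) score scale; the vertex
    −b/(2a) is the stationary point of the fitted parabola, with a
    delta-method SE.
    """

    group: str
    linear_beta: float
    linear_se: float
    linear_pval: float
    quadratic_beta: float
    quadratic_se: float
    quadratic_pval: float
    vertex_score: float
    vertex_se: float
    n: int


def build_unweighted_score(cohort: CohortTable,
                           risk_alleles: np.ndarray | None = None) -> pd.Series:
    """Additive unweighted genetic score: per-individual risk-allele count.

    Dosages are oriented to the named risk allele (2 − d where the matrix
    counts the other allele); missing dosages are replaced by that SNP's
    cohort mean.  SNPs that are entirely missing are excluded with a
    warning.
    """
    import logging

    risk = np.asarray(risk_alleles if risk_alleles is not None else cohort.risk_alleles)
    counted = np.asarray(cohort.effect_alleles
                         if cohort.effect_alleles is not None else risk)
    dos = cohort.dosages.to_numpy(float).copy()
    flip = risk != counted
    dos[:, flip] = 2.0 - dos[:, flip]

    counts = (~np.isnan(dos)).sum(axis=0)
    col_means = np.where(counts > 0, np.nansum(dos, axis=0) / np.maximum(counts, 1), np.nan)
    all_missing = counts == 0
    if all_missing.any():
        logging.getLogger(__name__).warning(
            "%d SNP(s) entirely missing; excluded from score", int(all_missing.sum()))
        dos = dos[:, ~all_missing]
        col_means = col_means[~all_missing]
    idx = np.where(np.isnan(dos))
    dos[idx] = col_means[idx[1]]
    return pd.Series(dos.sum(axis=1), index=cohort.dosages.index, name="genetic_score")


def _stable_bins(values: np.ndarray, q: int) -> np.ndarray:
    """Equal-count bins (±1) by stable rank; ties broken by input order."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * q) // n


def quantile_summary(score: pd.Series, outcome: pd.Series, q: int = 5,
                     transpose: bool = False) -> pd.DataFrame:
    """Mean outcome (with 95% normal CI) per score quantile bin.

    ``q`` is 5 for quintiles, 10 for deciles (any integer ≥ 2 works as
    long as the score has at least ``q`` distinct values).  With
    ``transpose`` the roles are swapped: mean score per outcome bin,
    mirroring plots with reproductive success on the x-axis.
    """
    if transpose:
        return quantile_summary(outcome, score, q=q, transpose=False).rename(
            columns={"mean_outcome": "mean_score"})
    df = pd.DataFrame({"score": score, "outcome": outcome}).dropna()
    if df["score"].nunique() < q:
        raise ValueError(f"cannot form {q} bins from {df['score'].nunique()} distinct scores")
    bins = _stable_bins(df["score"].to_numpy(), q)
    rows = []
    for b in range(q):
        vals = df["outcome"].to_numpy()[bins == b]
        nb = len(vals)
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(nb)) if nb > 1 else float("nan")
        rows.append({"bin": b + 1, "n": nb, "mean_outcome": mean,
                     "ci_low": mean - _Z95 * sem, "ci_high": mean + _Z95 * sem})
    return pd.DataFrame(rows)


def _ols(y: np.ndarray, X: np.ndarray):
    """Coefficients, SEs and residual df for an OLS fit (first column ones)."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    df = len(y) - X.shape[1]
    if df <= 0 or rank < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix rank-deficient")
    resid = y - X @ coef
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return coef, np.sqrt(np.diag(cov)), cov, df


def centile_removal_scan(
    score: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    fractions: list[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    case_flag: pd.Series | None = None,
    exclude_cases: bool = False,
) -> list[ScoreScanResult]:
    """Linear score–outcome regressions, cumulatively removing the top tail.

    For each fraction f the individuals with the highest f·n scores
    (stable rank, ties by input order) are dropped before fitting
    ``outcome ~ score + covariates`` by least squares.  ``fractions`` must
    be ascending; f = 0 is the plain full-sample regression.  With
    ``exclude_cases`` flagged individuals are removed throughout.
    """
    fractions = list(fractions)
    if sorted(fractions) != fractions:
        raise ValueError("fractions must be sorted ascending")
    df = pd.DataFrame({"score": score, "outcome": outcome})
    if covariates is not None:
        df = df.join(covariates)
    if exclude_cases:
        if case_flag is None:
            raise ValueError("exclude_cases requires a case_flag")
        df = df.loc[case_flag.reindex(df.index).fillna(0) == 0]
    df = df.dropna()
    if df.empty:
        raise ValueError("no complete cases to fit")
    s = df["score"].to_numpy()
    order = np.argsort(s, kind="stable")

    results = []
    n_total = len(df)
    for f in fractions:
        n_keep = n_total - int(np.floor(f * n_total))
        if n_keep < 3:
            raise ValueError(f"removal fraction {f} leaves too few individuals")
        keep_idx = order[:n_keep]
        sub = df.iloc[keep_idx]
        X = np.column_stack([
            np.ones(len(sub)),
            sub["score"].to_numpy(),
            sub.drop(columns=["score", "outcome"]).to_numpy(float),
        ])
        coef, ses, _, _ = _ols(sub["outcome"].to_numpy(), X)
        beta, se = float(coef[1]), float(ses[1])
        results.append(ScoreScanResult(
            removal_fraction=float(f), beta=beta, se=se,
            ci_low=beta - _Z95 * se, ci_high=beta + _Z95 * se,
            pval=float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else float("nan"),
            n=len(sub),
        ))
    return results


def quadratic_fit(
    score: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    by_sex: pd.Series | None = None,
) -> list[QuadraticFit]:
    """Quadratic regression outcome ~ score + score² (+ covariates).

    The score is mean-centered before squaring for numerical
    conditioning; reported coefficients are mapped back to the raw-score
    scale (the quadratic coefficient is unchanged by centering, the
    linear one is b₁ − 2·b₂·mean).  When ``by_sex`` is given, female (0)
    and male (1) strata are fitted separately in addition to the combined
    fit; any ``sex`` column in the covariates is dropped within strata.
    """
    groups: list[tuple[str, pd.Index]] = [("combined", score.index)]
    if by_sex is not None:
        groups += [("female", score.index[by_sex == 0]),
                   ("male", score.index[by_sex == 1])]

    fits = []
    for name, idx in groups:
        df = pd.DataFrame({"score": score, "outcome": outcome}).loc[idx]
        if covariates is not None:
            cov = covariates.loc[idx]
            if name != "combined" and "sex" in cov.columns:
                cov = cov.drop(columns=["sex"])
            df = df.join(cov)
        df = df.dropna()
        if len(df) < df.shape[1] + 2:  # not enough rows to fit
            fits.append(QuadraticFit(name, *([float("nan")] * 8), n=len(df)))
            continue
        s = df["score"].to_numpy()
        mean = s.mean()
        sc = s - mean
        X = np.column_stack([
            np.ones(len(df)), sc, sc**2,
            df.drop(columns=["score", "outcome"]).to_numpy(float),
        ])
        try:
            coef, ses, cov_mat, _ = _ols(df["outcome"].to_numpy(), X)
        except np.linalg.LinAlgError:
            fits.append(QuadraticFit(name, *([float("nan")] * 8), n=len(df)))
            continue
        b1c, b2 = float(coef[1]), float(coef[2])
        # raw-scale linear coefficient via the polynomial identity
        b1 = b1c - 2 * b2 * mean
        var1c, var2 = cov_mat[1, 1], cov_mat[2, 2]
        cov12 = cov_mat[1, 2]
        se1 = float(np.sqrt(var1c + 4 * mean**2 * var2 - 4 * mean * cov12))
        se2 = float(np.sqrt(var2))
        if b2 != 0:
            vertex = mean - b1c / (2 * b2)
            g = np.array([-1 / (2 * b2), b1c / (2 * b2**2)])
            v_var = g @ cov_mat[1:3, 1:3] @ g
            v_se = float(np.sqrt(v_var)) if v_var > 0 else float("nan")
        else:
            vertex, v_se = float("nan"), float("nan")
        fits.append(QuadraticFit(
            group=name,
            linear_beta=b1, linear_se=se1,
            linear_pval=float(2 * stats.norm.sf(abs(b1) / se1)) if se1 > 0 else float("nan"),
            quadratic_beta=b2, quadratic_se=se2,
            quadratic_pval=float(2 * stats.norm.sf(abs(b2) / se2)) if se2 > 0 else float("nan"),
            vertex_score=float(vertex), vertex_se=v_se, n=len(df),
        ))
    return fits
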