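"""Synthetic cohorts, two-sample GWAS summary statistics and LD-score panels.

Everything downstream of this module — association testing, harmonization,
the MR estimator suite, the genetic-score nonlinearity scans and the
LD-score genetic-correlation estimator — is exercised on data generated
here with a *known* causal architecture, so parameter recovery can be
checked against ground truth.

The generating model is the standard additive liability model: per-SNP
dosages are binomial(2, allele frequency) under Hardy–Weinberg
equilibrium, a weighted sum of dosages forms a genetic liability score
scaled to explain a configurable fraction of liability variance, and
fitness-related phenotypes (number of children, age at first birth,
number of sexual partners) derive from that score through a linear,
quadratic or cliff-edge map plus covariate effects and Gaussian noise.
The cliff-edge map implements the hypothesis that fitness rises with
liability up to a threshold and then drops sharply: a flat penalty is
applied above a configurable quantile of the genetic score.

A single genetic architecture (MAFs, allele labels, per-SNP liability
effects) is drawn once per seed and shared by :func:`gen_cohort` and
:func:`gen_two_sample_summary`, so an exposure summary table and a
cohort-derived outcome GWAS from the same config refer to the same
variants and can be harmonized against each other.  Exposure and outcome
noise use disjoint substreams of the master seed, mirroring the
non-overlapping samples of a two-sample design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream

__all__ = [
    "SimulationConfig",
    "CohortTable",
    "gen_cohort",
    "gen_two_sample_summary",
    "gen_ldsc_panel",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the scale of the real study design at desk size: a
    polygenic binary-liability exposure instrumented by ~100 independent
    genome-wide-significant SNPs estimated in a case-control GWAS
    (n ≈ 145k total), with fitness outcomes measured in a separate
    population cohort (summary n ≈ 300k; individual-level n = 20k).
    """

    n_individuals: int = 20_000
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    true_causal_effect: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    exposure_h2: float = 0.05
    nonlinearity: str = "linear"  # linear | quadratic | cliff_edge
    quadratic_coefficient: float = 0.0
    cliff_threshold_quantile: float = 0.9
    cliff_penalty: float = 0.0
    n_exposure_sample: int = 145_000
    n_outcome_sample: int = 300_000
    seed: int = 0
    # plumbing knobs
    allele_swap_fraction: float = 0.0
    palindromic_fraction: float = 0.1
    dosage_missing_rate: float = 0.02
    prevalence: float = 0.004
    count_model: str = "gaussian"  # gaussian | poisson
    liability_weights: str = "architecture"  # architecture | unit

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be at least 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be at least 1")
        for name in ("invalid_fraction", "exposure_h2", "allele_swap_fraction",
                     "palindromic_fraction", "dosage_missing_rate", "prevalence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.cliff_threshold_quantile < 1.0):
            raise ValueError("cliff_threshold_quantile must be in (0, 1)")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be non-negative")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.nonlinearity not in ("linear", "quadratic", "cliff_edge"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.liability_weights not in ("architecture", "unit"):
            raise ValueError(f"unknown liability_weights {self.liability_weights!r}")
        if self.dosage_missing_rate >= 1.0:
            raise ValueError("dosage_missing_rate must be < 1 (mean imputation needs data)")


@dataclass
class CohortTable:
    """Individual-level dosages, phenotypes and covariates.

    ``dosages`` is individuals × SNPs with values in [0, 2] or NaN,
    counting the effect allele; ``phenotypes`` carries
    number_of_children, age_at_first_birth (female-only, NaN elsewhere),
    n_sexual_partners, sex (male=1), age, pc1..pc10 and case_flag.
    ``risk_alleles`` names, per SNP, the liability-*increasing* allele.
    """

    dosages: pd.DataFrame
    phenotypes: pd.DataFrame
    risk_alleles: np.ndarray
    effect_alleles: np.ndarray | None = None  # allele counted by `dosages`
    other_alleles: np.ndarray | None = None
    liability_score: np.ndarray | None = None  # genetic score, variance = exposure_h2 (truth)


def _draw_alleles(rng: np.random.Generator, n_snps: int, palindromic_fraction: float):
    """Effect/other allele pairs, a configurable share of them palindromic."""
    eff = rng.choice(_BASES, size=n_snps)
    pal = rng.random(n_snps) < palindromic_fraction
    other = np.empty(n_snps, dtype="<U1")
    for j in range(n_snps):
        if pal[j]:
            other[j] = _COMPLEMENT[eff[j]]
        else:
            choices = [b for b in "ACGT" if b != eff[j] and b != _COMPLEMENT[eff[j]]]
            other[j] = rng.choice(choices)
    return eff.astype("<U1"), other


def _architecture(cfg: SimulationConfig) -> dict:
    """Draw the shared genetic architecture for one seed.

    Returns MAFs, effect-allele frequencies, allele labels and the true
    per-allele liability effects b_j, scaled so Σ 2·f(1−f)·b² equals
    ``exposure_h2`` on the unit-variance liability scale.
    """
    rng = substream(cfg.seed, "summary-architecture")
    m = cfg.n_snps
    mafs = rng.uniform(*cfg.maf_range, size=m)
    # instrument sets emulate genome-wide-significant hits: effect
    # magnitudes are bounded away from zero (a floor of 0.5 relative
    # units before the h² rescaling), so estimated signs are reliable and
    # orientation to the exposure-increasing allele is well defined
    b = rng.choice([-1.0, 1.0], size=m) * (0.5 + np.abs(rng.normal(size=m)))
    eff, other = _draw_alleles(rng, m, cfg.palindromic_fraction)
    # effect allele is the minor allele for roughly half the SNPs
    freq = np.where(rng.random(m) < 0.5, mafs, 1 - mafs)
    denom = np.sum(2 * freq * (1 - freq) * b**2)
    if denom > 0 and cfg.exposure_h2 > 0:
        b = b * np.sqrt(cfg.exposure_h2 / denom)
    snp_ids = np.array([f"rs{j + 1:05d}" for j in range(m)])
    return {"snp_ids": snp_ids, "mafs": mafs, "freq": freq, "b": b,
            "eff": eff, "other": other}


def _nonlinear_map(score: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Expected outcome shift as a function of the genetic liability score."""
    mu = cfg.true_causal_effect * score
    if cfg.nonlinearity == "quadratic":
        mu = mu + cfg.quadratic_coefficient * score**2
    elif cfg.nonlinearity == "cliff_edge":
        thresh = np.quantile(score, cfg.cliff_threshold_quantile)
        mu = mu + cfg.cliff_penalty * (score > thresh)
    return mu


def gen_cohort(config: SimulationConfig) -> CohortTable:
    """Simulate an individual-level cohort under the liability model.

    The heritable liability score is the weighted dosage sum (weights are
    the architecture's per-allele effects, or all-ones with
    ``liability_weights='unit'``), centered and scaled to variance
    ``exposure_h2`` on the unit-variance liability scale; the configured
    linear/quadratic/cliff-edge map acts on this score, and independent
    environmental noise is added per phenotype afterwards.  Schizophrenia
    case status is assigned by liability threshold at the configured
    prevalence (full liability = score + √(1−h²)·e).  Deterministic
    given ``config.seed``.
    """
    cfg = config
    n, m = cfg.n_individuals, cfg.n_snps
    arch = _architecture(cfg)

    rng_geno = substream(cfg.seed, "cohort-genotypes")
    rng_cov = substream(cfg.seed, "cohort-covariates")
    rng_noise = substream(cfg.seed, "cohort-noise")
    rng_miss = substream(cfg.seed, "cohort-missing")

    dosages = rng_geno.binomial(2, arch["freq"], size=(n, m)).astype(float)

    if cfg.liability_weights == "unit":
        weights = np.ones(m)
        risk = arch["eff"].copy()
    else:
        weights = arch["b"]
        risk = np.where(weights >= 0, arch["eff"], arch["other"])
    raw = dosages @ weights
    sd = raw.std()
    z = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
    # genetic liability score on the liability scale: variance exposure_h2,
    # so that per-SNP outcome effects equal true_causal_effect · b_j and the
    # two-sample summary generator describes the same causal system
    score = np.sqrt(cfg.exposure_h2) * z

    liability = score + np.sqrt(1 - cfg.exposure_h2) * rng_noise.normal(size=n)
    case_flag = (liability > stats.norm.ppf(1 - cfg.prevalence)).astype(int)

    sex = rng_cov.binomial(1, 0.46, size=n)  # male = 1
    age = rng_cov.integers(39, 73, size=n).astype(float)
    pcs = rng_cov.normal(size=(n, 10))

    shift = _nonlinear_map(score, cfg)
    age_c = (age - age.mean()) / age.std()

    def count_pheno(base, sdev, stream):
        mu = base + shift + 0.05 * age_c - 0.05 * sex + 0.02 * pcs[:, 0]
        if cfg.count_model == "poisson":
            lam = np.clip(mu, 0.05, None)
            return stream.poisson(lam).astype(float)
        vals = np.round(mu + stream.normal(0, sdev, size=n))
        return np.clip(vals, 0, None)

    children = count_pheno(1.8, 1.1, rng_noise)
    partners = count_pheno(5.8, 4.0, rng_noise)
    partners[rng_miss.random(n) < 0.05] = np.nan

    afb = 25.4 + shift + 0.3 * age_c + 0.05 * pcs[:, 0] + rng_noise.normal(0, 4.5, size=n)
    afb[sex == 1] = np.nan  # measured in females only
    afb[(sex == 0) & (rng_miss.random(n) < 0.10)] = np.nan

    if cfg.dosage_missing_rate > 0:
        mask = rng_miss.random((n, m)) < cfg.dosage_missing_rate
        dosages[mask] = np.nan

    ids = pd.Index([f"id{i:06d}" for i in range(n)], name="iid")
    pheno = pd.DataFrame(
        {
            "number_of_children": children,
            "age_at_first_birth": afb,
            "n_sexual_partners": partners,
            "sex": sex,
            "age": age,
            **{f"pc{k + 1}": pcs[:, k] for k in range(10)},
            "case_flag": case_flag,
        },
        index=ids,
    )
    dos = pd.DataFrame(dosages, index=ids, columns=arch["snp_ids"])
    return CohortTable(dosages=dos, phenotypes=pheno, risk_alleles=risk,
                       effect_alleles=arch["eff"], other_alleles=arch["other"],
                       liability_score=score)


def gen_two_sample_summary(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate exposure and outcome GWAS summary statistics for one instrument set.

    Estimates add noise to the architecture's true effects at
    se = 1/√(2·f(1−f)·N).  The true outcome effect is
    ``true_causal_effect``·b_j plus a pleiotropic intercept α_j on the
    invalid subset (zero-mean when balanced, mean ``pleiotropy_mean`` when
    directional).  A configurable fraction of outcome records have their
    allele labels swapped (effect sign flipped, frequency complemented) to
    exercise harmonization.
    """
    cfg = config
    m = cfg.n_snps
    arch = _architecture(cfg)
    freq, b = arch["freq"], arch["b"]

    rng_arch = substream(cfg.seed, "summary-pleiotropy")
    rng_exp = substream(cfg.seed, "summary-exposure-noise")
    rng_out = substream(cfg.seed, "summary-outcome-noise")

    alpha = np.zeros(m)
    if cfg.pleiotropy_mode != "none" and cfg.invalid_fraction > 0:
        k_invalid = int(round(cfg.invalid_fraction * m))
        idx = rng_arch.choice(m, size=k_invalid, replace=False)
        mean = cfg.pleiotropy_mean if cfg.pleiotropy_mode == "directional" else 0.0
        alpha[idx] = rng_arch.normal(mean, cfg.pleiotropy_sd, size=k_invalid)

    se_exp = 1.0 / np.sqrt(2 * freq * (1 - freq) * cfg.n_exposure_sample)
    se_out = 1.0 / np.sqrt(2 * freq * (1 - freq) * cfg.n_outcome_sample)
    beta_exp = b + rng_exp.normal(size=m) * se_exp
    # directional pleiotropy is defined relative to the exposure-increasing
    # allele (the orientation MR analyses, and the InSIDE assumption, use);
    # on the recorded allele its sign therefore follows sign(b)
    alpha_oriented = np.where(b >= 0, alpha, -alpha)
    beta_out = cfg.true_causal_effect * b + alpha_oriented + rng_out.normal(size=m) * se_out

    eaf_exp = np.clip(freq + rng_exp.normal(0, 0.003, size=m), 0.001, 0.999)
    eaf_out = np.clip(freq + rng_out.normal(0, 0.003, size=m), 0.001, 0.999)

    def table(beta, se, eaf, ea, oa, n, rng):
        z = beta / se
        return pd.DataFrame(
            {
                "snp": arch["snp_ids"],
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pval": 2 * stats.norm.sf(np.abs(z)),
                "n": n,
                "info": rng.uniform(0.9, 1.0, size=m).round(4),
            }
        )

    exposure = table(beta_exp, se_exp, eaf_exp, arch["eff"], arch["other"],
                     cfg.n_exposure_sample, rng_exp)

    ea_out, oa_out = arch["eff"].copy(), arch["other"].copy()
    beta_out_rec, eaf_out_rec = beta_out.copy(), eaf_out.copy()
    if cfg.allele_swap_fraction > 0:
        swap = rng_out.random(m) < cfg.allele_swap_fraction
        ea_out[swap], oa_out[swap] = oa_out[swap], ea_out[swap].copy()
        beta_out_rec[swap] *= -1
        eaf_out_rec[swap] = 1 - eaf_out_rec[swap]
    outcome = table(beta_out_rec, se_out, eaf_out_rec, ea_out, oa_out,
                    cfg.n_outcome_sample, rng_out)
    return exposure, outcome


def gen_ldsc_panel(M: int, h2_1: float, h2_2: float, rg: float,
                   N1: int, N2: int, seed: int, mean_ld: float = 40.0):
    """Simulate a per-SNP z-score panel under the LD-score regression model.

    LD scores l_j are drawn right-skewed (1 + gamma); per SNP the z-score
    pair is bivariate normal with E[z1²] = 1 + N1·h2_1·l_j/M,
    E[z1·z2] = √(N1·N2)·rg·√(h2_1·h2_2)·l_j/M and no sample-overlap term.
    Deterministic given ``seed``.
    """
    from .ldsc import LDScorePanel

    if not (-1.0 <= rg <= 1.0):
        raise ValueError(f"|rg| must be ≤ 1, got {rg}")
    for name, h2 in (("h2_1", h2_1), ("h2_2", h2_2)):
        if not (0.0 <= h2 <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {h2}")
    if M < 2:
        raise ValueError("M must be at least 2")

    rng = substream(seed, "ldsc-panel")
    shape = 2.0
    ld = 1.0 + rng.gamma(shape, (mean_ld - 1.0) / shape, size=M)

    v1 = 1.0 + N1 * h2_1 * ld / M
    v2 = 1.0 + N2 * h2_2 * ld / M
    c = np.sqrt(N1 * N2) * rg * np.sqrt(h2_1 * h2_2) * ld / M
    resid = v2 - c**2 / v1
    if np.any(resid < -1e-9) or np.any(v1 <= 0):
        j = int(np.argmin(resid))
        raise ValueError(
            "per-SNP z covariance not positive semi-definite "
            f"(snp {j}: var1={v1[j]:.4g}, var2={v2[j]:.4g}, cov={c[j]:.4g}; "
            f"h2_1={h2_1}, h2_2={h2_2}, rg={rg}, N1={N1}, N2={N2}, M={M})"
        )
    x1 = rng.normal(size=M)
    x2 = rng.normal(size=M)
    z1 = np.sqrt(v1) * x1
    z2 = c / np.sqrt(v1) * x1 + np.sqrt(np.clip(resid, 0, None)) * x2

    snp_ids = np.array([f"rs{j + 1:06d}" for j in range(M)])
    return LDScorePanel(snp_ids=snp_ids, ld_score=ld, z1=z1, z2=z2, n1=N1, n2=N2)
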