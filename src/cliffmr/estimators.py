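"""The two-sample MR estimator suite with instrument diagnostics.

Five complementary causal-effect estimators operate on harmonized
instruments (per-SNP exposure and outcome effects oriented to the
exposure-increasing allele):

* **IVW** — inverse-variance weighted meta-analysis of Wald ratios,
  equivalently a zero-intercept weighted regression of outcome on
  exposure effects; consistent only if every instrument is valid (or
  pleiotropy is balanced, under the multiplicative random-effects model).
* **MR-Egger** — the same regression with a free intercept; the intercept
  estimates average directional pleiotropy, the slope remains consistent
  under the InSIDE assumption.
* **Weighted median** — consistent if at least half the weight comes from
  valid instruments.
* **Simple / weighted mode** — consistent if the largest cluster of
  similar per-SNP ratio estimates comes from valid instruments.

Diagnostics: Cochran's Q (heterogeneity/overdispersion), the mean
F-statistic (instrument strength; >10 conventionally adequate) and
I²GX (regression-dilution reliability of MR-Egger; >0.9 desired).

Binary-liability exposures are rescaled per doubling of odds by the
factor 0.693 (ln 2 at the printed precision), and log-odds outcomes may
be exponentiated to odds ratios; both transformations leave the Wald
p-value untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._rng import substream
from .harmonize import harmonize

__all__ = [
    "MREstimate",
    "DOUBLING_FACTOR",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mode_estimator",
    "cochran_q",
    "mean_f_statistic",
    "i2_gx",
    "scale_binary_exposure",
    "to_odds_ratio",
    "run_mr_suite",
]

#: per-doubling-of-odds rescaling constant (ln 2 to three decimals; kept
#: at exactly 0.693 for bit-compatibility with published tables)
DOUBLING_FACTOR = 0.693

_Z95 = 1.96


@dataclass
class MREstimate:
    """One causal-effect estimate with its uncertainty and provenance."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    scale: str = "raw"  # raw | per_doubling_odds | odds_ratio
    diagnostics: dict = field(default_factory=dict)


def _finish(method: str, beta: float, se: float, k: int, diagnostics: dict | None = None,
            pval: float | None = None) -> MREstimate:
    if pval is None:
        pval = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else (0.0 if beta else 1.0)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z95 * se),
        ci_high=float(beta + _Z95 * se),
        pval=float(pval),
        n_snps=int(k),
        diagnostics=diagnostics or {},
    )


def _columns(instruments: pd.DataFrame):
    h = instruments
    return (
        h["beta_exp"].to_numpy(float),
        h["se_exp"].to_numpy(float),
        h["beta_out"].to_numpy(float),
        h["se_out"].to_numpy(float),
    )


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-instrument causal estimate beta_out/beta_exp (first-order SE)."""
    if beta_exp == 0:
        raise ZeroDivisionError("Wald ratio undefined: beta_exp is zero")
    return _finish("wald", beta_out / beta_exp, abs(se_out / beta_exp), 1)


def cochran_q(instruments: pd.DataFrame, beta: float | None = None) -> tuple[float, int]:
    """Cochran's Q about the IVW estimate (or a supplied slope); df = k − 1."""
    be, _, bo, so = _columns(instruments)
    w = 1.0 / so**2
    if beta is None:
        beta = float(np.sum(w * bo * be) / np.sum(w * be**2))
    q = float(np.sum(w * (bo - beta * be) ** 2))
    return q, len(be) - 1


def ivw(instruments: pd.DataFrame) -> MREstimate:
    """Random-effects IVW: zero-intercept WLS of outcome on exposure effects.

    Weights are 1/se_out²; the fixed-effect SE is inflated multiplicatively
    by √(Q/(k−1)) when Cochran's Q exceeds its degrees of freedom, which
    accommodates balanced pleiotropy as overdispersion.
    """
    k = len(instruments)
    if k == 0:
        raise ValueError("IVW needs at least one instrument")
    be, _, bo, so = _columns(instruments)
    if k == 1:  # exact reduction to the Wald ratio
        return _finish("ivw", bo[0] / be[0], abs(so[0] / be[0]), 1)
    w = 1.0 / so**2
    beta = float(np.sum(w * bo * be) / np.sum(w * be**2))
    se_fixed = float(1.0 / np.sqrt(np.sum(w * be**2)))
    diagnostics: dict = {}
    if k >= 2:
        q, q_df = cochran_q(instruments, beta)
        se = se_fixed * max(1.0, np.sqrt(q / q_df))
        diagnostics = {"cochran_q": q, "q_df": q_df}
    else:
        se = se_fixed
    return _finish("ivw", beta, se, k, diagnostics)


def mr_egger(instruments: pd.DataFrame) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: WLS of beta_out on beta_exp with a free intercept.

    Returns ``(slope, intercept)``.  SEs use the theoretical WLS covariance
    inflated by max(1, √(Q_egger/(k−2))) for k > 2.  Instruments must
    already be oriented beta_exp > 0 (harmonization's job).
    """
    k = len(instruments)
    if k < 2:
        raise ValueError("MR-Egger needs at least two instruments")
    be, _, bo, so = _columns(instruments)
    if np.ptp(be) == 0:
        raise ValueError("MR-Egger undefined: no spread in exposure effects")
    w = 1.0 / so**2
    X = sm.add_constant(be)
    res = sm.WLS(bo, X, weights=w).fit()
    intercept_b, slope_b = res.params
    # theoretical (fixed) covariance with known outcome variances
    fixed_se = np.sqrt(np.diag(res.normalized_cov_params))
    if k > 2:
        q_egger = float(res.ssr)  # weighted residual SS
        infl = max(1.0, np.sqrt(q_egger / (k - 2)))
    else:
        q_egger, infl = 0.0, 1.0
    diagnostics = {"q_egger": q_egger, "q_df": k - 2}
    slope = _finish("egger_slope", slope_b, fixed_se[1] * infl, k, diagnostics)
    intercept = _finish("egger_intercept", intercept_b, fixed_se[0] * infl, k, diagnostics)
    return slope, intercept


def _ratio_weights(be, so, weighted: bool):
    if weighted:
        return be**2 / so**2
    return np.ones_like(be)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w  # cumulative weight at each ratio's midpoint
    if cum[0] >= 0.5:
        return float(r[0])
    below = int(np.searchsorted(cum, 0.5, side="left")) - 1
    if below >= len(r) - 1:
        return float(r[-1])
    span = cum[below + 1] - cum[below]
    frac = 0.0 if span == 0 else (0.5 - cum[below]) / span
    return float(r[below] + frac * (r[below + 1] - r[below]))


def _parametric_bootstrap(point_fn, instruments, n_boot, seed, stage):
    """SD of a ratio-based estimator over parametric redraws of the inputs."""
    if n_boot <= 0:
        return float("nan")
    be, se_e, bo, so = _columns(instruments)
    rng = substream(seed, stage)
    stats_ = np.empty(n_boot)
    for b in range(n_boot):
        be_b = be + se_e * rng.standard_normal(be.shape)
        bo_b = bo + so * rng.standard_normal(bo.shape)
        stats_[b] = point_fn(be_b, bo_b)
    return float(np.std(stats_, ddof=1))


def weighted_median(instruments: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator over per-SNP Wald ratios.

    The estimate is the interpolated ratio at which the normalized
    cumulative inverse-variance weight crosses one half; the SE comes from
    a seeded parametric bootstrap (``n_boot = 0`` skips it, SE = NaN).
    """
    k = len(instruments)
    if k < 3:
        raise ValueError("weighted median needs at least three instruments")
    be, _, bo, so = _columns(instruments)
    weights = _ratio_weights(be, so, weighted=True)
    if not np.any(weights > 0):
        raise ValueError("weighted median undefined: all weights zero")
    beta = _weighted_median_point(bo / be, weights)

    def point(be_b, bo_b):
        w = _ratio_weights(be_b, so, weighted=True)
        return _weighted_median_point(bo_b / be_b, w)

    se = _parametric_bootstrap(point, instruments, n_boot, seed, "weighted-median-boot")
    est = _finish("weighted_median", beta, se, k) if se == se and se > 0 else MREstimate(
        "weighted_median", float(beta), float(se), float("nan"), float("nan"),
        float("nan"), k)
    return est


def _silverman_bandwidth(ratios: np.ndarray, phi: float) -> float:
    """Modified Silverman rule on the MAD scale, scaled by the tuning parameter."""
    k = len(ratios)
    sd = np.std(ratios, ddof=1) if k > 1 else 0.0
    mad = 1.4826 * np.median(np.abs(ratios - np.median(ratios)))
    candidates = [v for v in (sd, mad) if v > 0]
    if not candidates:
        return 0.0
    return phi * 0.9 * min(candidates) * k ** (-1 / 5)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, h: float) -> float:
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 10_000)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
    return float(grid[int(np.argmax(dens))])  # first max → smallest grid value


def mode_estimator(instruments: pd.DataFrame, weighted: bool = False, phi: float = 0.5,
                   n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Mode-based estimator: argmax of a normal-kernel density over Wald ratios.

    Bandwidth is ``phi`` times a modified Silverman rule using the median
    absolute deviation; the weighted variant weights each kernel by
    beta_exp²/se_out².  All-identical ratios are degenerate: the common
    ratio is returned with SE 0 and a ``degenerate`` diagnostic flag.
    """
    k = len(instruments)
    if k < 3:
        raise ValueError("mode estimator needs at least three instruments")
    be, _, bo, so = _columns(instruments)
    ratios = bo / be
    name = "weighted_mode" if weighted else "simple_mode"
    h = _silverman_bandwidth(ratios, phi) if np.ptp(ratios) > 0 else 0.0
    if h == 0:
        est = _finish(name, ratios[0], 0.0, k, {"degenerate": True}, pval=float("nan"))
        return est
    weights = _ratio_weights(be, so, weighted)
    beta = _mode_point(ratios, weights / weights.sum(), h)

    def point(be_b, bo_b):
        r = bo_b / be_b
        hb = _silverman_bandwidth(r, phi)
        if hb == 0:
            return r[0]
        w = _ratio_weights(be_b, so, weighted)
        return _mode_point(r, w / w.sum(), hb)

    se = _parametric_bootstrap(point, instruments, n_boot, seed, f"{name}-boot")
    if se == se and se > 0:
        return _finish(name, beta, se, k)
    return MREstimate(name, float(beta), float(se), float("nan"), float("nan"),
                      float("nan"), k)


def mean_f_statistic(instruments: pd.DataFrame) -> float:
    """Mean instrument-strength F: mean of beta_exp²/se_exp² across SNPs."""
    be, se_e, _, _ = _columns(instruments)
    if len(be) == 0:
        raise ValueError("no instruments")
    return float(np.mean(be**2 / se_e**2))


def i2_gx(instruments: pd.DataFrame, weighted: bool = True) -> float:
    """I²GX: reliability of the SNP-exposure effects for MR-Egger.

    The weighted variant uses inverse-variance weights about the IVW mean
    of beta_exp; the unweighted variant uses the plain mean with the mean
    squared SE as the common variance.  Truncated at zero.
    """
    be, se_e, _, _ = _columns(instruments)
    k = len(be)
    if k < 2:
        raise ValueError("I²GX needs at least two instruments")
    if weighted:
        w = 1.0 / se_e**2
        mean = np.sum(w * be) / np.sum(w)
        q_gx = float(np.sum(w * (be - mean) ** 2))
    else:
        mean = be.mean()
        q_gx = float(np.sum((be - mean) ** 2) / np.mean(se_e**2))
    if q_gx <= 0:
        return 0.0
    return max(0.0, (q_gx - (k - 1)) / q_gx)


def scale_binary_exposure(est: MREstimate) -> MREstimate:
    """Rescale a binary-liability-exposure estimate per doubling of odds (×0.693)."""
    if est.scale != "raw":
        raise ValueError(f"cannot rescale an estimate already on scale {est.scale!r}")
    c = DOUBLING_FACTOR
    return replace(est, beta=est.beta * c, se=est.se * c,
                   ci_low=est.ci_low * c, ci_high=est.ci_high * c,
                   scale="per_doubling_odds")


def to_odds_ratio(est: MREstimate, binary_exposure: bool = False) -> MREstimate:
    """Exponentiate a log-odds-scale estimate to an odds ratio.

    With ``binary_exposure`` the per-doubling rescaling (×0.693) is folded
    in first when the estimate is still raw.  CI bounds transform
    monotonically; the p-value is that of the underlying Wald test.
    """
    if est.scale == "odds_ratio":
        raise ValueError("estimate is already an odds ratio")
    if binary_exposure and est.scale == "raw":
        est = scale_binary_exposure(est)
    return replace(est, beta=float(np.exp(est.beta)),
                   ci_low=float(np.exp(est.ci_low)), ci_high=float(np.exp(est.ci_high)),
                   scale="odds_ratio")


def run_mr_suite(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    binary_exposure: bool = False,
    binary_outcome: bool = False,
    palindromic_policy: str = "infer_by_eaf",
    phi: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Harmonize and run the full five-method estimator suite.

    Returns one row per method (ivw, egger_slope, egger_intercept,
    weighted_median, simple_mode, weighted_mode) with beta/CI/p on the
    requested reporting scale plus shared diagnostics (Cochran's Q, mean
    F, unweighted and weighted I²GX).  The Egger intercept is never
    rescaled to the exposure's doubling-of-odds units: it lives on the
    outcome-per-SNP scale.
    """
    h = harmonize(exposure, outcome, palindromic_policy)
    if len(h) == 0:
        raise ValueError("no instruments survived harmonization")
    slope, intercept = mr_egger(h) if len(h) >= 2 else (None, None)
    ests: list[MREstimate] = [ivw(h)]
    if slope is not None:
        ests += [slope]
    if len(h) >= 3:
        ests += [
            weighted_median(h, n_boot=n_boot, seed=seed),
            mode_estimator(h, weighted=False, phi=phi, n_boot=n_boot, seed=seed),
            mode_estimator(h, weighted=True, phi=phi, n_boot=n_boot, seed=seed),
        ]

    if binary_exposure:
        ests = [scale_binary_exposure(e) if e.scale == "raw" else e for e in ests]
    if binary_outcome:
        ests = [to_odds_ratio(e) for e in ests]
    if intercept is not None:
        # the pleiotropy intercept is reported on its native (raw) scale,
        # exponentiated only when the outcome itself is log-odds
        ests.append(to_odds_ratio(intercept) if binary_outcome else intercept)

    q, q_df = cochran_q(h) if len(h) >= 2 else (float("nan"), 0)
    diag = {
        "cochran_q": q,
        "q_df": q_df,
        "mean_f": mean_f_statistic(h),
        "i2_gx": i2_gx(h, weighted=True) if len(h) >= 2 else float("nan"),
        "i2_gx_unweighted": i2_gx(h, weighted=False) if len(h) >= 2 else float("nan"),
    }
    rows = []
    for e in ests:
        rows.append(
            {
                "method": e.method,
                "beta": e.beta,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pval": e.pval,
                "n_snps": e.n_snps,
                "scale": e.scale,
                **diag,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["exclusions"] = h.attrs.get("exclusions", {})
    return table
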