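"""Causal estimators for two-sample Mendelian randomization.

All estimators consume a harmonized instrument table: per variant j, the
variant-exposure effect γ̂ⱼ with standard error σ_γⱼ and the
variant-outcome effect Γ̂ⱼ with standard error σ_Γⱼ, both expressed per
copy of the same effect allele.  The causal effect β is a log-odds ratio
of the outcome per 1-SD increment of the exposure; each estimator
reports β̂, its SE, a two-sided normal p-value, and OR = exp(β̂) with a
95% CI exp(β̂ ± 1.96·SE).

Estimators follow the scikit-learn protocol (``fit`` + fitted
attributes with trailing underscores); the module-level functions are
thin wrappers returning an :class:`MREstimate`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .harmonize import as_instrument_frame

Z95 = 1.96


@dataclass
class MREstimate:
    """One method's causal estimate (a result-table row)."""

    method: str
    n_snps: int
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _two_sided_p(beta: float, se: float) -> float:
    if se <= 0:
        return 1.0 if beta == 0 else 0.0
    return float(min(1.0, 2.0 * stats.norm.sf(abs(beta) / se)))


def _extract(X) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    df = as_instrument_frame(X)
    g = df["gamma_hat"].to_numpy(float)
    sg = df["se_gamma"].to_numpy(float)
    G = df["big_gamma_hat"].to_numpy(float)
    sG = df["se_big_gamma"].to_numpy(float)
    if np.any(sG <= 0) or np.any(sg < 0):
        raise ValueError("standard errors must be positive")
    return g, sg, G, sG


class _MRRegressorBase(BaseEstimator):
    """Shared fit plumbing: extract arrays, build the estimate record."""

    method_name = "base"

    def fit(self, X, y=None):
        g, sg, G, sG = _extract(X)
        self.n_snps_ = len(g)
        self._fit_arrays(g, sg, G, sG)
        self.or_ = math.exp(self.beta_)
        self.ci_low_ = math.exp(self.beta_ - Z95 * self.se_)
        self.ci_high_ = math.exp(self.beta_ + Z95 * self.se_)
        self.pval_ = _two_sided_p(self.beta_, self.se_)
        return self

    @property
    def result_(self) -> MREstimate:
        return MREstimate(
            method=self.method_name,
            n_snps=self.n_snps_,
            beta=float(self.beta_),
            se=float(self.se_),
            pval=float(self.pval_),
            or_=float(self.or_),
            ci_low=float(self.ci_low_),
            ci_high=float(self.ci_high_),
            intercept=getattr(self, "intercept_", None),
            intercept_se=getattr(self, "intercept_se_", None),
            intercept_pval=getattr(self, "intercept_pval_", None),
        )


def wald_ratios(X) -> pd.DataFrame:
    """Per-variant ratio estimates bⱼ = Γ̂ⱼ/γ̂ⱼ with first-order SEs."""
    df = as_instrument_frame(X)
    g, sg, G, sG = _extract(df)
    if np.any(g == 0):
        zero = df.loc[g == 0, "SNP"].tolist() if "SNP" in df else np.where(g == 0)[0]
        raise ValueError(f"zero exposure effect for: {zero}")
    out = pd.DataFrame(
        {
            "SNP": df["SNP"] if "SNP" in df else np.arange(len(g)),
            "ratio": G / g,
            "se_ratio": sG / np.abs(g),
        }
    )
    return out


class IVWEstimator(_MRRegressorBase):
    """Inverse-variance-weighted estimator.

    Weighted regression of Γ̂ on γ̂ through the origin with weights
    1/σ_Γⱼ² — equivalently the inverse-variance meta-analysis of the
    per-variant Wald ratios.  ``re_model="multiplicative"`` inflates the
    fixed-effect SE by max(1, √(Q/(L−1))); with homogeneous instruments
    (Q ≤ L−1) the two models coincide.
    """

    method_name = "IVW"

    def __init__(self, re_model: str = "multiplicative"):
        self.re_model = re_model

    def _fit_arrays(self, g, sg, G, sG):
        if len(g) < 2:
            raise ValueError("IVW needs ≥ 2 instruments; use wald_ratios for one")
        if self.re_model not in ("fixed", "multiplicative"):
            raise ValueError(f"unknown re_model: {self.re_model!r}")
        w = 1.0 / sG**2
        denom = float(np.sum(w * g * g))
        beta = float(np.sum(w * g * G)) / denom
        se = denom**-0.5
        q = float(np.sum(w * (G - beta * g) ** 2))
        self.q_stat_ = q
        if self.re_model == "multiplicative":
            se *= max(1.0, math.sqrt(q / (len(g) - 1)))
        self.beta_, self.se_ = beta, se


class EggerEstimator(_MRRegressorBase):
    """MR-Egger regression.

    Weighted least squares of Γ̂ on γ̂ *with* an intercept; instruments
    are first oriented so γ̂ⱼ ≥ 0 (negating both effects where needed).
    The slope estimates the causal effect under InSIDE; the intercept
    estimates average directional pleiotropy.  SEs carry the same
    multiplicative heterogeneity floor as IVW (denominator L−2).
    """

    method_name = "MR-Egger"

    def __init__(self, re_model: str = "multiplicative"):
        self.re_model = re_model

    def _fit_arrays(self, g, sg, G, sG):
        L = len(g)
        if L < 3:
            raise ValueError("Egger regression needs ≥ 3 instruments")
        flip = np.sign(g)
        flip[flip == 0] = 1.0
        x, y = g * flip, G * flip
        w = 1.0 / sG**2
        sw, swx, swy = np.sum(w), np.sum(w * x), np.sum(w * y)
        swxx, swxy = np.sum(w * x * x), np.sum(w * x * y)
        det = sw * swxx - swx**2
        if det <= 0:
            raise ValueError("degenerate design (all γ̂ identical?)")
        slope = (sw * swxy - swx * swy) / det
        icept = (swy - slope * swx) / sw
        resid = y - icept - slope * x
        q = float(np.sum(w * resid**2))
        self.q_stat_ = q
        scale = 1.0
        if self.re_model == "multiplicative":
            scale = max(1.0, math.sqrt(q / (L - 2)))
        se_slope = math.sqrt(sw / det) * scale
        se_icept = math.sqrt(swxx / det) * scale
        self.beta_, self.se_ = float(slope), float(se_slope)
        self.intercept_ = float(icept)
        self.intercept_se_ = float(se_icept)
        self.intercept_pval_ = _two_sided_p(icept, se_icept)


def i2gx(X) -> float:
    """I²_GX: attenuation diagnostic for the Egger NOME assumption.

    The weighted heterogeneity of the (oriented) exposure effects,
    I²_GX = (Q_GX − (L−1))/Q_GX with Q_GX = Σ(γ̂ⱼ−γ̄)²/σ_γⱼ².  Values
    near 1 mean exposure-effect measurement error is negligible; below
    ~0.9 the Egger slope is materially attenuated and SIMEX correction
    is warranted.  Floored at 0 for reporting.
    """
    g, sg, G, sG = _extract(X)
    if len(g) < 2:
        raise ValueError("I²_GX needs ≥ 2 instruments")
    if np.any(sg == 0):
        sg = np.where(sg == 0, np.finfo(float).tiny**0.25, sg)
    x = np.abs(g)
    w = 1.0 / sg**2
    xbar = np.sum(w * x) / np.sum(w)
    q_gx = float(np.sum(w * (x - xbar) ** 2))
    if q_gx == 0:
        return 0.0
    return max(0.0, (q_gx - (len(g) - 1)) / q_gx)


@dataclass
class SimexSettings:
    """SIMEX tuning: λ inflation grid, replicates per λ, extrapolant."""

    lambda_grid: tuple = (0.0, 0.5, 1.0, 1.5, 2.0)
    n_boot: int = 1000
    extrapolation: int = 2
    seed: int = 0

    def __post_init__(self):
        lam = tuple(float(x) for x in self.lambda_grid)
        if 0.0 not in lam or any(x < 0 for x in lam):
            raise ValueError("lambda_grid must be non-negative and contain 0")
        if self.n_boot < 100:
            raise ValueError("n_boot must be ≥ 100")
        if len(lam) <= self.extrapolation:
            raise ValueError("need more λ points than polynomial degree")
        self.lambda_grid = lam


def _egger_sums_slope_intercept(w, x, y):
    """Closed-form WLS slope/intercept per replicate (x: (B, L))."""
    sw = np.sum(w)
    swx = x @ w
    swy = float(np.sum(w * y))
    swxx = (x * x) @ w
    swxy = x @ (w * y)
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    icept = (swy - slope * swx) / sw
    return slope, icept


class SimexEggerEstimator(_MRRegressorBase):
    """Simulation-extrapolation correction of the MR-Egger slope.

    Measurement error in γ̂ attenuates the Egger slope toward zero
    (NOME violation).  SIMEX deliberately inflates that error: for each
    λ ≥ 0, γ̂ⱼ is perturbed with extra noise of variance λ·σ_γⱼ² and the
    Egger fit repeated ``n_boot`` times; the mean slope is modelled as a
    polynomial in λ and extrapolated back to λ = −1, the zero-error
    limit.  SEs come from a jackknife over instruments sharing the same
    λ-path and noise draws.
    """

    method_name = "MR-Egger SIMEX"

    def __init__(self, settings: SimexSettings | None = None):
        self.settings = settings

    def _fit_arrays(self, g, sg, G, sG):
        st = self.settings or SimexSettings()
        L = len(g)
        if L < 3:
            raise ValueError("SIMEX-Egger needs ≥ 3 instruments")
        rng = np.random.default_rng(st.seed)
        flip = np.sign(g)
        flip[flip == 0] = 1.0
        x0, y = g * flip, G * flip
        w = 1.0 / sG**2
        lams = np.asarray(st.lambda_grid)

        mean_slope = np.empty(len(lams))
        mean_icept = np.empty(len(lams))
        # leave-one-out means per λ, for the jackknife
        loo_slope = np.empty((len(lams), L))
        loo_icept = np.empty((len(lams), L))
        sw = np.sum(w)

        for i, lam in enumerate(lams):
            if lam == 0.0:
                x = x0[None, :]
            else:
                eps = rng.standard_normal((st.n_boot, L))
                x = x0[None, :] + math.sqrt(lam) * sg[None, :] * eps
            # per-replicate weighted sums; LOO versions by subtraction
            cwx = x * w[None, :]
            swx = cwx.sum(axis=1, keepdims=True)
            swy = float(np.sum(w * y))
            cwxx = x * cwx
            swxx = cwxx.sum(axis=1, keepdims=True)
            cwxy = x * (w * y)[None, :]
            swxy = cwxy.sum(axis=1, keepdims=True)

            det = sw * swxx - swx**2
            slope = (sw * swxy - swx * swy) / det
            icept = (swy - slope * swx) / sw
            mean_slope[i] = slope.mean()
            mean_icept[i] = icept.mean()

            sw_l = sw - w[None, :]
            swx_l = swx - cwx
            swy_l = swy - (w * y)[None, :]
            swxx_l = swxx - cwxx
            swxy_l = swxy - cwxy
            det_l = sw_l * swxx_l - swx_l**2
            slope_l = (sw_l * swxy_l - swx_l * swy_l) / det_l
            icept_l = (swy_l - slope_l * swx_l) / sw_l
            loo_slope[i] = slope_l.mean(axis=0)
            loo_icept[i] = icept_l.mean(axis=0)

        def extrapolate(series):
            coefs = np.polynomial.polynomial.polyfit(
                lams, series, st.extrapolation
            )
            return np.polynomial.polynomial.polyval(-1.0, coefs)

        beta = float(extrapolate(mean_slope))
        icept = float(extrapolate(mean_icept))

        # vectorized polynomial fit over the L jackknife columns
        V = np.vander(lams, st.extrapolation + 1, increasing=True)
        coef_s, *_ = np.linalg.lstsq(V, loo_slope, rcond=None)
        coef_i, *_ = np.linalg.lstsq(V, loo_icept, rcond=None)
        powers = (-1.0) ** np.arange(st.extrapolation + 1)
        jk_slope = powers @ coef_s
        jk_icept = powers @ coef_i
        fac = (L - 1) / L
        se = math.sqrt(fac * np.sum((jk_slope - jk_slope.mean()) ** 2))
        se_icept = math.sqrt(fac * np.sum((jk_icept - jk_icept.mean()) ** 2))

        self.beta_, self.se_ = beta, se
        self.intercept_ = icept
        self.intercept_se_ = se_icept
        self.intercept_pval_ = _two_sided_p(icept, se_icept)
        self.lambda_grid_ = lams
        self.mean_slopes_ = mean_slope
        self.mean_intercepts_ = mean_icept


class WeightedMedianEstimator(_MRRegressorBase):
    """Weighted median of the per-variant Wald ratios.

    Consistent when instruments carrying ≥ 50% of the weight are valid,
    so it tolerates substantial directional pleiotropy.  Weights are
    wⱼ = γ̂ⱼ²/σ_Γⱼ² (inverse ratio-variance, first order); the estimate
    interpolates the weighted empirical quantile function at 0.5.

    SE by bootstrap: ``se_method="pair"`` (default) resamples
    instruments with replacement; ``"parametric"`` redraws (γ̂ⱼ, Γ̂ⱼ)
    from their sampling distributions around the observed values.  The
    parametric scheme convolves the realized scatter with a fresh copy
    of the sampling noise and is therefore conservative (its SE runs
    ~20–40% high when the instruments are homogeneous); the pair
    bootstrap is calibrated and still reflects pleiotropic scatter.
    """

    method_name = "WME"

    def __init__(self, n_boot: int = 1000, seed: int = 0, se_method: str = "pair"):
        self.n_boot = n_boot
        self.seed = seed
        self.se_method = se_method

    @staticmethod
    def _weighted_median(b: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Row-wise weighted median with midpoint interpolation."""
        b = np.atleast_2d(b)
        w = np.atleast_2d(w)
        order = np.argsort(b, axis=1)
        bs = np.take_along_axis(b, order, axis=1)
        ws = np.take_along_axis(w, order, axis=1)
        ws = ws / ws.sum(axis=1, keepdims=True)
        p = np.cumsum(ws, axis=1) - ws / 2.0
        k = (p < 0.5).sum(axis=1)
        k = np.clip(k, 1, b.shape[1] - 1)
        p_hi = np.take_along_axis(p, k[:, None], axis=1)[:, 0]
        p_lo = np.take_along_axis(p, (k - 1)[:, None], axis=1)[:, 0]
        b_hi = np.take_along_axis(bs, k[:, None], axis=1)[:, 0]
        b_lo = np.take_along_axis(bs, (k - 1)[:, None], axis=1)[:, 0]
        frac = np.where(p_hi > p_lo, (0.5 - p_lo) / np.where(p_hi > p_lo, p_hi - p_lo, 1.0), 0.5)
        return b_lo + frac * (b_hi - b_lo)

    def _fit_arrays(self, g, sg, G, sG):
        if len(g) < 3:
            raise ValueError("weighted median needs ≥ 3 instruments")
        if np.any(g == 0):
            raise ValueError("zero exposure effect; drop the variant first")
        b = G / g
        w = g**2 / sG**2
        self.beta_ = float(self._weighted_median(b, w)[0])
        rng = np.random.default_rng(self.seed)
        L = len(g)
        if self.se_method == "pair":
            idx = rng.integers(0, L, size=(self.n_boot, L))
            boots = self._weighted_median(b[idx], w[idx])
        elif self.se_method == "parametric":
            gb = g[None, :] + sg[None, :] * rng.standard_normal((self.n_boot, L))
            Gb = G[None, :] + sG[None, :] * rng.standard_normal((self.n_boot, L))
            gb = np.where(gb == 0, np.finfo(float).eps, gb)
            boots = self._weighted_median(Gb / gb, gb**2 / sG[None, :] ** 2)
        else:
            raise ValueError(f"unknown se_method {self.se_method!r}")
        self.se_ = float(np.std(boots, ddof=1))


def raps_profile_score(beta: float, g, sg, G, sG) -> float:
    """Derivative of the error-in-variables profile log-likelihood.

    l(β) = −½ Σ (Γ̂ⱼ−βγ̂ⱼ)²/vⱼ(β), vⱼ(β) = σ_Γⱼ² + β²σ_γⱼ²; the score
    is Σ [γ̂ⱼ rⱼ/vⱼ + βσ_γⱼ² rⱼ²/vⱼ²] with rⱼ = Γ̂ⱼ−βγ̂ⱼ.  The second
    term corrects the O(βσ_γ²) bias of the naive ratio score; with
    σ_γ = 0 the score reduces to the fixed-effect IVW normal equation.
    """
    r = G - beta * g
    v = sG**2 + beta**2 * sg**2
    return float(np.sum(g * r / v + beta * sg**2 * r**2 / v**2))


class RAPSEstimator(_MRRegressorBase):
    """Robust adjusted profile score (simple model, no overdispersion).

    Maximizes the profile likelihood that treats both γ̂ⱼ and Γ̂ⱼ as
    noisy, removing the weak-instrument attenuation IVW suffers when
    σ_γⱼ is non-negligible.  The root of the profile score is found by
    safeguarded bracketing around the IVW estimate; SE comes from the
    observed information of the profile likelihood (more stable than
    the empirical sandwich on QC-trimmed panels, whose residual
    dispersion is deflated by outlier removal).
    """

    method_name = "RAPS"

    def _fit_arrays(self, g, sg, G, sG):
        if len(g) < 3:
            raise ValueError("RAPS needs ≥ 3 instruments")
        ivw_fit = IVWEstimator(re_model="fixed").fit(
            np.column_stack([g, sg, G, sG])
        )
        b0, s0 = ivw_fit.beta_, max(ivw_fit.se_, 1e-6)

        def score(b):
            return raps_profile_score(b, g, sg, G, sG)

        half = 10 * s0
        lo, hi = b0 - half, b0 + half
        for _ in range(60):
            if score(lo) * score(hi) < 0:
                break
            half *= 2.0
            lo, hi = b0 - half, b0 + half
        else:
            raise ValueError("profile score has no sign change in bracket")
        beta = optimize.brentq(score, lo, hi, xtol=1e-14, rtol=8.9e-16)

        h = 1e-6 * max(1.0, abs(beta))
        dpsi = (score(beta + h) - score(beta - h)) / (2 * h)
        self.beta_ = float(beta)
        self.se_ = float(1.0 / math.sqrt(abs(dpsi)))


class GSMREstimator(_MRRegressorBase):
    """Generalized summary-data MR with HEIDI outlier filtering.

    Instruments failing the HEIDI heterogeneity screen (ratio deviating
    from the IVW estimate beyond sampling error) are removed first; the
    causal effect is then the inverse-variance average of Wald ratios
    with both sampling errors in the weights,
    Var(bⱼ) = (σ_Γⱼ² + β̂²σ_γⱼ²)/γ̂ⱼ², iterated from the IVW estimate
    (plugging the pooled β̂ rather than each noisy bⱼ into the variance
    keeps the weights independent of the per-variant ratio noise, which
    otherwise drags the pooled estimate toward zero).  Instruments are
    assumed LD-independent (the identity-correlation special case,
    guaranteed upstream by LD pruning).
    """

    method_name = "GSMR"

    def __init__(self, heidi_threshold: float = 0.01):
        self.heidi_threshold = heidi_threshold

    def fit(self, X, y=None):
        from .qc import heidi_filter  # circular at import time

        df = as_instrument_frame(X)
        if len(df) < 3:
            raise ValueError("GSMR needs ≥ 3 instruments")
        if self.heidi_threshold > 0:
            kept, removed = heidi_filter(df, p_threshold=self.heidi_threshold)
        else:
            kept, removed = df, []
        if len(kept) < 3:
            raise ValueError("fewer than 3 instruments survive HEIDI")
        self.heidi_removed_ = list(removed)
        return super().fit(kept)

    def _fit_arrays(self, g, sg, G, sG):
        b = G / g
        w = g**2 / sG**2
        beta = float(np.sum(w * b) / np.sum(w))  # IVW initialization
        for _ in range(3):
            w = g**2 / (sG**2 + beta**2 * sg**2)
            beta = float(np.sum(w * b) / np.sum(w))
        self.beta_ = beta
        self.se_ = float(np.sum(w) ** -0.5)


# ---------------------------------------------------------------------------
# functional wrappers

def ivw(X, re_model: str = "multiplicative") -> MREstimate:
    return IVWEstimator(re_model=re_model).fit(X).result_


def egger(X, re_model: str = "multiplicative") -> MREstimate:
    return EggerEstimator(re_model=re_model).fit(X).result_


def simex_egger(X, settings: SimexSettings | None = None) -> MREstimate:
    return SimexEggerEstimator(settings=settings).fit(X).result_


def weighted_median(X, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    return WeightedMedianEstimator(n_boot=n_boot, seed=seed).fit(X).result_


def raps(X) -> MREstimate:
    return RAPSEstimator().fit(X).result_


def gsmr(X, heidi_threshold: float = 0.01) -> MREstimate:
    return GSMREstimator(heidi_threshold=heidi_threshold).fit(X).result_
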