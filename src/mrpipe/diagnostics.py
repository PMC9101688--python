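"""Heterogeneity statistics, leave-one-out sensitivity, figure data.

Cochran's Q measures dispersion of the per-variant outcome effects
around the fitted causal line; I² = (Q − df)/Q expresses the excess
over its expectation.  I² is kept both signed and floored at zero (Q
below its degrees of freedom yields a negative signed value whose
magnitude is what result tables conventionally print).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import IVWEstimator, MREstimate, wald_ratios
from .harmonize import as_instrument_frame


@dataclass
class HeterogeneityReport:
    """Cochran's Q decomposition for one causal estimate."""

    q_stat: float
    df: int
    pval: float
    i2_signed: float
    i2_floored: float
    per_snp_q: np.ndarray

    @property
    def i2_magnitude(self) -> float:
        """|I²| as conventionally printed (sign dropped)."""
        return abs(self.i2_signed)

    def to_dict(self) -> dict:
        return {
            "q_stat": self.q_stat,
            "df": self.df,
            "pval": self.pval,
            "i2_signed": self.i2_signed,
            "i2_floored": self.i2_floored,
        }


def i_squared(q: float, df: int) -> float:
    """Signed I² = (Q − df)/Q; 0 when Q = 0."""
    return 0.0 if q == 0 else (q - df) / q


def cochran_q(instruments, beta: float) -> HeterogeneityReport:
    """Cochran's Q of the instruments around causal slope ``beta``.

    qⱼ = (Γ̂ⱼ − β·γ̂ⱼ)²/σ_Γⱼ²; Q = Σqⱼ on L−1 degrees of freedom with
    an upper-tail χ² p-value.
    """
    df_ = as_instrument_frame(instruments)
    if len(df_) < 2:
        raise ValueError("Cochran's Q needs ≥ 2 instruments")
    g = df_["gamma_hat"].to_numpy(float)
    G = df_["big_gamma_hat"].to_numpy(float)
    sG = df_["se_big_gamma"].to_numpy(float)
    per = (G - beta * g) ** 2 / sG**2
    q = float(np.sum(per))
    dof = len(g) - 1
    pval = float(stats.chi2.sf(q, dof))
    signed = i_squared(q, dof)
    return HeterogeneityReport(
        q_stat=q,
        df=dof,
        pval=pval,
        i2_signed=signed,
        i2_floored=max(0.0, signed),
        per_snp_q=per,
    )


@dataclass
class LeaveOneOutResult:
    rows: pd.DataFrame
    full_estimate: MREstimate


def leave_one_out(instruments, re_model: str = "multiplicative") -> LeaveOneOutResult:
    """IVW re-estimated with each instrument excluded in turn.

    Rows are sorted by rsID.  A single variant dominating the estimate
    shows up as the one row that departs from the full-set value.
    """
    df = as_instrument_frame(instruments).reset_index(drop=True)
    if len(df) < 3:
        raise ValueError("leave-one-out needs ≥ 3 instruments")
    full = IVWEstimator(re_model=re_model).fit(df).result_
    rows = []
    for i in range(len(df)):
        sub = df.drop(index=i)
        est = IVWEstimator(re_model=re_model).fit(sub).result_
        rows.append(
            {
                "SNP": df.loc[i, "SNP"],
                "beta": est.beta,
                "se": est.se,
                "or_": est.or_,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    out = pd.DataFrame(rows).sort_values("SNP", kind="mergesort").reset_index(drop=True)
    return LeaveOneOutResult(rows=out, full_estimate=full)


def funnel_scatter_data(instruments, estimates: list[MREstimate]) -> dict:
    """Figure-ready tables: scatter, funnel and forest.

    scatter — per-variant (γ̂, Γ̂) with 1.96·SE error bars plus one
    (method, slope, intercept) row per estimate; funnel — per-variant
    Wald ratio against its precision 1/SE with reference lines at each
    method's slope; forest — per-method OR with 95% CI.
    """
    if not estimates:
        raise ValueError("need at least one causal estimate")
    df = as_instrument_frame(instruments)
    scatter = pd.DataFrame(
        {
            "SNP": df["SNP"],
            "gamma_hat": df["gamma_hat"],
            "gamma_err": 1.96 * df["se_gamma"],
            "big_gamma_hat": df["big_gamma_hat"],
            "big_gamma_err": 1.96 * df["se_big_gamma"],
        }
    )
    slopes = pd.DataFrame(
        {
            "method": [e.method for e in estimates],
            "slope": [e.beta for e in estimates],
            "intercept": [e.intercept if e.intercept is not None else 0.0 for e in estimates],
        }
    )
    ratios = wald_ratios(df)
    funnel = pd.DataFrame(
        {
            "SNP": ratios["SNP"],
            "ratio": ratios["ratio"],
            "precision": 1.0 / ratios["se_ratio"],
        }
    )
    forest = pd.DataFrame([e.to_dict() for e in estimates])[
        ["method", "n_snps", "or_", "ci_low", "ci_high", "pval"]
    ]
    return {"scatter": scatter, "slopes": slopes, "funnel": funnel, "forest": forest}


def summarize_results(
    estimates: list[MREstimate],
    het: HeterogeneityReport,
    egger_est: MREstimate | None = None,
    simex_est: MREstimate | None = None,
) -> dict:
    """Result tables: per-method estimates and heterogeneity/pleiotropy.

    The first table has one row per method (beta, SE, p, OR, CI, and
    intercept columns populated only on Egger-family rows); the second
    carries Q, its p, both I² conventions, and the Egger / SIMEX-Egger
    intercepts with 95% CIs.
    """
    counts = {e.n_snps for e in estimates if e.method != "GSMR"}
    if len(counts) > 1:
        raise ValueError(f"estimates computed on different instrument sets: {counts}")
    mr_rows = pd.DataFrame([e.to_dict() for e in estimates])
    mr_rows = mr_rows.rename(columns={"method": "method", "n_snps": "nsnp"})

    def icept_cols(est: MREstimate | None, label: str) -> dict:
        if est is None or est.intercept is None:
            return {
                f"{label}_intercept": np.nan,
                f"{label}_intercept_low": np.nan,
                f"{label}_intercept_high": np.nan,
                f"{label}_intercept_p": np.nan,
            }
        return {
            f"{label}_intercept": est.intercept,
            f"{label}_intercept_low": est.intercept - 1.96 * est.intercept_se,
            f"{label}_intercept_high": est.intercept + 1.96 * est.intercept_se,
            f"{label}_intercept_p": est.intercept_pval,
        }

    het_row = {
        "q_stat": het.q_stat,
        "q_df": het.df,
        "q_pval": het.pval,
        "i2_signed": het.i2_signed,
        "i2_magnitude_pct": 100.0 * het.i2_magnitude,
        **icept_cols(egger_est, "egger"),
        **icept_cols(simex_est, "simex"),
    }
    return {"mr_results": mr_rows, "heterogeneity": pd.DataFrame([het_row])}
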