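"""Instrument selection and quality control.

The selection cascade for MR instruments: genome-wide significance
filter, LD pruning to mutually independent variants, user-supplied
exclusion lists (e.g. variants associated with known confounders in a
phenome-scan), then heterogeneity-based outlier removal on the
harmonized set (radial Cochran's Q, MR-PRESSO, HEIDI).  A
:class:`QcLedger` accounts for every variant at every stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import IVWEstimator
from .harmonize import as_instrument_frame
from .io import GwasTable

logger = logging.getLogger(__name__)


@dataclass
class QcLedger:
    """Per-stage accounting: counts chain exactly across the cascade."""

    stage_names: list = field(default_factory=list)
    counts_in: list = field(default_factory=list)
    counts_out: list = field(default_factory=list)
    removed: list = field(default_factory=list)  # list of [(rsID, reason), ...]

    def add_stage(self, name: str, n_in: int, removed: list) -> None:
        n_out = n_in - len(removed)
        if self.counts_out and n_in != self.counts_out[-1]:
            raise ValueError(
                f"ledger break at {name}: in={n_in} != previous out={self.counts_out[-1]}"
            )
        self.stage_names.append(name)
        self.counts_in.append(n_in)
        self.counts_out.append(n_out)
        self.removed.append(list(removed))
        logger.info("stage %-22s %4d -> %4d (-%d)", name, n_in, n_out, len(removed))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": self.stage_names,
                "n_in": self.counts_in,
                "n_out": self.counts_out,
                "n_removed": [len(r) for r in self.removed],
            }
        )

    def removed_frame(self) -> pd.DataFrame:
        rows = [
            (stage, snp, reason)
            for stage, rem in zip(self.stage_names, self.removed)
            for snp, reason in rem
        ]
        return pd.DataFrame(rows, columns=["stage", "SNP", "reason"])


# ---------------------------------------------------------------------------
# pre-harmonization stages (operate on a GwasTable)

def select_genomewide(table: GwasTable, p_threshold: float = 5e-8):
    """Retain variants with p strictly below the genome-wide threshold."""
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    keep = table.records["pval"] < p_threshold
    removed = [(s, "not_genomewide") for s in table.records.loc[~keep, "SNP"]]
    return table.subset(keep.to_numpy()), removed


def ld_prune(
    table: GwasTable,
    ld: dict | None,
    r2_max: float = 0.001,
    window_kb: float = 1000.0,
    positions: dict | None = None,
    missing_pair_error: bool = False,
):
    """Greedy LD pruning to mutually independent variants.

    Variants are visited in ascending p-value order (ties broken by
    rsID); a variant is accepted iff its r² with every already-accepted
    variant within ``window_kb`` is below ``r2_max``.  ``ld`` maps
    frozenset pairs of rsIDs (or (a, b) tuples) to r²; absent pairs
    count as r² = 0 (warn, or raise when ``missing_pair_error``).
    ``positions`` maps rsID to a (chrom, pos_bp) tuple or a bare
    position; without positions every pair is a candidate.
    """
    ld = ld or {}

    def lookup(a: str, b: str) -> float:
        for key in ((a, b), (b, a), frozenset((a, b))):
            if key in ld:
                return float(ld[key])
        if ld:
            if missing_pair_error:
                raise KeyError(f"no LD entry for pair ({a}, {b})")
            logger.warning("LD pair (%s, %s) missing; assuming r²=0", a, b)
        return 0.0

    def within_window(a: str, b: str) -> bool:
        if not positions or a not in positions or b not in positions:
            return True
        pa, pb = positions[a], positions[b]
        ca, xa = pa if isinstance(pa, tuple) else (0, pa)
        cb, xb = pb if isinstance(pb, tuple) else (0, pb)
        return ca == cb and abs(xa - xb) <= window_kb * 1000.0

    order = table.records.sort_values(
        ["pval", "SNP"], kind="mergesort"
    )["SNP"].tolist()
    accepted: list[str] = []
    removed = []
    for snp in order:
        if any(
            within_window(snp, kept) and lookup(snp, kept) >= r2_max
            for kept in accepted
        ):
            removed.append((snp, "ld"))
        else:
            accepted.append(snp)
    keep_mask = table.records["SNP"].isin(accepted).to_numpy()
    return table.subset(keep_mask), removed


def apply_exclusion_list(table: GwasTable, exclusions: dict | set):
    """Drop variants on a precomputed exclusion list.

    ``exclusions`` is either a set of rsIDs or a mapping rsID → reason
    (e.g. the trait a phenome-scan flagged at the Bonferroni level).
    """
    if not isinstance(exclusions, dict):
        exclusions = {s: "excluded" for s in exclusions}
    present = set(table.records["SNP"])
    for snp in exclusions:
        if snp not in present:
            logger.warning("exclusion list rsID %s not in table; ignored", snp)
    removed = [(s, exclusions[s]) for s in table.records["SNP"] if s in exclusions]
    keep = ~table.records["SNP"].isin(exclusions).to_numpy()
    return table.subset(keep), removed


def read_exclusion_list(path) -> dict:
    """Two-column TSV (rsID, reason) → mapping; header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] == 1:
        df[1] = "excluded"
    first = str(df.iloc[0, 0]).lower()
    if first in ("snp", "rsid", "id"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# instrument strength

@dataclass
class InstrumentStrength:
    """Variance explained and F statistic of the instrument set."""

    r2_total: float
    f_stat: float
    n: int
    k: int
    per_snp_r2: np.ndarray

    def to_dict(self) -> dict:
        return {
            "r2_total": self.r2_total,
            "f_stat": self.f_stat,
            "n": self.n,
            "k": self.k,
        }


def f_statistic(r2: float, n: int, k: int) -> float:
    """First-stage F from variance explained: F = R²(n−1−K) / ((1−R²)K)."""
    if n <= k + 1:
        raise ValueError("need n > K + 1")
    return r2 * (n - 1 - k) / ((1.0 - r2) * k)


def instrument_strength(instruments, n: int, method: str = "eaf") -> InstrumentStrength:
    """Instrument-set strength from the harmonized exposure effects.

    Per-variant variance explained (standardized exposure):
    R²ⱼ = 2fⱼ(1−fⱼ)γ̂ⱼ² with fⱼ the exposure effect-allele frequency
    (``method="eaf"``), or the large-sample alternative zⱼ²/(zⱼ²+n)
    (``method="z"``).  F uses the joint formula above.
    """
    df = as_instrument_frame(instruments)
    g = df["gamma_hat"].to_numpy(float)
    k = len(df)
    if n <= k + 1:
        raise ValueError("need n > K + 1")
    if method == "eaf":
        if "eaf_exposure" not in df.columns or df["eaf_exposure"].isna().any():
            bad = (
                df.loc[df["eaf_exposure"].isna(), "SNP"].tolist()
                if "eaf_exposure" in df.columns
                else "all"
            )
            raise ValueError(f"missing exposure EAF for: {bad}")
        f = df["eaf_exposure"].to_numpy(float)
        per = 2.0 * f * (1.0 - f) * g**2
    elif method == "z":
        z = g / df["se_gamma"].to_numpy(float)
        per = z**2 / (z**2 + n)
    else:
        raise ValueError(f"unknown method {method!r}")
    r2 = float(np.sum(per))
    return InstrumentStrength(
        r2_total=r2, f_stat=f_statistic(r2, n, k), n=int(n), k=k, per_snp_r2=per
    )


# ---------------------------------------------------------------------------
# post-harmonization outlier filters

def radial_q_filter(
    instruments, alpha: float = 0.05, iterate: bool = True
) -> tuple[pd.DataFrame, list, "pd.DataFrame"]:
    """Remove per-variant radial Cochran's-Q outliers.

    With the IVW estimate β̂, each variant contributes
    qⱼ = wⱼ(bⱼ − β̂)², bⱼ = Γ̂ⱼ/γ̂ⱼ, wⱼ = γ̂ⱼ²/σ_Γⱼ² — asymptotically
    χ²₁ under homogeneity.  Variants with qⱼ above the upper-α χ²₁
    quantile are removed; with ``iterate`` the IVW estimate and the test
    repeat until nothing is removed (or < 3 variants would remain).
    Returns (retained, removed, per-variant q table of the final pass).
    """
    df = as_instrument_frame(instruments).reset_index(drop=True)
    if len(df) < 3:
        raise ValueError("radial Q filter needs ≥ 3 instruments")
    if not (0 <= alpha < 1):
        raise ValueError("alpha in [0, 1)")
    crit = math.inf if alpha == 0 else stats.chi2.ppf(1 - alpha, df=1)
    removed: list = []
    current = df
    while True:
        g = current["gamma_hat"].to_numpy(float)
        G = current["big_gamma_hat"].to_numpy(float)
        sG = current["se_big_gamma"].to_numpy(float)
        w = g**2 / sG**2
        b = G / g
        beta = float(np.sum(w * b) / np.sum(w))
        q = w * (b - beta) ** 2
        out = q > crit
        if not out.any():
            qtab = pd.DataFrame(
                {"SNP": current["SNP"], "q_contribution": q, "ratio": b}
            )
            return current.reset_index(drop=True), removed, qtab
        # refuse to iterate below the minimum set size
        if len(current) - int(out.sum()) < 3:
            order = np.argsort(q)[::-1]
            out = np.zeros(len(current), bool)
            out[order[: len(current) - 3]] = True
        removed.extend(
            (s, "radial_q") for s in current.loc[out, "SNP"]
        )
        current = current.loc[~out]
        if not iterate or len(current) < 3:
            g = current["gamma_hat"].to_numpy(float)
            G = current["big_gamma_hat"].to_numpy(float)
            sG = current["se_big_gamma"].to_numpy(float)
            w = g**2 / sG**2
            b = G / g
            beta = float(np.sum(w * b) / np.sum(w))
            q = w * (b - beta) ** 2
            qtab = pd.DataFrame(
                {"SNP": current["SNP"], "q_contribution": q, "ratio": b}
            )
            return current.reset_index(drop=True), removed, qtab


def _loo_ivw_slopes(g, G, sG):
    """Leave-one-out fixed-effect IVW slopes, vectorized by subtraction."""
    w = 1.0 / sG**2
    num, den = np.sum(w * g * G), np.sum(w * g * g)
    return (num - w * g * G) / (den - w * g * g)


def mr_presso_filter(
    instruments,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list, float]:
    """MR-PRESSO global pleiotropy test and outlier removal.

    Observed statistic: RSS = Σⱼ wⱼ(Γ̂ⱼ − β̂₍₋ⱼ₎γ̂ⱼ)² with
    leave-one-out IVW slopes β̂₍₋ⱼ₎ and wⱼ = 1/σ_Γⱼ².  The null
    distribution comes from ``n_sim`` parametric draws
    Γ̂ⱼ* ~ N(β̂₍₋ⱼ₎γ̂ⱼ, σ_Γⱼ²), γ̂ⱼ* ~ N(γ̂ⱼ, σ_γⱼ²), recomputing the
    same statistic.  If the global p < ``alpha``, per-variant outlier
    p-values (fraction of simulated jth residuals exceeding the observed
    one) are Bonferroni-compared to ``alpha`` and flagged variants
    removed.  Returns (retained, removed, global p).
    """
    df = as_instrument_frame(instruments).reset_index(drop=True)
    L = len(df)
    if L < 4:
        raise ValueError("MR-PRESSO needs ≥ 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be ≥ 100")
    if n_sim < 10 / alpha:
        raise ValueError(
            f"n_sim={n_sim} too small to resolve alpha={alpha}; "
            f"need ≥ {int(10 / alpha)}"
        )
    rng = np.random.default_rng(seed)
    g = df["gamma_hat"].to_numpy(float)
    sg = df["se_gamma"].to_numpy(float)
    G = df["big_gamma_hat"].to_numpy(float)
    sG = df["se_big_gamma"].to_numpy(float)
    w = 1.0 / sG**2

    beta_loo = _loo_ivw_slopes(g, G, sG)
    obs_res2 = w * (G - beta_loo * g) ** 2
    obs_rss = float(np.sum(obs_res2))

    g_sim = g[None, :] + sg[None, :] * rng.standard_normal((n_sim, L))
    G_sim = beta_loo[None, :] * g[None, :] + sG[None, :] * rng.standard_normal(
        (n_sim, L)
    )
    wg2 = w[None, :] * g_sim**2
    wgG = w[None, :] * g_sim * G_sim
    den = wg2.sum(axis=1, keepdims=True) - wg2
    num = wgG.sum(axis=1, keepdims=True) - wgG
    beta_loo_sim = num / den
    sim_res2 = w[None, :] * (G_sim - beta_loo_sim * g_sim) ** 2
    sim_rss = sim_res2.sum(axis=1)

    global_p = float((np.sum(sim_rss >= obs_rss) + 1) / (n_sim + 1))
    removed: list = []
    if global_p < alpha:
        per_p = (np.sum(sim_res2 >= obs_res2[None, :], axis=0) + 1) / (n_sim + 1)
        flag = per_p < alpha / L
        removed = [(s, "mr_presso") for s in df.loc[flag, "SNP"]]
        df = df.loc[~flag].reset_index(drop=True)
    return df, removed, global_p


def heidi_filter(
    instruments, p_threshold: float = 0.01
) -> tuple[pd.DataFrame, list]:
    """HEIDI-style single-instrument heterogeneity screen.

    Against the IVW estimate β̂, each variant's deviation
    dⱼ = bⱼ − β̂ has Var(dⱼ) ≈ σ_Γⱼ²/γ̂ⱼ² + β̂²σ_γⱼ²/γ̂ⱼ² (first
    order); variants with a two-sided normal p below ``p_threshold``
    are removed, and the test repeats once on the survivors.
    """
    df = as_instrument_frame(instruments).reset_index(drop=True)
    if len(df) < 3:
        raise ValueError("HEIDI needs ≥ 3 instruments")
    removed: list = []
    current = df
    for _ in range(2):  # single iteration after the initial pass
        if p_threshold <= 0 or len(current) < 3:
            break
        g = current["gamma_hat"].to_numpy(float)
        sg = current["se_gamma"].to_numpy(float)
        G = current["big_gamma_hat"].to_numpy(float)
        sG = current["se_big_gamma"].to_numpy(float)
        w = g**2 / sG**2
        b = G / g
        beta = float(np.sum(w * b) / np.sum(w))
        var_d = sG**2 / g**2 + beta**2 * sg**2 / g**2
        p = 2.0 * stats.norm.sf(np.abs(b - beta) / np.sqrt(var_d))
        out = p < p_threshold
        if not out.any():
            break
        if len(current) - int(out.sum()) < 3:
            order = np.argsort(p)
            out = np.zeros(len(current), bool)
            out[order[: len(current) - 3]] = True
        removed.extend((s, "heidi") for s in current.loc[out, "SNP"])
        current = current.loc[~out].reset_index(drop=True)
    return current.reset_index(drop=True), removed
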