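"""Config-driven end-to-end two-sample MR analysis.

Fixed stage order: genome-wide significance filter → LD pruning →
exclusion list → harmonization → radial Q outliers → MR-PRESSO →
HEIDI → instrument strength → five causal estimators (+ I²_GX and,
when it falls below 0.9, SIMEX-corrected Egger) → heterogeneity,
leave-one-out and figure tables.  Every stochastic stage gets its own
seed derived from the master seed and the stage name, so inserting or
disabling a stage never perturbs the draws of the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import (
    cochran_q,
    funnel_scatter_data,
    leave_one_out,
    summarize_results,
)
from .estimators import (
    SimexSettings,
    egger,
    gsmr,
    i2gx,
    ivw,
    raps,
    simex_egger,
    weighted_median,
)
from .harmonize import harmonize_instruments
from .io import GwasTable, read_gwas_table, write_table
from .qc import (
    QcLedger,
    apply_exclusion_list,
    heidi_filter,
    instrument_strength,
    ld_prune,
    mr_presso_filter,
    radial_q_filter,
    read_exclusion_list,
    select_genomewide,
)
from .simulate import SimConfig, scenario_presets, simulate_two_sample

logger = logging.getLogger(__name__)

SIMEX_I2GX_TRIGGER = 0.9


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2³¹."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


@dataclass
class FileSpec:
    path: str
    column_map: dict = field(default_factory=dict)
    delimiter: str | None = "\t"


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one input mode must be set."""

    exposure: FileSpec | None = None
    outcome: FileSpec | None = None
    simulate_preset: str | None = None
    sim_config: SimConfig | None = None
    exclusion_path: str | None = None
    ld: dict | None = None
    positions: dict | None = None

    gwas_p: float = 5e-8
    ld_r2: float = 0.001
    ld_window_kb: float = 1000.0
    palindrome_band: tuple[float, float] = (0.42, 0.58)
    radial_alpha: float = 0.05
    radial_iterate: bool = True
    presso_nsim: int = 1000
    presso_alpha: float = 0.05
    heidi_p: float = 0.01
    re_model: str = "multiplicative"
    wme_nboot: int = 1000
    simex: SimexSettings | None = None
    force_simex: bool | None = None  # None: auto (I²_GX < 0.9)
    exposure_n: int | None = None

    run_gwas_filter: bool = True
    run_ld_prune: bool = True
    run_exclusions: bool = True
    run_radial: bool = True
    run_presso: bool = True
    run_heidi: bool = True

    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        sim_mode = self.simulate_preset is not None or self.sim_config is not None
        file_mode = self.exposure is not None and self.outcome is not None
        if sim_mode == file_mode:
            raise ValueError(
                "choose exactly one input mode: (exposure, outcome) files "
                "or a simulation preset/config"
            )
        if not (0 < self.gwas_p <= 1):
            raise ValueError("gwas_p must be in (0, 1]")
        lo, hi = self.palindrome_band
        if not (0 < lo < 0.5 < hi < 1):
            raise ValueError("palindrome_band must straddle 0.5")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the output bundle as a dict.

    Bundle keys: harmonized (DataFrame), ledger (QcLedger), estimates
    (list of MREstimate), tables (dict of result DataFrames), strength,
    heterogeneity, loo, i2gx, truth (simulation only), manifest.
    """
    cfg = config
    ledger = QcLedger()
    truth = None

    if cfg.sim_config is not None or cfg.simulate_preset is not None:
        sim = cfg.sim_config or scenario_presets(
            cfg.simulate_preset, seed=stage_seed(cfg.seed, "simulate")
        )
        exposure, outcome, truth = simulate_two_sample(sim)
        exposure_n = cfg.exposure_n or sim.n_exposure
    else:
        exposure = read_gwas_table(
            cfg.exposure.path,
            column_map=cfg.exposure.column_map,
            delimiter=cfg.exposure.delimiter,
            trait_label="exposure",
        )
        outcome = read_gwas_table(
            cfg.outcome.path,
            column_map=cfg.outcome.column_map,
            delimiter=cfg.outcome.delimiter,
            trait_label="outcome",
        )
        exposure_n = cfg.exposure_n or int(
            np.nanmedian(exposure.records["n"].to_numpy(float))
        )

    table = exposure
    if cfg.run_gwas_filter:
        table, removed = select_genomewide(table, cfg.gwas_p)
        ledger.add_stage("genomewide_filter", len(removed) + len(table), removed)
    else:
        ledger.add_stage("genomewide_filter (skipped)", len(table), [])

    if cfg.run_ld_prune:
        table, removed = ld_prune(
            table, cfg.ld, r2_max=cfg.ld_r2, window_kb=cfg.ld_window_kb,
            positions=cfg.positions,
        )
        ledger.add_stage("ld_prune", len(removed) + len(table), removed)
    else:
        ledger.add_stage("ld_prune (skipped)", len(table), [])

    if cfg.run_exclusions and cfg.exclusion_path:
        exclusions = read_exclusion_list(cfg.exclusion_path)
        table, removed = apply_exclusion_list(table, exclusions)
        ledger.add_stage("exclusion_list", len(removed) + len(table), removed)
    else:
        ledger.add_stage("exclusion_list (skipped)", len(table), [])

    harmonized, hreport = harmonize_instruments(
        table, outcome, palindrome_eaf_band=cfg.palindrome_band
    )
    ledger.add_stage("harmonize", hreport.n_input, hreport.dropped_ids)

    if cfg.run_radial:
        harmonized, removed, radial_tab = radial_q_filter(
            harmonized, alpha=cfg.radial_alpha, iterate=cfg.radial_iterate
        )
        ledger.add_stage("radial_q", len(removed) + len(harmonized), removed)
    else:
        radial_tab = None
        ledger.add_stage("radial_q (skipped)", len(harmonized), [])

    if cfg.run_presso:
        harmonized, removed, presso_p = mr_presso_filter(
            harmonized,
            n_sim=cfg.presso_nsim,
            seed=stage_seed(cfg.seed, "mr_presso"),
            alpha=cfg.presso_alpha,
        )
        ledger.add_stage("mr_presso", len(removed) + len(harmonized), removed)
    else:
        presso_p = None
        ledger.add_stage("mr_presso (skipped)", len(harmonized), [])

    if cfg.run_heidi:
        harmonized, removed = heidi_filter(harmonized, p_threshold=cfg.heidi_p)
        ledger.add_stage("heidi", len(removed) + len(harmonized), removed)
    else:
        ledger.add_stage("heidi (skipped)", len(harmonized), [])

    strength = instrument_strength(harmonized, n=exposure_n)
    logger.info(
        "instrument strength: R²=%.4f F=%.1f (K=%d)",
        strength.r2_total, strength.f_stat, strength.k,
    )

    ivw_est = ivw(harmonized, re_model=cfg.re_model)
    egger_est = egger(harmonized, re_model=cfg.re_model)
    wme_est = weighted_median(
        harmonized, n_boot=cfg.wme_nboot, seed=stage_seed(cfg.seed, "wme")
    )
    raps_est = raps(harmonized)
    gsmr_est = gsmr(harmonized, heidi_threshold=cfg.heidi_p)

    i2gx_val = i2gx(harmonized)
    run_simex = (
        cfg.force_simex
        if cfg.force_simex is not None
        else i2gx_val < SIMEX_I2GX_TRIGGER
    )
    simex_est = None
    if run_simex:
        st = cfg.simex or SimexSettings()
        st = dataclasses.replace(st, seed=stage_seed(cfg.seed, "simex"))
        simex_est = simex_egger(harmonized, settings=st)

    estimates = [ivw_est, egger_est, wme_est, raps_est, gsmr_est]
    if simex_est is not None:
        estimates.append(simex_est)

    het = cochran_q(harmonized, ivw_est.beta)
    loo = leave_one_out(harmonized, re_model=cfg.re_model)
    figures = funnel_scatter_data(harmonized, estimates)
    tables = summarize_results(estimates, het, egger_est, simex_est)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {
            s: stage_seed(cfg.seed, s)
            for s in ("simulate", "mr_presso", "wme", "simex")
        },
        "i2gx": i2gx_val,
        "simex_ran": bool(run_simex),
        "presso_global_p": presso_p,
        "instrument_strength": strength.to_dict(),
        "config": _config_echo(cfg),
    }

    bundle = {
        "harmonized": harmonized,
        "ledger": ledger,
        "estimates": estimates,
        "tables": tables,
        "strength": strength,
        "heterogeneity": het,
        "loo": loo,
        "figures": figures,
        "i2gx": i2gx_val,
        "presso_global_p": presso_p,
        "radial_table": radial_tab,
        "truth": truth,
        "manifest": manifest,
    }
    if cfg.out_dir:
        write_bundle(bundle, cfg.out_dir)
    return bundle


def _config_echo(cfg: PipelineConfig) -> dict:
    def enc(v):
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
        if isinstance(v, (tuple, list)):
            return [enc(x) for x in v]
        if isinstance(v, dict):
            return {str(k): enc(x) for k, x in v.items()}
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    return {k: enc(v) for k, v in dataclasses.asdict(cfg).items()}


def write_bundle(bundle: dict, out_dir) -> None:
    """Serialize the output bundle as TSVs plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(bundle["harmonized"], out / "harmonized.tsv")
    write_table(bundle["ledger"].to_frame(), out / "qc_ledger.tsv")
    write_table(bundle["ledger"].removed_frame(), out / "qc_removed.tsv")
    write_table(bundle["tables"]["mr_results"], out / "mr_results.tsv")
    write_table(bundle["tables"]["heterogeneity"], out / "heterogeneity.tsv")
    write_table(bundle["loo"].rows, out / "loo.tsv")
    for name in ("scatter", "slopes", "funnel", "forest"):
        write_table(bundle["figures"][name], out / f"{name}.tsv")
    if bundle["truth"] is not None:
        write_table(bundle["truth"]["per_snp"], out / "truth.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2, default=str)


def render_plots(bundle: dict, out_dir) -> list:
    """Optional PNG rendering of the scatter, funnel and forest data."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(6, 5))
    sc = bundle["figures"]["scatter"]
    ax.errorbar(
        sc["gamma_hat"], sc["big_gamma_hat"],
        xerr=sc["gamma_err"], yerr=sc["big_gamma_err"],
        fmt="o", ms=3, alpha=0.5, lw=0.5,
    )
    xs = np.linspace(0, sc["gamma_hat"].max() * 1.05, 50)
    for _, row in bundle["figures"]["slopes"].iterrows():
        ax.plot(xs, row["intercept"] + row["slope"] * xs, label=row["method"])
    ax.set_xlabel("variant-exposure effect (SD)")
    ax.set_ylabel("variant-outcome effect (log OR)")
    ax.legend(fontsize=7)
    fig.savefig(out / "scatter.png", dpi=150)
    plt.close(fig)
    written.append(out / "scatter.png")

    fig, ax = plt.subplots(figsize=(5, 5))
    fu = bundle["figures"]["funnel"]
    ax.plot(fu["ratio"], fu["precision"], "o", ms=3, alpha=0.6)
    for _, row in bundle["figures"]["slopes"].iterrows():
        if row["method"] in ("IVW", "MR-Egger"):
            ax.axvline(row["slope"], ls="--", lw=1, label=row["method"])
    ax.set_xlabel("per-variant ratio estimate (log OR per SD)")
    ax.set_ylabel("precision 1/SE")
    ax.legend(fontsize=7)
    fig.savefig(out / "funnel.png", dpi=150)
    plt.close(fig)
    written.append(out / "funnel.png")

    fig, ax = plt.subplots(figsize=(6, 3))
    fo = bundle["figures"]["forest"]
    ypos = np.arange(len(fo))[::-1]
    ax.errorbar(
        fo["or_"], ypos,
        xerr=[fo["or_"] - fo["ci_low"], fo["ci_high"] - fo["or_"]],
        fmt="s", capsize=3,
    )
    ax.axvline(1.0, color="grey", lw=1)
    ax.set_yticks(ypos)
    ax.set_yticklabels(fo["method"])
    ax.set_xlabel("OR per 1-SD exposure (95% CI)")
    fig.tight_layout()
    fig.savefig(out / "forest.png", dpi=150)
    plt.close(fig)
    written.append(out / "forest.png")
    return written
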