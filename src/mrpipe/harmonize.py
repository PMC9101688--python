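"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR needs both effect estimates expressed per copy of the same
effect allele.  Sources may report the opposite allele (swap: negate the
effect, complement the frequency), the complementary strand (A<->T,
C<->G), or both.  Palindromic variants (A/T or C/G) are strand-ambiguous:
their orientation can only be inferred from allele frequencies, and only
when the frequency is away from 0.5; inside the intermediate band they
are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GwasTable

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical columns of a harmonized instrument table.
HARMONIZED_COLUMNS = [
    "SNP",
    "effect_allele",
    "other_allele",
    "gamma_hat",
    "se_gamma",
    "big_gamma_hat",
    "se_big_gamma",
    "eaf_exposure",
    "eaf_outcome",
]


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"not an ACGT base: {base!r}") from None


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is A/T or C/G in either order."""
    a, b = effect_allele.upper(), other_allele.upper()
    if a not in _COMPLEMENT or b not in _COMPLEMENT:
        raise ValueError(f"not ACGT bases: {effect_allele!r}/{other_allele!r}")
    if a == b:
        raise ValueError("effect and other allele must differ")
    return _COMPLEMENT[a] == b


@dataclass
class HarmonizationReport:
    """Accounting of what happened to every exposure variant."""

    n_input: int = 0
    n_matched: int = 0
    n_flipped: int = 0
    n_palindromic_dropped: int = 0
    n_unmatched: int = 0
    dropped_ids: list = field(default_factory=list)  # (rsID, reason)

    def check(self) -> None:
        assert self.n_matched + self.n_unmatched == self.n_input

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped_ids, columns=["SNP", "reason"])


def harmonize_instruments(
    exposure: GwasTable,
    outcome: GwasTable,
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Align exposure and outcome effects onto a common effect allele.

    For each exposure variant present in the outcome table: a direct
    allele match is kept as-is; swapped alleles negate the outcome effect
    and complement its EAF; a match that only succeeds after strand
    complement is complemented first (swap handled the same way after).
    Palindromic variants are oriented by EAF concordance — dropped when
    either study's EAF lies inside ``palindrome_eaf_band`` or is missing.

    Returns a DataFrame with :data:`HARMONIZED_COLUMNS` and a
    :class:`HarmonizationReport`.  γ̂ denotes the variant-exposure effect,
    Γ̂ the variant-outcome effect.
    """
    lo, hi = palindrome_eaf_band
    if not (0.0 < lo < 0.5 < hi < 1.0):
        raise ValueError(f"palindrome_eaf_band must straddle 0.5: {palindrome_eaf_band}")

    out_ix = outcome.records.set_index("SNP")
    report = HarmonizationReport(n_input=len(exposure.records))
    rows = []

    for rec in exposure.records.itertuples(index=False):
        if rec.SNP not in out_ix.index:
            report.n_unmatched += 1
            report.dropped_ids.append((rec.SNP, "not_in_outcome"))
            continue
        report.n_matched += 1
        o = out_ix.loc[rec.SNP]
        e1, e2 = rec.effect_allele, rec.other_allele
        o1, o2 = o["effect_allele"], o["other_allele"]
        o_beta, o_se, o_eaf = o["beta"], o["se"], o["eaf"]

        if is_palindromic(e1, e2):
            # same pair up to order is the only reconcilable configuration
            if {o1, o2} != {e1, e2}:
                report.dropped_ids.append((rec.SNP, "allele_mismatch"))
                continue
            eaf_exp, eaf_out = rec.eaf, o_eaf
            # strand is ambiguous; an allele swap is indistinguishable from
            # a strand flip, so orientation comes from frequency alone
            if o1 != e1:
                o_beta, o_eaf = -o_beta, 1.0 - o_eaf
                eaf_out = o_eaf
            if (
                pd.isna(eaf_exp)
                or pd.isna(eaf_out)
                or lo <= eaf_exp <= hi
                or lo <= eaf_out <= hi
            ):
                report.n_palindromic_dropped += 1
                report.dropped_ids.append((rec.SNP, "palindromic_intermediate"))
                continue
            if (eaf_exp < 0.5) != (eaf_out < 0.5):
                # frequencies imply the outcome labels the opposite allele
                o_beta, eaf_out = -o_beta, 1.0 - eaf_out
                report.n_flipped += 1
            rows.append(
                (rec.SNP, e1, e2, rec.beta, rec.se, o_beta, o_se, eaf_exp, eaf_out)
            )
            continue

        if (o1, o2) == (e1, e2):
            pass
        elif (o1, o2) == (e2, e1):
            o_beta = -o_beta
            o_eaf = 1.0 - o_eaf if pd.notna(o_eaf) else o_eaf
            report.n_flipped += 1
        else:
            c1, c2 = complement(o1), complement(o2)
            if (c1, c2) == (e1, e2):
                pass
            elif (c1, c2) == (e2, e1):
                o_beta = -o_beta
                o_eaf = 1.0 - o_eaf if pd.notna(o_eaf) else o_eaf
                report.n_flipped += 1
            else:
                report.dropped_ids.append((rec.SNP, "allele_mismatch"))
                continue
        rows.append(
            (rec.SNP, e1, e2, rec.beta, rec.se, o_beta, o_se, rec.eaf, o_eaf)
        )

    harmonized = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    report.check()
    logger.info(
        "harmonized %d/%d variants (%d sign-flipped, %d palindromic dropped, "
        "%d unmatched)",
        len(harmonized),
        report.n_input,
        report.n_flipped,
        report.n_palindromic_dropped,
        report.n_unmatched,
    )
    return harmonized, report


def as_instrument_frame(obj) -> pd.DataFrame:
    """Coerce a harmonized table (DataFrame or array-like) for estimators.

    Arrays are interpreted as columns ``gamma_hat, se_gamma,
    big_gamma_hat, se_big_gamma`` in that order.
    """
    if isinstance(obj, pd.DataFrame):
        missing = [
            c
            for c in ("gamma_hat", "se_gamma", "big_gamma_hat", "se_big_gamma")
            if c not in obj.columns
        ]
        if missing:
            raise ValueError(f"instrument frame missing columns: {missing}")
        return obj
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("expected (L, 4) array: gamma, se_gamma, Gamma, se_Gamma")
    df = pd.DataFrame(
        arr, columns=["gamma_hat", "se_gamma", "big_gamma_hat", "se_big_gamma"]
    )
    df.insert(0, "SNP", [f"snp{i}" for i in range(len(df))])
    return df
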