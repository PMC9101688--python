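"""Reading, validating and writing GWAS summary-statistic tables.

A summary-statistic table carries, per variant, the effect allele, the
other allele, the effect-allele frequency (EAF), the per-allele effect
estimate (SD units for a quantitative exposure, log-odds for a binary
outcome), its standard error, the association p-value and the sample
size.  Files are delimited text in whatever column layout the source
consortium chose; a ``column_map`` translates source headers to the
canonical schema.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order for summary-statistic tables.
CANONICAL_COLUMNS = [
    "SNP",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: Tokens accepted as "missing" on input; "NA" is emitted on output.
NA_TOKENS = {"", "NA", ".", "na", "NaN", "nan"}

VALID_BASES = frozenset("ACGT")


class GwasIOError(ValueError):
    """Configuration or validation failure while reading a summary file."""


@dataclass
class GwasTable:
    """A validated GWAS summary-statistic table.

    ``records`` is a DataFrame with the canonical columns
    (:data:`CANONICAL_COLUMNS`); ``eaf`` and ``n`` may contain NaN.
    """

    records: pd.DataFrame
    trait_label: str = ""
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise GwasIOError(f"table missing canonical columns: {missing}")
        if self.records["SNP"].duplicated().any():
            dups = self.records.loc[self.records["SNP"].duplicated(), "SNP"]
            raise GwasIOError(f"duplicate variant ids: {sorted(set(dups))[:5]} ...")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, mask_or_ids) -> "GwasTable":
        """New table restricted to a boolean mask or iterable of SNP ids."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and len(
            mask_or_ids
        ) == len(self.records) and pd.api.types.is_bool_dtype(
            pd.Series(mask_or_ids)
        ):
            sub = self.records.loc[pd.Series(mask_or_ids, index=self.records.index)]
        else:
            keep = set(mask_or_ids)
            sub = self.records[self.records["SNP"].isin(keep)]
        return GwasTable(sub.reset_index(drop=True), trait_label=self.trait_label)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a canonical-column frame into (valid, rejected-with-reason)."""
    reasons = pd.Series("", index=df.index, dtype=object)

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    bad_allele = ~(ea.isin(VALID_BASES) & oa.isin(VALID_BASES))
    same_allele = (ea == oa) & ~bad_allele
    reasons[bad_allele] = "invalid_allele"
    reasons[same_allele] = "identical_alleles"

    numeric_bad = df["beta"].isna() | df["se"].isna() | df["pval"].isna()
    reasons[numeric_bad & (reasons == "")] = "unparseable_numeric"
    reasons[(df["se"] <= 0) & (reasons == "")] = "nonpositive_se"
    bad_p = (df["pval"] <= 0) | (df["pval"] > 1)
    reasons[bad_p & (reasons == "")] = "pval_out_of_range"
    bad_eaf = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
    reasons[bad_eaf & (reasons == "")] = "eaf_out_of_range"
    bad_n = df["n"].notna() & (df["n"] <= 0)
    reasons[bad_n & (reasons == "")] = "nonpositive_n"

    ok = reasons == ""
    valid = df[ok].copy()
    valid["effect_allele"] = ea[ok]
    valid["other_allele"] = oa[ok]
    rejected = df[~ok].copy()
    rejected["reason"] = reasons[~ok]
    return valid, rejected


def read_gwas_table(
    path,
    column_map: dict[str, str] | None = None,
    delimiter: str = "\t",
    trait_label: str = "",
    max_reject_fraction: float = 0.05,
) -> GwasTable:
    """Read a delimited summary-statistic file into a validated table.

    Parameters
    ----------
    path : str or Path
        File with a header line.
    column_map : dict, optional
        ``{source_column: canonical_field}`` mapping; canonical fields are
        SNP, effect_allele, other_allele, eaf, beta, se, pval, n.  Columns
        already named canonically need no entry.  ``eaf`` and ``n`` are
        optional; the others must be resolvable.
    delimiter : str
        Field separator; ``None`` splits on any whitespace run.
    max_reject_fraction : float
        Rows violating invariants are collected and dropped with a logged,
        row-indexed diagnostic; if more than this fraction of data rows
        fail, reading aborts (the file is probably mis-mapped).
    """
    read_kwargs = dict(dtype=str, keep_default_na=False, comment=None)
    if delimiter is None:
        df = pd.read_csv(path, sep=r"\s+", **read_kwargs)
    else:
        df = pd.read_csv(path, sep=delimiter, **read_kwargs)

    column_map = dict(column_map or {})
    rename = {src: dst for src, dst in column_map.items()}
    missing_src = [c for c in rename if c not in df.columns]
    if missing_src:
        raise GwasIOError(
            f"mapped columns absent from header of {path}: {missing_src}; "
            f"header was {list(df.columns)}"
        )
    df = df.rename(columns=rename)

    required = ["SNP", "effect_allele", "other_allele", "beta", "se", "pval"]
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise GwasIOError(
            f"cannot resolve required fields {absent} in {path}; "
            "provide a column_map"
        )
    for optional in ("eaf", "n"):
        if optional not in df.columns:
            df[optional] = "NA"

    df = df[CANONICAL_COLUMNS].copy()
    n_input = len(df)
    for col in ("eaf", "beta", "se", "pval", "n"):
        raw = df[col].astype(str).str.strip()
        raw[raw.isin(NA_TOKENS)] = "NaN"
        df[col] = pd.to_numeric(raw, errors="coerce")

    valid, rejected = _validate_rows(df)
    if len(rejected):
        for idx, row in rejected.iterrows():
            logger.warning(
                "rejected row %d (%s): %s", idx, row.get("SNP", "?"), row["reason"]
            )
        frac = len(rejected) / max(n_input, 1)
        if frac > max_reject_fraction:
            raise GwasIOError(
                f"{len(rejected)}/{n_input} rows rejected "
                f"({frac:.1%} > {max_reject_fraction:.1%}); aborting"
            )

    valid = valid.reset_index(drop=True)
    valid["n"] = valid["n"].astype(float)
    return GwasTable(valid, trait_label=trait_label, rejected=rejected)


def _format_value(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float) and (math.isnan(x) or pd.isna(x)):
        return "NA"
    if isinstance(x, (float, np.floating)):
        if float(x) == int(x) and abs(x) < 1e15:
            return repr(float(x)) if abs(x) < 1e6 else f"{x:.10g}"
        return f"{x:.10g}"
    return str(x)


def write_table(table, path) -> None:
    """Write a table as tab-delimited text with ≥10 significant digits.

    Accepts a :class:`GwasTable` or any DataFrame (result tables share the
    same serialization: tabs, "NA" for missing).
    """
    df = table.records if isinstance(table, GwasTable) else table
    out = df.copy()
    for col in out.columns:
        out[col] = out[col].map(_format_value)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    """Read back any table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", na_values=sorted(NA_TOKENS - {""}))
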