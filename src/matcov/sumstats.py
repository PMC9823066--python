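"""GWAS summary statistics: in-memory container and tab-delimited I/O.

The on-disk format is the LDSC/METAL-style tab-delimited table with one row
per SNP and columns SNP, A1, A2, FRQ, BETA, SE, Z, P, N. Reading tolerates
the common column-name aliases declared in :data:`COLUMN_ALIASES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED = ["SNP", "A1", "A2", "BETA", "SE", "N"]
CANONICAL = ["SNP", "A1", "A2", "FRQ", "BETA", "SE", "Z", "P", "N"]

#: alias -> canonical, applied case-insensitively
COLUMN_ALIASES = {
    "snp": "SNP", "rsid": "SNP", "markername": "SNP", "id": "SNP",
    "a1": "A1", "allele1": "A1", "effect_allele": "A1", "ea": "A1",
    "a2": "A2", "allele2": "A2", "other_allele": "A2", "oa": "A2", "nea": "A2",
    "frq": "FRQ", "freq": "FRQ", "eaf": "FRQ", "maf": "FRQ", "freq1": "FRQ",
    "beta": "BETA", "effect": "BETA", "b": "BETA", "est": "BETA",
    "se": "SE", "stderr": "SE", "std_err": "SE",
    "z": "Z", "zscore": "Z", "z_score": "Z",
    "p": "P", "pval": "P", "p_value": "P", "p-value": "P", "pvalue": "P",
    "n": "N", "nobs": "N", "samplesize": "N", "n_total": "N",
}

_NUMERIC = ["FRQ", "BETA", "SE", "Z", "P", "N"]


@dataclass
class SumStats:
    """One GWAS's per-SNP results plus design metadata.

    ``design`` is "own" (own genotype, own phenotype) or "proxy" (maternal
    genotype, offspring phenotype).
    """

    table: pd.DataFrame
    trait: str = ""
    design: str = "own"
    meta_log: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sumstats missing mandatory columns: {missing}")
        if self.design not in ("own", "proxy"):
            raise ValueError(f"design must be 'own' or 'proxy', got {self.design!r}")
        t = self.table
        if "Z" not in t.columns:
            t["Z"] = t["BETA"] / t["SE"]
        if "P" not in t.columns:
            from scipy import stats
            t["P"] = 2 * stats.norm.sf(np.abs(t["Z"]))

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def __len__(self) -> int:
        return len(self.table)


def _canonicalize(columns) -> dict:
    out = {}
    for c in columns:
        key = str(c).strip().lower()
        if key in COLUMN_ALIASES:
            out[c] = COLUMN_ALIASES[key]
        elif str(c).upper() in CANONICAL:
            out[c] = str(c).upper()
    return out


def read_sumstats(path: str | Path, trait: str = "", design: str = "own") -> SumStats:
    """Read a tab-delimited (optionally gzipped) sumstats file.

    Raises ValueError listing missing mandatory columns, or the 1-based data
    line numbers of rows with malformed numeric cells (those rows are
    rejected, not silently coerced).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns=_canonicalize(df.columns))
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    bad = pd.Series(False, index=df.index)
    for c in [c for c in _NUMERIC if c in df.columns]:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad |= vals.isna() & df[c].notna()
        df[c] = vals
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
        raise ValueError(f"{path}: malformed numeric cells on lines {lines}")
    return SumStats(df.reset_index(drop=True), trait=trait, design=design)


def write_sumstats(ss: SumStats, path: str | Path) -> None:
    """Write the canonical tab-delimited layout (gzip if path ends in .gz)."""
    cols = [c for c in CANONICAL if c in ss.table.columns]
    extra = [c for c in ss.table.columns if c not in cols]
    ss.table[cols + extra].to_csv(path, sep="\t", index=False, na_rep="NA")
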