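"""Per-SNP association and fixed-effects meta-analysis.

``run_gwas`` performs ordinary least squares of a (covariate-residualized)
phenotype on each SNP's allele dosage, one SNP at a time, vectorized across
SNPs. The "proxy" design pairs maternal dosages with offspring phenotypes;
with a purely fetal architecture its per-allele effects are attenuated by
the 0.5 mother-offspring genotype correlation.

``meta_fixed`` is METAL-style fixed-effects meta-analysis with allele
alignment to the first study, supporting inverse-variance and
sample-size-weighted-z schemes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SumStats

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _residualize(y: np.ndarray, covariates) -> tuple[np.ndarray, int]:
    """Residualize y on [1, covariates]; returns (residual, n_parameters)."""
    n = len(y)
    if covariates is None:
        return y - y.mean(), 1
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    design = np.column_stack([np.ones(n), c])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef, design.shape[1]


def _scan(dosages, Y, dof, chunk=2048):
    """Vectorized per-SNP simple regression of each column of Y (already
    residualized, mean zero) on each dosage column."""
    n, m = np.shape(dosages)
    t = Y.shape[1]
    syy = np.einsum("ij,ij->j", Y, Y)
    beta = np.empty((m, t))
    se = np.empty((m, t))
    freq = np.empty(m)
    Y32 = Y.astype(np.float32)
    int_dosages = np.issubdtype(np.asarray(dosages).dtype, np.integer)
    for s in range(0, m, chunk):
        x8 = np.asarray(dosages[:, s : s + chunk])
        x = x8.astype(np.float32)
        if int_dosages:
            # allele counts are 0/1/2: sum x = n1 + 2 n2, sum x^2 = n1 + 4 n2
            n2 = np.count_nonzero(x8 == 2, axis=0)
            colsum = x8.sum(axis=0, dtype=np.int64)
            xm = colsum / n
            sxx = (colsum + 2 * n2) - n * xm**2
        else:
            xm = x.mean(axis=0, dtype=np.float64)
            sxx = np.einsum("ij,ij->j", x, x, dtype=np.float64) - n * xm**2
        sxy = (x.T @ Y32).astype(np.float64)  # residual mean zero: no centering
        with np.errstate(divide="ignore", invalid="ignore"):
            b = sxy / sxx[:, None]
            resid_var = np.maximum(syy[None, :] - b * sxy, 0.0) / dof
            s2 = np.sqrt(resid_var / sxx[:, None])
        mono = sxx <= 0
        b[mono] = np.nan
        s2[mono] = np.nan
        beta[s : s + len(b)] = b
        se[s : s + len(b)] = s2
        freq[s : s + len(b)] = xm / 2.0
    return beta, se, freq


def _as_sumstats(snp_map, beta, se, freq, n, design, trait):
    with np.errstate(invalid="ignore"):
        z = beta / se
    table = pd.DataFrame(
        {
            "SNP": snp_map["SNP"].to_numpy(),
            "A1": snp_map["A1"].to_numpy(),
            "A2": snp_map["A2"].to_numpy(),
            "FRQ": freq,
            "BETA": beta,
            "SE": se,
            "Z": z,
            "P": 2 * stats.norm.sf(np.abs(z)),
            "N": n,
            "MONOMORPHIC": np.isnan(beta),
        }
    )
    return SumStats(table, trait=trait, design=design)


def _default_snp_map(m):
    return pd.DataFrame({"SNP": [f"rs{i + 1}" for i in range(m)], "A1": "A", "A2": "G"})


def run_gwas(dosages, phenotype, covariates=None, snp_map=None,
             design: str = "own", trait: str = "", chunk: int = 2048) -> SumStats:
    """Per-SNP least-squares association scan.

    Parameters
    ----------
    dosages : (n, m) allele counts; for design="proxy" these are the
        mothers' dosages and ``phenotype`` the offspring phenotype.
    phenotype, covariates : per-individual arrays (complete cases). The
        phenotype is residualized on [intercept, covariates] first, then
        each SNP is tested by simple least squares on the residual.
    snp_map : DataFrame with SNP/A1/A2 (and optionally FRQ) per column of
        ``dosages``; synthesized if absent.

    Monomorphic SNPs are emitted with missing beta/se and a MONOMORPHIC
    flag, never dropped.
    """
    return run_gwas_multi(dosages, {trait or "y": phenotype}, covariates,
                          snp_map=snp_map, design=design, chunk=chunk)[trait or "y"]


def run_gwas_multi(dosages, phenotypes, covariates=None, snp_map=None,
                   design: str = "own", chunk: int = 2048) -> dict:
    """Association scans of several phenotypes measured on the same
    individuals against the same dosage matrix (shared genotype pass)."""
    phenotypes = dict(phenotypes) if not isinstance(phenotypes, pd.DataFrame) else {
        c: phenotypes[c] for c in phenotypes.columns}
    n, m = np.shape(dosages)
    Y = np.column_stack([np.asarray(v, dtype=float) for v in phenotypes.values()])
    if Y.shape[0] != n:
        raise ValueError("phenotype length does not match dosage rows")
    cols = []
    n_par = 1
    for j in range(Y.shape[1]):
        r, n_par = _residualize(Y[:, j], covariates)
        cols.append(r)
    if n < n_par + 3:
        raise ValueError("need at least 3 more individuals than covariates")
    Y = np.column_stack(cols)
    beta, se, freq = _scan(dosages, Y, dof=n - n_par - 1, chunk=chunk)
    if snp_map is None:
        snp_map = _default_snp_map(m)
    return {
        name: _as_sumstats(snp_map, beta[:, j], se[:, j], freq, n, design, name)
        for j, name in enumerate(phenotypes)
    }


def _align_to(ref: pd.DataFrame, other: pd.DataFrame, log: dict) -> pd.DataFrame:
    """Align `other` alleles to `ref` (indexed by SNP); flip betas on swap."""
    df = other.set_index("SNP").loc[ref["SNP"]].reset_index()
    same = (df["A1"].to_numpy() == ref["A1"].to_numpy()) & (
        df["A2"].to_numpy() == ref["A2"].to_numpy())
    swapped = (df["A1"].to_numpy() == ref["A2"].to_numpy()) & (
        df["A2"].to_numpy() == ref["A1"].to_numpy())
    df.loc[swapped, "BETA"] = -df.loc[swapped, "BETA"]
    if "FRQ" in df.columns:
        df.loc[swapped, "FRQ"] = 1 - df.loc[swapped, "FRQ"]
    df.loc[swapped, ["A1", "A2"]] = ref.loc[swapped, ["A1", "A2"]].to_numpy()
    bad = ~(same | swapped)
    log["irreconcilable_alleles"] = log.get("irreconcilable_alleles", 0) + int(bad.sum())
    df.loc[bad, "BETA"] = np.nan
    return df


def meta_fixed(studies: list[SumStats], scheme: str = "ivw") -> SumStats:
    """Fixed-effects meta-analysis of >= 2 studies matched by SNP identifier.

    Alleles are aligned to the first study; strand-ambiguous (A/T, C/G)
    SNPs are dropped with a count recorded in ``meta_log``, as are SNPs
    whose alleles cannot be reconciled. scheme="ivw" combines with inverse
    variance weights; scheme="z" uses sample-size-weighted z statistics
    (the combined beta/se are then back-computed from z, N and frequency-free
    unit scaling is not attempted: beta is the ivw average, se implied by z).
    """
    if len(studies) < 2:
        raise ValueError("meta_fixed needs at least 2 studies")
    if scheme not in ("ivw", "z"):
        raise ValueError(f"unknown scheme {scheme!r}")
    log: dict = {}

    first = studies[0].table
    ambiguous = first.apply(
        lambda r: (str(r["A1"]).upper(), str(r["A2"]).upper()) in _AMBIGUOUS, axis=1
    ).to_numpy()
    log["strand_ambiguous_dropped"] = int(ambiguous.sum())
    ref = first.loc[~ambiguous].reset_index(drop=True)

    common = ref["SNP"]
    for st in studies[1:]:
        common = common[common.isin(st.table["SNP"])]
    ref = ref.set_index("SNP").loc[common].reset_index()
    if len(ref) == 0:
        raise ValueError("zero overlapping SNPs across studies")

    aligned = [ref] + [_align_to(ref, st.table, log) for st in studies[1:]]
    betas = np.column_stack([a["BETA"].to_numpy(dtype=float) for a in aligned])
    ses = np.column_stack([a["SE"].to_numpy(dtype=float) for a in aligned])
    ns = np.column_stack([a["N"].to_numpy(dtype=float) for a in aligned])

    ok = np.isfinite(betas).all(axis=1) & np.isfinite(ses).all(axis=1)
    log["incomplete_dropped"] = int((~ok).sum()) - log.get("irreconcilable_alleles", 0)
    betas, ses, ns, ref = betas[ok], ses[ok], ns[ok], ref.loc[ok].reset_index(drop=True)
    if len(ref) == 0:
        raise ValueError("zero overlapping SNPs after allele reconciliation")

    n_tot = ns.sum(axis=1)
    if scheme == "ivw":
        w = 1.0 / ses**2
        beta = (w * betas).sum(axis=1) / w.sum(axis=1)
        se = w.sum(axis=1) ** -0.5
        z = beta / se
    else:
        zs = betas / ses
        z = (np.sqrt(ns) * zs).sum(axis=1) / np.sqrt(n_tot)
        w = 1.0 / ses**2
        beta = (w * betas).sum(axis=1) / w.sum(axis=1)
        se = np.abs(beta / np.where(z == 0, np.nan, z))
    out = pd.DataFrame(
        {
            "SNP": ref["SNP"],
            "A1": ref["A1"],
            "A2": ref["A2"],
            "FRQ": ref["FRQ"] if "FRQ" in ref.columns else np.nan,
            "BETA": beta,
            "SE": se,
            "Z": z,
            "P": 2 * stats.norm.sf(np.abs(z)),
            "N": n_tot,
        }
    )
    return SumStats(out, trait=studies[0].trait, design=studies[0].design, meta_log=log)
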