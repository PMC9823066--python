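"""LD score regression: stage 1 of the two-stage covariance-structure method.

Univariate LD score regression regresses per-SNP GWAS chi-square statistics
on N * l / M (l the SNP's LD score, M the SNP count): the slope estimates
SNP heritability and the free intercept absorbs confounding. Bivariate
regression of z1*z2 on sqrt(N1*N2) * l / M estimates the genetic covariance
between two GWAS; its free intercept absorbs sample overlap times
phenotypic correlation. Standard errors and the joint sampling covariance V
of all k(k+1)/2 estimates come from a delete-one-block jackknife over
position-ordered SNP blocks, computed on a common block partition so
cross-element covariances are captured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import vech_indices


# ---------------------------------------------------------------------------
# LD scores


@dataclass
class LDScores:
    """Per-SNP LD scores. ``table`` columns: SNP, IDX, L2."""

    table: pd.DataFrame
    n_ref: int

    @property
    def m(self) -> int:
        """SNP count backing the scores (the default M for regressions)."""
        return int(self.table["L2"].notna().sum())


def compute_ld_scores(ref_dosages, window_snps: int, snp_map=None) -> LDScores:
    """Bias-adjusted LD scores from a reference dosage panel.

    l_j = sum over |k - j| <= window of r2_adj(j, k), with
    r2_adj = r2 - (1 - r2) / (n - 2); the self term contributes exactly 1.
    Monomorphic reference SNPs get an undefined (NaN) score and are masked
    from downstream regressions.
    """
    x = np.asarray(ref_dosages, dtype=np.float32)
    n, m = x.shape
    if n < 100:
        raise ValueError(f"reference panel needs >= 100 individuals, got {n}")
    sd = x.std(axis=0)
    mono = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - x.mean(axis=0)) / sd
    z[:, mono] = 0.0
    ell = np.ones(m)
    adj = 1.0 / (n - 2)
    for d in range(1, min(window_snps, m - 1) + 1):
        r = np.einsum("ij,ij->j", z[:, :-d], z[:, d:]) / n
        r2a = r * r - (1 - r * r) * adj
        ell[:-d] += r2a
        ell[d:] += r2a
    ell[mono] = np.nan
    if snp_map is not None:
        snp = snp_map["SNP"].to_numpy()
        idx = snp_map["IDX"].to_numpy() if "IDX" in snp_map.columns else np.arange(m)
    else:
        snp, idx = [f"rs{i + 1}" for i in range(m)], np.arange(m)
    return LDScores(pd.DataFrame({"SNP": snp, "IDX": idx, "L2": ell}), n_ref=n)


def write_ld_scores(ld: LDScores, path) -> None:
    ld.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_ld_scores(path, n_ref: int = 0) -> LDScores:
    return LDScores(pd.read_csv(path, sep="\t"), n_ref=n_ref)


# ---------------------------------------------------------------------------
# weighted block-jackknife regression machinery


def _block_slices(m: int, n_blocks: int) -> list[slice]:
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def _wls_jackknife(x, y, w, blocks):
    """Weighted LS of y on [x, 1] with delete-one-block estimates.

    Returns (est, delete, se): est and se are length-2 (slope, intercept);
    delete is (n_blocks, 2).
    """
    X = np.column_stack([x, np.ones_like(x)])
    n_blocks = len(blocks)
    A = np.zeros((n_blocks, 2, 2))
    c = np.zeros((n_blocks, 2))
    for i, b in enumerate(blocks):
        Xw = X[b] * w[b, None]
        A[i] = Xw.T @ X[b]
        c[i] = Xw.T @ y[b]
    A_tot, c_tot = A.sum(axis=0), c.sum(axis=0)
    est = np.linalg.solve(A_tot, c_tot)
    delete = np.stack(
        [np.linalg.solve(A_tot - A[i], c_tot - c[i]) for i in range(n_blocks)]
    )
    pseudo = n_blocks * est - (n_blocks - 1) * delete
    se = np.sqrt(pseudo.var(axis=0, ddof=1) / n_blocks)
    return est, delete, se


def _merge(ss, ld: LDScores):
    t = ss.table[["SNP", "Z", "N"]].merge(ld.table, on="SNP", how="inner")
    t = t.dropna(subset=["Z", "L2"]).sort_values("IDX").reset_index(drop=True)
    return t


def _uni_weights(ell, n, h2, M):
    h2 = float(np.clip(h2, 0.0, 1.0))
    het = 2.0 * (1.0 + n * h2 * ell / M) ** 2
    return 1.0 / (np.maximum(ell, 1.0) * het)


def _biv_weights(ell, n1, n2, h1, h2, rho, icpt, M):
    h1 = float(np.clip(h1, 0.0, 1.0))
    h2 = float(np.clip(h2, 0.0, 1.0))
    a = (1.0 + n1 * h1 * ell / M) * (1.0 + n2 * h2 * ell / M)
    b = (np.sqrt(n1 * n2) * rho * ell / M + icpt) ** 2
    return 1.0 / (np.maximum(ell, 1.0) * np.maximum(a + b, 0.05))


# ---------------------------------------------------------------------------
# estimators


@dataclass
class LdscFit:
    """Result of one LD score regression (slope on the (co)heritability scale)."""

    est: float
    se: float
    intercept: float
    intercept_se: float
    n_snps: int
    M: int
    delete_values: np.ndarray  # (n_blocks, 2): slope, intercept

    @property
    def z(self) -> float:
        return self.est / self.se

    @property
    def reliable(self) -> bool:
        """Z > 4, the conventional threshold for estimates stable enough to
        support downstream genetic-correlation modelling."""
        return bool(self.z > 4)


class LDScoreRegression(BaseEstimator):
    """Univariate LD score regression (SNP heritability).

    Two-step weighting: heteroskedasticity weights 1 / (2 (1 + N h2 l / M)^2)
    times LD overcounting weights 1 / l, with h2 updated once from a first
    pass. Standard errors by delete-one-block jackknife.

    Attributes (after ``fit(sumstats, ld_scores)``): ``h2_``, ``h2_se_``,
    ``intercept_``, ``intercept_se_``, ``z_``, ``reliable_``, ``n_snps_``,
    ``fit_`` (the underlying :class:`LdscFit`).
    """

    def __init__(self, n_blocks: int = 200, M: int | None = None, min_snps: int = 200):
        self.n_blocks = n_blocks
        self.M = M
        self.min_snps = min_snps

    def fit(self, sumstats, ld_scores: LDScores):
        t = _merge(sumstats, ld_scores)
        if len(t) < self.min_snps:
            raise ValueError(f"only {len(t)} SNPs after merge; need >= {self.min_snps}")
        if self.n_blocks < 20:
            raise ValueError("n_blocks must be >= 20")
        M = self.M or ld_scores.m
        ell, n = t["L2"].to_numpy(), t["N"].to_numpy(dtype=float)
        y = t["Z"].to_numpy() ** 2
        x = n * ell / M
        blocks = _block_slices(len(t), self.n_blocks)
        h2_0 = M * (y.mean() - 1.0) / (n * ell).mean()
        est, _, _ = _wls_jackknife(x, y, _uni_weights(ell, n, h2_0, M), blocks)
        w = _uni_weights(ell, n, est[0], M)
        est, delete, se = _wls_jackknife(x, y, w, blocks)
        self.fit_ = LdscFit(est[0], se[0], est[1], se[1], len(t), M, delete)
        self.h2_, self.h2_se_ = self.fit_.est, self.fit_.se
        self.intercept_, self.intercept_se_ = self.fit_.intercept, self.fit_.intercept_se
        self.z_, self.reliable_ = self.fit_.z, self.fit_.reliable
        self.n_snps_ = self.fit_.n_snps
        return self


class CrossTraitLDScoreRegression(BaseEstimator):
    """Bivariate LD score regression (genetic covariance between two GWAS).

    Regresses z1 * z2 on sqrt(N1 N2) * l / M with a free intercept that
    absorbs sample overlap times phenotypic correlation.

    Attributes: ``gencov_``, ``gencov_se_``, ``intercept_``,
    ``intercept_se_``, ``n_snps_``, ``fit_``.
    """

    def __init__(self, n_blocks: int = 200, M: int | None = None, min_snps: int = 200):
        self.n_blocks = n_blocks
        self.M = M
        self.min_snps = min_snps

    def fit(self, sumstats1, sumstats2, ld_scores: LDScores, h2_pair=None):
        if self.n_blocks < 20:
            raise ValueError("n_blocks must be >= 20")
        t1, t2 = _merge(sumstats1, ld_scores), _merge(sumstats2, ld_scores)
        t = t1.merge(t2[["SNP", "Z", "N"]], on="SNP", suffixes=("1", "2"))
        t = t.sort_values("IDX").reset_index(drop=True)
        if len(t) < self.min_snps:
            raise ValueError(f"only {len(t)} SNPs in intersection; need >= {self.min_snps}")
        M = self.M or ld_scores.m
        ell = t["L2"].to_numpy()
        z1, z2 = t["Z1"].to_numpy(), t["Z2"].to_numpy()
        n1, n2 = t["N1"].to_numpy(dtype=float), t["N2"].to_numpy(dtype=float)
        if h2_pair is None:
            # two-step univariate slope for each trait, matching the joint
            # estimator's weighting exactly
            h2_pair = []
            for z, n in ((z1, n1), (z2, n2)):
                y_u, x_u = z * z, n * ell / M
                h2_0 = M * (y_u.mean() - 1.0) / (n * ell).mean()
                blocks_u = _block_slices(len(t), self.n_blocks)
                e, _, _ = _wls_jackknife(x_u, y_u, _uni_weights(ell, n, h2_0, M), blocks_u)
                e, _, _ = _wls_jackknife(x_u, y_u, _uni_weights(ell, n, e[0], M), blocks_u)
                h2_pair.append(e[0])
        h1, h2 = h2_pair
        y = z1 * z2
        x = np.sqrt(n1 * n2) * ell / M
        blocks = _block_slices(len(t), self.n_blocks)
        rho_0 = M * y.mean() / (np.sqrt(n1 * n2) * ell).mean()
        w = _biv_weights(ell, n1, n2, h1, h2, rho_0, 0.0, M)
        est, _, _ = _wls_jackknife(x, y, w, blocks)
        w = _biv_weights(ell, n1, n2, h1, h2, est[0], est[1], M)
        est, delete, se = _wls_jackknife(x, y, w, blocks)
        self.fit_ = LdscFit(est[0], se[0], est[1], se[1], len(t), M, delete)
        self.gencov_, self.gencov_se_ = self.fit_.est, self.fit_.se
        self.intercept_, self.intercept_se_ = self.fit_.intercept, self.fit_.intercept_se
        self.n_snps_ = self.fit_.n_snps
        return self


# ---------------------------------------------------------------------------
# joint stack


@dataclass
class CovarianceStack:
    """Genetic covariance matrix S with jackknife sampling covariance V.

    V covers the k(k+1)/2 unique elements of S in row-wise upper-triangle
    (vech) order: (0,0), (0,1), ..., (0,k-1), (1,1), ..., (k-1,k-1).
    ``intercepts`` holds univariate intercepts on the diagonal and
    cross-trait intercepts off it.
    """

    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray
    labels: list[str]
    M: int
    n_blocks: int
    N: np.ndarray
    pseudovalues: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.S.shape[0]

    def se_matrix(self) -> np.ndarray:
        """Jackknife SEs arranged like S."""
        k = self.k
        out = np.zeros((k, k))
        for v, (i, j) in zip(np.sqrt(np.diag(self.V)), vech_indices(k)):
            out[i, j] = out[j, i] = v
        return out


class JointLDScoreRegression(BaseEstimator):
    """All k(k+1)/2 univariate/bivariate regressions on one block partition.

    The delete-one-block estimates of every regression are computed on the
    same position-ordered blocks of the common SNP set, so the jackknife
    pseudovalues capture the sampling covariance between any two elements
    of S (needed as the weight/covariance input V of the stage-2 model).
    """

    def __init__(self, n_blocks: int = 200, M: int | None = None, min_snps: int = 200):
        self.n_blocks = n_blocks
        self.M = M
        self.min_snps = min_snps

    def fit(self, sumstats_list, ld_scores: LDScores):
        k = len(sumstats_list)
        if k < 2:
            raise ValueError("need >= 2 GWAS")
        if self.n_blocks < 20:
            raise ValueError("n_blocks must be >= 20")
        tables = [_merge(ss, ld_scores) for ss in sumstats_list]
        common = tables[0]["SNP"]
        for t in tables[1:]:
            common = common[common.isin(t["SNP"])]
        if len(common) < self.min_snps:
            raise ValueError(
                f"only {len(common)} SNPs shared across {k} GWAS "
                f"(inputs had {[len(t) for t in tables]}); need >= {self.min_snps}"
            )
        tables = [t.set_index("SNP").loc[common].reset_index() for t in tables]
        order = tables[0]["IDX"].argsort().to_numpy()
        tables = [t.iloc[order].reset_index(drop=True) for t in tables]
        M = self.M or ld_scores.m
        m = len(order)
        blocks = _block_slices(m, self.n_blocks)
        ell = tables[0]["L2"].to_numpy()
        zs = [t["Z"].to_numpy() for t in tables]
        ns = [t["N"].to_numpy(dtype=float) for t in tables]

        # univariate pass first: h2 estimates feed the bivariate weights
        uni: dict[int, tuple] = {}
        for i in range(k):
            y, x = zs[i] ** 2, ns[i] * ell / M
            h2_0 = M * (y.mean() - 1.0) / (ns[i] * ell).mean()
            est, _, _ = _wls_jackknife(x, y, _uni_weights(ell, ns[i], h2_0, M), blocks)
            w = _uni_weights(ell, ns[i], est[0], M)
            uni[i] = _wls_jackknife(x, y, w, blocks)

        pairs = vech_indices(k)
        S = np.zeros((k, k))
        intercepts = np.zeros((k, k))
        delete = np.zeros((self.n_blocks, len(pairs)))
        ests = np.zeros(len(pairs))
        for e, (i, j) in enumerate(pairs):
            if i == j:
                est, dele, _ = uni[i]
            else:
                y = zs[i] * zs[j]
                x = np.sqrt(ns[i] * ns[j]) * ell / M
                rho_0 = M * y.mean() / (np.sqrt(ns[i] * ns[j]) * ell).mean()
                w = _biv_weights(ell, ns[i], ns[j], uni[i][0][0], uni[j][0][0], rho_0, 0.0, M)
                est, _, _ = _wls_jackknife(x, y, w, blocks)
                w = _biv_weights(ell, ns[i], ns[j], uni[i][0][0], uni[j][0][0], est[0], est[1], M)
                est, dele, _ = _wls_jackknife(x, y, w, blocks)
            S[i, j] = S[j, i] = est[0]
            intercepts[i, j] = intercepts[j, i] = est[1]
            ests[e] = est[0]
            delete[:, e] = dele[:, 0]

        nb = self.n_blocks
        pseudo = nb * ests[None, :] - (nb - 1) * delete
        V = np.atleast_2d(np.cov(pseudo, rowvar=False)) / nb

        labels = [getattr(ss, "trait", "") or f"gwas{i}" for i, ss in enumerate(sumstats_list)]
        self.stack_ = CovarianceStack(
            S=S, V=V, intercepts=intercepts, labels=labels, M=M, n_blocks=nb,
            N=np.array([float(np.median(n)) for n in ns]), pseudovalues=pseudo,
            meta={"n_snps": m},
        )
        self.S_, self.V_, self.intercepts_ = S, V, intercepts
        return self


# ---------------------------------------------------------------------------
# functional wrappers (the operation surface)


def univariate_ldsc(ss, ld: LDScores, n_blocks: int = 200, M: int | None = None) -> LdscFit:
    """SNP heritability by univariate LD score regression."""
    return LDScoreRegression(n_blocks=n_blocks, M=M).fit(ss, ld).fit_


def bivariate_ldsc(ss1, ss2, ld: LDScores, n_blocks: int = 200,
                   M: int | None = None) -> LdscFit:
    """Genetic covariance between two GWAS by bivariate LD score regression."""
    return CrossTraitLDScoreRegression(n_blocks=n_blocks, M=M).fit(ss1, ss2, ld).fit_


def build_S_V(sumstats_list, ld: LDScores, n_blocks: int = 200,
              M: int | None = None) -> CovarianceStack:
    """Joint genetic covariance matrix S and sampling covariance V."""
    return JointLDScoreRegression(n_blocks=n_blocks, M=M).fit(sumstats_list, ld).stack_


def floor_psd(V: np.ndarray, floor: float = 0.0) -> tuple[np.ndarray, float]:
    """Eigenvalue-floor a symmetric matrix; returns (matrix, min eigenvalue)."""
    w, u = np.linalg.eigh((V + V.T) / 2)
    lam_min = float(w.min())
    if lam_min < floor:
        warnings.warn(
            f"sampling covariance not PSD (min eigenvalue {lam_min:.3g}); flooring",
            stacklevel=2,
        )
        scale = abs(w).max()
        V = u @ np.diag(np.maximum(w, 1e-12 * max(scale, 1e-30))) @ u.T
    return (V + V.T) / 2, lam_min


def write_stack(stack: CovarianceStack, out_dir) -> None:
    """Serialize a CovarianceStack as a directory of tab-delimited files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(stack.S, index=stack.labels, columns=stack.labels).to_csv(
        out / "S.tsv", sep="\t")
    names = [f"{stack.labels[i]}:{stack.labels[j]}" for i, j in vech_indices(stack.k)]
    pd.DataFrame(stack.V, index=names, columns=names).to_csv(out / "V.tsv", sep="\t")
    pd.DataFrame(stack.intercepts, index=stack.labels, columns=stack.labels).to_csv(
        out / "intercepts.tsv", sep="\t")
    meta = pd.Series(
        {"M": stack.M, "n_blocks": stack.n_blocks,
         "N": ",".join(str(x) for x in stack.N),
         "labels": ",".join(stack.labels),
         "vech_order": "row-wise upper triangle (0,0),(0,1),...,(k-1,k-1)"}
    )
    meta.to_csv(out / "meta.tsv", sep="\t", header=False)


def read_stack(in_dir) -> CovarianceStack:
    p = Path(in_dir)
    S = pd.read_csv(p / "S.tsv", sep="\t", index_col=0)
    V = pd.read_csv(p / "V.tsv", sep="\t", index_col=0).to_numpy()
    icpt = pd.read_csv(p / "intercepts.tsv", sep="\t", index_col=0).to_numpy()
    meta = pd.read_csv(p / "meta.tsv", sep="\t", header=None, index_col=0)[1]
    return CovarianceStack(
        S=S.to_numpy(), V=V, intercepts=icpt, labels=list(S.columns),
        M=int(meta["M"]), n_blocks=int(meta["n_blocks"]),
        N=np.array([float(x) for x in str(meta["N"]).split(",")]),
    )
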