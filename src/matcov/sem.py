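"""Stage 2: the four-variable maternal/fetal structural equation model.

The four GWAS — own birthweight (BW), offspring birthweight reported via
the mother (BW_M), own later-life trait (T) and offspring trait via the
mother (T_M) — are modelled as linear functions of four latent genetic
variables: the fetal and maternal genomes acting on birthweight (F_BW,
M_BW) and on the trait (F_T, M_T). The loadings are fixed by biometric
principles (a genome loads 1 on its own-genotype GWAS and 1/2 on the
relative's, because mother and offspring genotypes correlate 0.5):

    Lambda = [[1, 1/2, 0,   0  ],      observed order (BW, BW_M, T, T_M)
              [1/2, 1, 0,   0  ],      latent order (F_BW, M_BW, F_T, M_T)
              [0,   0, 1,   1/2],
              [0,   0, 1/2, 1  ]]

The free parameters are the 10 unique elements of the latent covariance
Psi: four heritabilities and six genetic covariances, among them the
maternal-pleiotropy term cov(M_BW, M_T) (a Barker-type signal) and the
fetal-pleiotropy term cov(F_BW, F_T) (a fetal-insulin-type signal). With 10
observed moments the model is just-identified: Psi = Lambda^-1 S Lambda^-T
in closed form, and the weighted-least-squares fit must agree with it. The
fixed 1/2 loadings implicitly correct the proxy-design power attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from ._utils import unvech, vech, vech_indices
from .ldsc import CovarianceStack, floor_psd

OBSERVED_NAMES = ("BW", "BW_M", "T", "T_M")
LATENT_NAMES = ("F_BW", "M_BW", "F_T", "M_T")

_half = 0.5
LAMBDA = np.array(
    [
        [1.0, _half, 0.0, 0.0],
        [_half, 1.0, 0.0, 0.0],
        [0.0, 0.0, 1.0, _half],
        [0.0, 0.0, _half, 1.0],
    ]
)
# inverse of the 2x2 biometric block [[1, .5], [.5, 1]] (determinant 3/4)
LAMBDA_INV = np.array(
    [
        [4 / 3, -2 / 3, 0.0, 0.0],
        [-2 / 3, 4 / 3, 0.0, 0.0],
        [0.0, 0.0, 4 / 3, -2 / 3],
        [0.0, 0.0, -2 / 3, 4 / 3],
    ]
)

PAIRS = vech_indices(4)
#: names of the 10 free parameters in vech order
PARAM_NAMES = [
    f"h2_{LATENT_NAMES[i]}" if i == j else f"cov_{LATENT_NAMES[i]},{LATENT_NAMES[j]}"
    for i, j in PAIRS
]
#: the six latent covariance pairs, in vech order
COV_PAIRS = [(i, j) for i, j in PAIRS if i != j]


def model_implied_cov(psi: np.ndarray) -> np.ndarray:
    """Sigma(theta) = Lambda Psi Lambda^T."""
    psi = np.asarray(psi, dtype=float)
    if not np.allclose(psi, psi.T, atol=1e-8):
        raise ValueError("psi must be symmetric")
    sigma = LAMBDA @ psi @ LAMBDA.T
    return (sigma + sigma.T) / 2


def closed_form_solve(S: np.ndarray) -> np.ndarray:
    """Exact Psi = Lambda^-1 S Lambda^-T (just-identified model)."""
    S = np.asarray(S, dtype=float)
    psi = LAMBDA_INV @ S @ LAMBDA_INV.T
    return (psi + psi.T) / 2


def _design_matrix() -> np.ndarray:
    """K with vech(Lambda Psi Lambda^T) = K vech(Psi) (the model is linear)."""
    K = np.zeros((10, 10))
    for col, (i, j) in enumerate(PAIRS):
        basis = np.zeros((4, 4))
        basis[i, j] = basis[j, i] = 1.0
        K[:, col] = vech(LAMBDA @ basis @ LAMBDA.T)
    return K


K_DESIGN = _design_matrix()


@dataclass
class FitResult:
    """Estimated latent covariance with uncertainty.

    ``theta`` holds the 10 free parameters (vech of Psi, row-wise upper
    triangle, order F_BW, M_BW, F_T, M_T); ``vcov_theta`` their sandwich
    sampling covariance; ``residual`` is S - Sigma(theta_hat), which must
    vanish at convergence for this just-identified (df = 0) model.
    """

    theta: np.ndarray
    se: np.ndarray
    vcov_theta: np.ndarray
    psi: np.ndarray
    residual: np.ndarray
    fit_value: float
    df: int
    converged: bool
    method: str
    n_iter: int = 0

    @property
    def named(self) -> pd.Series:
        return pd.Series(self.theta, index=PARAM_NAMES)

    def summary(self) -> pd.DataFrame:
        z = self.theta / self.se
        return pd.DataFrame(
            {
                "parameter": PARAM_NAMES,
                "estimate": self.theta,
                "se": self.se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
                "ci_lower": self.theta - 1.96 * self.se,
                "ci_upper": self.theta + 1.96 * self.se,
            }
        )


class NonConvergenceError(RuntimeError):
    def __init__(self, message, last_theta=None, grad_norm=None):
        super().__init__(message)
        self.last_theta = last_theta
        self.grad_norm = grad_norm


class MaternalFetalSEM(BaseEstimator):
    """Fit the maternal/fetal latent covariance model to (S, V).

    Parameters
    ----------
    method : "dwls" (default; weight matrix diag(V)), "wls" (full V), or
        "ml" (normal-theory discrepancy). For this just-identified model all
        three reach the same point estimate; they differ only in the path
        taken there. Standard errors are sandwich estimates propagating the
        jackknife V.
    grad_tol : convergence requirement on the gradient infinity norm.

    Attributes after ``fit``: ``theta_``, ``psi_``, ``se_``,
    ``vcov_theta_``, ``residual_``, ``fit_value_``, ``result_``.
    """

    def __init__(self, method: str = "dwls", grad_tol: float = 1e-8,
                 max_iter: int = 500):
        self.method = method
        self.grad_tol = grad_tol
        self.max_iter = max_iter

    def fit(self, stack: CovarianceStack | np.ndarray, V: np.ndarray | None = None,
            theta_init: np.ndarray | None = None):
        if isinstance(stack, CovarianceStack):
            S, V = stack.S, stack.V
        else:
            S = np.asarray(stack, dtype=float)
            if V is None:
                raise ValueError("V is required when S is passed as an array")
        if S.shape != (4, 4):
            raise ValueError("the model is defined for exactly 4 GWAS (BW, BW_M, T, T_M)")
        if self.method not in ("dwls", "wls", "ml"):
            raise ValueError(f"unknown method {self.method!r}")
        V, lam_min = floor_psd(np.asarray(V, dtype=float))
        self.v_min_eigenvalue_ = lam_min

        s = vech(S)
        if self.method == "dwls":
            w_inv = np.diag(1.0 / np.diag(V))
        elif self.method == "wls":
            w_inv = np.linalg.inv(V)
        else:
            w_inv = None

        x0 = vech(closed_form_solve(S)) if theta_init is None else np.asarray(theta_init, float)

        if self.method in ("dwls", "wls"):
            def objective(theta):
                r = s - K_DESIGN @ theta
                return float(r @ w_inv @ r)

            def grad(theta):
                r = s - K_DESIGN @ theta
                return -2.0 * K_DESIGN.T @ (w_inv @ r)
        else:
            def objective(theta):
                sigma = model_implied_cov(unvech(theta))
                sign, logdet = np.linalg.slogdet(sigma)
                if sign <= 0:
                    return 1e10
                _, logdet_s = np.linalg.slogdet(S)
                return float(logdet + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - 4)

            grad = None

        # ML relies on numeric differentiation, whose noise floor sits well
        # above the analytic-gradient tolerance used for (D)WLS
        gtol = self.grad_tol if grad is not None else max(self.grad_tol, 1e-5)
        res = optimize.minimize(
            objective, x0, jac=grad, method="BFGS",
            options={"gtol": gtol / 10, "maxiter": self.max_iter},
        )
        g = res.jac if res.jac is not None else optimize.approx_fprime(res.x, objective)
        gnorm = float(np.abs(g).max())
        if gnorm > gtol and not res.success and res.fun > 1e-10:
            raise NonConvergenceError(
                f"SEM fit did not converge: gradient inf-norm {gnorm:.3g}",
                last_theta=res.x, grad_norm=gnorm,
            )

        theta = res.x
        # sandwich covariance; Delta = dsigma/dtheta = K (linear model)
        if self.method in ("dwls", "wls"):
            bread = np.linalg.inv(K_DESIGN.T @ w_inv @ K_DESIGN) @ K_DESIGN.T @ w_inv
        else:
            bread = np.linalg.inv(K_DESIGN)  # just-identified: theta = K^-1 s
        vcov = bread @ V @ bread.T
        psi = unvech(theta)
        residual = S - model_implied_cov(psi)
        self.result_ = FitResult(
            theta=theta, se=np.sqrt(np.diag(vcov)), vcov_theta=vcov, psi=psi,
            residual=residual, fit_value=float(res.fun), df=0,
            converged=True, method=self.method, n_iter=int(res.nit),
        )
        self.theta_, self.psi_ = theta, psi
        self.se_, self.vcov_theta_ = self.result_.se, vcov
        self.residual_, self.fit_value_ = residual, self.result_.fit_value
        return self

    def genetic_correlations(self, pairs=None) -> pd.DataFrame:
        """Delta-method genetic correlations from the fitted Psi."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "result_")
        return genetic_correlations(self.result_, pairs=pairs)


def fit_sem(stack: CovarianceStack, method: str = "dwls", **kwargs) -> FitResult:
    """Fit the maternal/fetal SEM to a CovarianceStack."""
    return MaternalFetalSEM(method=method, **kwargs).fit(stack).result_


def genetic_correlations(fit: FitResult, pairs=None, ci_level: float = 0.95) -> pd.DataFrame:
    """Genetic correlations r_ij = psi_ij / sqrt(psi_ii psi_jj) with
    delta-method SEs and untruncated confidence intervals.

    An interval endpoint beyond +-1 sets ``out_of_bounds``; a non-positive
    fitted variance makes the correlation undefined for that pair (flagged,
    not dropped).
    """
    if pairs is None:
        pairs = COV_PAIRS
    crit = stats.norm.ppf(0.5 + ci_level / 2)
    idx = {pair: e for e, pair in enumerate(PAIRS)}
    rows = []
    for i, j in pairs:
        pii, pjj, pij = fit.psi[i, i], fit.psi[j, j], fit.psi[i, j]
        name = f"{LATENT_NAMES[i]},{LATENT_NAMES[j]}"
        if pii <= 0 or pjj <= 0:
            rows.append({"pair": name, "r_g": np.nan, "se": np.nan,
                         "ci_lower": np.nan, "ci_upper": np.nan,
                         "out_of_bounds": False, "undefined": True})
            continue
        r = pij / np.sqrt(pii * pjj)
        grad = np.zeros(10)
        grad[idx[(i, j)]] = 1.0 / np.sqrt(pii * pjj)
        grad[idx[(i, i)]] = -r / (2 * pii)
        grad[idx[(j, j)]] = -r / (2 * pjj)
        se = float(np.sqrt(grad @ fit.vcov_theta @ grad))
        lo, hi = r - crit * se, r + crit * se
        rows.append({"pair": name, "r_g": r, "se": se, "ci_lower": lo,
                     "ci_upper": hi, "out_of_bounds": bool(abs(lo) > 1 or abs(hi) > 1),
                     "undefined": False})
    return pd.DataFrame(rows)
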