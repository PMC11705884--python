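"""Ridge-regression BLUP marker effects and the trait-vs-year effect comparison.

The model is y = Xb + Zu + e with u ~ N(0, sigma2_u I) and e ~ N(0, sigma2_e I)
- ridge regression with penalty lambda = sigma2_e / sigma2_u chosen by REML.
The restricted likelihood is profiled on lambda through a single spectral
decomposition of the marker kernel in the space orthogonal to the fixed
effects, then optimised on a log grid refined by bounded minimisation.

Candidate-SNP effects are estimated twice - once with the morphological trait
as response (contemporary samples) and once with collection year (all
samples); a negative rank correlation between the two effect vectors is the
signature of directional selection moving trait-increasing alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import glcore
from ._stats import spearman_test
from .assoc import CONTEMPORARY_YEAR
from .glcore import GLMatrix
from .simulate import trait_column

__all__ = [
    "RidgeFit",
    "EffectComparison",
    "ridge_blup",
    "beta_for_response",
    "compare_effects",
    "cross_sex_effects",
]

LAMBDA_BOUNDS = (1e-6, 1e6)


@dataclass
class RidgeFit:
    beta: np.ndarray  # marker effects, one per column of Z
    fixed: np.ndarray  # fixed-effect estimates
    sigma2_u: float
    sigma2_e: float
    lam: float  # sigma2_e / sigma2_u
    loglik: float  # restricted log-likelihood at the optimum (nan at fixed lam)
    zero_columns: np.ndarray  # indices of all-constant marker columns (beta forced 0)


@dataclass
class EffectComparison:
    rho: float
    p: float
    n: int
    method: str
    beta_a: np.ndarray
    beta_b: np.ndarray


def ridge_blup(
    Z: np.ndarray,
    y: np.ndarray,
    X: np.ndarray | None = None,
    lam: float | None = None,
    bounds: tuple[float, float] = LAMBDA_BOUNDS,
) -> RidgeFit:
    """REML ridge BLUP of marker effects (the mixed.solve model).

    With lam=None the variance ratio is estimated by REML; a supplied lam
    skips REML and returns the closed-form ridge solution
    beta = (Z'Z + lam I)^-1 Z'(y - X b) with b the GLS fixed-effect estimate.
    Dosage columns enter unstandardised.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = Z.shape
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if y.size != n:
        raise ValueError("response length mismatch")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    p = np.linalg.matrix_rank(X)

    zero_cols = np.flatnonzero(Z.std(axis=0) == 0)
    K = Z @ Z.T

    loglik = np.nan
    if lam is None:
        # restricted space: orthonormal basis U2 with U2'X = 0; then
        # U2'y ~ N(0, sigma2_u (Lambda + lam I)) after diagonalising U2'K U2
        Qfull, _ = np.linalg.qr(X, mode="complete")
        U2 = Qfull[:, p:]
        lam_i, V = np.linalg.eigh(U2.T @ K @ U2)
        lam_i = np.maximum(lam_i, 0.0)
        eta = V.T @ (U2.T @ y)
        q = n - p
        if float(eta @ eta) <= 1e-300:
            # degenerate response in the restricted space: no variance to split
            b = np.linalg.lstsq(X, y, rcond=None)[0]
            return RidgeFit(
                beta=np.zeros(m),
                fixed=b,
                sigma2_u=0.0,
                sigma2_e=0.0,
                lam=np.inf,
                loglik=np.nan,
                zero_columns=zero_cols,
            )

        def neg_rll(log_lam: float) -> float:
            h = lam_i + np.exp(log_lam)
            return float(q * np.log(eta @ (eta / h)) + np.log(h).sum())

        lo, hi = np.log(bounds[0]), np.log(bounds[1])
        grid = np.linspace(lo, hi, 121)
        vals = [neg_rll(g) for g in grid]
        k = int(np.argmin(vals))
        a = grid[max(k - 1, 0)]
        b_ = grid[min(k + 1, grid.size - 1)]
        res = minimize_scalar(neg_rll, bounds=(a, b_), method="bounded")
        log_lam = float(res.x) if res.fun <= vals[k] else float(grid[k])
        lam = float(np.exp(log_lam))
        h = lam_i + lam
        sigma2_u = float(eta @ (eta / h)) / q
        sigma2_e = lam * sigma2_u
        loglik = -0.5 * (
            q * np.log(2 * np.pi * sigma2_u) + np.log(h).sum() + q
        )
    else:
        lam = float(lam)
        sigma2_u = np.nan
        sigma2_e = np.nan

    H = K + lam * np.eye(n)
    Hinv_y = np.linalg.solve(H, y)
    Hinv_X = np.linalg.solve(H, X)
    XtHX = X.T @ Hinv_X
    b = np.linalg.solve(XtHX, X.T @ Hinv_y)
    r = y - X @ b
    u = Z.T @ np.linalg.solve(H, r)
    if zero_cols.size:
        u[zero_cols] = 0.0
    return RidgeFit(
        beta=u,
        fixed=b,
        sigma2_u=sigma2_u,
        sigma2_e=sigma2_e,
        lam=lam,
        loglik=loglik,
        zero_columns=zero_cols,
    )


def _candidate_indices(gl: GLMatrix, candidates: pd.DataFrame) -> list[int]:
    pairs = list(zip(candidates["chrom"], candidates["pos"]))
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicated candidate site in list")
    return [gl.site_index(c, p) for c, p in pairs]


def beta_for_response(
    gl: GLMatrix,
    samples: pd.DataFrame,
    candidates: pd.DataFrame,
    response: str,
    sex: str,
    contemporary_only: bool | None = None,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Ridge-BLUP effect sizes at candidate SNPs for one response and sex.

    Morphological responses use contemporary samples only; year uses all
    years.  Z holds expected minor-allele dosages at the candidate sites.
    Fixed effects default to an intercept only.  Returns a table indexed by
    site with a beta_<response> column.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate SNPs supplied")
    samples = samples.reset_index(drop=True)
    if contemporary_only is None:
        contemporary_only = response != "year"
    keep = (samples["sex"] == sex).to_numpy()
    if contemporary_only:
        keep &= (samples["year"] >= CONTEMPORARY_YEAR).to_numpy()
    if response == "year":
        y_all = samples["year"].to_numpy(dtype=float)
    else:
        col = trait_column(response)
        if col not in samples.columns:
            raise KeyError(f"response column {col!r} not in sample table")
        y_all = samples[col].to_numpy(dtype=float)
    keep &= ~np.isnan(y_all)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError(f"no individuals in sex={sex!r} subset for {response!r}")

    site_idx = _candidate_indices(gl, candidates)
    sub = gl.take_individuals(idx).take_sites(site_idx)
    dos = glcore.dosages(sub)
    Z = dos.eg.T  # individuals x SNPs
    X = np.ones((idx.size, 1))
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, dtype=float)])
    fit = ridge_blup(Z, y_all[idx], X=X)
    out = sub.sites.copy()
    out[f"beta_{response}"] = fit.beta
    out["response"] = response
    out["sex"] = sex
    out["n"] = idx.size
    return out


def compare_effects(beta_a, beta_b) -> EffectComparison:
    """Spearman rank correlation between two paired effect-size vectors.

    Average-rank ties; exact permutation p for n <= 9, t approximation above.
    Pairing is positional: callers must supply betas for the same sites in the
    same minor-allele orientation.
    """
    a = np.asarray(beta_a, dtype=float)
    b = np.asarray(beta_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("effect vectors must be 1-D and paired")
    if a.size < 4:
        raise ValueError(f"need at least 4 shared SNPs, got {a.size}")
    rho, p, method = spearman_test(a, b)
    return EffectComparison(rho=rho, p=p, n=a.size, method=method, beta_a=a, beta_b=b)


def cross_sex_effects(
    gl: GLMatrix,
    samples: pd.DataFrame,
    candidates: pd.DataFrame,
    response: str,
    discovery_sex: str,
    evaluate_sex: str,
    contemporary_only: bool | None = None,
) -> pd.DataFrame:
    """Effect sizes in the opposite sex at candidates discovered in one sex."""
    if evaluate_sex == discovery_sex:
        raise ValueError("evaluation sex equals discovery sex")
    return beta_for_response(
        gl,
        samples,
        candidates,
        response=response,
        sex=evaluate_sex,
        contemporary_only=contemporary_only,
    )
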