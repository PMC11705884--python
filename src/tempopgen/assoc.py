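"""Sex-stratified genotype-likelihood GWAS via a latent-genotype score test.

Genotypes are never called: each site enters the test through its posterior
expected dosage E[g] and posterior variance Var(g).  The score test fits the
null regression of the response on the covariates only, then measures how well
the covariate-projected dosage explains the null residuals, inflating the
information by the summed posterior dosage variance so genotype uncertainty
cannot manufacture signal.  With certain genotypes it reduces exactly to the
classical OLS score test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import glcore
from .glcore import GLMatrix, DosageMatrix
from .simulate import trait_column

__all__ = ["AssocConfig", "score_test_site", "run_gwas", "select_candidates"]

CONTEMPORARY_YEAR = 2005  # "contemporary" samples: collected 2005 or later

MORPH_RESPONSES = {"bill", "tarsus", "wing", "relative_bill", "relative_wing"}


@dataclass
class AssocConfig:
    """One GWAS run: response, sex stratum, covariates, screening thresholds."""

    response: str = "bill"
    sex: str = "M"
    n_pcs: int = 10
    use_library_covariate: bool = True
    min_maf: float = 0.1
    candidate_cutoff: float = 1e-5
    contemporary_only: bool | None = None  # default: True for morphology responses
    ld_window_kb: float = 500.0
    ld_r2_max: float = 0.05

    def __post_init__(self):
        if not 0 < self.candidate_cutoff < 1:
            raise ValueError("candidate_cutoff must lie in (0, 1)")
        if self.contemporary_only is None:
            self.contemporary_only = self.response in MORPH_RESPONSES

    @property
    def tarsus_covariate(self) -> bool:
        # tarsus length enters as a body-size covariate for bill and wing only
        return self.response in {"bill", "wing"}


def score_test_site(eg, vg, y, C):
    """Latent-genotype score test of one site against a response.

    Null model: OLS of y on covariates C (which must include an intercept).
    With residuals e and residual variance s2 (denominator n - rank(C)), and
    g* the covariate-projected expected dosage:

        U = g*'e / s2,   I = (g*'g* + sum Var(g)) / s2,   T = U^2 / I

    T is referred to chi-square(1).  Returns (T, p, sign) or
    (nan, nan, reason-string) when the site is untestable.
    """
    eg = np.asarray(eg, dtype=float)
    vg = np.asarray(vg, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(C, dtype=float)
    n = y.size
    if not (eg.size == vg.size == n == C.shape[0]):
        raise ValueError("length mismatch between dosages, response, covariates")
    Q, R = np.linalg.qr(C)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10))
    e = y - Q @ (Q.T @ y)
    dof = n - rank
    if dof <= 0:
        raise ValueError("more covariates than individuals")
    s2 = float(e @ e) / dof
    if s2 <= 0:
        return np.nan, np.nan, "zero residual variance"
    gstar = eg - Q @ (Q.T @ eg)
    gss = float(gstar @ gstar)
    if gss < 1e-10:
        return np.nan, np.nan, "monomorphic"
    U = float(gstar @ e) / s2
    info = (gss + float(vg.sum())) / s2
    T = U * U / info
    p = float(stats.chi2.sf(T, df=1))
    return T, p, float(np.sign(U))


def _response_vector(samples: pd.DataFrame, response: str) -> np.ndarray:
    col = trait_column(response)
    if col not in samples.columns:
        raise KeyError(f"response column {col!r} not in sample table")
    return samples[col].to_numpy(dtype=float)


def run_gwas(
    gl: GLMatrix,
    samples: pd.DataFrame,
    cfg: AssocConfig,
    pcs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run the score test at every site for one sex stratum.

    Subsetting: the stated sex; contemporary years only for morphology
    responses; individuals missing the response are dropped for this run.
    PC covariates, unless supplied, are recomputed on the sex subset from
    LD-thinned sites.  Sites with folded EM frequency below min_maf are
    excluded.  The run is fully deterministic.
    """
    samples = samples.reset_index(drop=True)
    if len(samples) != gl.n_individuals:
        raise ValueError("sample table and GL matrix disagree on individuals")
    keep = (samples["sex"] == cfg.sex).to_numpy()
    if cfg.contemporary_only:
        keep &= (samples["year"] >= CONTEMPORARY_YEAR).to_numpy()
    y_all = _response_vector(samples, cfg.response)
    keep &= ~np.isnan(y_all)
    idx = np.flatnonzero(keep)
    sub = gl.take_individuals(idx)
    y = y_all[idx]
    n = idx.size

    dos = glcore.dosages(sub)
    cols = [np.ones(n)]
    if pcs is None and cfg.n_pcs > 0:
        thin_idx = glcore.ld_thin(sub, cfg.ld_window_kb, cfg.ld_r2_max, dosage=dos)
        thin_dos = DosageMatrix(dos.eg[thin_idx], dos.vg[thin_idx], dos.freq[thin_idx])
        pcs = glcore.pca(thin_dos, n_axes=cfg.n_pcs)
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        if pcs.shape[0] != n:
            raise ValueError("pcs rows must match the sex/year subset")
        cols.append(pcs)
    if cfg.use_library_covariate and samples["library"].iloc[idx].nunique() > 1:
        lib = pd.get_dummies(samples["library"].iloc[idx], drop_first=True)
        cols.append(lib.to_numpy(dtype=float))
    if cfg.tarsus_covariate:
        tarsus = samples[trait_column("tarsus")].iloc[idx].to_numpy(dtype=float)
        cols.append(tarsus[:, None])
    C = np.column_stack(cols)
    if C.shape[1] >= n:
        raise ValueError(f"{C.shape[1]} covariates for {n} individuals")

    with np.errstate(invalid="ignore"):
        maf_ok = glcore.folded_maf(dos.freq) >= cfg.min_maf
    maf_ok &= ~np.isnan(dos.freq)

    # vectorised score test: one null fit, then matrix projections per site
    Q, R = np.linalg.qr(C)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10))
    e = y - Q @ (Q.T @ y)
    dof = n - rank
    s2 = float(e @ e) / dof
    EG = dos.eg  # (S, n)
    Gstar = EG - (EG @ Q) @ Q.T
    gss = np.einsum("ij,ij->i", Gstar, Gstar)
    testable = maf_ok & (gss >= 1e-10) & (s2 > 0)
    U = (Gstar @ e) / s2
    info = (gss + dos.vg.sum(axis=1)) / s2
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(testable, U * U / info, np.nan)
    p = np.where(testable, stats.chi2.sf(T, df=1), np.nan)
    sign = np.where(testable, np.sign(U), np.nan)
    reason = np.where(maf_ok, "", "maf")
    reason = np.where(maf_ok & ~testable, "monomorphic", reason)
    out = sub.sites.copy()
    out["maf"] = glcore.folded_maf(dos.freq)
    out["T"] = T
    out["p"] = p
    out["sign"] = sign
    out["n"] = n
    out["reason"] = reason
    return out.reset_index(drop=True)


def select_candidates(results: pd.DataFrame, cutoff: float = 1e-5) -> pd.DataFrame:
    """Sites with p below the genome-wide cutoff, sorted by chromosome, position."""
    if len(results) == 0:
        raise ValueError("empty association results")
    hit = results[results["p"] < cutoff]
    return hit.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def manhattan(results: pd.DataFrame, ax=None, cutoff: float = 1e-5):
    """Minimal Manhattan plot of -log10 p by position (one axis, no styling)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for i, (chrom, grp) in enumerate(results.groupby("chrom", sort=True)):
        ax.scatter(grp["pos"], -np.log10(grp["p"]), s=4, label=str(chrom))
    ax.axhline(-np.log10(cutoff), color="red", lw=0.8)
    ax.set_xlabel("position")
    ax.set_ylabel("-log10 p")
    return ax
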