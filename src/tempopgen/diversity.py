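"""Genetic diversity from genotype likelihoods: SAF, folded SFS, theta_W, pi.

The sample-allele-frequency (SAF) likelihood at a site is P(data | j) for
j = 0..2n copies of the minor allele among 2n sampled chromosomes.  It is the
coefficient vector of the polynomial product over individuals
prod_i [GL_i(0) + 2 GL_i(1) x + GL_i(2) x^2], with coefficient j divided by
C(2n, j) - a flat (missing) individual contributes the factor (1 + x)^2 and
therefore, after the binomial division, no information.  Site SAFs are pooled
by an EM over the site-frequency-spectrum simplex (the realSFS estimator),
and Watterson's theta / nucleotide diversity follow from the folded SFS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .glcore import GLMatrix, NoDataError, informative_mask

__all__ = [
    "FoldedSFS",
    "site_saf",
    "saf_matrix",
    "fold_saf",
    "estimate_sfs_em",
    "theta_pi_from_sfs",
    "window_diversity",
    "individual_heterozygosity",
]

MIN_SITES_PER_WINDOW = 50  # EM is unstable on tiny windows; such windows get a flag


@dataclass
class FoldedSFS:
    """Expected site counts per folded frequency bin (j = 0..n minor copies)."""

    counts: np.ndarray
    n_chrom: int  # 2n sampled chromosomes
    loglik: float = np.nan

    @property
    def total_sites(self) -> float:
        return float(self.counts.sum())


def _log_binom(n: int) -> np.ndarray:
    j = np.arange(n + 1)
    return gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)


def site_saf(gl_site: np.ndarray) -> np.ndarray:
    """SAF likelihood vector for one site over n individuals (length 2n + 1).

    Computed by iterated polynomial convolution with per-step renormalisation
    (so products over many individuals cannot underflow), then divided by
    C(2n, j) and scaled to a maximum of 1.
    """
    L = np.asarray(gl_site, dtype=float)
    n = L.shape[0]
    if n < 1:
        raise ValueError("need at least one individual")
    L = L / L.max(axis=1, keepdims=True)
    c = np.array([1.0])
    for i in range(n):
        c = np.convolve(c, np.array([L[i, 0], 2.0 * L[i, 1], L[i, 2]]))
        m = c.max()
        if m <= 0:
            raise NoDataError("zero SAF polynomial (all-zero triplet)")
        c = c / m
    c = c * np.exp(-_log_binom(2 * n))
    return c / c.max()


def saf_matrix(gl: GLMatrix | np.ndarray) -> np.ndarray:
    """SAF vectors for every site: (S, 2n + 1)."""
    likes = gl.likes if isinstance(gl, GLMatrix) else np.asarray(gl)
    return np.stack([site_saf(likes[s]) for s in range(likes.shape[0])])


def fold_saf(saf: np.ndarray) -> np.ndarray:
    """Fold SAF (or SFS) bins j and 2n - j; the middle bin is unpaired."""
    arr = np.asarray(saf, dtype=float)
    was_1d = arr.ndim == 1
    saf = np.atleast_2d(arr)
    two_n = saf.shape[1] - 1
    n = two_n // 2
    out = saf[:, : n + 1].copy()
    out[:, :n] += saf[:, :n:-1][:, :n]
    return out[0] if was_1d else out


def estimate_sfs_em(
    saf: np.ndarray,
    folded: bool = True,
    tol: float = 1e-8,
    max_iter: int = 500,
    return_history: bool = False,
):
    """Maximum-likelihood SFS from per-site SAF vectors by EM (realSFS-style).

    Maximises sum_s log sum_j phi_j SAF[s, j] over the probability simplex.
    With folded=True the SAF is folded before the EM runs.  Returns a
    FoldedSFS whose counts are phi_hat times the number of sites; the
    incomplete-data log-likelihood is non-decreasing across iterations.
    """
    saf = np.atleast_2d(np.asarray(saf, dtype=float))
    if saf.shape[0] == 0:
        raise NoDataError("empty site set")
    two_n = saf.shape[1] - 1
    if folded:
        saf = fold_saf(saf)
    S, K = saf.shape
    phi = np.full(K, 1.0 / K)
    history = []
    ll_prev = -np.inf
    for _ in range(max_iter):
        w = saf * phi
        s = w.sum(axis=1)
        ll = float(np.log(s).sum())
        history.append(ll)
        phi_new = (w / s[:, None]).mean(axis=0)
        if ll - ll_prev < tol and np.abs(phi_new - phi).max() < tol:
            phi = phi_new
            break
        phi = phi_new
        ll_prev = ll
    sfs = FoldedSFS(counts=phi * S, n_chrom=two_n, loglik=history[-1])
    if return_history:
        return sfs, history
    return sfs


def theta_pi_from_sfs(sfs: FoldedSFS, total_sites: float | None = None):
    """Per-site Watterson's theta and nucleotide diversity from a folded SFS.

    S = sum of variable bins; theta_W = S / a with a the harmonic number
    H(n_chrom - 1); pi = sum_j j (n_chrom - j) / C(n_chrom, 2) * count_j
    (the pairwise-difference weight, identical for j and n_chrom - j so
    folding is safe).  Both are divided by the total site count.
    """
    if sfs.n_chrom < 2:
        raise ValueError("need at least 2 chromosomes")
    counts = np.asarray(sfs.counts, dtype=float)
    if total_sites is None:
        total_sites = counts.sum()
    if total_sites <= 0:
        raise ValueError("no sites")
    j = np.arange(counts.size)
    seg = counts[1:].sum()
    a = np.sum(1.0 / np.arange(1, sfs.n_chrom))
    theta_w = seg / a / total_sites
    w_pi = j * (sfs.n_chrom - j) / (sfs.n_chrom * (sfs.n_chrom - 1) / 2.0)
    pi = float((w_pi * counts).sum()) / total_sites
    return float(theta_w), pi


def window_diversity(
    gl: GLMatrix,
    samples: pd.DataFrame,
    window: int = 10_000,
    min_per_year: int = 5,
    min_sites: int = MIN_SITES_PER_WINDOW,
) -> pd.DataFrame:
    """Windowed theta_W and pi per year group.

    Years with at least min_per_year sampled individuals are analysed
    separately; for each non-overlapping window ([k*window, (k+1)*window),
    0-based half-open, sites assigned by pos - 1) a folded SFS is fitted to the
    window's SAF vectors over that year's individuals and converted to
    per-site theta_W and pi.  Windows with fewer than min_sites informative
    sites are emitted with low_data=True (trend fits should drop them).
    """
    samples = samples.reset_index(drop=True)
    year_counts = samples["year"].value_counts()
    years = sorted(int(y) for y in year_counts[year_counts >= min_per_year].index)
    rows = []
    if not years:
        import warnings

        warnings.warn("no year has enough samples; empty diversity table")
        return pd.DataFrame(
            columns=["chrom", "start", "end", "year", "n_sites", "thetaW", "pi", "low_data"]
        )
    pos0 = gl.sites["pos"].to_numpy() - 1  # 0-based
    win_id = pos0 // window
    chroms = gl.sites["chrom"].to_numpy()
    for year in years:
        ind = np.flatnonzero((samples["year"] == year).to_numpy())
        sub = gl.take_individuals(ind)
        has_data = informative_mask(sub.likes).any(axis=1)
        for chrom in pd.unique(chroms):
            on_chrom = chroms == chrom
            for w in np.unique(win_id[on_chrom]):
                sel = np.flatnonzero(on_chrom & (win_id == w) & has_data)
                n_sites = sel.size
                rec = {
                    "chrom": chrom,
                    "start": int(w) * window,
                    "end": (int(w) + 1) * window,
                    "year": year,
                    "n_sites": n_sites,
                    "thetaW": np.nan,
                    "pi": np.nan,
                    "low_data": n_sites < min_sites,
                }
                if n_sites > 0:
                    saf = saf_matrix(sub.likes[sel])
                    sfs = estimate_sfs_em(saf, folded=True)
                    tw, pi = theta_pi_from_sfs(sfs, total_sites=n_sites)
                    rec["thetaW"], rec["pi"] = tw, pi
                rows.append(rec)
    return pd.DataFrame(rows)


def individual_heterozygosity(gl_ind: np.ndarray) -> float:
    """Proportion of heterozygous sites for one individual, from its 2-chromosome SFS.

    Fits the single-individual SFS over all informative sites and returns the
    heterozygous mass eta_1 / (eta_0 + eta_1 + eta_2).  The three genotype
    bins are kept unfolded: folding merges the two homozygous states, and at
    low depth that lets heterozygous sites whose few reads all show one allele
    be absorbed as the opposite homozygote, biasing the estimate down; the
    unfolded mixture contains the true genotype proportions and is consistent.
    """
    L = np.asarray(gl_ind, dtype=float)
    if L.ndim != 2 or L.shape[1] != 3:
        raise ValueError("expected (S, 3) likelihoods for one individual")
    info = informative_mask(L)
    if not info.any():
        raise NoDataError("no informative sites for individual")
    L = L[info]
    saf = saf_matrix(L[:, None, :])
    sfs = estimate_sfs_em(saf, folded=False, max_iter=2000)
    eta = sfs.counts
    return float(eta[1] / eta.sum())
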