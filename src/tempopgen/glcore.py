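"""Genotype-likelihood core: data model, BEAGLE I/O, EM estimators, filters, dosages, PCA, LD.

Low-coverage sequencing does not support confident genotype calls, so every
individual carries, at every site, three likelihoods P(reads | g) for
g in {0, 1, 2} copies of the minor allele.  All downstream statistics in this
package are computed from those triplets rather than from called genotypes:
allele frequencies by an EM under Hardy-Weinberg, polymorphism by a likelihood
ratio test, genotype dosages as posterior means, and PCA / LD on the dosages.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SiteInfo",
    "GLMatrix",
    "FilterConfig",
    "DosageMatrix",
    "BeagleParseError",
    "NoDataError",
    "read_beagle",
    "write_beagle",
    "certain_gl",
    "informative_mask",
    "estimate_maf_em",
    "estimate_maf_em_matrix",
    "snp_lrt",
    "het_excess_filter",
    "apply_filters",
    "dosages",
    "pca",
    "ld_r2",
    "ld_thin",
]

ALLELE_CODES = {"0": "A", "1": "C", "2": "G", "3": "T"}
ALLELE_TO_CODE = {v: k for k, v in ALLELE_CODES.items()}

EM_TOL = 1e-6
EM_MAX_ITER = 200


class BeagleParseError(ValueError):
    """Malformed BEAGLE genotype-likelihood file."""


class NoDataError(ValueError):
    """No individual carries information at the site."""


@dataclass(frozen=True)
class SiteInfo:
    chrom: str
    pos: int  # 1-based
    major: str
    minor: str

    def __post_init__(self):
        if self.major == self.minor:
            raise ValueError(f"major == minor ({self.major}) at {self.chrom}:{self.pos}")


@dataclass
class GLMatrix:
    """Genotype likelihoods for S sites x N individuals x 3 genotypes.

    Triplet order is (hom-major, het, hom-minor).  Each triplet is scaled so
    its maximum is 1; a flat triplet (1,1,1) encodes a missing (zero-read)
    observation.
    """

    sites: pd.DataFrame  # columns chrom, pos, major, minor
    likes: np.ndarray  # (S, N, 3)
    ids: list[str]

    def __post_init__(self):
        self.likes = np.asarray(self.likes, dtype=float)
        if self.likes.ndim != 3 or self.likes.shape[2] != 3:
            raise ValueError(f"likelihood array must be (S, N, 3), got {self.likes.shape}")
        if len(self.sites) != self.likes.shape[0]:
            raise ValueError("site table and likelihood array disagree on S")
        if len(self.ids) != self.likes.shape[1]:
            raise ValueError("ids and likelihood array disagree on N")
        if np.any(self.likes < 0):
            raise ValueError("negative genotype likelihoods")
        mx = self.likes.max(axis=2)
        if np.any(mx <= 0):
            raise ValueError("all-zero likelihood triplet")
        self.likes = self.likes / mx[:, :, None]
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return self.likes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.likes.shape[1]

    def take_sites(self, idx) -> "GLMatrix":
        idx = np.asarray(idx)
        return GLMatrix(self.sites.iloc[idx], self.likes[idx], list(self.ids))

    def take_individuals(self, idx) -> "GLMatrix":
        idx = np.asarray(idx)
        return GLMatrix(self.sites, self.likes[:, idx], [self.ids[i] for i in idx])

    def site_index(self, chrom: str, pos: int) -> int:
        hit = np.flatnonzero((self.sites["chrom"] == chrom) & (self.sites["pos"] == pos))
        if hit.size == 0:
            raise KeyError(f"site {chrom}:{pos} not in GL matrix")
        return int(hit[0])


@dataclass(frozen=True)
class FilterConfig:
    """Site filters mirrored from ANGSD-style variant screening."""

    min_maf: float = 0.02
    min_individuals: int = 1
    snp_pval: float = 2e-6
    max_het_freq: float = 0.5
    exclude_chroms: tuple[str, ...] = ()

    def __post_init__(self):
        if not 0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must lie in [0, 0.5)")
        if not 0 < self.snp_pval <= 1:
            raise ValueError("snp_pval must lie in (0, 1]")


@dataclass
class DosageMatrix:
    """Posterior expected minor-allele dosage and its variance, per site x individual."""

    eg: np.ndarray  # (S, N) in [0, 2]
    vg: np.ndarray  # (S, N) >= 0
    freq: np.ndarray  # (S,) EM allele-frequency estimate


# ---------------------------------------------------------------------------
# BEAGLE I/O


def _decode_allele(tok: str, lineno: int) -> str:
    tok = str(tok).strip()
    if tok in ALLELE_CODES:
        return ALLELE_CODES[tok]
    if tok.upper() in ALLELE_TO_CODE:
        return tok.upper()
    raise BeagleParseError(f"line {lineno}: unrecognised allele code {tok!r}")


def read_beagle(path) -> GLMatrix:
    """Read a (optionally gzipped) BEAGLE genotype-likelihood file.

    Layout: header row, then one row per site with columns
    ``marker allele1 allele2`` followed by three likelihood columns per
    individual.  Markers are ``chrom_position``.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline().split()
        if len(header) < 6 or (len(header) - 3) % 3 != 0:
            raise BeagleParseError(
                f"line 1: header has {len(header)} columns; expected 3 + 3*individuals"
            )
        n_ind = (len(header) - 3) // 3
        ids = [header[3 + 3 * i] for i in range(n_ind)]
        chroms, poss, majors, minors, rows = [], [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != 3 + 3 * n_ind:
                raise BeagleParseError(
                    f"line {lineno}: {len(toks)} columns, expected {3 + 3 * n_ind}"
                )
            marker = toks[0]
            if "_" not in marker:
                raise BeagleParseError(f"line {lineno}: marker {marker!r} not 'chrom_pos'")
            chrom, pos_s = marker.rsplit("_", 1)
            try:
                pos = int(pos_s)
            except ValueError:
                raise BeagleParseError(
                    f"line {lineno}: marker {marker!r} has non-integer position"
                ) from None
            try:
                vals = np.array(toks[3:], dtype=float)
            except ValueError:
                raise BeagleParseError(f"line {lineno}: non-numeric likelihood") from None
            if np.any(vals < 0):
                raise BeagleParseError(f"line {lineno}: negative likelihood")
            chroms.append(chrom)
            poss.append(pos)
            majors.append(_decode_allele(toks[1], lineno))
            minors.append(_decode_allele(toks[2], lineno))
            rows.append(vals.reshape(n_ind, 3))
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "major": majors, "minor": minors})
    likes = np.array(rows) if rows else np.empty((0, n_ind, 3))
    return GLMatrix(sites, likes, ids)


def write_beagle(gl: GLMatrix, path) -> None:
    """Write a GLMatrix in BEAGLE layout (gzip if the path ends in .gz).

    Gzip output is written with a zeroed timestamp so identical matrices
    produce byte-identical files.
    """
    import io

    if str(path).endswith(".gz"):
        def opener(p, mode):
            return io.TextIOWrapper(
                gzip.GzipFile(filename="", mode="wb", fileobj=open(p, "wb"), mtime=0)
            )
    else:
        opener = open
    with opener(path, "wt") as fh:
        cols = ["marker", "allele1", "allele2"]
        for iid in gl.ids:
            cols += [iid] * 3
        fh.write("\t".join(cols) + "\n")
        for s in range(gl.n_sites):
            row = gl.sites.iloc[s]
            out = [
                f"{row.chrom}_{row.pos}",
                ALLELE_TO_CODE.get(row.major, row.major),
                ALLELE_TO_CODE.get(row.minor, row.minor),
            ]
            out += [f"{v:.6f}" for v in gl.likes[s].ravel()]
            fh.write("\t".join(out) + "\n")


def certain_gl(genotypes: np.ndarray) -> np.ndarray:
    """One-hot GL triplets for known genotypes (-1 marks missing -> flat)."""
    g = np.asarray(genotypes)
    likes = np.zeros(g.shape + (3,))
    for k in (0, 1, 2):
        likes[..., k] = (g == k) | (g == -1)
    return likes.astype(float)


# ---------------------------------------------------------------------------
# EM allele frequency and site tests


def informative_mask(likes: np.ndarray) -> np.ndarray:
    """True where a triplet carries information (not all three equal)."""
    return ~(
        np.isclose(likes[..., 0], likes[..., 1]) & np.isclose(likes[..., 1], likes[..., 2])
    )


def _hwe(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)


def estimate_maf_em(
    gl_site: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    return_loglik: bool = False,
):
    """EM estimate of the minor-allele frequency at one site under HWE.

    Iterates f <- mean over informative individuals of E[g | GL, f] / 2 with a
    Hardy-Weinberg prior ((1-f)^2, 2f(1-f), f^2).  The incomplete-data
    log-likelihood is non-decreasing across iterations.  The site likelihood
    can be multimodal for adversarial triplets, so the EM is restarted from a
    few spread-out frequencies and the best-likelihood fit is returned.
    """
    L = np.asarray(gl_site, dtype=float)
    info = informative_mask(L)
    if not info.any():
        raise NoDataError("all GL triplets flat at site")
    L = L[info]
    L = L / L.max(axis=1, keepdims=True)

    def run(f0):
        f = f0
        hist = []
        for _ in range(max_iter):
            w = L * _hwe(f)
            s = w.sum(axis=1)
            hist.append(np.log(s).sum())
            post = w / s[:, None]
            f_new = float(np.mean(post[:, 1] * 0.5 + post[:, 2]))
            if abs(f_new - f) < tol:
                f = f_new
                break
            f = f_new
        f = float(np.clip(f, 0.0, 1.0))
        hist.append(np.log((L * _hwe(f)).sum(axis=1)).sum())
        return f, hist

    fits = [run(f0) for f0 in (0.1, 0.5, 0.9)]
    # EM converges sublinearly towards a boundary maximum; offer f = 0, 1
    # directly and keep whichever candidate maximises the likelihood
    for fb in (0.0, 1.0):
        with np.errstate(divide="ignore"):
            ll_b = float(np.log((L * _hwe(fb)).sum(axis=1)).sum())
        fits.append((fb, [ll_b]))
    f, ll_hist = max(fits, key=lambda fh: fh[1][-1])
    if return_loglik:
        return f, ll_hist
    return f


def estimate_maf_em_matrix(
    likes: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER
) -> np.ndarray:
    """Vectorised per-site EM allele frequencies for an (S, N, 3) array.

    Sites with no informative individual get NaN.
    """
    L = np.asarray(likes, dtype=float)
    info = informative_mask(L)  # (S, N)
    n_inf = info.sum(axis=1)
    f = np.full(L.shape[0], 0.25)
    ok = n_inf > 0
    for _ in range(max_iter):
        prior = _hwe(f)  # (S, 3)
        w = L * prior[:, None, :]
        s = w.sum(axis=2)
        s = np.where(s > 0, s, 1.0)
        eg = (w[..., 1] * 0.5 + w[..., 2]) / s  # E[g]/2 per individual
        with np.errstate(invalid="ignore"):
            f_new = np.where(ok, (eg * info).sum(axis=1) / np.maximum(n_inf, 1), f)
        if np.nanmax(np.abs(f_new - f), initial=0.0) < tol:
            f = f_new
            break
        f = f_new
    f = np.clip(f, 0.0, 1.0)
    f[~ok] = np.nan
    return f


def _site_loglik(L: np.ndarray, f: float) -> float:
    """Incomplete-data log-likelihood at frequency f over informative rows of L."""
    w = (L * _hwe(f)).sum(axis=1)
    if np.any(w <= 0):
        return -np.inf
    return float(np.log(w).sum())


def snp_lrt(gl_site: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER):
    """Likelihood-ratio test that a site is polymorphic.

    Compares the EM-fitted frequency against the better of the two fixed
    frequencies (0 and 1); the statistic is referred to a chi-square with one
    degree of freedom, as in ANGSD's -SNP_pval screen.

    Returns (LRT, p).
    """
    L = np.asarray(gl_site, dtype=float)
    info = informative_mask(L)
    if not info.any():
        raise NoDataError("all GL triplets flat at site")
    L = L[info]
    L = L / L.max(axis=1, keepdims=True)
    f_hat = estimate_maf_em(L, tol=tol, max_iter=max_iter)
    ll_hat = _site_loglik(L, f_hat)
    ll_0 = max(_site_loglik(L, 0.0), _site_loglik(L, 1.0))
    lrt = max(0.0, 2.0 * (ll_hat - ll_0))
    p = float(stats.chi2.sf(lrt, df=1))
    return lrt, p


def het_excess_filter(
    gl_site: np.ndarray,
    max_het_freq: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = EM_MAX_ITER,
):
    """Paralog screen: drop sites whose fitted heterozygote fraction is too high.

    Genotype frequencies (pi0, pi1, pi2) are fitted by EM as an unconstrained
    three-category mixture (no Hardy-Weinberg restriction); collapsed repeats
    map reads from two loci onto one site and show up as excess heterozygotes.

    Returns (keep, pi1_hat).
    """
    L = np.asarray(gl_site, dtype=float)
    info = informative_mask(L)
    if not info.any():
        raise NoDataError("all GL triplets flat at site")
    L = L[info]
    L = L / L.max(axis=1, keepdims=True)
    pi = np.full(3, 1.0 / 3.0)
    for _ in range(max_iter):
        w = L * pi
        post = w / w.sum(axis=1, keepdims=True)
        pi_new = post.mean(axis=0)
        if np.abs(pi_new - pi).max() < tol:
            pi = pi_new
            break
        pi = pi_new
    pi1 = float(pi[1])
    return pi1 <= max_het_freq, pi1


def folded_maf(f: np.ndarray) -> np.ndarray:
    """Fold an allele frequency onto the minor allele: min(f, 1-f)."""
    f = np.asarray(f, dtype=float)
    return np.minimum(f, 1.0 - f)


def apply_filters(gl: GLMatrix, cfg: FilterConfig):
    """Apply the site filters in a fixed order and report per-filter drop counts.

    Order: chromosome exclusion -> min informative individuals -> folded MAF ->
    polymorphism LRT -> heterozygote-excess.  Each count is the number of sites
    dropped at that stage among survivors of the previous stages.

    Returns (filtered GLMatrix, dict of drop counts).
    """
    counts = {
        "exclude_chroms": 0,
        "min_individuals": 0,
        "min_maf": 0,
        "snp_lrt": 0,
        "max_het_freq": 0,
    }
    alive = np.ones(gl.n_sites, dtype=bool)

    if cfg.exclude_chroms:
        bad = gl.sites["chrom"].isin(cfg.exclude_chroms).to_numpy()
        counts["exclude_chroms"] = int(bad.sum())
        alive &= ~bad

    info_counts = informative_mask(gl.likes).sum(axis=1)
    bad = alive & (info_counts < cfg.min_individuals)
    counts["min_individuals"] = int(bad.sum())
    alive &= ~bad

    if cfg.min_maf > 0:
        freqs = estimate_maf_em_matrix(gl.likes)
        with np.errstate(invalid="ignore"):
            bad = alive & ~(folded_maf(freqs) >= cfg.min_maf)
        counts["min_maf"] = int(bad.sum())
        alive &= ~bad

    if cfg.snp_pval < 1:
        for s in np.flatnonzero(alive):
            if info_counts[s] == 0:
                continue  # nothing to test; minInd governs these
            _, p = snp_lrt(gl.likes[s])
            if not p < cfg.snp_pval:
                counts["snp_lrt"] += 1
                alive[s] = False

    if cfg.max_het_freq < 1:
        for s in np.flatnonzero(alive):
            if info_counts[s] == 0:
                continue
            keep, _ = het_excess_filter(gl.likes[s], cfg.max_het_freq)
            if not keep:
                counts["max_het_freq"] += 1
                alive[s] = False

    return gl.take_sites(np.flatnonzero(alive)), counts


# ---------------------------------------------------------------------------
# Dosages, PCA, LD


def dosages(gl: GLMatrix, freqs: np.ndarray | None = None) -> DosageMatrix:
    """Posterior expected dosages E[g | GL, f] with an HWE prior at the EM frequency.

    A flat triplet yields the prior-only posterior, so E[g] = 2f there.
    """
    if freqs is None:
        freqs = estimate_maf_em_matrix(gl.likes)
    freqs = np.asarray(freqs, dtype=float)
    f = np.where(np.isnan(freqs), 0.0, freqs)
    prior = _hwe(f)  # (S, 3)
    w = gl.likes * prior[:, None, :]
    s = w.sum(axis=2, keepdims=True)
    s = np.where(s > 0, s, 1.0)
    post = w / s
    eg = post[..., 1] + 2.0 * post[..., 2]
    eg2 = post[..., 1] + 4.0 * post[..., 2]
    vg = np.maximum(eg2 - eg**2, 0.0)
    return DosageMatrix(eg=eg, vg=vg, freq=freqs)


def pca(dosage: DosageMatrix, n_axes: int = 10) -> np.ndarray:
    """PC scores per individual from frequency-standardised dosages.

    Per site, E[g] is centred by 2f and scaled by sqrt(2f(1-f)); the top
    eigenvectors of the individual x individual covariance give the scores.
    Sign convention: the first nonzero entry of each score vector is positive.
    """
    eg, f = dosage.eg, np.nan_to_num(dosage.freq, nan=0.0)
    n_ind = eg.shape[1]
    if n_axes >= n_ind:
        raise ValueError(f"n_axes={n_axes} must be < n_individuals={n_ind}")
    denom = np.sqrt(2 * f * (1 - f))
    use = denom > 0
    X = (eg[use] - 2 * f[use, None]) / denom[use, None]
    cov = X.T @ X / max(use.sum(), 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:n_axes]
    scores = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    for k in range(scores.shape[1]):
        nz = np.flatnonzero(np.abs(scores[:, k]) > 1e-12)
        if nz.size and scores[nz[0], k] < 0:
            scores[:, k] *= -1
    return scores


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two expected-dosage vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant dosage vector: correlation undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_thin(
    gl: GLMatrix,
    window_kb: float = 500.0,
    r2_max: float = 0.05,
    dosage: DosageMatrix | None = None,
) -> np.ndarray:
    """Greedy LD thinning: scan sites in position order per chromosome and drop
    any site correlated above r2_max with a previously kept site within the
    window.  Returns indices (into gl) of kept sites.
    """
    if dosage is None:
        dosage = dosages(gl)
    eg = dosage.eg
    # unit-normalised centred dosages so r is a single dot product
    centred = eg - eg.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    constant = norms == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(constant[:, None], 0.0, centred / np.where(norms == 0, 1, norms)[:, None])

    window_bp = window_kb * 1000.0
    kept: list[int] = []
    all_pos = gl.sites["pos"].to_numpy()
    all_chrom = gl.sites["chrom"].to_numpy()
    for chrom in pd.unique(all_chrom):
        idx = np.flatnonzero(all_chrom == chrom)
        idx = idx[np.argsort(all_pos[idx], kind="stable")]
        kept_chrom: list[int] = []
        kept_pos: list[int] = []
        for s in idx:
            pos = all_pos[s]
            drop = False
            if kept_chrom and not constant[s]:
                lo = np.searchsorted(kept_pos, pos - window_bp)
                near = kept_chrom[lo:]
                if near:
                    r = np.asarray(unit[near]) @ unit[s]
                    drop = bool(np.any(r * r > r2_max))
            if not drop:
                kept_chrom.append(s)
                kept_pos.append(pos)
        kept.extend(kept_chrom)
    return np.array(sorted(kept), dtype=int)
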