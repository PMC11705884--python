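"""Forward simulation of temporally sampled cohorts with known polygenic truth.

The generator emulates the downstream products of a museum-cohort resequencing
design: a few hundred low-coverage (~4X) diploid individuals sampled across
~three decades, two sexes, three correlated morphological traits (bill, tarsus
and wing length) with a sparse polygenic basis, and causal allele frequencies
that respond to directional selection on a trait while all sites drift.

Sites are simulated independently (no linkage); individuals are drawn
independently each year from that year's population frequencies.  Every random
draw flows from the single config seed through named substreams, so identical
configs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .glcore import GLMatrix, FilterConfig, certain_gl

__all__ = [
    "SimConfig",
    "Architecture",
    "CohortTruth",
    "draw_architecture",
    "selection_step",
    "simulate_trajectories",
    "simulate_cohort",
    "simulate_gls",
    "simulate_climate_grid",
    "demo_filter_matrix",
    "trait_column",
]

TRAIT_COLUMNS = {"bill": "bill_mm", "tarsus": "tarsus_mm", "wing": "wing_mm"}

# named substreams so each stage draws from an independent, reproducible stream
_STREAMS = {"architecture": 1, "trajectories": 2, "cohort": 3, "gl": 4, "climate": 5}


def trait_column(name: str) -> str:
    """Map a trait name to its sample-table column (bill -> bill_mm)."""
    return TRAIT_COLUMNS.get(name, name)


@dataclass
class SimConfig:
    """Study-design knobs for the cohort generator.

    Defaults emulate the sequenced-cohort design the package targets: 29
    sampling years (1986-2014) at 8 birds per year (232 individuals), ~4X mean
    depth, three traits with heritability near 0.5 from 8 causal alleles each,
    and weak directional selection pushing bill length down.  Trait units:
    selection gradients, allelic effects, sex effects and residuals are all on
    the standardized (phenotypic-SD) scale; measurements are emitted in mm via
    per-trait means and scales.
    """

    n_sites: int = 1000
    n_causal_per_trait: int = 8
    years: tuple[int, int] = (1986, 2014)  # inclusive
    n_per_year: int | Mapping[int, int] = 8
    effective_size: int | None = 5000  # None disables drift
    selection_gradient: Mapping[str, float] = field(
        default_factory=lambda: {"bill": -0.03, "tarsus": 0.0, "wing": 0.0}
    )
    effect_sd: float = 0.4
    effect_dist: str = "normal"  # "normal": N(0, sd); "fixed": +-effect_sd, random sign
    trait_residual_sd: float = 0.7
    residual_corr: float = 0.3
    sex_effect: Mapping[str, float] = field(
        default_factory=lambda: {"bill": -0.15, "tarsus": 0.4, "wing": 0.4}
    )
    trait_means: Mapping[str, float] = field(
        default_factory=lambda: {"bill": 9.3, "tarsus": 30.0, "wing": 89.0}
    )
    trait_scales: Mapping[str, float] = field(
        default_factory=lambda: {"bill": 0.65, "tarsus": 1.2, "wing": 2.5}
    )
    mean_depth: float = 4.0
    error_rate: float = 0.01
    init_freq: float | None = None  # scalar overrides the uniform range
    init_freq_range: tuple[float, float] = (0.05, 0.95)
    chrom: str = "chr1"
    site_spacing_bp: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_sites <= 0 or self.n_causal_per_trait <= 0:
            raise ValueError("counts must be positive")
        if not 0 < self.error_rate < 0.5:
            raise ValueError("error_rate must lie in (0, 0.5)")
        if self.n_causal_per_trait * len(self.traits) > self.n_sites:
            raise ValueError("causal sites exceed n_sites")
        if self.years[1] < self.years[0]:
            raise ValueError("years range reversed")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if isinstance(self.n_per_year, int) and self.n_per_year <= 0:
            raise ValueError("n_per_year must be positive")

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.trait_means.keys())

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def counts_per_year(self) -> dict[int, int]:
        if isinstance(self.n_per_year, Mapping):
            return {y: int(self.n_per_year.get(y, 0)) for y in self.year_list}
        return {y: int(self.n_per_year) for y in self.year_list}

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


@dataclass
class Architecture:
    """Ground-truth genetic architecture: initial frequencies and causal effects."""

    init_freqs: np.ndarray  # (S,)
    causal_idx: dict[str, np.ndarray]  # trait -> site indices
    causal_beta: dict[str, np.ndarray]  # trait -> effects (standardized units)


@dataclass
class CohortTruth:
    """Everything the generator knows that the analysis must recover."""

    genotypes: np.ndarray  # (S, N) in {0, 1, 2}
    trajectories: np.ndarray  # (S, Y)
    architecture: Architecture
    z_genetic: pd.DataFrame  # standardized genetic values per individual per trait
    samples: pd.DataFrame  # id, sex, year, library, <trait>_mm columns
    config: SimConfig

    def realized_heritability(self, trait: str) -> float:
        """Var(genetic) / Var(standardized phenotype) over the simulated cohort."""
        g = self.z_genetic[trait].to_numpy()
        z = (
            self.samples[trait_column(trait)].to_numpy() - self.config.trait_means[trait]
        ) / self.config.trait_scales[trait]
        return float(np.var(g) / np.var(z))


def expected_heritability(config: SimConfig, arch: Architecture, trait: str) -> float:
    """h2 implied by the drawn architecture at the initial frequencies."""
    p = arch.init_freqs[arch.causal_idx[trait]]
    var_g = float(np.sum(2 * p * (1 - p) * arch.causal_beta[trait] ** 2))
    var_sex = 0.25 * config.sex_effect.get(trait, 0.0) ** 2
    return var_g / (var_g + config.trait_residual_sd**2 + var_sex)


def draw_architecture(config: SimConfig) -> Architecture:
    rng = config.rng("architecture")
    if config.init_freq is not None:
        p0 = np.full(config.n_sites, float(config.init_freq))
    else:
        lo, hi = config.init_freq_range
        p0 = rng.uniform(lo, hi, size=config.n_sites)
    # disjoint causal blocks per trait, in random site order
    perm = rng.permutation(config.n_sites)
    causal_idx, causal_beta = {}, {}
    k = config.n_causal_per_trait
    for t, trait in enumerate(config.traits):
        idx = np.sort(perm[t * k : (t + 1) * k])
        causal_idx[trait] = idx
        if config.effect_dist == "fixed":
            causal_beta[trait] = config.effect_sd * rng.choice([-1.0, 1.0], size=k)
        elif config.effect_dist == "graded":
            # evenly spaced magnitudes around effect_sd with random signs: every
            # locus is detectable and the magnitudes carry a true ordering
            mags = config.effect_sd * np.linspace(0.8, 1.6, k)
            causal_beta[trait] = rng.permutation(mags) * rng.choice([-1.0, 1.0], size=k)
        elif config.effect_dist == "normal":
            causal_beta[trait] = rng.normal(0.0, config.effect_sd, size=k)
        else:
            raise ValueError(f"unknown effect_dist {config.effect_dist!r}")
    return Architecture(init_freqs=p0, causal_idx=causal_idx, causal_beta=causal_beta)


def selection_step(p, s: float, beta, sigma_g: float):
    """One deterministic generation of truncation-free directional selection.

    delta p = s * beta * p(1-p) / sigma_g, the single-locus response of an
    allele of effect beta to a gradient s on a trait with genetic SD sigma_g.
    """
    p = np.asarray(p, dtype=float)
    return np.clip(p + s * np.asarray(beta) * p * (1 - p) / sigma_g, 0.0, 1.0)


def simulate_trajectories(config: SimConfig, arch: Architecture | None = None) -> np.ndarray:
    """Per-site allele-frequency trajectories across the sampling years.

    Each year step applies the deterministic selection response at causal
    sites (per trait, scaled by that year's genetic SD), then binomial drift
    over 2 * effective_size gametes at every site.
    """
    if arch is None:
        arch = draw_architecture(config)
    rng = config.rng("trajectories")
    years = config.year_list
    S, Y = config.n_sites, len(years)
    traj = np.empty((S, Y))
    p = arch.init_freqs.copy()
    traj[:, 0] = p
    two_ne = None if config.effective_size is None else 2 * int(config.effective_size)
    for t in range(1, Y):
        for trait in config.traits:
            s_k = config.selection_gradient.get(trait, 0.0)
            if s_k == 0.0:
                continue
            idx = arch.causal_idx[trait]
            beta = arch.causal_beta[trait]
            sigma_g = np.sqrt(np.sum(2 * p[idx] * (1 - p[idx]) * beta**2))
            if sigma_g <= 1e-12:
                continue
            p[idx] = selection_step(p[idx], s_k, beta, sigma_g)
        if two_ne is not None:
            p = rng.binomial(two_ne, np.clip(p, 0.0, 1.0)) / two_ne
        p = np.clip(p, 0.0, 1.0)
        traj[:, t] = p
    return traj


def simulate_cohort(config: SimConfig, trajectories: np.ndarray, arch: Architecture):
    """Sample individuals from the yearly frequencies and assign phenotypes.

    Genotype ~ Binomial(2, p[site, year]); standardized trait
    z = sum_j beta_j g_j + sex_effect * 1[male] + correlated residual; the
    emitted measurement is mean + scale * z.  Library labels split by
    sampling-year halves to mimic batch structure.
    """
    years = config.year_list
    if trajectories.shape != (config.n_sites, len(years)):
        raise ValueError(
            f"trajectories shape {trajectories.shape} != "
            f"({config.n_sites}, {len(years)})"
        )
    rng = config.rng("cohort")
    counts = config.counts_per_year()
    year_of = np.concatenate([[y] * counts[y] for y in years]).astype(int)
    n = year_of.size
    year_idx = np.searchsorted(years, year_of)
    geno = rng.binomial(2, trajectories[:, year_idx])  # (S, N)
    is_male = rng.integers(0, 2, size=n).astype(bool)
    mid_year = (config.years[0] + config.years[1]) // 2
    library = np.where(year_of <= mid_year, "005", "006")

    traits = config.traits
    resid_sd = config.trait_residual_sd
    if resid_sd == 0:
        eps = np.zeros((n, len(traits)))
    else:
        corr = np.full((len(traits), len(traits)), config.residual_corr)
        np.fill_diagonal(corr, 1.0)
        eps = rng.multivariate_normal(
            np.zeros(len(traits)), corr * resid_sd**2, size=n, method="cholesky"
        )

    ids = [f"ind_{i:04d}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "id": ids,
            "sex": np.where(is_male, "M", "F"),
            "year": year_of,
            "library": library,
        }
    )
    z_gen = {}
    for t, trait in enumerate(traits):
        idx = arch.causal_idx[trait]
        g = geno[idx]  # (k, N)
        zg = arch.causal_beta[trait] @ g
        z_gen[trait] = zg
        z = zg + config.sex_effect.get(trait, 0.0) * is_male + eps[:, t]
        samples[trait_column(trait)] = config.trait_means[trait] + config.trait_scales[trait] * z
    truth = CohortTruth(
        genotypes=geno,
        trajectories=trajectories,
        architecture=arch,
        z_genetic=pd.DataFrame(z_gen),
        samples=samples,
        config=config,
    )
    return truth, samples


def gl_from_counts(depth, minor_reads, error_rate: float) -> np.ndarray:
    """GL triplet(s) for observed (depth, minor-read-count) pairs.

    GL(g) = C(d, k) q_g^k (1 - q_g)^(d - k) with q = (eps, 1/2, 1 - eps),
    scaled so each triplet's maximum is 1; zero depth gives a flat triplet.
    """
    d = np.asarray(depth)
    k = np.asarray(minor_reads)
    q = np.array([error_rate, 0.5, 1.0 - error_rate])
    with np.errstate(divide="ignore", invalid="ignore"):
        loggl = k[..., None] * np.log(q) + (d - k)[..., None] * np.log(1 - q)
    loggl = loggl - loggl.max(axis=-1, keepdims=True)
    likes = np.exp(loggl)
    likes[np.broadcast_to(d[..., None] == 0, likes.shape)] = 1.0
    return likes


def simulate_gls(
    genotypes: np.ndarray,
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator | int,
    ids: list[str] | None = None,
    chrom: str = "chr1",
    site_spacing_bp: int = 1000,
) -> GLMatrix:
    """Low-coverage genotype likelihoods from true genotypes.

    Per individual per site: depth d ~ Poisson(mean_depth); minor-allele read
    count k ~ Binomial(d, q_g) with q = (eps, 1/2, 1-eps); GL(g) is the
    binomial likelihood of k, scaled so the triplet maximum is 1.  Zero depth
    yields a flat (missing) triplet.
    """
    g = np.asarray(genotypes)
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotypes must be coded 0/1/2")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    S, N = g.shape
    q = np.array([error_rate, 0.5, 1.0 - error_rate])
    d = rng.poisson(mean_depth, size=(S, N))
    k = rng.binomial(d, q[g])
    likes = gl_from_counts(d, k, error_rate)
    if ids is None:
        ids = [f"ind_{i:04d}" for i in range(N)]
    positions = (np.arange(S) + 1) * site_spacing_bp
    alleles = np.array(["A", "C", "G", "T"])
    maj = alleles[np.arange(S) % 4]
    mno = alleles[(np.arange(S) + 1) % 4]
    sites = pd.DataFrame({"chrom": chrom, "pos": positions, "major": maj, "minor": mno})
    return GLMatrix(sites, likes, list(ids))


def simulate_full(config: SimConfig):
    """Convenience: architecture -> trajectories -> cohort -> GL matrix.

    Returns (truth, samples, gl).
    """
    arch = draw_architecture(config)
    traj = simulate_trajectories(config, arch)
    truth, samples = simulate_cohort(config, traj, arch)
    gl = simulate_gls(
        truth.genotypes,
        config.mean_depth,
        config.error_rate,
        config.rng("gl"),
        ids=list(samples["id"]),
        chrom=config.chrom,
        site_spacing_bp=config.site_spacing_bp,
    )
    return truth, samples, gl


# ---------------------------------------------------------------------------
# Climate grid


def simulate_climate_grid(
    n_points: int,
    years: tuple[int, int],
    trend_mean: float,
    noise_sd: float,
    seed: int,
    trend_sd: float = 0.0,
    frac_positive: float | None = None,
):
    """Daily min/max temperature and precipitation on a synthetic grid.

    Each point gets a linear per-year trend drawn around trend_mean (spread
    trend_sd) applied to all three variables, a shared seasonal temperature
    cycle, and i.i.d. daily noise of SD noise_sd.  If frac_positive is given,
    trend signs are forced so that fraction of points trends upward.  Returns
    (daily DataFrame, point-truth DataFrame with the true trends).
    """
    y0, y1 = years
    if y1 - y0 + 1 < 3:
        raise ValueError("need at least 3 years")
    rng = np.random.default_rng([int(seed), _STREAMS["climate"]])
    lat = rng.uniform(44.0, 60.0, size=n_points).round(3)
    lon = rng.uniform(-100.0, -70.0, size=n_points).round(3)
    trends = rng.normal(trend_mean, trend_sd, size=n_points)
    if frac_positive is not None:
        n_pos = int(round(frac_positive * n_points))
        mag = np.abs(trends)
        mag[mag < 1e-9] = abs(trend_mean) if trend_mean != 0 else 1e-3
        signs = np.full(n_points, -1.0)
        signs[rng.permutation(n_points)[:n_pos]] = 1.0
        trends = mag * signs
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    yr = dates.year.to_numpy()
    season = 12.0 * np.cos(2 * np.pi * (doy - 200) / 365.25)
    frames = []
    for p in range(n_points):
        dy = (yr - y0) * trends[p]
        tmax = 12.0 + season + dy + rng.normal(0, noise_sd, size=dates.size)
        tmin = tmax - 10.0 + rng.normal(0, noise_sd, size=dates.size)
        prcp = np.maximum(
            rng.exponential(2.0, size=dates.size) + dy + rng.normal(0, noise_sd, size=dates.size),
            0.0,
        )
        frames.append(
            pd.DataFrame(
                {
                    "point_id": f"pt_{p:03d}",
                    "lat": lat[p],
                    "lon": lon[p],
                    "date": dates,
                    "tmin": tmin,
                    "tmax": tmax,
                    "prcp": prcp,
                }
            )
        )
    daily = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(
        {"point_id": [f"pt_{p:03d}" for p in range(n_points)], "lat": lat, "lon": lon, "trend": trends}
    )
    return daily, truth


# ---------------------------------------------------------------------------
# Handcrafted filter demonstration fixture


def demo_filter_matrix():
    """A 10-site, 12-individual GL matrix built backwards from the site filters.

    With FilterConfig(min_maf=0.05, min_individuals=6, snp_pval=2e-6,
    max_het_freq=0.5): 2 sites fail the informative-individual minimum, 3 are
    (certainly) monomorphic and fail the MAF floor, 1 carries only a weak
    polymorphism signal and fails the LRT, 1 is all-heterozygous and fails the
    paralog screen, and 3 clean polymorphic sites survive.

    Returns (GLMatrix, FilterConfig, expected drop-count dict).
    """
    n_ind = 12

    def from_counts(n0, n1, n2):
        return certain_gl(np.array([0] * n0 + [1] * n1 + [2] * n2))

    rows = []
    # 3 survivors: clean polymorphic mixtures
    rows.append(from_counts(6, 4, 2))
    rows.append(from_counts(7, 4, 1))
    rows.append(from_counts(5, 5, 2))
    # 2 minInd failures: only 5 informative individuals
    low = certain_gl(np.array([0, 0, 0, 1, 1] + [-1] * 7))
    rows.append(low)
    rows.append(low.copy())
    # 3 MAF failures: certainly monomorphic
    rows.append(from_counts(12, 0, 0))
    rows.append(from_counts(12, 0, 0))
    rows.append(from_counts(0, 0, 12))
    # 1 SNP-LRT failure: weak, nearly flat heterozygote preference
    rows.append(np.tile([0.9, 1.0, 0.9], (n_ind, 1)))
    # 1 paralog (het-excess) failure: all certainly heterozygous
    rows.append(from_counts(0, 12, 0))

    likes = np.array(rows)
    S = likes.shape[0]
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": (np.arange(S) + 1) * 1000,
            "major": "A",
            "minor": "C",
        }
    )
    gl = GLMatrix(sites, likes, [f"ind_{i:02d}" for i in range(n_ind)])
    cfg = FilterConfig(min_maf=0.05, min_individuals=6, snp_pval=2e-6, max_het_freq=0.5)
    expected = {
        "exclude_chroms": 0,
        "min_individuals": 2,
        "min_maf": 3,
        "snp_lrt": 1,
        "max_het_freq": 1,
    }
    return gl, cfg, expected
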