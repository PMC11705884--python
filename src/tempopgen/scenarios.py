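"""Named simulation studies used for end-to-end verification.

Each function simulates data with known truth, runs the relevant slice of the
analysis, and returns the measured quantities together with that truth.  The
study designs are fixed here (sample sizes, effect scales, selection
strength) so tests and reports exercise the same conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assoc, diversity, effects, glcore, simulate

__all__ = [
    "selection_recovery_config",
    "selection_recovery_replicate",
    "score_test_null_calibration",
    "sfs_recovery",
    "neutral_window_diversity",
    "heterozygosity_recovery",
]


def selection_recovery_config(seed: int, selection: bool = True) -> simulate.SimConfig:
    """30-year cohort with graded bill-length alleles under directional selection.

    Design: 8 causal loci with evenly graded effects (all individually
    detectable at the genome-wide cutoff given ~750 contemporary males) and a
    gradient of -0.06 phenotypic SD per year on bill length, strong enough to
    move causal frequencies by ~0.1-0.2 over three decades without fixing
    them.  With selection=False the same architecture evolves by drift only.
    """
    return simulate.SimConfig(
        n_sites=600,
        n_causal_per_trait=8,
        years=(1985, 2014),
        n_per_year=150,
        effect_sd=0.5,
        effect_dist="graded",
        trait_residual_sd=0.35,
        init_freq_range=(0.35, 0.65),
        effective_size=20_000,
        selection_gradient={"bill": -0.06 if selection else 0.0, "tarsus": 0.0, "wing": 0.0},
        seed=seed,
    )


def selection_recovery_replicate(seed: int, selection: bool = True) -> dict:
    """One full pipeline pass: GWAS -> candidates -> ridge betas -> Spearman.

    Returns n_candidates, rho, p (rho/p are NaN when fewer than 4 candidates).
    """
    cfg = selection_recovery_config(seed, selection)
    truth, samples, gl = simulate.simulate_full(cfg)
    res = assoc.run_gwas(gl, samples, assoc.AssocConfig(response="bill", sex="M", n_pcs=10))
    cands = assoc.select_candidates(res, 1e-5)
    out = {"n_candidates": len(cands), "rho": np.nan, "p": np.nan}
    if len(cands) >= 4:
        bm = effects.beta_for_response(gl, samples, cands, "bill", "M")
        by = effects.beta_for_response(gl, samples, cands, "year", "M")
        comp = effects.compare_effects(bm["beta_bill"].to_numpy(), by["beta_year"].to_numpy())
        out.update(rho=comp.rho, p=comp.p)
    return out


def score_test_null_calibration(seed: int, n_sites: int = 10_000, n_ind: int = 200) -> dict:
    """Type-I error of the latent-genotype score test on permuted-null sites.

    Genotypes are drawn at HWE from uniform(0.1, 0.9) frequencies, known with
    certainty (the regime where the statistic must match its chi-square(1)
    reference exactly; posterior dosage variance only makes it conservative),
    and tested against a response independent of every site.  Returns the
    rejection rate at alpha = 0.05 and the Kolmogorov-Smirnov p-value for
    p-value uniformity.
    """
    from scipy import stats

    rng = np.random.default_rng([int(seed), 11])
    freqs = rng.uniform(0.1, 0.9, size=n_sites)
    geno = rng.binomial(2, freqs[:, None], size=(n_sites, n_ind))
    gl = glcore.GLMatrix(
        pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, n_sites + 1),
                "major": "A",
                "minor": "C",
            }
        ),
        glcore.certain_gl(geno),
        [f"i{k}" for k in range(n_ind)],
    )
    y = rng.normal(size=n_ind)
    dos = glcore.dosages(gl)
    # vectorised version of score_test_site with intercept-only covariates
    e = y - y.mean()
    s2 = float(e @ e) / (n_ind - 1)
    G = dos.eg - dos.eg.mean(axis=1, keepdims=True)
    gss = np.einsum("ij,ij->i", G, G)
    U = (G @ e) / s2
    info = (gss + dos.vg.sum(axis=1)) / s2
    ok = gss > 1e-10
    T = np.where(ok, U * U / info, np.nan)
    pvals = stats.chi2.sf(T, df=1)
    pvals = pvals[ok]
    rate = float(np.mean(pvals < 0.05))
    ks_p = float(stats.kstest(pvals, "uniform").pvalue)
    return {"rejection_rate": rate, "ks_uniform_p": ks_p, "n_sites": int(ok.sum())}


def _neutral_allele_counts(rng, n_sites: int, n_chrom: int, theta: float) -> np.ndarray:
    """Minor-allele counts per site under the infinite-sites neutral SFS.

    P(count = j) proportional to theta / j for j = 1..n_chrom-1; the remaining
    mass is monomorphic.  theta is the per-site population mutation rate.
    """
    j = np.arange(1, n_chrom)
    pj = theta / j
    p_mono = 1.0 - pj.sum()
    if p_mono < 0:
        raise ValueError("theta too large for this sample size")
    probs = np.concatenate([[p_mono], pj])
    return rng.choice(np.arange(n_chrom), size=n_sites, p=probs)


def _genotypes_from_counts(rng, counts: np.ndarray, n_ind: int) -> np.ndarray:
    """Random assignment of j allele copies onto 2n chromosomes, paired into diploids."""
    S = counts.size
    geno = np.zeros((S, n_ind), dtype=int)
    two_n = 2 * n_ind
    for s in range(S):
        j = counts[s]
        if j == 0:
            continue
        chroms = rng.choice(two_n, size=j, replace=False)
        np.add.at(geno[s], chroms // 2, 1)
    return geno


def sfs_recovery(
    seed: int,
    n_sites: int = 2000,
    n_ind: int = 10,
    mean_depth: float = 4.0,
    theta: float = 0.05,
) -> dict:
    """Folded SFS estimated from low-coverage GLs vs the true folded spectrum.

    Sites are drawn from a neutral SFS at a polymorphism density an order of
    magnitude above typical vertebrate genomes (so variable bins carry real
    mass), genotyped at the stated depth, and the EM-estimated folded spectrum
    is compared to the true allele-count histogram by total-variation
    distance.
    """
    rng = np.random.default_rng([int(seed), 12])
    counts = _neutral_allele_counts(rng, n_sites, 2 * n_ind, theta)
    geno = _genotypes_from_counts(rng, counts, n_ind)
    gl = simulate.simulate_gls(geno, mean_depth, 0.01, rng)
    saf = diversity.saf_matrix(gl)
    sfs = diversity.estimate_sfs_em(saf, folded=True)
    folded_true = np.minimum(counts, 2 * n_ind - counts)
    true_hist = np.bincount(folded_true, minlength=n_ind + 1).astype(float)
    est = sfs.counts / sfs.counts.sum()
    tru = true_hist / true_hist.sum()
    tv = 0.5 * float(np.abs(est - tru).sum())
    return {"tv_distance": tv, "n_sites": n_sites}


def neutral_window_diversity(
    seed: int,
    theta: float = 0.005,
    n_windows: int = 30,
    sites_per_window: int = 400,
    n_ind: int = 15,
    mean_depth: float = 4.0,
) -> dict:
    """Windowed theta_W and pi on neutral data with known per-site theta.

    All sites (variable or not) enter the GL matrix so per-site estimates are
    on the genomic scale; window means are compared to the simulated theta.
    """
    rng = np.random.default_rng([int(seed), 13])
    S = n_windows * sites_per_window
    counts = _neutral_allele_counts(rng, S, 2 * n_ind, theta)
    geno = _genotypes_from_counts(rng, counts, n_ind)
    # pack sites_per_window sites into each 10-kb window
    spacing = max(10_000 // sites_per_window, 1)
    gl = simulate.simulate_gls(geno, mean_depth, 0.01, rng, site_spacing_bp=spacing)
    samples = pd.DataFrame(
        {
            "id": gl.ids,
            "sex": "F",
            "year": 2000,
            "library": "005",
        }
    )
    wd = diversity.window_diversity(gl, samples, window=10_000, min_per_year=5)
    ok = wd[~wd["low_data"]]
    return {
        "mean_thetaW": float(ok["thetaW"].mean()),
        "mean_pi": float(ok["pi"].mean()),
        "true_theta": theta,
        "n_windows": int(len(ok)),
    }


def heterozygosity_recovery(
    seed: int, n_sites: int = 50_000, het_fraction: float = 0.002, mean_depth: float = 4.0
) -> dict:
    """Single-individual heterozygosity at 4X vs the simulated truth."""
    rng = np.random.default_rng([int(seed), 14])
    geno = (rng.random(n_sites) < het_fraction).astype(int)[:, None]
    gl = simulate.simulate_gls(geno, mean_depth, 0.005, rng)
    est = diversity.individual_heterozygosity(gl.likes[:, 0, :])
    return {"estimate": est, "truth": float(geno.mean())}
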