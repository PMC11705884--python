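"""Genotype-likelihood core: I/O, EM frequency, site tests, dosages, PCA, LD."""

import gzip

import numpy as np
import pandas as pd
import pytest

from tempopgen import glcore, simulate
from tempopgen.glcore import (
    BeagleParseError,
    FilterConfig,
    GLMatrix,
    NoDataError,
    apply_filters,
    certain_gl,
    dosages,
    estimate_maf_em,
    het_excess_filter,
    ld_r2,
    ld_thin,
    pca,
    read_beagle,
    snp_lrt,
    write_beagle,
)

from conftest import gl_matrix_from_genotypes


def grid_search_maf(likes, step=1e-5):
    """Independent 1-D grid-search maximiser of the HWE site likelihood."""
    L = np.asarray(likes, dtype=float)
    L = L[glcore.informative_mask(L)]
    L = L / L.max(axis=1, keepdims=True)
    fs = np.arange(0.0, 1.0 + step, step)
    hwe = np.stack([(1 - fs) ** 2, 2 * fs * (1 - fs), fs**2], axis=1)
    ll = np.log(L @ hwe.T).sum(axis=0)
    return fs[np.argmax(ll)], ll.max()


class TestBeagleIO:
    def test_handcrafted_file(self, tmp_path):
        path = tmp_path / "toy.beagle"
        path.write_text(
            "marker allele1 allele2 ind1 ind1 ind1 ind2 ind2 ind2\n"
            "chr1_100 0 1 1.0 0.5 0.0 0.0 1.0 0.2\n"
            "chr2_1234567 2 3 0.3 1.0 0.3 1.0 1.0 1.0\n"
        )
        gl = read_beagle(path)
        assert gl.likes.shape == (2, 2, 3)
        assert list(gl.sites["chrom"]) == ["chr1", "chr2"]
        assert gl.sites["pos"].iloc[1] == 1234567
        assert gl.sites.loc[0, "major"] == "A" and gl.sites.loc[0, "minor"] == "C"
        assert gl.sites.loc[1, "major"] == "G" and gl.sites.loc[1, "minor"] == "T"

    def test_round_trip(self, tmp_path, small_cohort):
        _, _, _, gl = small_cohort
        path = tmp_path / "rt.beagle.gz"
        write_beagle(gl, path)
        back = read_beagle(path)
        assert np.allclose(gl.likes, back.likes, atol=1e-6)
        assert back.ids == gl.ids
        pd.testing.assert_frame_equal(gl.sites, back.sites)

    def test_gzip_output_is_reproducible(self, tmp_path, small_cohort):
        _, _, _, gl = small_cohort
        write_beagle(gl, tmp_path / "a.beagle.gz")
        write_beagle(gl, tmp_path / "b.beagle.gz")
        assert (tmp_path / "a.beagle.gz").read_bytes() == (tmp_path / "b.beagle.gz").read_bytes()

    @pytest.mark.parametrize(
        "row, match",
        [
            ("chr1_100 0 1 1.0 0.5", "columns"),
            ("badmarker 0 1 1.0 0.5 0.0 0.0 1.0 0.2", "not 'chrom_pos'"),
            ("chr1_100 0 1 1.0 -0.5 0.0 0.0 1.0 0.2", "negative"),
            ("chr1_abc 0 1 1.0 0.5 0.0 0.0 1.0 0.2", "non-integer"),
        ],
    )
    def test_parse_errors_name_line(self, tmp_path, row, match):
        path = tmp_path / "bad.beagle"
        header = "marker allele1 allele2 i1 i1 i1 i2 i2 i2\n"
        path.write_text(header + "chr1_50 0 1 1 1 1 1 1 1\n" + row + "\n")
        with pytest.raises(BeagleParseError, match=match) as err:
            read_beagle(path)
        assert "line 3" in str(err.value)


class TestMafEM:
    def test_certain_homozygous_major(self):
        gl = certain_gl(np.zeros(6, dtype=int))
        assert estimate_maf_em(gl) == pytest.approx(0.0, abs=1e-6)

    def test_certain_heterozygotes(self):
        gl = certain_gl(np.ones(4, dtype=int))
        assert estimate_maf_em(gl) == pytest.approx(0.5, abs=1e-6)

    def test_matches_grid_search_on_mixed_triplets(self, rng):
        for _ in range(5):
            likes = rng.uniform(0.01, 1.0, size=(3, 3))
            f_em = estimate_maf_em(likes, tol=1e-10, max_iter=2000)
            f_grid, _ = grid_search_maf(likes)
            assert f_em == pytest.approx(f_grid, abs=1e-4)

    def test_loglik_nondecreasing(self, rng):
        likes = rng.uniform(0.01, 1.0, size=(12, 3))
        _, hist = estimate_maf_em(likes, return_loglik=True)
        assert np.all(np.diff(hist) >= -1e-9)

    def test_certain_genotypes_give_empirical_frequency(self, rng):
        for _ in range(5):
            g = rng.integers(0, 3, size=20)
            f = estimate_maf_em(certain_gl(g), tol=1e-12, max_iter=2000)
            assert f == pytest.approx(g.sum() / 40.0, abs=1e-6)

    def test_all_flat_raises(self):
        with pytest.raises(NoDataError):
            estimate_maf_em(np.ones((5, 3)))


class TestSnpLrt:
    def test_monomorphic_certain(self):
        lrt, p = snp_lrt(certain_gl(np.zeros(8, dtype=int)))
        assert lrt == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_nonnegative(self, rng):
        for _ in range(10):
            lrt, _ = snp_lrt(rng.uniform(0.01, 1.0, size=(8, 3)))
            assert lrt >= 0

    def test_matches_grid_oracle_for_het_signal(self, rng):
        likes = np.tile([0.05, 1.0, 0.05], (6, 1)) + rng.uniform(0, 0.02, (6, 3))
        lrt, _ = snp_lrt(likes, tol=1e-10, max_iter=5000)
        _, ll_hat = grid_search_maf(likes)
        L = likes / likes.max(axis=1, keepdims=True)
        ll0 = max(np.log(L[:, 0]).sum(), np.log(L[:, 2]).sum())
        assert lrt == pytest.approx(2 * (ll_hat - ll0), abs=1e-3)


class TestHetExcess:
    def test_all_het_dropped(self):
        keep, pi1 = het_excess_filter(certain_gl(np.ones(10, dtype=int)), 0.5)
        assert pi1 == pytest.approx(1.0) and not keep

    def test_all_hom_kept(self):
        keep, pi1 = het_excess_filter(certain_gl(np.zeros(10, dtype=int)), 0.5)
        assert pi1 == pytest.approx(0.0) and keep

    def test_certain_mixture_fixed_point(self):
        g = np.array([1] * 6 + [0] * 4)
        keep, pi1 = het_excess_filter(certain_gl(g), 0.5)
        assert pi1 == pytest.approx(0.6, abs=1e-6) and not keep


class TestApplyFilters:
    def test_constructed_fixture_counts(self):
        gl, cfg, expected = simulate.demo_filter_matrix()
        kept, counts = apply_filters(gl, cfg)
        assert counts == expected
        assert kept.n_sites == 3

    def test_vacuous_filters_keep_everything(self, small_cohort):
        _, _, _, gl = small_cohort
        cfg = FilterConfig(min_maf=0.0, min_individuals=0, snp_pval=1.0, max_het_freq=1.0)
        kept, counts = apply_filters(gl, cfg)
        assert kept.n_sites == gl.n_sites
        assert all(v == 0 for v in counts.values())

    def test_individual_permutation_invariance(self):
        gl, cfg, _ = simulate.demo_filter_matrix()
        perm = np.random.default_rng(5).permutation(gl.n_individuals)
        kept_a, _ = apply_filters(gl, cfg)
        kept_b, _ = apply_filters(gl.take_individuals(perm), cfg)
        assert list(kept_a.sites["pos"]) == list(kept_b.sites["pos"])

    def test_idempotent(self):
        gl, cfg, _ = simulate.demo_filter_matrix()
        once, _ = apply_filters(gl, cfg)
        twice, counts = apply_filters(once, cfg)
        assert twice.n_sites == once.n_sites
        assert all(v == 0 for v in counts.values())

    def test_chromosome_exclusion(self, small_cohort):
        _, _, _, gl = small_cohort
        cfg = FilterConfig(
            min_maf=0.0,
            min_individuals=0,
            snp_pval=1.0,
            max_het_freq=1.0,
            exclude_chroms=("chr1",),
        )
        kept, counts = apply_filters(gl, cfg)
        assert kept.n_sites == 0 and counts["exclude_chroms"] == gl.n_sites


class TestDosages:
    def test_certain_heterozygote(self):
        gl = gl_matrix_from_genotypes(np.array([[1, 1, 1, 1]]))
        dos = dosages(gl)
        assert np.allclose(dos.eg, 1.0) and np.allclose(dos.vg, 0.0, atol=1e-12)

    def test_flat_triplet_prior_moments(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "major": ["A"], "minor": ["C"]})
        gl = GLMatrix(sites, np.ones((1, 1, 3)), ["i0"])
        dos = dosages(gl, freqs=np.array([0.3]))
        assert dos.eg[0, 0] == pytest.approx(0.6)
        assert dos.vg[0, 0] == pytest.approx(0.42)

    def test_hand_posterior(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "major": ["A"], "minor": ["C"]})
        gl = GLMatrix(sites, np.array([[[1.0, 0.5, 0.01]]]), ["i0"])
        f = 0.2
        w = np.array([1.0, 0.5, 0.01]) * np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        post = w / w.sum()
        dos = dosages(gl, freqs=np.array([f]))
        assert dos.eg[0, 0] == pytest.approx(post[1] + 2 * post[2], abs=1e-12)

    def test_posterior_simplex_and_range(self, small_cohort):
        _, _, _, gl = small_cohort
        dos = dosages(gl)
        assert np.all(dos.eg >= 0) and np.all(dos.eg <= 2)
        assert np.all(dos.vg >= -1e-12)
        # E[g^2] consistency: Var + E^2 <= 4
        assert np.all(dos.vg + dos.eg**2 <= 4 + 1e-9)


class TestPca:
    def test_two_groups_separate(self, rng):
        n_a, n_b, S = 15, 15, 120
        fa, fb = rng.uniform(0.1, 0.4, S), rng.uniform(0.6, 0.9, S)
        ga = rng.binomial(2, fa[:, None], (S, n_a))
        gb = rng.binomial(2, fb[:, None], (S, n_b))
        gl = gl_matrix_from_genotypes(np.hstack([ga, gb]))
        scores = pca(dosages(gl), n_axes=2)
        pc1 = scores[:, 0]
        sep = abs(pc1[:n_a].mean() - pc1[n_a:].mean())
        spread = pc1[:n_a].std() + pc1[n_a:].std()
        assert sep > spread  # groups split along PC1

    def test_rank_one_matrix(self):
        g = np.tile(np.array([[0], [1], [2]]), (1, 8))  # identical individuals
        gl = gl_matrix_from_genotypes(g)
        dos = dosages(gl)
        eg = dos.eg + np.random.default_rng(0).normal(0, 1e-9, dos.eg.shape)
        from tempopgen.glcore import DosageMatrix

        scores = pca(DosageMatrix(eg, dos.vg, dos.freq), n_axes=3)
        # all variance on PC1; later axes carry ~nothing
        norms = np.linalg.norm(scores, axis=0)
        assert norms[1] < 1e-6 and norms[2] < 1e-6

    def test_scores_orthogonal(self, small_cohort):
        _, _, _, gl = small_cohort
        scores = pca(dosages(gl), n_axes=3)
        assert abs(scores[:, 0] @ scores[:, 1]) < 1e-8

    def test_too_many_axes(self, small_cohort):
        _, _, _, gl = small_cohort
        with pytest.raises(ValueError):
            pca(dosages(gl), n_axes=gl.n_individuals)


class TestLD:
    def test_perfect_and_flipped(self, rng):
        a = rng.integers(0, 3, 30).astype(float)
        assert ld_r2(a, a) == pytest.approx(1.0)
        assert ld_r2(a, 2 - a) == pytest.approx(1.0)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="constant"):
            ld_r2(np.ones(10), np.arange(10.0))

    def test_three_linked_sites_keep_first(self, rng):
        base = rng.integers(0, 3, 40)
        g = np.vstack([base, base, base])
        gl = gl_matrix_from_genotypes(g, positions=[1000, 2000, 3000])
        kept = ld_thin(gl, window_kb=500, r2_max=0.05)
        assert list(kept) == [0]

    def test_independent_sites_mostly_kept(self, rng):
        S, N = 60, 400  # null |r| ~ 1/sqrt(N) stays clear of the 0.05 r2 cutoff
        g = rng.binomial(2, 0.5, size=(S, N))
        gl = gl_matrix_from_genotypes(g)
        kept = ld_thin(gl, window_kb=500, r2_max=0.05)
        assert len(kept) >= S - 2
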