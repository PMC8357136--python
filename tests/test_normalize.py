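import numpy as np
import pandas as pd
import pytest

from crossclock.datasets import CountDataset
from crossclock.normalize import (
    CountNormalizer,
    NormalizationError,
    log_counts,
    log_cpm,
    normalize_dataset,
    rle_factors,
    rle_size_factors,
    study_effect_score,
    tmm_factors,
)

from _oracles import rle_size_factors_bruteforce, tmm_factors_bruteforce
from conftest import make_dataset


def random_nb_dataset(n_genes, n_samples, seed, depth_spread=1.0):
    rng = np.random.default_rng(seed)
    base = rng.uniform(1, 200, size=(n_genes, 1))
    depth = np.exp(rng.normal(0, depth_spread, size=n_samples))
    counts = rng.negative_binomial(4, 4 / (4 + base * depth[None, :]))
    counts[0, :] += 1  # keep at least one gene positive everywhere (for RLE)
    return make_dataset(counts, ages=np.linspace(20, 80, n_samples))


class TestTMM:
    def test_identical_samples_unit_factors(self):
        col = np.array([5, 50, 500, 17, 3])
        ds = make_dataset(np.tile(col[:, None], 4), ages=[10, 20, 30, 40])
        np.testing.assert_allclose(tmm_factors(ds).factors, 1.0, atol=1e-12)

    def test_pure_scaling_absorbed_by_library_size(self):
        col = np.array([5, 50, 500, 17, 3])
        ds = make_dataset(np.column_stack([col, 3 * col]), ages=[10, 80])
        np.testing.assert_allclose(tmm_factors(ds).factors, 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed,shape", [(0, (20, 3)), (1, (50, 4)), (2, (200, 10))])
    def test_matches_bruteforce_oracle(self, seed, shape):
        ds = random_nb_dataset(*shape, seed=seed)
        f = tmm_factors(ds)
        expected, ref = tmm_factors_bruteforce(ds.counts.to_numpy(), ds.gene_ids)
        np.testing.assert_allclose(f.factors, expected, atol=1e-10, rtol=0)

    def test_invariant_to_global_rescaling(self):
        # scaling every sample by the same constant leaves M, the trims
        # and the relative precision weights unchanged
        ds = random_nb_dataset(80, 5, seed=3)
        f0 = tmm_factors(ds).factors
        ds2 = CountDataset(counts=ds.counts * 7, metadata=ds.metadata.copy())
        np.testing.assert_allclose(tmm_factors(ds2).factors, f0, atol=1e-9)

    def test_near_invariant_to_scaling_one_sample(self):
        # M-values absorb a single sample's depth change exactly, but its
        # precision weights shift with library size, so invariance is
        # approximate rather than exact
        ds = random_nb_dataset(80, 5, seed=3)
        f0 = tmm_factors(ds).factors
        scaled = ds.counts.copy()
        scaled.iloc[:, 2] *= 7
        ds2 = CountDataset(counts=scaled, metadata=ds.metadata.copy())
        np.testing.assert_allclose(tmm_factors(ds2).factors, f0, rtol=0.02)

    def test_geometric_mean_one(self):
        for seed in range(5):
            f = tmm_factors(random_nb_dataset(60, 6, seed=seed)).factors
            assert abs(np.exp(np.mean(np.log(f))) - 1) < 1e-9

    def test_sample_permutation_permutes_factors(self):
        ds = random_nb_dataset(60, 6, seed=9)
        f0 = tmm_factors(ds).factors
        perm = np.array([3, 1, 5, 0, 4, 2])
        ds2 = CountDataset(counts=ds.counts.iloc[:, perm], metadata=ds.metadata.iloc[perm])
        np.testing.assert_allclose(tmm_factors(ds2).factors, f0[perm], atol=1e-12)

    def test_no_shared_positive_genes_is_an_error(self):
        counts = np.array([[10, 0], [0, 10], [5, 0]])
        ds = make_dataset(counts, ages=[10, 80])
        with pytest.raises(NormalizationError, match="s0[12]"):
            tmm_factors(ds)

    def test_agrees_loosely_with_edger(self, tmp_path):
        # conventions differ in trim-boundary handling, so agreement is
        # approximate; this is an independent-software sanity check
        Rscript = pytest.importorskip("shutil").which("Rscript")
        if Rscript is None:
            pytest.skip("Rscript unavailable")
        ds = random_nb_dataset(500, 6, seed=4)
        ds.counts.to_csv(tmp_path / "m.tsv", sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR));'
            'x <- as.matrix(read.delim("%s", row.names=1));'
            'f <- calcNormFactors(x, method="TMM");'
            'cat(sprintf("%%.10f\\n", f))' % (tmp_path / "m.tsv")
        )
        import subprocess

        res = subprocess.run([Rscript, str(script)], capture_output=True, text=True)
        if res.returncode != 0:
            pytest.skip(f"edgeR unavailable: {res.stderr[:200]}")
        theirs = np.array([float(v) for v in res.stdout.split()])
        ours = tmm_factors(ds).factors
        np.testing.assert_allclose(ours, theirs, rtol=0.03)


class TestRLE:
    def test_identical_samples_equal_factors(self):
        col = np.array([5, 50, 500, 17, 3])
        ds = make_dataset(np.tile(col[:, None], 4), ages=[10, 20, 30, 40])
        np.testing.assert_allclose(rle_size_factors(ds), rle_size_factors(ds)[0])

    def test_scaled_sample_scales_raw_size_factor(self):
        base = np.array([5, 50, 500, 17, 3])
        c = 4
        ds = make_dataset(np.column_stack([base, base, c * base]), ages=[10, 40, 80])
        s = rle_size_factors(ds)
        np.testing.assert_allclose(s[2] / s[0], c, rtol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, seed):
        ds = random_nb_dataset(50, 4, seed=seed)
        np.testing.assert_allclose(
            rle_size_factors(ds),
            rle_size_factors_bruteforce(ds.counts.to_numpy()),
            atol=1e-10,
            rtol=0,
        )

    def test_no_common_positive_gene_is_an_error(self):
        counts = np.array([[10, 0], [0, 10]])
        ds = make_dataset(counts, ages=[10, 80])
        with pytest.raises(NormalizationError, match="positive"):
            rle_size_factors(ds)

    def test_convention_matches_tmm_scale(self):
        # reported factors have geometric mean 1, like TMM
        ds = random_nb_dataset(80, 5, seed=7)
        f = rle_factors(ds).factors
        assert abs(np.exp(np.mean(np.log(f))) - 1) < 1e-9


class TestLogCPM:
    def test_zero_count_closed_form(self):
        # one sample with N * f = 1e6 and a zero count -> log2(0.5)
        counts = np.zeros((2, 4), dtype=int)
        counts[1, :] = 1_000_000 // 2
        counts[0, 0] = 0
        counts[1, 0] = 1_000_000
        ds = make_dataset(counts, ages=[10, 20, 30, 40])
        from crossclock.normalize import library_factors

        nm = log_cpm(ds, library_factors(ds))
        assert nm.values.iloc[0, 0] == pytest.approx(np.log2(0.5), abs=1e-12)

    def test_monotone_in_counts(self):
        ds = random_nb_dataset(30, 4, seed=5)
        fac, nm = normalize_dataset(ds, method="tmm")
        doubled = ds.counts.copy()
        doubled.iloc[3, 1] = 2 * doubled.iloc[3, 1] + 1
        ds2 = CountDataset(counts=doubled, metadata=ds.metadata.copy())
        nm2 = log_cpm(ds2, fac)
        assert nm2.values.iloc[3, 1] > nm.values.iloc[3, 1]

    def test_misaligned_factors_rejected(self):
        ds = random_nb_dataset(30, 4, seed=6)
        fac = tmm_factors(ds)
        fac.sample_ids = list(reversed(fac.sample_ids))
        with pytest.raises(NormalizationError, match="aligned"):
            log_cpm(ds, fac)


class TestStudyEffectScore:
    def test_identical_studies_zero(self):
        counts = np.tile(np.array([5, 50, 500])[:, None], 6)
        ds = make_dataset(counts, ages=np.linspace(20, 80, 6), studies=["a"] * 3 + ["b"] * 3)
        assert study_effect_score(log_counts(ds), ds.metadata) == 0.0

    def test_offset_studies_closed_form(self):
        # +1 log2 unit everywhere: means {m, m+1} -> variance 0.25
        base = np.array([[4, 4, 8, 8], [16, 16, 32, 32]])
        ds = make_dataset(base, ages=[10, 20, 30, 40], studies=["a", "a", "b", "b"])
        vals = np.log2(ds.counts.to_numpy())
        nm = log_counts(ds)
        nm.values.iloc[:, :] = vals  # exact powers of two, drop the pseudocount
        assert study_effect_score(nm, ds.metadata) == pytest.approx(0.25, abs=1e-12)

    def test_single_study_is_an_error(self):
        ds = make_dataset(np.ones((3, 4), dtype=int), ages=[10, 20, 30, 40])
        with pytest.raises(NormalizationError, match="2 studies"):
            study_effect_score(log_counts(ds), ds.metadata)


class TestCountNormalizerEstimator:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = CountNormalizer(method="rle", pseudocount=1.0)
        assert clone(est).get_params()["pseudocount"] == 1.0
        ds = random_nb_dataset(40, 5, seed=8)
        X = ds.counts.T  # samples x genes
        out = est.fit_transform(X)
        assert out.shape == X.shape
        assert np.isfinite(out.to_numpy()).all()

    def test_transform_requires_matching_samples(self):
        ds = random_nb_dataset(40, 5, seed=8)
        est = CountNormalizer().fit(ds.counts.T)
        with pytest.raises(NormalizationError, match="samples"):
            est.transform(ds.counts.T.iloc[:3])
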