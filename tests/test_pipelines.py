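"""Secure pipelines against their plaintext twins: QC filters,
association scan, oblivious access, Bloom binning, hinge SGD."""

import numpy as np
import pytest

from mpcbio import Session, PartitionCache
from mpcbio import pipelines as pl
from mpcbio import synthetic as syn
from mpcbio.sharing import reveal, reveal_reals, share_reals, share_secret


@pytest.fixture(scope="module")
def gwas_data():
    return syn.gen_genotypes(n_individuals=60, n_snps=20, miss_rate=0.05,
                             n_causal=3, hwe_violators=2, inbreeding=0.9, seed=42)


class TestQCFilters:
    def test_missing_rate_example(self):
        # genotypes [0, -1, 2, -1]: missing rate 0.5 fails a 10% cutoff
        G = np.array([[0], [-1], [2], [-1]])
        th = pl.QCThresholds.make(miss_max=0.1, maf_min=0.0001, hwe_chi2_max=1000)
        assert not pl.qc_filters_plain(G, th)[0]
        th2 = pl.QCThresholds.make(miss_max=0.5, maf_min=0.0001, hwe_chi2_max=1000)
        assert pl.qc_filters_plain(G, th2)[0]

    def test_maf_example(self):
        # genotypes [0,1,2,2,1]: alt freq 0.6, MAF 0.4
        G = np.array([[0], [1], [2], [2], [1]])
        assert pl.qc_filters_plain(G, pl.QCThresholds.make(1.0, 0.4, 1000))[0]
        assert not pl.qc_filters_plain(G, pl.QCThresholds.make(1.0, 0.45, 1000))[0]

    def test_hwe_chi2_example_counts(self):
        # counts (30, 20, 50) at n=100: chi2 ~ 34.03 > 23.93 -> fail
        chi2 = pl.hwe_chi2_plain(30, 20, 50)
        assert abs(chi2 - 34.03) < 0.1
        G = np.array([[0]] * 30 + [[1]] * 20 + [[2]] * 50)
        th = pl.QCThresholds.make(1.0, 0.01, 23.93)
        assert not pl.qc_filters_plain(G, th)[0]
        th_loose = pl.QCThresholds.make(1.0, 0.01, 35.0)
        assert pl.qc_filters_plain(G, th_loose)[0]

    def test_secure_mask_equals_plain(self, gwas_data):
        s = Session(seed=8)
        cache = PartitionCache()
        th = pl.QCThresholds.make()
        shared = pl.share_genotypes(gwas_data.genotypes, s)
        mask = pl.qc_filters(shared, th, s, cache)
        assert (mask == pl.qc_filters_plain(gwas_data.genotypes, th)).all()

    def test_planted_violators_fail(self, gwas_data):
        th = pl.QCThresholds.make()
        mask = pl.qc_filters_plain(gwas_data.genotypes, th)
        assert not mask[gwas_data.hwe_violators].any()


class TestAssociation:
    def test_perfectly_correlated_snp(self):
        """A genotype column proportional to the phenotype gives r^2 ~ 1."""
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=80)
        y = (g - g.mean()) / g.std()
        s = Session(seed=9)
        cache = PartitionCache()
        gs = share_secret(g.reshape(-1, 1), s)
        ys = share_reals(y, s)
        beta, r2 = pl.association_scan(gs, ys, s, cache)
        assert abs(r2[0] - 1.0) <= 1e-3

    def test_null_snps_mean_r2(self):
        """Independent genotypes: E[r^2] = 1/(n-1); the mean over 100
        null SNPs must fall within 3 standard errors."""
        rng = np.random.default_rng(1)
        n, m = 200, 100
        G = rng.integers(0, 3, size=(n, m))
        y = rng.normal(size=n)
        y = (y - y.mean()) / y.std()
        _, r2 = pl.association_plain(G, y)
        expect = 1 / (n - 1)
        se = expect * np.sqrt(2 / m)   # r2 ~ chi2_1/(n-1) roughly; var ~ 2 expect^2
        assert abs(r2.mean() - expect) <= 3 * se

    def test_secure_matches_plain_within_1e3(self, gwas_data):
        s = Session(seed=10)
        cache = PartitionCache()
        th = pl.QCThresholds.make()
        res = pl.run_gwas(gwas_data.genotypes, gwas_data.phenotype, th, s, cache)
        ys = (gwas_data.phenotype - gwas_data.phenotype.mean()) / gwas_data.phenotype.std()
        beta_p, r2_p = pl.association_plain(gwas_data.genotypes[:, res["kept"]], ys)
        assert np.max(np.abs(res["beta"] - beta_p)) <= 1e-3
        assert np.max(np.abs(res["r2"] - r2_p)) <= 1e-3

    def test_optimized_uses_fewer_rounds(self, gwas_data):
        th = pl.QCThresholds.make()
        rounds = {}
        for optimized in (True, False):
            s = Session(seed=11)
            pl.run_gwas(gwas_data.genotypes, gwas_data.phenotype, th, s,
                        optimized=optimized)
            rounds[optimized] = s.metrics.rounds
        assert rounds[True] < rounds[False]

    def test_zero_variance_snp_statistic_is_zero(self):
        G = np.column_stack([np.ones(30, dtype=int),
                             np.random.default_rng(3).integers(0, 3, 30)])
        y = np.random.default_rng(4).normal(size=30)
        y = (y - y.mean()) / y.std()
        s = Session(seed=12)
        cache = PartitionCache()
        beta, r2 = pl.association_scan(share_secret(G, s), share_reals(y, s),
                                       s, cache)
        assert abs(beta[0]) <= 1e-6 and abs(r2[0]) <= 1e-6

    def test_reveal_log_contains_only_documented_outputs(self, gwas_data):
        s = Session(seed=13)
        th = pl.QCThresholds.make()
        pl.run_gwas(gwas_data.genotypes, gwas_data.phenotype, th, s)
        labels = {e["label"] for e in s.reveal_log}
        assert labels == {"output:qc_mask", "output:assoc_beta", "output:assoc_r2"}


class TestObliviousRead:
    def test_example(self, session, cache):
        arr = share_secret([7, 8, 9], session)
        ind = share_secret([0, 1, 0], session)
        assert int(reveal(pl.oblivious_read(arr, ind, session, cache), session)) == 8

    def test_all_indices_up_to_64(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(0, 1000, size=64)
        s = Session(seed=14)
        c = PartitionCache()
        arr = share_secret(vals, s)
        for i in range(64):
            onehot = np.zeros(64, dtype=int)
            onehot[i] = 1
            got = int(reveal(pl.oblivious_read(arr, share_secret(onehot, s), s, c), s))
            assert got == vals[i]

    def test_transcript_independent_of_index(self):
        sizes = []
        for i in (0, 2):
            s = Session(seed=15)
            c = PartitionCache()
            arr = share_secret([5, 6, 7], s)
            onehot = np.zeros(3, dtype=int)
            onehot[i] = 1
            pl.oblivious_read(arr, share_secret(onehot, s), s, c)
            sizes.append((s.metrics.rounds, s.metrics.total_bytes,
                          sum(s.metrics.messages.values())))
        assert sizes[0] == sizes[1]


class TestBloom:
    def test_membership_bits(self):
        index = pl.BloomIndex(np.zeros((1, 16), dtype=int), 2, 16, 4)
        index.bits[0, [2, 5]] = 1
        s = Session(seed=16)
        c = PartitionCache()
        for positions, want in (([2, 5], 1), ([2, 6], 0)):
            onehots = np.zeros((1, 2, 16), dtype=int)
            for j, p in enumerate(positions):
                onehots[0, j, p] = 1
            score = pl.bloom_query(index, share_secret(onehots, s), s, c)
            assert int(reveal(score, s).reshape(-1)[0]) == want

    def test_20_reads_match_plaintext_exactly(self):
        data = syn.gen_reads(n_reads=20, seed=17)
        index = pl.build_bloom_index(data.kmer_sets)
        s = Session(seed=17)
        c = PartitionCache()
        secure = pl.classify_reads_secure(index, data.reads, s, c)
        plain = np.array([pl.bloom_classify_plain(index, r) for r in data.reads])
        assert (secure == plain).all()
        assert (secure == data.labels).mean() >= 0.8

    def test_transcripts_identical_across_queries(self):
        data = syn.gen_reads(n_reads=4, seed=18)
        index = pl.build_bloom_index(data.kmer_sets)
        stats = []
        for read in data.reads:
            s = Session(seed=19)
            c = PartitionCache()
            pl.classify_reads_secure(index, [read], s, c)
            stats.append((s.metrics.rounds, s.metrics.total_bytes,
                          sum(s.metrics.messages.values())))
        assert len(set(stats)) == 1

    def test_reveals_labels_only(self):
        data = syn.gen_reads(n_reads=2, seed=20)
        index = pl.build_bloom_index(data.kmer_sets)
        s = Session(seed=20)
        pl.classify_reads_secure(index, data.reads, s, PartitionCache())
        assert {e["label"] for e in s.reveal_log} == {"output:bin_label"}


class TestHingeSGD:
    def test_single_step_update(self):
        # w=0, x=(1,1), y=+1, lr=0.1: margin 0 < 1, so w -> (0.1, 0.1)
        s = Session(seed=21)
        c = PartitionCache()
        X = share_reals(np.array([[1.0, 1.0]]), s)
        y = share_secret(np.array([1]), s)
        w, b = pl.hinge_sgd_train(X, y, pl.SGDHyperParams(0.1, 1, 0), s, c,
                                  max_steps=1)
        got_w = reveal_reals(w, s)
        assert np.allclose(got_w, [0.1, 0.1], atol=1e-6)
        assert abs(reveal_reals(b, s) - 0.1) <= 1e-6

    def test_secure_trajectory_matches_plain_fixed_100_steps(self):
        X, y = syn.gen_linear_features(n=50, seed=22)
        hp = pl.SGDHyperParams(0.1, 2, 3)
        s = Session(seed=22)
        c = PartitionCache()
        w, b = pl.hinge_sgd_train(share_reals(X, s), share_secret(y, s), hp,
                                  s, c, max_steps=100)
        wp, bp = pl.hinge_sgd_plain_fixed(X, y, hp, max_steps=100)
        w_sec = reveal_reals(w, s)
        w_ref = np.array([int(v) for v in wp]) / 2.0 ** 32
        assert np.max(np.abs(w_sec - w_ref)) <= 1e-3
        assert abs(reveal_reals(b, s) - int(bp) / 2.0 ** 32) <= 1e-3

    def test_classify_matches_plain_and_reveals_labels_only(self):
        X, y = syn.gen_linear_features(n=60, seed=23)
        hp = pl.SGDHyperParams(0.1, 2, 5)
        s = Session(seed=23)
        c = PartitionCache()
        Xs = share_reals(X, s)
        w, b = pl.hinge_sgd_train(Xs, share_secret(y, s), hp, s, c)
        labels = pl.classify(pl.ClassifierModel([w], [b], [1], hp), Xs, s, c)
        wp, bp = pl.hinge_sgd_plain_fixed(X, y, hp)
        plain = pl.classify_plain_fixed(wp, bp, X)
        assert (labels == plain).all()
        assert {e["label"] for e in s.reveal_log} == {"output:class_label"}

    def test_multiclass_argmax_classify(self):
        s = Session(seed=24)
        c = PartitionCache()
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        Xs = share_reals(X, s)
        w0 = share_reals(np.array([1.0, 0.0]), s)
        w1 = share_reals(np.array([0.0, 1.0]), s)
        zero = share_reals(0.0, s)
        model = pl.ClassifierModel([w0, w1], [zero, zero], [0, 1],
                                   pl.SGDHyperParams())
        labels = pl.classify(model, Xs, s, c)
        assert list(labels) == [0, 1]
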