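"""Beaver partitions, caching, secure products, and one-round
polynomial evaluation."""

import numpy as np
import pytest

from mpcbio import Session
from mpcbio.beaver import (
    BeaverTriple,
    DegreeCapError,
    PartitionCache,
    PolynomialSpec,
    ensure_partitions,
    evaluate_polynomial,
    inner_product,
    matrix_multiply,
    multiply,
    multiply_with_triple,
    partition,
    propagate_partition,
)
from mpcbio.sharing import ShareError, add_local, mul_public, reveal, share_secret


class TestPartitionCache:
    def test_first_call_opens_second_reuses(self, session, cache):
        x = share_secret(11, session)
        r0 = session.metrics.rounds
        partition(x, session, cache)
        assert session.metrics.rounds - r0 == 1
        partition(x, session, cache)
        assert session.metrics.rounds - r0 == 1
        assert cache.hits == 1 and cache.misses == 1

    def test_partition_identity(self, session, cache):
        x = share_secret(1234, session)
        p = partition(x, session, cache)
        q = session.domain.modulus
        r = reveal(p.mask, session, "output:test")
        assert (int(p.residual) + int(r)) % q == 1234

    def test_mutation_invalidates(self, session, cache):
        x = share_secret(5, session)
        y = share_secret(3, session)
        partition(x, session, cache)
        x.iadd(y)  # in-place update bumps the version
        r0 = session.metrics.rounds
        partition(x, session, cache)
        assert session.metrics.rounds - r0 == 1   # fresh opening, not a hit
        assert cache.invalidations == 1

    def test_three_partitions_for_xy_xz(self, session, cache):
        x, y, z = (share_secret(v, session) for v in (2, 3, 4))
        multiply(x, y, session, cache)
        multiply(x, z, session, cache)
        assert cache.misses == 3
        assert cache.hits == 1


class TestPropagation:
    def test_add_propagation_identity(self, session, cache):
        x = share_secret(10, session)
        y = share_secret(20, session)
        px, py = ensure_partitions([x, y], session, cache)
        z = add_local(x, y)
        r0 = session.metrics.rounds
        pz = propagate_partition("add", (px, py), z, cache)
        assert session.metrics.rounds == r0
        q = session.domain.modulus
        r = reveal(pz.mask, session, "output:test")
        assert (int(pz.residual) + int(r)) % q == 30

    def test_mul_public_propagation(self, session, cache):
        x = share_secret(10, session)
        (px,) = ensure_partitions([x], session, cache)
        z = mul_public(x, 7)
        pz = propagate_partition("mul_public", (px,), z, cache, public=7)
        q = session.domain.modulus
        r = reveal(pz.mask, session, "output:test")
        assert (int(pz.residual) + int(r)) % q == 70

    def test_derived_partition_reused_by_multiply(self, session, cache):
        x = share_secret(10, session)
        y = share_secret(20, session)
        w = share_secret(3, session)
        px, py, _ = ensure_partitions([x, y, w], session, cache)
        z = add_local(x, y)
        propagate_partition("add", (px, py), z, cache)
        r0 = session.metrics.rounds
        out = multiply(z, w, session, cache)   # both warm: zero rounds
        assert session.metrics.rounds == r0
        assert int(reveal(out, session)) == 90

    def test_stale_input_rejected(self, session, cache):
        x = share_secret(10, session)
        (px,) = ensure_partitions([x], session, cache)
        x.iadd(share_secret(1, session))
        z = mul_public(x, 2)
        with pytest.raises(ShareError):
            propagate_partition("mul_public", (px,), z, cache, public=2)


class TestMultiply:
    def test_examples(self, session, cache):
        x = share_secret(6, session)
        y = share_secret(7, session)
        assert int(reveal(multiply(x, y, session, cache), session)) == 42
        one = share_secret(1, session)
        assert int(reveal(multiply(x, one, session, cache), session)) == 6

    def test_oracle_100_random_pairs(self, session, cache, rng):
        q = session.domain.modulus
        a = rng.integers(0, 2**60, size=100)
        b = rng.integers(0, 2**60, size=100)
        x = share_secret(a, session)
        y = share_secret(b, session)
        got = reveal(multiply(x, y, session, cache), session)
        assert (got == (a.astype(object) * b.astype(object)) % q).all()

    def test_cold_one_round_warm_zero(self, session, cache):
        x = share_secret(3, session)
        y = share_secret(4, session)
        r0 = session.metrics.rounds
        multiply(x, y, session, cache)
        assert session.metrics.rounds - r0 == 1
        r0 = session.metrics.rounds
        multiply(x, y, session, cache)
        assert session.metrics.rounds - r0 == 0

    def test_triple_based_multiply(self, session):
        a_sh, b_sh, c_sh = session.dealer.issue_triple((), session.domain)
        from mpcbio.sharing import SharedTensor
        triple = BeaverTriple(
            SharedTensor(a_sh, session.domain, session),
            SharedTensor(b_sh, session.domain, session),
            SharedTensor(c_sh, session.domain, session),
        )
        x = share_secret(9, session)
        y = share_secret(8, session)
        r0 = session.metrics.rounds
        z = multiply_with_triple(x, y, triple, session)
        assert session.metrics.rounds - r0 == 1
        assert int(reveal(z, session)) == 72


class TestInnerProduct:
    def test_example(self, session, cache):
        x = share_secret([1, 2, 3], session)
        y = share_secret([4, 5, 6], session)
        assert int(reveal(inner_product(x, y, session, cache), session)) == 32

    def test_zero_vector(self, session, cache):
        x = share_secret([1, 2, 3], session)
        z = share_secret([0, 0, 0], session)
        assert int(reveal(inner_product(x, z, session, cache), session)) == 0

    def test_rounds_independent_of_length(self):
        counts = {}
        for n in (10, 1000):
            s = Session(seed=17)
            c = PartitionCache()
            x = share_secret(list(range(n)), s)
            y = share_secret(list(range(n)), s)
            r0 = s.metrics.rounds
            inner_product(x, y, s, c)
            counts[n] = s.metrics.rounds - r0
        assert counts[10] == counts[1000] <= 2

    def test_length_mismatch(self, session, cache):
        with pytest.raises(ShareError):
            inner_product(share_secret([1, 2], session),
                          share_secret([1, 2, 3], session), session, cache)


class TestMatrixMultiply:
    def test_identity(self, session, cache):
        M = np.arange(4).reshape(2, 2)
        I = np.eye(2, dtype=int)
        out = matrix_multiply(share_secret(I, session), share_secret(M, session),
                              session, cache)
        assert (reveal(out, session) == M.astype(object)).all()

    def test_random_4x4_oracle(self, session, cache, rng):
        q = session.domain.modulus
        A = rng.integers(0, 2**40, size=(4, 4))
        B = rng.integers(0, 2**40, size=(4, 4))
        out = matrix_multiply(share_secret(A, session), share_secret(B, session),
                              session, cache)
        assert (reveal(out, session) == (A.astype(object) @ B.astype(object)) % q).all()

    def test_rounds_bounded_regardless_of_size(self):
        for n in (2, 8):
            s = Session(seed=23)
            c = PartitionCache()
            A = share_secret(np.ones((n, n), dtype=int), s)
            B = share_secret(np.ones((n, n), dtype=int), s)
            r0 = s.metrics.rounds
            matrix_multiply(A, B, s, c)
            assert s.metrics.rounds - r0 <= 3


class TestPolynomialEvaluation:
    def test_example_3x2y_plus_2y(self, session, cache):
        x = share_secret(2, session)
        y = share_secret(5, session)
        spec = PolynomialSpec([3, 2], [[2, 1], [0, 1]])
        out = evaluate_polynomial(spec, [x, y], session, cache)
        assert int(reveal(out, session)) == 70

    def test_mult3_one_round_vs_two_sequential(self):
        s1 = Session(seed=31)
        c1 = PartitionCache()
        vs = [share_secret(v, s1) for v in (2, 3, 4)]
        r0 = s1.metrics.rounds
        out = evaluate_polynomial(PolynomialSpec([1], [[1, 1, 1]]), vs, s1, c1)
        assert s1.metrics.rounds - r0 == 1
        assert int(reveal(out, s1)) == 24

        s2 = Session(seed=31)
        c2 = PartitionCache()
        vs = [share_secret(v, s2) for v in (2, 3, 4)]
        r0 = s2.metrics.rounds
        t = multiply(multiply(vs[0], vs[1], s2, c2), vs[2], s2, c2)
        assert s2.metrics.rounds - r0 == 2
        assert int(reveal(t, s2)) == 24

    def test_each_variable_partitioned_once(self, session, cache):
        x = share_secret(2, session)
        y = share_secret(3, session)
        spec = PolynomialSpec([1, 1, 1], [[2, 1], [1, 2], [1, 1]])
        evaluate_polynomial(spec, [x, y], session, cache)
        assert cache.misses == 2

    def test_50_random_polynomials_oracle(self, rng):
        """Degree <= 3 polynomials in <= 4 variables match plaintext."""
        q = Session(seed=0).domain.modulus
        for trial in range(50):
            s = Session(seed=1000 + trial)
            c = PartitionCache()
            nv = int(rng.integers(1, 5))
            nm = int(rng.integers(1, 4))
            exps = np.zeros((nm, nv), dtype=int)
            for i in range(nm):
                budget = int(rng.integers(0, 4))
                for _ in range(budget):
                    exps[i, rng.integers(nv)] += 1
            coeffs = [int(v) for v in rng.integers(-5, 6, size=nm)]
            vals = [int(v) for v in rng.integers(0, 100, size=nv)]
            spec = PolynomialSpec(coeffs, exps)
            shares = [share_secret(v, s) for v in vals]
            out = evaluate_polynomial(spec, shares, s, c)
            assert int(reveal(out, s)) == spec.evaluate_plain(vals, q)

    def test_degree_cap_error(self, session, cache):
        vs = [share_secret(v, session) for v in (2, 3)]
        spec = PolynomialSpec([1], [[3, 2]])
        with pytest.raises(DegreeCapError):
            evaluate_polynomial(spec, vs, session, cache, degree_cap=4)

    def test_warm_cache_costs_zero_extra_rounds(self, session, cache):
        x = share_secret(2, session)
        y = share_secret(5, session)
        spec = PolynomialSpec([3, 2], [[2, 1], [0, 1]])
        evaluate_polynomial(spec, [x, y], session, cache)
        r0 = session.metrics.rounds
        out = evaluate_polynomial(spec, [x, y], session, cache)
        assert session.metrics.rounds == r0
        assert int(reveal(out, session)) == 70

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PolynomialSpec([1, 2], [[1, 0]])
        with pytest.raises(ValueError):
            PolynomialSpec([1], [[-1, 0]])
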