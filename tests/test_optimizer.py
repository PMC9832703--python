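"""Expression graphs: lazy building, polynomial expansion, pattern
rewrites, planning, and optimized execution."""

import numpy as np
import pytest
import sympy

from mpcbio import Session, PartitionCache
from mpcbio import optimizer as opt
from mpcbio.sharing import reveal, reveal_reals, share_reals, share_secret

from dag_helpers import brute_force_min_rounds, eval_plain, random_int_dag, to_expr


class TestBuild:
    def test_structural_sharing(self, session):
        x = opt.secret(share_secret(2, session))
        y = opt.secret(share_secret(3, session))
        z = opt.secret(share_secret(4, session))
        node = opt.build(x * y + x * z)
        left, right = node.children
        assert left.children[0] is right.children[0]   # x appears once

    def test_constant_folding(self, session):
        x = opt.secret(share_secret(2, session))
        assert opt.build(x + 0) is opt.build(x)
        assert opt.build(x * 1) is opt.build(x)
        assert opt.build(x * 0).op == "leaf_public"
        assert (x ** 1).node is x.node

    def test_building_is_lazy(self, session):
        snap = session.metrics.snapshot()
        x = opt.secret(share_secret(2, session))
        y = opt.secret(share_secret(3, session))
        _ = (x * y + x ** 3) * 5 - y
        assert session.metrics.snapshot() == snap


class TestExpandToPolynomial:
    def test_binomial_square(self, session):
        x = opt.secret(share_secret(2, session))
        y = opt.secret(share_secret(3, session))
        spec, order = opt.expand_to_polynomial(opt.build((x + y) ** 2))
        assert sorted(spec.coeffs) == [1, 1, 2]
        assert spec.degree == 2

    def test_degree_refusal_is_a_value(self, session):
        x, y, z = (opt.secret(share_secret(v, session)) for v in (2, 3, 4))
        assert opt.expand_to_polynomial(opt.build(x * y * z), cap=2) is None

    def test_non_arithmetic_raises(self, session):
        a = opt.secret(share_reals(1.0, session), is_fp=True)
        b = opt.secret(share_reals(2.0, session), is_fp=True)
        with pytest.raises(TypeError):
            opt.expand_to_polynomial(opt.build(a / b))

    def test_random_trees_match_sympy(self, session, rng):
        """Collected (coeffs, exponents) evaluate identically to sympy's
        expansion on 20 random arithmetic trees."""
        for _ in range(20):
            dag, values = random_int_dag(rng, depth=3)
            leaves = [opt.secret(share_secret(v, session)) for v in values]
            node = opt.build(to_expr(dag, leaves))
            res = opt.expand_to_polynomial(node, cap=50)
            assert res is not None
            spec, order = res
            syms = sympy.symbols(f"v0:{len(values)}")
            sym_leaf = {leaves[i].node.leaf_id: syms[i] for i in range(len(values))}

            def sym_eval(n):
                if n[0] == "var":
                    return syms[n[1]]
                if n[0] == "pow":
                    return sym_eval(n[1]) ** n[2]
                a, b = sym_eval(n[1]), sym_eval(n[2])
                return {"add": a + b, "sub": a - b, "mul": a * b}[n[0]]

            want = sympy.expand(sym_eval(dag))
            got = sum(
                c * sympy.prod([sym_leaf[l] ** int(p) for l, p in zip(order, row)])
                for c, row in zip(spec.coeffs, spec.exponents)
            )
            assert sympy.simplify(want - got) == 0


class TestRewrites:
    def test_div_by_sqrt_pattern(self, session):
        a = opt.secret(share_reals(3.0, session), is_fp=True)
        b = opt.secret(share_reals(4.0, session), is_fp=True)
        node = opt.rewrite_patterns(opt.build(a / opt.sqrt_expr(b)))
        assert node.op == "mul"
        assert node.children[1].op == "invsqrt"
        assert node.annotation == "div_by_sqrt"

    def test_diag_matmul_becomes_row_scale(self, session):
        d = opt.diag(share_secret([1, 2, 3], session))
        M = opt.secret(share_secret(np.arange(9).reshape(3, 3), session))
        node = opt.rewrite_patterns(opt.build(d @ M))
        assert node.op == "row_scale"
        assert node.annotation == "diag_vectorized"

    def test_idempotence(self, session):
        a = opt.secret(share_reals(3.0, session), is_fp=True)
        b = opt.secret(share_reals(4.0, session), is_fp=True)
        x = opt.secret(share_secret(2, session))
        for expr in (a / opt.sqrt_expr(b), x * x + x ** 5):
            once = opt.rewrite_patterns(opt.build(expr))
            assert opt.rewrite_patterns(once) is once

    def test_untouched_graph_unchanged(self, session):
        x = opt.secret(share_secret(2, session))
        y = opt.secret(share_secret(3, session))
        node = opt.build(x * y + y)
        assert opt.rewrite_patterns(node) is node

    def test_row_scale_executes_correctly(self, session, cache):
        dvec = np.array([1, 2, 3])
        M = np.arange(9).reshape(3, 3)
        d = opt.diag(share_secret(dvec, session))
        Ms = opt.secret(share_secret(M, session))
        out, _ = opt.run_optimized(d @ Ms, session, cache)
        want = (np.diag(dvec) @ M).astype(object)
        assert (reveal(out, session) == want).all()

    def test_pow_beyond_cap_splits(self, session):
        x = opt.secret(share_secret(2, session))
        node = opt.rewrite_patterns(opt.build(x ** 5), cap=4)
        assert node.op == "mul"
        assert node.annotation == "degree_split"


class TestPlan:
    def test_xy_plus_xz_three_partitions_one_round(self, session, cache):
        x, y, z = (opt.secret(share_secret(v, session)) for v in (2, 3, 4))
        p = opt.plan(opt.build(x * y + x * z), cache, 4, session)
        assert p.predicted_rounds == 1
        assert len(p.partition_schedule) == 3

    def test_warm_cache_zero_new_partitions(self, session, cache):
        xs = share_secret(2, session)
        ys = share_secret(3, session)
        from mpcbio.beaver import ensure_partitions
        ensure_partitions([xs, ys], session, cache)
        x, y = opt.secret(xs), opt.secret(ys)
        p = opt.plan(opt.build(x * y), cache, 4, session)
        assert p.predicted_rounds == 0
        assert p.partition_schedule == []

    def test_degree_five_splits_into_stages(self, session, cache):
        x = opt.secret(share_secret(2, session))
        p = opt.plan(opt.build(x ** 5), cache, 4, session)
        assert len([s for s in p.steps if s.kind in ("poly", "op")]) >= 2
        out = opt.execute(p, session, cache)
        assert int(reveal(out, session)) == 32

    def test_small_dag_round_optimality(self, rng):
        """Planner round count equals the brute-force minimum over all
        valid plans for random DAGs with <= 4 internal nodes."""
        checked = 0
        while checked < 15:
            s = Session(seed=500 + checked)
            c = PartitionCache()
            dag, values = random_int_dag(rng, depth=2)
            leaves = [opt.secret(share_secret(v, s)) for v in values]
            node = opt.rewrite_patterns(opt.build(to_expr(dag, leaves)))
            n_internal = len([n for n in opt._topo([node])
                              if n.op not in ("leaf_secret", "leaf_public")])
            if n_internal == 0 or n_internal > 4:
                continue
            p = opt.plan(node, c, 4, s)
            assert p.predicted_rounds == brute_force_min_rounds(node, 4)
            checked += 1

    def test_plan_dump_is_json(self, session, cache):
        x, y = (opt.secret(share_secret(v, session)) for v in (2, 3))
        p = opt.plan(opt.build(x * y), cache, 4, session)
        import json
        parsed = json.loads(p.dump())
        assert "predicted_rounds" in parsed


class TestExecute:
    def test_predicted_rounds_match_observed(self, rng):
        for trial in range(10):
            s = Session(seed=700 + trial)
            c = PartitionCache()
            dag, values = random_int_dag(rng, depth=3)
            leaves = [opt.secret(share_secret(v, s)) for v in values]
            node = opt.build(to_expr(dag, leaves))
            p = opt.plan(node, c, 4, s)
            opt.execute(p, s, c)   # raises if prediction is violated

    def test_optimized_equals_naive_never_more_rounds(self, rng):
        """Semantic preservation + round dominance on 30 random DAGs
        (the full 200-DAG sweep runs in the acceptance suite)."""
        q = Session(seed=0).domain.modulus
        for trial in range(30):
            s = Session(seed=900 + trial)
            dag, values = random_int_dag(rng)
            leaves = [opt.secret(share_secret(v, s)) for v in values]
            node = opt.build(to_expr(dag, leaves))
            want = eval_plain(dag, values, q)

            r0 = s.metrics.rounds
            naive = opt.naive_execute(node, s)
            naive_rounds = s.metrics.rounds - r0
            assert int(reveal(naive, s)) == want

            c = PartitionCache()
            r0 = s.metrics.rounds
            out, plan = opt.run_optimized(node, s, c)
            opt_rounds = s.metrics.rounds - r0
            assert int(reveal(out, s)) == want
            assert opt_rounds <= naive_rounds

    def test_second_execution_reuses_partitions(self, session):
        x, y, z = (opt.secret(share_secret(v, session)) for v in (2, 3, 4))
        node = opt.build(x * y + x * z)
        c = PartitionCache()
        opt.run_optimized(node, session, c)
        misses_first = c.misses
        r0 = session.metrics.rounds
        out, _ = opt.run_optimized(node, session, c)
        assert c.misses == misses_first      # no new partitions at all
        assert session.metrics.rounds == r0  # and zero communication
        assert int(reveal(out, session)) == 2 * 3 + 2 * 4

    def test_fp_expression_matches_float_reference(self, session):
        a = opt.secret(share_reals(3.0, session), is_fp=True)
        b = opt.secret(share_reals(4.0, session), is_fp=True)
        cpc = PartitionCache()
        out, _ = opt.run_optimized(a / opt.sqrt_expr(b) + a * b, session, cpc)
        assert abs(reveal_reals(out, session) - (3 / 2 + 12)) <= 1e-3
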