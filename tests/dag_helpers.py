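"""Shared helpers for optimizer tests: random expression DAGs and an
independent plaintext evaluator / plan-cost enumerator."""

from __future__ import annotations

import numpy as np

from mpcbio import optimizer as opt


def random_int_dag(rng, n_vars=None, depth=4, reuse_p=0.4):
    """A random arithmetic expression DAG over integer secret leaves.

    Returns (expr, leaf_values) where leaf_values maps leaf order to the
    plaintext integers.  Subexpressions are reused with probability
    ``reuse_p`` so the DAG is not a tree.
    """
    n_vars = n_vars or int(rng.integers(2, 7))
    values = [int(v) for v in rng.integers(0, 50, size=n_vars)]
    pool = []  # (expr, plain_fn) built so far

    def leaf(i):
        return ("var", i)

    nodes = [leaf(i) for i in range(n_vars)]
    n_internal = int(rng.integers(1, 2 ** depth))
    for _ in range(n_internal):
        op = rng.choice(["add", "sub", "mul", "mul", "pow"])
        if op == "pow":
            child = nodes[int(rng.integers(len(nodes)))]
            e = int(rng.integers(2, 4))
            nodes.append(("pow", child, e))
        else:
            a = nodes[int(rng.integers(len(nodes)))]
            b = nodes[int(rng.integers(len(nodes)))]
            nodes.append((op, a, b))
    root = nodes[-1]
    return root, values


def eval_plain(node, values, q):
    """Independent plaintext evaluation of a helper-DAG, mod q."""
    kind = node[0]
    if kind == "var":
        return values[node[1]] % q
    if kind == "pow":
        return pow(eval_plain(node[1], values, q), node[2], q)
    a = eval_plain(node[1], values, q)
    b = eval_plain(node[2], values, q)
    if kind == "add":
        return (a + b) % q
    if kind == "sub":
        return (a - b) % q
    return (a * b) % q


def to_expr(node, leaves):
    """Convert a helper-DAG into optimizer Expr form (memoized so shared
    subexpressions map to shared nodes)."""
    memo = {}

    def go(n):
        key = id(n)
        if key in memo:
            return memo[key]
        kind = n[0]
        if kind == "var":
            out = leaves[n[1]]
        elif kind == "pow":
            out = go(n[1]) ** n[2]
        else:
            a, b = go(n[1]), go(n[2])
            out = {"add": a + b, "sub": a - b, "mul": a * b}[kind]
        memo[key] = out
        return out

    return go(node)


# ---------------------------------------------------------------------------
# independent brute-force plan enumeration (round-count oracle)

def brute_force_min_rounds(root_node, cap=4):
    """Minimum round count over all valid plans, enumerated directly.

    A plan decides, for every eligible arithmetic node, whether to
    evaluate it as one generalized polynomial (degree <= cap) or to
    recurse per-operation.  Cost model (independent re-statement of the
    engine's accounting): each step opens the partitions of the operands
    it touches in one batched round; an operand costs nothing if some
    earlier step already partitioned it; results of earlier steps are
    always cold when first consumed; local ops are free.
    """
    eligible = []

    def collect(n, seen):
        if n in seen or n.op in ("leaf_secret", "leaf_public"):
            return
        seen.add(n)
        res = None
        try:
            res = opt.expand_to_polynomial(n, cap)
        except TypeError:
            res = None
        if res is not None and opt._has_mul(n):
            eligible.append(n)
        for c in n.children:
            collect(c, seen)

    collect(root_node, set())

    from itertools import combinations
    best = None
    subsets = [frozenset()]
    for k in range(1, len(eligible) + 1):
        subsets += [frozenset(s) for s in combinations(eligible, k)]
    for S in subsets:
        rounds = _cost(root_node, S, cap)
        if best is None or rounds < best:
            best = rounds
    return best


def _cost(root, chosen, cap):
    rounds = 0
    partitioned = set()
    done = set()

    def need(keys):
        nonlocal rounds
        cold = [k for k in keys if k not in partitioned]
        partitioned.update(cold)
        return 1 if cold else 0

    def visit(n):
        nonlocal rounds
        if n in done or n.op == "leaf_public":
            return
        if n in chosen:
            _, order = opt.expand_to_polynomial(n, cap)
            rounds += need(list(order))
            done.add(n)
            return
        for c in n.children:
            visit(c)
        if n.op == "leaf_secret":
            done.add(n)
            return
        key = lambda c: c.leaf_id if c.op == "leaf_secret" else c
        ops = [c for c in n.children if c.op != "leaf_public"]
        if n.op == "mul" and len(ops) == 2:
            rounds += need([key(c) for c in ops])
        elif n.op == "pow_const":
            rounds += need([key(ops[0])])
        elif n.op == "mul":
            pass  # public scaling is local in integer mode
        done.add(n)

    visit(root)
    return rounds
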