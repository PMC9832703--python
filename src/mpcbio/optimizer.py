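"""Lazy expression graphs over secret handles, with the protocol-level
optimizations applied as graph passes at run time.

Writing ``x * y + x * z`` on secure handles does not communicate: it
builds a hash-consed DAG (shared sub-expressions are represented once).
Before execution the graph goes through three passes:

1. **Pattern rewrites** — ``a / sqrt(b)`` becomes ``a * invsqrt(b)``
   (the inverse square root is a free by-product of the square-root
   iteration); a matrix product with a diagonal-tagged matrix becomes an
   elementwise row scaling (O(n^2) instead of O(n^3) scalar products);
   exponents above the polynomial degree cap are split into
   multiplication chains.

2. **Polynomial expansion** — any pure {add, sub, mul, pow} subtree
   with integer coefficients can be collected into the generalized form
   ``sum_i c_i prod_j x_j^{p_ij}`` and evaluated in one online round by
   generalized Beaver partitioning, provided its degree stays under the
   cap (the dealer-correlation count grows exponentially with degree,
   so expansion past the cap is refused and the expression is divided
   into smaller stages that lean on partition caching instead).

3. **Planning** — per subtree, choose between the polynomial route and
   a chain of cached multiplications, minimizing (rounds, then dealer
   correlations) lexicographically; each secret variable is partitioned
   at most once per plan.  Plans are found by exhaustive search on small
   graphs and greedily (largest expandable subtree first) on large ones.

Graphs whose leaves are fixed-point encoded, or that contain division /
square-root nodes, are executed with truncating fixed-point protocols;
polynomial collapsing is disabled there because monomials of different
degree carry different fixed-point scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product as iter_product

import numpy as np

from .domains import FixedPointCodec
from .runtime import Session
from .sharing import (
    SharedTensor,
    add_local,
    add_public,
    mul_public,
    neg_local,
    sub_local,
)
from .beaver import (
    PartitionCache,
    PolynomialSpec,
    multiply,
    matrix_multiply,
    evaluate_polynomial,
)
from . import fixedpoint as fxp

__all__ = [
    "ExprNode",
    "Expr",
    "ExecutionPlan",
    "secret",
    "public",
    "diag",
    "sqrt_expr",
    "build",
    "expand_to_polynomial",
    "rewrite_patterns",
    "plan",
    "execute",
    "naive_execute",
    "run_optimized",
]

_ARITH = {"add", "sub", "mul", "pow_const"}
_LEAF = {"leaf_secret", "leaf_public"}


@dataclass(frozen=True)
class ExprNode:
    op: str
    children: tuple = ()
    exponent: int | None = None
    public_value: object = None
    leaf_id: int | None = None
    is_fp: bool = False
    diag_tag: bool = False
    shape: tuple = ()
    annotation: str | None = None

    def __repr__(self) -> str:  # compact, for plan dumps
        if self.op == "leaf_secret":
            return f"s{self.leaf_id}"
        if self.op == "leaf_public":
            return f"p({self.public_value})"
        if self.op == "pow_const":
            return f"({self.children[0]!r})^{self.exponent}"
        return f"{self.op}({', '.join(repr(c) for c in self.children)})"


_intern: dict = {}
_leaf_tensors: dict[int, SharedTensor] = {}


def _node(op, children=(), exponent=None, public_value=None, leaf_id=None,
          is_fp=False, diag_tag=False, shape=(), annotation=None) -> ExprNode:
    """Hash-consing constructor: structurally equal nodes are one object."""
    key = (op, tuple(id(c) for c in children), exponent,
           public_value if not isinstance(public_value, float) else ("f", public_value),
           leaf_id, is_fp, diag_tag, shape, annotation)
    node = _intern.get(key)
    if node is None:
        node = ExprNode(op, tuple(children), exponent, public_value, leaf_id,
                        is_fp, diag_tag, shape, annotation)
        _intern[key] = node
    return node


def _is_zero(n: ExprNode) -> bool:
    return n.op == "leaf_public" and n.public_value == 0


def _is_one(n: ExprNode) -> bool:
    return n.op == "leaf_public" and n.public_value == 1


class Expr:
    """User-facing handle with overloaded arithmetic; building is lazy
    and communication-free."""

    def __init__(self, node: ExprNode) -> None:
        self.node = node

    # helpers ----------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Expr":
        if isinstance(other, Expr):
            return other
        if isinstance(other, (int, float)):
            return public(other)
        raise TypeError(f"cannot use {type(other).__name__} in a secure expression")

    def _fp(self, *others) -> bool:
        return self.node.is_fp or any(o.node.is_fp for o in others)

    # operators --------------------------------------------------------

    def __add__(self, other):
        other = self._coerce(other)
        if _is_zero(other.node):
            return self
        if _is_zero(self.node):
            return other
        return Expr(_node("add", (self.node, other.node),
                          is_fp=self._fp(other), shape=self.node.shape or other.node.shape))

    __radd__ = __add__

    def __sub__(self, other):
        other = self._coerce(other)
        if _is_zero(other.node):
            return self
        return Expr(_node("sub", (self.node, other.node),
                          is_fp=self._fp(other), shape=self.node.shape or other.node.shape))

    def __mul__(self, other):
        other = self._coerce(other)
        if _is_one(other.node):
            return self
        if _is_one(self.node):
            return other
        if _is_zero(other.node) or _is_zero(self.node):
            return public(0)
        return Expr(_node("mul", (self.node, other.node),
                          is_fp=self._fp(other), shape=self.node.shape or other.node.shape))

    __rmul__ = __mul__

    def __pow__(self, e):
        if not isinstance(e, int) or e < 0:
            raise TypeError("exponents must be non-negative integers")
        if e == 0:
            return public(1)
        if e == 1:
            return self
        return Expr(_node("pow_const", (self.node,), exponent=e,
                          is_fp=self.node.is_fp, shape=self.node.shape))

    def __truediv__(self, other):
        other = self._coerce(other)
        return Expr(_node("div", (self.node, other.node), is_fp=True,
                          shape=self.node.shape or other.node.shape))

    def __matmul__(self, other):
        other = self._coerce(other)
        shape = (self.node.shape[0], other.node.shape[1])
        return Expr(_node("matmul", (self.node, other.node),
                          is_fp=self._fp(other), diag_tag=False, shape=shape))

    def __lt__(self, other):
        other = self._coerce(other)
        return Expr(_node("compare", (self.node, other.node), is_fp=self._fp(other),
                          shape=self.node.shape or other.node.shape))


def secret(x: SharedTensor, is_fp: bool = False, diag: bool = False) -> Expr:
    """Wrap a shared tensor as an expression leaf.

    ``is_fp`` marks fixed-point encoded payloads; ``diag`` tags a shared
    vector as the diagonal of a (conceptual) diagonal matrix, enabling
    the row-scaling rewrite for products against it.
    """
    _leaf_tensors[x.handle] = x
    return Expr(_node("leaf_secret", leaf_id=x.handle, is_fp=is_fp,
                      diag_tag=diag, shape=x.shape))


def public(c) -> Expr:
    is_fp = isinstance(c, float) and not float(c).is_integer()
    if isinstance(c, float) and float(c).is_integer():
        c = int(c)
    return Expr(_node("leaf_public", public_value=c, is_fp=is_fp))


def diag(vec: SharedTensor, is_fp: bool = False) -> Expr:
    return secret(vec, is_fp=is_fp, diag=True)


def sqrt_expr(x: Expr) -> Expr:
    return Expr(_node("sqrt", (x.node,), is_fp=True, shape=x.node.shape))


def build(expr: Expr) -> ExprNode:
    """Finalize a lazily captured expression (no communication)."""
    return expr.node


# ---------------------------------------------------------------------------
# polynomial expansion

def _poly_of(node: ExprNode, order: list[int]):
    """Recursive expansion into {exponent-tuple: int coeff} over the
    secret leaves listed in ``order``.  Raises TypeError off the
    arithmetic fragment."""
    nv = len(order)
    if node.op == "leaf_public":
        if not isinstance(node.public_value, int):
            raise TypeError("non-integer public constant in polynomial expansion")
        return {(0,) * nv: node.public_value}
    if node.op == "leaf_secret":
        exps = [0] * nv
        exps[order.index(node.leaf_id)] = 1
        return {tuple(exps): 1}
    if node.op == "add" or node.op == "sub":
        a = _poly_of(node.children[0], order)
        b = _poly_of(node.children[1], order)
        sign = 1 if node.op == "add" else -1
        out = dict(a)
        for k, v in b.items():
            out[k] = out.get(k, 0) + sign * v
            if out[k] == 0:
                del out[k]
        return out
    if node.op == "mul":
        a = _poly_of(node.children[0], order)
        b = _poly_of(node.children[1], order)
        out = {}
        for ka, va in a.items():
            for kb, vb in b.items():
                k = tuple(x + y for x, y in zip(ka, kb))
                out[k] = out.get(k, 0) + va * vb
                if out[k] == 0:
                    del out[k]
        return out
    if node.op == "pow_const":
        base = _poly_of(node.children[0], order)
        out = {(0,) * nv: 1}
        for _ in range(node.exponent):
            nxt = {}
            for ka, va in out.items():
                for kb, vb in base.items():
                    k = tuple(x + y for x, y in zip(ka, kb))
                    nxt[k] = nxt.get(k, 0) + va * vb
            out = {k: v for k, v in nxt.items() if v != 0}
        return out
    raise TypeError(f"operation {node.op!r} is outside the polynomial fragment")


def _secret_leaves(node: ExprNode, acc=None) -> list[int]:
    """Distinct secret-leaf ids in deterministic first-visit order."""
    if acc is None:
        acc = []
    if node.op == "leaf_secret":
        if node.leaf_id not in acc:
            acc.append(node.leaf_id)
    for c in node.children:
        _secret_leaves(c, acc)
    return acc


def expand_to_polynomial(node: ExprNode, cap: int = 4):
    """Collect an arithmetic subtree into a :class:`PolynomialSpec`.

    Returns ``(spec, leaf_ids)`` or ``None`` as a *refusal* when the
    degree exceeds the cap.  Non-arithmetic subtrees raise TypeError.
    """
    order = _secret_leaves(node)
    poly = _poly_of(node, order)
    if not poly:
        poly = {(0,) * len(order): 0}
    degree = max(sum(k) for k in poly)
    if degree > cap:
        return None
    items = sorted(poly.items())
    spec = PolynomialSpec([v for _, v in items], np.array([k for k, _ in items],
                                                          dtype=int).reshape(len(items), len(order)))
    return spec, order


# ---------------------------------------------------------------------------
# rewrites

def rewrite_patterns(node: ExprNode, cap: int = 4) -> ExprNode:
    """Bottom-up algebraic rewrites; idempotent.

    * ``div(a, sqrt(b))``  ->  ``mul(a, invsqrt(b))``
    * ``matmul(diag(d), M)``  ->  ``row_scale(d, M)`` (and the mirrored
      ``matmul(M, diag(d))`` -> column scaling)
    * ``pow_const`` with exponent above the cap  ->  balanced product
      chain of capped powers.
    """
    kids = tuple(rewrite_patterns(c, cap) for c in node.children)
    if node.op == "div" and kids[1].op == "sqrt":
        inv = _node("invsqrt", (kids[1].children[0],), is_fp=True,
                    shape=kids[1].shape, annotation="div_by_sqrt")
        return _node("mul", (kids[0], inv), is_fp=True, shape=node.shape,
                     annotation="div_by_sqrt")
    if node.op == "matmul" and kids[0].op == "leaf_secret" and kids[0].diag_tag:
        return _node("row_scale", kids, is_fp=node.is_fp, shape=node.shape,
                     annotation="diag_vectorized")
    if node.op == "matmul" and kids[1].op == "leaf_secret" and kids[1].diag_tag:
        return _node("col_scale", kids, is_fp=node.is_fp, shape=node.shape,
                     annotation="diag_vectorized")
    if node.op == "pow_const" and (node.exponent > cap or node.is_fp):
        e = node.exponent
        base = kids[0]
        # fp powers decompose fully into (truncating) multiplications;
        # integer powers split only past the polynomial degree cap
        chunk = 1 if node.is_fp else cap
        if e > chunk:
            left = rewrite_patterns(
                _node("pow_const", (base,), exponent=e - (e // 2),
                      is_fp=node.is_fp, shape=node.shape), cap)
            right = rewrite_patterns(
                _node("pow_const", (base,), exponent=e // 2,
                      is_fp=node.is_fp, shape=node.shape), cap)
            return _node("mul", (left, right), is_fp=node.is_fp, shape=node.shape,
                         annotation="degree_split")
    if kids == node.children:
        return node
    return _node(node.op, kids, node.exponent, node.public_value, node.leaf_id,
                 node.is_fp, node.diag_tag, node.shape, node.annotation)


# ---------------------------------------------------------------------------
# planning

@dataclass
class PlanStep:
    kind: str            # "poly" | "op"
    node: ExprNode
    spec: PolynomialSpec | None = None
    var_ids: list[int] | None = None


@dataclass
class ExecutionPlan:
    steps: list[PlanStep]
    predicted_rounds: int
    predicted_correlations: int
    partition_schedule: list[int]      # leaf ids, each at most once
    exact_rounds: bool                 # integer-mode plans predict exactly
    roots: list[ExprNode] = field(default_factory=list)

    def dump(self) -> str:
        return json.dumps({
            "steps": [
                {"kind": s.kind, "node": repr(s.node),
                 **({"degree": s.spec.degree} if s.spec else {})}
                for s in self.steps
            ],
            "predicted_rounds": self.predicted_rounds,
            "predicted_correlations": self.predicted_correlations,
            "partition_schedule": self.partition_schedule,
        }, indent=2)


def _poly_eligible(node: ExprNode, cap: int) -> bool:
    if node.is_fp or node.op not in ("mul", "pow_const", "add", "sub"):
        return False
    try:
        return expand_to_polynomial(node, cap) is not None
    except TypeError:
        return False


def _has_mul(node: ExprNode) -> bool:
    if node.op in ("mul", "pow_const"):
        return True
    return any(_has_mul(c) for c in node.children)


def _monomial_requests(spec: PolynomialSpec) -> int:
    """Dealer mask-product requests the evaluation will make: distinct
    nonzero expansion exponent vectors, minus those served directly by a
    partition's own mask share (a single variable at power one)."""
    seen = set()
    for row in spec.exponents:
        for ks in iter_product(*[range(int(p) + 1) for p in row]):
            if any(ks):
                seen.add(ks)
    singles = {k for k in seen if sum(k) == 1}
    return len(seen - singles)


_FP_COSTS_CACHE: dict = {}


def _fp_round_costs(session: Session) -> dict[str, int]:
    """Per-primitive round costs for this session configuration,
    measured once on a throwaway probe session (deterministic)."""
    key = (session.n_parties, session.domain.modulus, session.codec.frac_bits,
           session.codec.compare_bits)
    if key in _FP_COSTS_CACHE:
        return _FP_COSTS_CACHE[key]
    from .sharing import share_reals
    probe = Session(session.n_parties, session.domain, session.codec, seed=7)
    cache = PartitionCache()
    costs = {}
    a = share_reals(3.0, probe)
    b = share_reals(2.0, probe)
    r0 = probe.metrics.rounds
    fxp.truncate(a, probe)
    costs["trunc"] = probe.metrics.rounds - r0
    r0 = probe.metrics.rounds
    fxp.less_than_zero(a, probe, cache)
    costs["compare"] = probe.metrics.rounds - r0
    r0 = probe.metrics.rounds
    fxp.divide(share_reals(3.0, probe), share_reals(2.0, probe), probe, cache)
    costs["div"] = probe.metrics.rounds - r0
    r0 = probe.metrics.rounds
    fxp.sqrt_invsqrt(share_reals(2.0, probe), probe, cache)
    costs["sqrt"] = probe.metrics.rounds - r0
    costs["invsqrt"] = costs["sqrt"]
    _FP_COSTS_CACHE[key] = costs
    return costs


def _simulate(roots: list[ExprNode], chosen: set, cap: int,
              fp_costs: dict[str, int], warm: set) -> tuple[int, int, list[PlanStep], list[int]]:
    """Predict (rounds, dealer correlations) for one decision set and
    emit the step list.  Mirrors exactly what `execute` will do."""
    steps: list[PlanStep] = []
    partitioned: set = set(warm)
    schedule: list[int] = []
    rounds = 0
    correlations = 0
    done: dict[ExprNode, str] = {}

    def need(keys) -> int:
        nonlocal rounds
        cold = [k for k in keys if k not in partitioned]
        for k in cold:
            partitioned.add(k)
            if isinstance(k, int):
                schedule.append(k)
        return 1 if cold else 0

    def visit(node: ExprNode):
        nonlocal rounds, correlations
        if node in done or node.op == "leaf_public":
            return
        if node in chosen:
            spec, order = expand_to_polynomial(node, cap)
            rounds += need(order)
            correlations += _monomial_requests(spec)
            steps.append(PlanStep("poly", node, spec, order))
            done[node] = "poly"
            return
        for c in node.children:
            visit(c)
        if node.op == "leaf_secret":
            done[node] = "leaf"
            return
        key_of = lambda c: c.leaf_id if c.op == "leaf_secret" else c
        ops = [c for c in node.children if c.op != "leaf_public"]
        if node.op == "mul" and len(ops) < 2:
            # multiplication by a public constant: share-local, except that
            # a fixed-point constant costs one truncation round
            if node.is_fp and isinstance(
                    next(c.public_value for c in node.children
                         if c.op == "leaf_public"), float):
                rounds += fp_costs["trunc"]
        elif node.op in ("row_scale", "col_scale"):
            # the broadcast diagonal is a fresh tensor: always one opening
            for c in ops:
                partitioned.add(key_of(c))
            rounds += 1
            correlations += 1
            if node.is_fp:
                rounds += fp_costs["trunc"]
        elif node.op in ("mul", "matmul"):
            rounds += need([key_of(c) for c in ops])
            correlations += 1
            if node.is_fp:
                rounds += fp_costs["trunc"]
        elif node.op == "pow_const":
            # integer-mode pow at or under the cap: single-variable polynomial
            rounds += need([key_of(ops[0])])
            spec = PolynomialSpec([1], np.array([[node.exponent]]))
            correlations += _monomial_requests(spec)
        elif node.op in ("add", "sub"):
            if node.is_fp and any(c.op == "leaf_public" and isinstance(c.public_value, float)
                                  for c in node.children):
                pass  # public constant encoded locally; no round
        elif node.op == "div":
            rounds += fp_costs["div"]
            correlations += 1
        elif node.op in ("sqrt", "invsqrt"):
            rounds += fp_costs[node.op]
            correlations += 1
        elif node.op == "compare":
            rounds += fp_costs["compare"]
            correlations += 1
        steps.append(PlanStep("op", node))
        done[node] = "op"

    for r in roots:
        visit(r)
    return rounds, correlations, steps, schedule


def plan(roots, cache: PartitionCache, cap: int = 4,
         session: Session | None = None, exhaustive_limit: int = 10) -> ExecutionPlan:
    """Choose the cheapest execution strategy for one or more root
    expressions (lexicographic in rounds, then dealer correlations).

    Exhaustive over all consistent expansion choices when the graph has
    at most ``exhaustive_limit`` internal nodes; greedy
    (largest-expandable-polynomial first) beyond that.
    """
    if isinstance(roots, ExprNode):
        roots = [roots]
    roots = [rewrite_patterns(r, cap) for r in roots]
    fp_mode = any(_needs_fp_costs(r) for r in roots)
    fp_costs = _fp_round_costs(session) if (fp_mode and session is not None) else {
        "trunc": 1, "compare": 9, "div": 60, "sqrt": 40, "invsqrt": 40}
    warm = _warm_leaves(roots, cache)

    internal = [n for n in _topo(roots) if n.op not in _LEAF]
    candidates = [
        n for n in internal
        if _poly_eligible(n, cap) and _has_mul(n)
    ]
    best = None
    if len(internal) <= exhaustive_limit and len(candidates) <= 12:
        from itertools import combinations
        subsets = [set()]
        for k in range(1, len(candidates) + 1):
            subsets += [set(c) for c in combinations(candidates, k)]
        for S in subsets:
            r, c, steps, sched = _simulate(roots, S, cap, fp_costs, warm)
            score = (r, c, len(S))  # prefer cached-multiply chains on ties
            if best is None or score < best[0]:
                best = (score, steps, sched, r, c)
    else:
        # greedy: expand maximal eligible subtrees top-down
        S: set = set()
        covered: set = set()

        def mark(n):
            covered.add(n)
            for ch in n.children:
                mark(ch)

        for n in reversed(_topo(roots)):
            if n in covered or n.op in _LEAF:
                continue
            if n in candidates:
                S.add(n)
                mark(n)
        r, c, steps, sched = _simulate(roots, S, cap, fp_costs, warm)
        best = ((r, c, len(S)), steps, sched, r, c)
    _, steps, sched, r, c = best
    return ExecutionPlan(steps, r, c, sched, exact_rounds=not fp_mode, roots=roots)


def _needs_fp_costs(node: ExprNode) -> bool:
    """True when the graph contains ops whose round cost is predicted
    from probe measurements rather than partition analysis (these
    predictions are upper bounds, not exact)."""
    if node.is_fp or node.op in ("div", "sqrt", "invsqrt", "compare"):
        return True
    return any(_needs_fp_costs(c) for c in node.children)


def _warm_leaves(roots, cache: PartitionCache) -> set:
    warm = set()
    for r in roots:
        for lid in _secret_leaves_any(r):
            t = _leaf_tensors.get(lid)
            if t is not None:
                entry = cache._store.get(lid)
                if entry is not None and entry.source_key == t.key():
                    warm.add(lid)
    return warm


def _secret_leaves_any(node: ExprNode, acc=None) -> list[int]:
    if acc is None:
        acc = []
    if node.op == "leaf_secret" and node.leaf_id not in acc:
        acc.append(node.leaf_id)
    for c in node.children:
        _secret_leaves_any(c, acc)
    return acc


def _topo(roots) -> list[ExprNode]:
    order, seen = [], set()

    def visit(n):
        if n in seen:
            return
        seen.add(n)
        for c in n.children:
            visit(c)
        order.append(n)

    for r in roots:
        visit(r)
    return order


# ---------------------------------------------------------------------------
# execution

def _enc_public(c, session: Session, shape, fp: bool):
    codec = session.codec
    if fp:
        v = round(float(c) * (1 << codec.frac_bits))
    else:
        v = int(c)
    return np.full(shape or (), v % session.domain.modulus, dtype=object)


def execute(planned: ExecutionPlan, session: Session, cache: PartitionCache,
            check_rounds: bool = True):
    """Run a plan; verifies the round prediction against observed
    metrics (exactly in integer mode, as an upper bound in fixed-point
    mode where operand warmness inside compound primitives can only
    reduce rounds)."""
    r0 = session.metrics.rounds
    values: dict[ExprNode, SharedTensor] = {}
    results = [_exec_steps(planned, session, cache, values, root)
               for root in planned.roots]
    observed = session.metrics.rounds - r0
    if check_rounds:
        if planned.exact_rounds and observed != planned.predicted_rounds:
            raise RuntimeError(
                f"plan predicted {planned.predicted_rounds} rounds, observed {observed}"
            )
        if observed > planned.predicted_rounds:
            raise RuntimeError(
                f"plan predicted at most {planned.predicted_rounds} rounds, observed {observed}"
            )
    return results[0] if len(results) == 1 else results


def _exec_steps(planned, session, cache, values, root):
    step_for = {s.node: s for s in planned.steps}

    def value_of(node: ExprNode) -> SharedTensor:
        if node in values:
            return values[node]
        out = compute(node)
        values[node] = out
        return out

    def leaf_tensor(lid: int) -> SharedTensor:
        return _leaf_tensors[lid]

    def compute(node: ExprNode) -> SharedTensor:
        codec = session.codec
        q = session.domain.modulus
        step = step_for.get(node)
        if step is not None and step.kind == "poly":
            vars_ = [leaf_tensor(l) for l in step.var_ids]
            if not vars_:  # constant polynomial
                return fxp.public_shared(
                    _enc_public(step.spec.coeffs[0], session, node.shape, False),
                    session)
            return evaluate_polynomial(step.spec, vars_, session, cache,
                                       degree_cap=max(step.spec.degree, 1))
        if node.op == "leaf_secret":
            return leaf_tensor(node.leaf_id)
        if node.op == "leaf_public":
            return fxp.public_shared(_enc_public(node.public_value, session,
                                                 node.shape, node.is_fp), session)
        ch = node.children
        if node.op in ("add", "sub"):
            sides = []
            for c in ch:
                if c.op == "leaf_public":
                    sides.append(("pub", c.public_value))
                else:
                    sides.append(("sec", value_of(c)))
            if sides[0][0] == "pub":  # normalize: secret side first
                sides = [sides[1], ("pub", sides[0][1])] if node.op == "add" else sides
            a_kind, a = sides[0]
            b_kind, b = sides[1]
            if a_kind == "pub":
                a = fxp.public_shared(_enc_public(a, session, node.shape, node.is_fp), session)
                a_kind = "sec"
            if b_kind == "pub":
                cval = _enc_public(b, session, a.shape, node.is_fp)
                return add_public(a, cval) if node.op == "add" else add_public(a, (-cval) % q)
            return add_local(a, b) if node.op == "add" else sub_local(a, b)
        if node.op == "mul":
            pub = [c for c in ch if c.op == "leaf_public"]
            sec = [c for c in ch if c.op != "leaf_public"]
            if pub:
                x = value_of(sec[0])
                cval = pub[0].public_value
                if node.is_fp and isinstance(cval, float):
                    return fxp.fp_scale(x, cval, session)
                return mul_public(x, int(cval) % q)
            x, y = value_of(ch[0]), value_of(ch[1])
            if node.is_fp:
                return fxp.fp_multiply(x, y, session, cache)
            return multiply(x, y, session, cache)
        if node.op == "pow_const":
            x = value_of(ch[0])
            spec = PolynomialSpec([1], np.array([[node.exponent]]))
            return evaluate_polynomial(spec, [x], session, cache,
                                       degree_cap=node.exponent)
        if node.op == "matmul":
            return matrix_multiply(value_of(ch[0]), value_of(ch[1]), session, cache)
        if node.op in ("row_scale", "col_scale"):
            d = value_of(ch[0] if node.op == "row_scale" else ch[1])
            M = value_of(ch[1] if node.op == "row_scale" else ch[0])
            axis = 1 if node.op == "row_scale" else 0
            tiled = SharedTensor(
                [np.broadcast_to(p[:, None] if axis == 1 else p[None, :], M.shape).copy()
                 for p in d.payloads], d.domain, session)
            out = multiply(tiled, M, session, cache)
            return fxp.truncate(out, session) if node.is_fp else out
        if node.op == "div":
            return fxp.divide(value_of(ch[0]), value_of(ch[1]), session, cache)
        if node.op == "sqrt":
            return fxp.sqrt_invsqrt(value_of(ch[0]), session, cache)[0]
        if node.op == "invsqrt":
            return fxp.sqrt_invsqrt(value_of(ch[0]), session, cache)[1]
        if node.op == "compare":
            return fxp.less_than(value_of(ch[0]), value_of(ch[1]), session, cache)
        raise TypeError(f"cannot execute op {node.op!r}")

    return value_of(root)


def naive_execute(root: ExprNode, session: Session):
    """Reference execution with no rewrites, no polynomial collapsing,
    and no partition reuse: every multiplication opens fresh partitions.
    The optimizer's results must match this (and never use more rounds)."""
    values: dict[ExprNode, SharedTensor] = {}

    def compute(node: ExprNode) -> SharedTensor:
        if node in values:
            return values[node]
        cache = PartitionCache()  # fresh per op: no reuse anywhere
        codec = session.codec
        q = session.domain.modulus
        ch = node.children
        if node.op == "leaf_secret":
            out = _leaf_tensors[node.leaf_id]
        elif node.op == "leaf_public":
            out = fxp.public_shared(_enc_public(node.public_value, session,
                                                node.shape, node.is_fp), session)
        elif node.op in ("add", "sub"):
            a, b = compute(ch[0]), compute(ch[1])
            out = add_local(a, b) if node.op == "add" else sub_local(a, b)
        elif node.op == "mul":
            a, b = compute(ch[0]), compute(ch[1])
            out = (fxp.fp_multiply(a, b, session, PartitionCache())
                   if node.is_fp else multiply(a, b, session, PartitionCache()))
        elif node.op == "pow_const":
            out = compute(ch[0])
            for _ in range(node.exponent - 1):
                base = compute(ch[0])
                out = (fxp.fp_multiply(out, base, session, PartitionCache())
                       if node.is_fp else multiply(out, base, session, PartitionCache()))
        elif node.op == "matmul":
            a, b = compute(ch[0]), compute(ch[1])
            if ch[0].op == "leaf_secret" and ch[0].diag_tag:
                a = _densify_diag(a, session)
            if ch[1].op == "leaf_secret" and ch[1].diag_tag:
                b = _densify_diag(b, session)
            out = matrix_multiply(a, b, session, PartitionCache())
        elif node.op == "div":
            out = fxp.divide(compute(ch[0]), compute(ch[1]), session, PartitionCache())
        elif node.op == "sqrt":
            out = fxp.sqrt_invsqrt(compute(ch[0]), session, PartitionCache())[0]
        elif node.op == "compare":
            out = fxp.less_than(compute(ch[0]), compute(ch[1]), session, PartitionCache())
        else:
            raise TypeError(f"cannot execute op {node.op!r}")
        values[node] = out
        return out

    return compute(root)


def _densify_diag(d: SharedTensor, session: Session) -> SharedTensor:
    n = d.shape[0]
    payloads = []
    for p in d.payloads:
        m = np.zeros((n, n), dtype=object)
        for i in range(n):
            m[i, i] = p[i]
        payloads.append(m)
    return SharedTensor(payloads, d.domain, session)


def run_optimized(expr: Expr | ExprNode, session: Session,
                  cache: PartitionCache | None = None, cap: int = 4):
    """Convenience: rewrite, plan, and execute one expression."""
    node = expr.node if isinstance(expr, Expr) else expr
    cache = cache if cache is not None else PartitionCache()
    p = plan(node, cache, cap, session)
    return execute(p, session, cache), p
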