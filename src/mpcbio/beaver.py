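"""Beaver partitions, caching, secure multiplication, and one-round
generalized polynomial evaluation.

A *Beaver partition* of a shared secret ``x`` is the pair
``(e, [r])`` with ``e = x - r`` opened publicly and ``r`` a fresh
dealer mask: since ``x = e + r``, any product of partitioned secrets
expands into public residual terms plus mask monomials the dealer can
supply.  Opening ``e`` is the only communication a multiplication ever
needs, and — crucially — the partition can be *cached and reused* in
every later multiplication as long as ``x`` is unchanged, and
*propagated* for free through addition, subtraction and public scaling.

The same machinery evaluates a whole polynomial

    f(x_1..x_n) = sum_i c_i * prod_j x_j^{p_ij}

in a single online round: each variable is partitioned once (one batched
opening), each ``prod_j (e_j + r_j)^{p_ij}`` is expanded binomially, and
the dealer supplies a share of every mask monomial ``prod_j r_j^{k_j}``
that appears.  The number of dealer correlations grows with the number
of expansion terms — exponentially in the degree — which is why a
degree cap is enforced and higher-degree expressions fall back to
chained cached multiplications.

Round accounting: a multiply / inner-product / matmul / polynomial call
costs exactly one round when it must open partitions (all cold operands
are batched into a single exchange) and zero rounds when every operand's
partition is cached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product as iter_product

import numpy as np

from .domains import ModulusDomain, mod_pow, as_tensor
from .runtime import Session
from .sharing import SharedTensor, ShareError, add_local, sub_local, mul_public, add_public

__all__ = [
    "BeaverPartition",
    "BeaverTriple",
    "PartitionCache",
    "PolynomialSpec",
    "DegreeCapError",
    "partition",
    "ensure_partitions",
    "propagate_partition",
    "multiply",
    "multiply_with_triple",
    "inner_product",
    "matrix_multiply",
    "evaluate_polynomial",
]


class DegreeCapError(ValueError):
    """Polynomial degree exceeds the configured cap; fall back to
    cached-multiply chains."""


@dataclass
class BeaverPartition:
    """(public residual, shared mask) for one secret, version-stamped."""

    residual: np.ndarray                 # e = x - r, identical at all parties
    mask: SharedTensor                   # [r]
    mask_expr: dict[int, int]            # r as a linear combo of dealer masks
    source: SharedTensor
    source_key: tuple[int, int]

    @property
    def valid(self) -> bool:
        return self.source.key() == self.source_key


@dataclass
class BeaverTriple:
    """Classic pre-shared (a, b, c) with c = a*b (or a@b for matrices)."""

    a: SharedTensor
    b: SharedTensor
    c: SharedTensor
    matmul: bool = False


class PartitionCache:
    """Partition store keyed by secret handle; never serves a stale entry.

    Counters: ``hits`` (reuse), ``misses`` (partitions actually opened),
    ``invalidations`` (entries dropped because the secret mutated), and a
    memo of dealer mask-monomials keyed by the participating variables'
    (handle, version) pairs.
    """

    def __init__(self) -> None:
        self._store: dict[int, BeaverPartition] = {}
        self.hits = 0
        self.misses = 0
        self.invalidations = 0
        self._monomials: dict[tuple, list[np.ndarray]] = {}

    def lookup(self, x: SharedTensor) -> BeaverPartition | None:
        entry = self._store.get(x.handle)
        if entry is not None:
            if entry.source_key == x.key():
                self.hits += 1
                return entry
            self.invalidations += 1
            del self._store[x.handle]
        return None

    def store(self, p: BeaverPartition) -> None:
        self.misses += 1
        self._store[p.source.handle] = p

    def store_derived(self, p: BeaverPartition) -> None:
        """Cache a propagated partition without counting an opening."""
        self._store[p.source.handle] = p

    def monomial(self, key: tuple):
        return self._monomials.get(key)

    def store_monomial(self, key: tuple, payloads) -> None:
        self._monomials[key] = payloads

    def counters(self) -> dict:
        return {
            "hits": self.hits,
            "misses": self.misses,
            "invalidations": self.invalidations,
        }


def ensure_partitions(
    xs: list[SharedTensor], session: Session, cache: PartitionCache
) -> list[BeaverPartition]:
    """Partition every input, opening all cold residuals in ONE round.

    Cached partitions are returned with zero communication; all cache
    misses share a single batched exchange, so the round cost of any
    downstream operation is 1 (some operand cold) or 0 (all warm).
    """
    out: list[BeaverPartition | None] = []
    cold: list[tuple[int, SharedTensor, int, SharedTensor]] = []
    for x in xs:
        hit = cache.lookup(x)
        out.append(hit)
        if hit is None:
            mid, mask_payloads = session.dealer.issue_mask(x.shape, x.domain)
            mask = SharedTensor(mask_payloads, x.domain, session)
            cold.append((len(out) - 1, x, mid, mask))
    if cold:
        diffs = [sub_local(x, mask).payloads for (_, x, _, mask) in cold]
        opened = session.open_payloads(diffs, "masked:partition", cold[0][1].domain)
        for (slot, x, mid, mask), e in zip(cold, opened):
            p = BeaverPartition(e, mask, {mid: 1}, x, x.key())
            cache.store(p)
            out[slot] = p
    return out  # type: ignore[return-value]


def partition(x: SharedTensor, session: Session, cache: PartitionCache) -> BeaverPartition:
    """Beaver-partition one secret (cache miss costs one round)."""
    return ensure_partitions([x], session, cache)[0]


def _merge_exprs(a: dict[int, int], b: dict[int, int], sign: int = 1) -> dict[int, int]:
    out = dict(a)
    for k, v in b.items():
        out[k] = out.get(k, 0) + sign * v
        if out[k] == 0:
            del out[k]
    return out


def propagate_partition(
    op: str,
    inputs,
    result: SharedTensor,
    cache: PartitionCache,
    public=None,
) -> BeaverPartition:
    """Derive the partition of ``result`` from its operands' partitions
    with zero communication.

    Addition, subtraction and public scalar operations are invariant to
    Beaver partitioning: e.g. ``e_{x+y} = e_x + e_y`` with mask
    ``r_x + r_y``.  Raises on stale inputs.
    """
    parts = inputs if isinstance(inputs, (list, tuple)) else [inputs]
    for p in parts:
        if not p.valid:
            raise ShareError("stale partition input to propagation")
    d = result.domain
    q = d.modulus
    if op == "add":
        px, py = parts
        out = BeaverPartition(
            (px.residual + py.residual) % q,
            add_local(px.mask, py.mask),
            _merge_exprs(px.mask_expr, py.mask_expr),
            result, result.key(),
        )
    elif op == "sub":
        px, py = parts
        out = BeaverPartition(
            (px.residual - py.residual) % q,
            sub_local(px.mask, py.mask),
            _merge_exprs(px.mask_expr, py.mask_expr, sign=-1),
            result, result.key(),
        )
    elif op == "mul_public":
        (px,) = parts
        c = int(public) % q
        out = BeaverPartition(
            (px.residual * c) % q,
            mul_public(px.mask, c),
            {k: (v * c) % q for k, v in px.mask_expr.items()},
            result, result.key(),
        )
    elif op == "add_public":
        (px,) = parts
        c = as_tensor(public, d)
        out = BeaverPartition(
            (px.residual + c) % q, px.mask, dict(px.mask_expr), result, result.key()
        )
    else:
        raise ValueError(f"cannot propagate partitions through {op!r}")
    cache.store_derived(out)
    return out


def _combine_product(px: BeaverPartition, py: BeaverPartition,
                     rxy_payloads, session: Session, domain: ModulusDomain,
                     matmul: bool = False) -> SharedTensor:
    """Local combination x*y = e_x e_y + e_x r_y + e_y r_x + r_x r_y."""
    q = domain.modulus
    if matmul:
        pub = (px.residual @ py.residual) % q
        payloads = [
            ((px.residual @ ry) + (rx @ py.residual) + rxy) % q
            for rx, ry, rxy in zip(px.mask.payloads, py.mask.payloads, rxy_payloads)
        ]
    else:
        pub = (px.residual * py.residual) % q
        payloads = [
            (px.residual * ry + rx * py.residual + rxy) % q
            for rx, ry, rxy in zip(px.mask.payloads, py.mask.payloads, rxy_payloads)
        ]
    payloads[0] = (payloads[0] + pub) % q
    return SharedTensor(payloads, domain, session)


def multiply(x: SharedTensor, y: SharedTensor, session: Session,
             cache: PartitionCache) -> SharedTensor:
    """Elementwise secure product via (cached) Beaver partitions.

    One round when a partition must be opened (both operands batched),
    zero when both are warm; plus one dealer correlation for
    ``[r_x * r_y]``.
    """
    if x.shape != y.shape:
        raise ShareError("shape mismatch in multiply")
    px, py = ensure_partitions([x, y], session, cache)
    rxy = session.dealer.issue_mask_product([(px.mask_expr, 1), (py.mask_expr, 1)])
    return _combine_product(px, py, rxy, session, x.domain)


def inner_product(x: SharedTensor, y: SharedTensor, session: Session,
                  cache: PartitionCache) -> SharedTensor:
    """Share of sum_i x_i y_i; round count independent of vector length."""
    if x.shape != y.shape or len(x.shape) != 1:
        raise ShareError("inner_product expects equal-length vectors")
    px, py = ensure_partitions([x, y], session, cache)
    rxy = session.dealer.issue_mask_product(
        [(px.mask_expr, 1), (py.mask_expr, 1)], sum_result=True
    )
    q = x.domain.modulus
    pub = int(np.sum(px.residual * py.residual)) % q
    payloads = []
    for rx, ry, rs in zip(px.mask.payloads, py.mask.payloads, rxy):
        v = (int(np.sum(px.residual * ry)) + int(np.sum(rx * py.residual)) + int(rs)) % q
        payloads.append(np.array(v, dtype=object))
    payloads[0] = np.array((int(payloads[0]) + pub) % q, dtype=object)
    return SharedTensor(payloads, x.domain, session)


def matrix_multiply(A: SharedTensor, B: SharedTensor, session: Session,
                    cache: PartitionCache) -> SharedTensor:
    """Share of A @ B via a matrix Beaver partition pair; rounds <= 1."""
    if len(A.shape) != 2 or len(B.shape) != 2 or A.shape[1] != B.shape[0]:
        raise ShareError("inner dimensions disagree in matrix_multiply")
    pA, pB = ensure_partitions([A, B], session, cache)
    rAB = session.dealer.issue_mask_matmul(pA.mask_expr, pB.mask_expr)
    return _combine_product(pA, pB, rAB, session, A.domain, matmul=True)


def multiply_with_triple(x: SharedTensor, y: SharedTensor, triple: BeaverTriple,
                         session: Session) -> SharedTensor:
    """Classic one-shot Beaver multiplication with a pre-shared triple
    (no caching; one opening round for the pair (x-a, y-b))."""
    q = x.domain.modulus
    dx_p = sub_local(x, triple.a).payloads
    dy_p = sub_local(y, triple.b).payloads
    dx, dy = session.open_payloads([dx_p, dy_p], "masked:triple_open", x.domain)
    if triple.matmul:
        pub = (dx @ dy) % q
        payloads = [
            ((dx @ b) + (a @ dy) + c) % q
            for a, b, c in zip(triple.a.payloads, triple.b.payloads, triple.c.payloads)
        ]
    else:
        pub = (dx * dy) % q
        payloads = [
            (dx * b + a * dy + c) % q
            for a, b, c in zip(triple.a.payloads, triple.b.payloads, triple.c.payloads)
        ]
    payloads[0] = (payloads[0] + pub) % q
    return SharedTensor(payloads, x.domain, session)


@dataclass
class PolynomialSpec:
    """The generalized polynomial form sum_i c_i prod_j x_j^{p_ij}.

    ``coeffs`` are public integers (signed; embedded mod q at evaluation
    time) and ``exponents`` is the m-by-n matrix of non-negative integer
    powers.  Fixed-point coefficients are intentionally not supported
    here: monomials of different total degree carry different fixed-point
    scales, so real-coefficient polynomials are handled upstream by the
    optimizer as truncated multiplication chains.
    """

    coeffs: list[int]
    exponents: np.ndarray

    def __post_init__(self) -> None:
        self.exponents = np.asarray(self.exponents, dtype=int)
        if self.exponents.ndim != 2 or len(self.coeffs) != self.exponents.shape[0]:
            raise ValueError("coeffs/exponents shape mismatch")
        if (self.exponents < 0).any():
            raise ValueError("exponents must be non-negative")

    @property
    def n_vars(self) -> int:
        return self.exponents.shape[1]

    @property
    def degree(self) -> int:
        return int(self.exponents.sum(axis=1).max(initial=0))

    def evaluate_plain(self, xs, modulus: int | None = None):
        """Reference evaluation over Python ints (or mod q)."""
        total = 0
        for c, row in zip(self.coeffs, self.exponents):
            term = c
            for xj, p in zip(xs, row):
                term *= xj ** int(p)
            total += term
        return total % modulus if modulus is not None else total


def evaluate_polynomial(
    spec: PolynomialSpec,
    vars: list[SharedTensor],
    session: Session,
    cache: PartitionCache,
    degree_cap: int = 4,
) -> SharedTensor:
    """Evaluate ``spec`` on shared variables in at most one online round.

    Every variable is partitioned at most once (cold partitions share a
    single batched opening); each residual-mask binomial expansion term
    ``prod_j C(p_ij, k_j) e_j^{p_ij - k_j} * prod_j r_j^{k_j}`` is
    combined locally with a dealer-issued share of the mask monomial.
    Mask monomials are memoized per (variable-version, exponent) key so
    repeated evaluations reuse dealer correlations.

    Raises :class:`DegreeCapError` when ``spec.degree > degree_cap``.
    """
    if len(vars) != spec.n_vars:
        raise ShareError("variable count does not match the polynomial spec")
    if spec.degree > degree_cap:
        raise DegreeCapError(
            f"degree {spec.degree} exceeds cap {degree_cap}"
        )
    domain = vars[0].domain
    q = domain.modulus
    shape = vars[0].shape
    for v in vars:
        if v.shape != shape or v.domain != domain:
            raise ShareError("polynomial variables must share shape and domain")
    parts = ensure_partitions(list(vars), session, cache)

    n = session.n_parties
    acc = [np.zeros(shape, dtype=object) for _ in range(n)]
    pub_acc = np.zeros(shape, dtype=object)

    for c, row in zip(spec.coeffs, spec.exponents):
        c = int(c) % q
        # binomial expansion of prod_j (e_j + r_j)^{p_j}
        ranges = [range(int(p) + 1) for p in row]
        for ks in iter_product(*ranges):
            coef = c
            e_pub = np.ones(shape, dtype=object)
            for p_j, k_j, part in zip(row, ks, parts):
                p_j = int(p_j)
                if p_j == 0:
                    continue
                coef = coef * math.comb(p_j, k_j)
                if p_j - k_j > 0:
                    e_pub = (e_pub * mod_pow(part.residual, p_j - k_j, domain)) % q
            coef = coef % q
            term_pub = (e_pub * coef) % q
            if all(k == 0 for k in ks):
                pub_acc = (pub_acc + term_pub) % q
                continue
            involved = tuple(
                (v.handle, v.version, k) for v, k in zip(vars, ks) if k > 0
            )
            mono = cache.monomial(involved)
            if mono is None:
                mono = session.dealer.issue_mask_product(
                    [(part.mask_expr, k) for part, k in zip(parts, ks) if k > 0]
                )
                cache.store_monomial(involved, mono)
            for i in range(n):
                acc[i] = (acc[i] + term_pub * mono[i]) % q
    acc[0] = (acc[0] + pub_acc) % q
    return SharedTensor(acc, domain, session)
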