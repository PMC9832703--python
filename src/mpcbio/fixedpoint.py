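"""Secure fixed-point arithmetic: truncation, comparison, division,
square root, and field-to-ring conversion.

Everything here reduces to three dealer-assisted primitives:

* **Probabilistic truncation** — to rescale after a fixed-point product,
  open the value under a large uniform mask, shift the public opening,
  and subtract the dealer-shared shifted mask ``[r >> f]``.  The result
  is within one unit in the last place of the exact shift; exact
  truncation would cost extra rounds for no benefit at these precisions.

* **Sign extraction (LTZ)** — the comparison workhorse.  The input is
  offset into a positive window, opened under a mask whose low bits the
  dealer shares *bitwise*, and the sign bit is recovered exactly from
  the public opening, the shared high mask bits, and a borrow bit
  computed by a bitwise public-vs-shared comparison circuit (suffix
  products of per-bit equality indicators, evaluated as a balanced tree
  of batched secure multiplications).  The round count is fixed by the
  configured comparison width — identical for every input, which is
  what makes comparison-based pipelines transcript-oblivious — and
  grows only logarithmically with that width.

* **Goldschmidt-style iteration** — division and square root are
  multiplicative iterations seeded from a normalized operand.  The
  square-root iteration produces the inverse square root as a by-product
  for free, so ``a / sqrt(b)`` is computed as ``a * invsqrt(b)`` rather
  than a square root followed by a full division.

No protocol in this module uses a modular inverse, so every operation is
available in the power-of-two ring as well as in the prime field.
"""

from __future__ import annotations

import math

import numpy as np

from .domains import DomainError, DomainKind, FixedPointCodec, ModulusDomain
from .runtime import Session
from .sharing import (
    SharedTensor,
    ShareError,
    add_local,
    add_public,
    mul_public,
    neg_local,
    sub_local,
    sum_axis,
)
from .beaver import PartitionCache, multiply

__all__ = [
    "truncate",
    "fp_multiply",
    "fp_scale",
    "fp_from_int",
    "less_than",
    "less_than_zero",
    "mux",
    "argmax",
    "sqrt_invsqrt",
    "divide",
    "div_by_sqrt",
    "convert_domain",
    "zeros_like_shared",
    "public_shared",
]


# ---------------------------------------------------------------------------
# small helpers

def zeros_like_shared(shape, session: Session, domain: ModulusDomain | None = None) -> SharedTensor:
    domain = domain or session.domain
    n = session.n_parties
    return SharedTensor([np.zeros(shape, dtype=object) for _ in range(n)], domain, session)


def public_shared(value, session: Session, domain: ModulusDomain | None = None) -> SharedTensor:
    """A trivial sharing of a public tensor (party 1 holds it)."""
    domain = domain or session.domain
    z = zeros_like_shared(np.asarray(value, dtype=object).shape, session, domain)
    return add_public(z, value)


def _stack(tensors: list[SharedTensor]) -> SharedTensor:
    """Stack shared tensors along a new leading axis (local)."""
    sess, domain = tensors[0].session, tensors[0].domain
    n = tensors[0].n_parties
    payloads = [
        np.stack([t.payloads[i] for t in tensors], axis=0) for i in range(n)
    ]
    return SharedTensor(payloads, domain, sess)


def _shift_up(x: SharedTensor, step: int, identity: int = 1) -> SharedTensor:
    """shifted[j] = x[j+step], padded at the end with a public constant."""
    L = x.shape[0]
    n = x.n_parties
    payloads = []
    for i in range(n):
        p = x.payloads[i]
        pad_shape = (min(step, L),) + x.shape[1:]
        pad = np.full(pad_shape, identity if i == 0 else 0, dtype=object)
        payloads.append(np.concatenate([p[step:], pad], axis=0) if step < L else pad)
    return SharedTensor(payloads, x.domain, x.session)


def _codec(session: Session, codec: FixedPointCodec | None) -> FixedPointCodec:
    return codec or session.codec


# ---------------------------------------------------------------------------
# truncation and fixed-point products

def truncate(x: SharedTensor, session: Session, f: int | None = None,
             codec: FixedPointCodec | None = None) -> SharedTensor:
    """Share of approximately ``x / 2^f`` (signed), within +-1 ulp.

    Uses a dealer pair ``([r], [r >> f])`` with r uniform on
    ``[0, 2^(R+s))``: the signed value is offset into ``(0, 2^R)``,
    ``x + offset + r`` is opened (statistically masked, no modular
    wrap), shifted publicly, and the shifted mask share is subtracted.
    One communication round.
    """
    codec = _codec(session, codec)
    f = codec.frac_bits if f is None else f
    R = codec.range_bits
    s = codec.slack_bits
    domain = x.domain
    offset = 1 << (R - 1)
    r_sh, r_hi_sh = session.dealer.issue_trunc_pair(x.shape, domain, R + s, f)
    r = SharedTensor(r_sh, domain, session)
    r_hi = SharedTensor(r_hi_sh, domain, session)
    masked = add_public(add_local(x, r), offset)
    [c] = session.open_payloads([masked.payloads], "masked:truncate", domain)
    c_hi = np.empty(c.shape, dtype=object)
    fc, fh = c.reshape(-1), c_hi.reshape(-1)
    for i in range(fc.size):
        fh[i] = int(fc[i]) >> f
    out = add_public(neg_local(r_hi), c_hi)
    return add_public(out, -(offset >> f) % domain.modulus)


def fp_multiply(x: SharedTensor, y: SharedTensor, session: Session,
                cache: PartitionCache, codec: FixedPointCodec | None = None) -> SharedTensor:
    """Fixed-point product: integer product of encodings, then truncate."""
    codec = _codec(session, codec)
    return truncate(multiply(x, y, session, cache), session, codec.frac_bits, codec)


def fp_scale(x: SharedTensor, c: float, session: Session,
             codec: FixedPointCodec | None = None) -> SharedTensor:
    """Multiply by a public real constant (scale shares, then truncate)."""
    codec = _codec(session, codec)
    cc = round(float(c) * (1 << codec.frac_bits))
    return truncate(mul_public(x, cc % x.domain.modulus), session, codec.frac_bits, codec)


def fp_from_int(x: SharedTensor, codec: FixedPointCodec | None = None,
                session: Session | None = None) -> SharedTensor:
    """Reinterpret an integer-valued share as fixed point (scale by 2^f)."""
    codec = _codec(session or x.session, codec)
    return mul_public(x, 1 << codec.frac_bits)


# ---------------------------------------------------------------------------
# comparison

def less_than_zero(d: SharedTensor, session: Session, cache: PartitionCache,
                   codec: FixedPointCodec | None = None) -> SharedTensor:
    """Share of the exact sign bit: 1 if the signed value of d is < 0.

    Requires |signed value| < 2^compare_bits (encoded units).  The round
    count is a fixed function of ``compare_bits`` only; transcripts are
    identical for every input of the same shape.
    """
    codec = _codec(session, codec)
    M = codec.compare_bits
    s = codec.slack_bits
    domain = d.domain
    q = domain.modulus
    if (1 << (M + s + 2)) >= q:
        raise DomainError("compare_bits + slack exceed the domain width")
    shape = d.shape
    n_bits = M + s + 1

    # y = d + 2^M in (0, 2^(M+1)); mask r < 2^(M+s+1) shared bitwise
    _, bit_sh = session.dealer.issue_bits((n_bits,) + shape, domain)
    bits = SharedTensor(bit_sh, domain, session)
    weights = np.array([1 << i for i in range(n_bits)], dtype=object).reshape(
        (n_bits,) + (1,) * len(shape)
    )
    r = sum_axis(mul_public(bits, weights), axis=0)
    hi_w = np.array(
        [0] * M + [1 << (i - M) for i in range(M, n_bits)], dtype=object
    ).reshape((n_bits,) + (1,) * len(shape))
    r_hi = sum_axis(mul_public(bits, hi_w), axis=0)

    y = add_public(d, 1 << M)
    [c] = session.open_payloads([add_local(y, r).payloads], "masked:compare", domain)

    flat_c = [int(v) for v in np.asarray(c, dtype=object).reshape(-1)]
    c_hi = np.array([v >> M for v in flat_c], dtype=object).reshape(shape)
    c_bits = np.array(
        [[(v >> j) & 1 for v in flat_c] for j in range(M)], dtype=object
    ).reshape((M,) + shape)

    low_bits = bits.slice(slice(0, M))
    # eq_j = 1 iff bit_j(r) == bit_j(c); gt_j = 1 iff r_j > c_j. Affine in r_j.
    one_minus = add_public(neg_local(low_bits), np.ones((M,) + shape, dtype=object))
    eq_payloads = []
    gt_payloads = []
    for i in range(low_bits.n_parties):
        eq_payloads.append(
            np.where(c_bits == 1, low_bits.payloads[i], one_minus.payloads[i]) % q
        )
        gt_payloads.append(np.where(c_bits == 1, 0, low_bits.payloads[i]) % q)
    eq = SharedTensor(eq_payloads, domain, session)
    gt = SharedTensor(gt_payloads, domain, session)

    # suffix products P[j] = prod_{t >= j} eq[t], balanced doubling tree
    P = eq
    step = 1
    while step < M:
        P = multiply(P, _shift_up(P, step), session, cache)
        step *= 2
    borrow_terms = multiply(gt, _shift_up(P, 1), session, cache)
    u = sum_axis(borrow_terms, axis=0)  # 1 iff c_low < r_low

    # floor(y / 2^M) = c_hi - r_hi - u, in {0,1}; LTZ = 1 - that bit
    bit = sub_local(public_shared(c_hi, session, domain), add_local(r_hi, u))
    return add_public(neg_local(bit), np.ones(shape, dtype=object))


def less_than(x: SharedTensor, y: SharedTensor, session: Session,
              cache: PartitionCache, codec: FixedPointCodec | None = None) -> SharedTensor:
    """Share of [x < y] (signed encoded values)."""
    return less_than_zero(sub_local(x, y), session, cache, codec)


def mux(bit: SharedTensor, x: SharedTensor, y: SharedTensor, session: Session,
        cache: PartitionCache) -> SharedTensor:
    """Oblivious select: bit ? x : y (bit is an unscaled 0/1 share)."""
    return add_local(y, multiply(bit, sub_local(x, y), session, cache))


def argmax(scores: list[SharedTensor], session: Session, cache: PartitionCache,
           codec: FixedPointCodec | None = None) -> list[SharedTensor]:
    """One-hot sharing of the argmax of a list of shared scalars/vectors.

    Sequential pairwise tournament of secure comparisons; ties break
    toward the lower index.
    """
    best = scores[0]
    onehot = [public_shared(np.ones(best.shape, dtype=object), session, best.domain)]
    onehot += [zeros_like_shared(best.shape, session, best.domain) for _ in scores[1:]]
    for i in range(1, len(scores)):
        b = less_than(best, scores[i], session, cache, codec)
        best = mux(b, scores[i], best, session, cache)
        keep = add_public(neg_local(b), np.ones(b.shape, dtype=object))
        for j in range(i):
            onehot[j] = multiply(onehot[j], keep, session, cache)
        onehot[i] = b
    return onehot


# ---------------------------------------------------------------------------
# normalization, square root, division

def _normalize(b: SharedTensor, session: Session, cache: PartitionCache,
               codec: FixedPointCodec, lo: int, hi: int,
               range_hint: float | None, secure_normalize: bool):
    """Return (sigma, sqrt_sigma, b_hat) with b_hat = b * sigma in [1/2, 1).

    sigma = 2^-(e+1) for b in [2^e, 2^(e+1)).  With a public
    ``range_hint`` the exponent is public and sigma is a constant;
    otherwise a single batched comparison against all powers of two in
    [2^lo, 2^hi] yields a shared one-hot over exponents, and sigma /
    sqrt(sigma) are public-weighted sums of the one-hot bits.
    """
    f = codec.frac_bits
    if range_hint is not None:
        e = math.floor(math.log2(range_hint))
        sigma_c = 2.0 ** (-e - 1)
        return None, None, fp_scale(b, sigma_c, session, codec), sigma_c
    if not secure_normalize:
        raise DomainError(
            "no public range hint given and secure normalization is disabled"
        )
    exps = list(range(lo, hi + 1))
    # z_i = [b < 2^i], batched into ONE comparison on a stacked tensor
    diffs = _stack([add_public(b, -(round(2.0 ** i * (1 << f))) % b.domain.modulus)
                    for i in exps])
    z = less_than_zero(diffs, session, cache, codec)
    zs = [z.slice(i) for i in range(len(exps))]
    onehot = []  # w_i = [2^i <= b < 2^(i+1)] for i in lo-1..hi-1 plus edges
    prev = zeros_like_shared(b.shape, session, b.domain)
    segments = []  # (exponent e, weight share)
    for i, e in enumerate(exps):
        w = sub_local(zs[i], prev)
        segments.append((e - 1, w))
        prev = zs[i]
    top = add_public(neg_local(prev), np.ones(b.shape, dtype=object))
    segments.append((hi, top))  # b >= 2^hi clamps to the top octave
    q = b.domain.modulus
    sig_w = np.array([round(2.0 ** (-e - 1) * (1 << f)) % q for e, _ in segments],
                     dtype=object)
    sqs_w = np.array([round(2.0 ** (-(e + 1) / 2.0) * (1 << f)) % q for e, _ in segments],
                     dtype=object)
    ws = _stack([w for _, w in segments])
    shape_pad = (len(segments),) + (1,) * len(b.shape)
    sigma = sum_axis(mul_public(ws, sig_w.reshape(shape_pad)), axis=0)
    sqrt_sigma = sum_axis(mul_public(ws, sqs_w.reshape(shape_pad)), axis=0)
    b_hat = fp_multiply(b, sigma, session, cache, codec)
    return sigma, sqrt_sigma, b_hat, None


def sqrt_invsqrt(b: SharedTensor, session: Session, cache: PartitionCache,
                 codec: FixedPointCodec | None = None, n_iter: int = 10,
                 range_hint: float | None = None, secure_normalize: bool = True,
                 lo: int = -16, hi: int = 16) -> tuple[SharedTensor, SharedTensor]:
    """Shares of (sqrt(b), 1/sqrt(b)) for b > 0.

    Newton-Goldschmidt iteration ``y <- y (3 - b_hat y^2) / 2`` on the
    normalized operand; the inverse square root falls out as the
    by-product and the square root itself is one extra multiplication
    ``sqrt(b) = b * invsqrt(b)``.
    """
    codec = _codec(session, codec)
    sigma, sqrt_sigma, b_hat, sigma_c = _normalize(
        b, session, cache, codec, lo, hi, range_hint, secure_normalize
    )
    three = np.full(b.shape, 3 << codec.frac_bits, dtype=object)
    # y0 = 3 - 2 b_hat: crude affine seed on [1/2, 1), fixed by the iteration
    y = add_public(mul_public(b_hat, -2 % b.domain.modulus), three)
    for _ in range(n_iter):
        y2 = fp_multiply(y, y, session, cache, codec)
        t = fp_multiply(b_hat, y2, session, cache, codec)
        y = fp_multiply(y, fp_scale(add_public(neg_local(t), three), 0.5, session, codec),
                        session, cache, codec)
    # 1/sqrt(b) = 1/sqrt(b_hat / sigma) = sqrt(sigma) * y
    if range_hint is not None:
        inv_sqrt = fp_scale(y, math.sqrt(sigma_c), session, codec)
    else:
        inv_sqrt = fp_multiply(y, sqrt_sigma, session, cache, codec)
    root = fp_multiply(b, inv_sqrt, session, cache, codec)
    return root, inv_sqrt


def divide(a: SharedTensor, b: SharedTensor, session: Session, cache: PartitionCache,
           codec: FixedPointCodec | None = None, n_iter: int = 10,
           range_hint: float | None = None, secure_normalize: bool = True,
           lo: int = -16, hi: int = 16) -> SharedTensor:
    """Share of a / b via an iterative reciprocal (no modular inverse).

    The divisor's sign is extracted obliviously, the reciprocal of |b|
    is computed by the quadratic iteration ``w <- w (2 - b_hat w)``, and
    the sign is re-applied, so negative divisors are supported.
    """
    codec = _codec(session, codec)
    q = b.domain.modulus
    sb = less_than_zero(b, session, cache, codec)
    sign = add_public(mul_public(sb, -2 % q), np.ones(b.shape, dtype=object))  # +-1
    b_abs = multiply(b, sign, session, cache)  # unscaled +-1: no truncation
    sigma, _, b_hat, sigma_c = _normalize(
        b_abs, session, cache, codec, lo, hi, range_hint, secure_normalize
    )
    two = np.full(b.shape, 2 << codec.frac_bits, dtype=object)
    # w0 = 48/17 - 32/17 b_hat: minimax affine seed for 1/x on [1/2, 1)
    w = add_public(
        truncate(mul_public(b_hat, (-round(32 / 17 * (1 << codec.frac_bits))) % q),
                 session, codec.frac_bits, codec),
        np.full(b.shape, round(48 / 17 * (1 << codec.frac_bits)), dtype=object),
    )
    for _ in range(n_iter):
        t = fp_multiply(b_hat, w, session, cache, codec)
        w = fp_multiply(w, add_public(neg_local(t), two), session, cache, codec)
    if range_hint is not None:
        recip = fp_scale(w, sigma_c, session, codec)
    else:
        recip = fp_multiply(w, sigma, session, cache, codec)
    out = fp_multiply(a, recip, session, cache, codec)
    return multiply(out, sign, session, cache)


def div_by_sqrt(a: SharedTensor, b: SharedTensor, session: Session,
                cache: PartitionCache, codec: FixedPointCodec | None = None,
                **kwargs) -> SharedTensor:
    """Share of a / sqrt(b) as ``a * invsqrt(b)`` — one multiplication
    instead of a square root followed by a full division, so strictly
    fewer rounds than ``divide(a, sqrt(b))``."""
    codec = _codec(session, codec)
    _, inv_sqrt = sqrt_invsqrt(b, session, cache, codec, **kwargs)
    return fp_multiply(a, inv_sqrt, session, cache, codec)


# ---------------------------------------------------------------------------
# domain conversion

def convert_domain(x: SharedTensor, src: ModulusDomain, dst: ModulusDomain,
                   session: Session, value_bits: int = 80,
                   slack_bits: int = 40) -> SharedTensor:
    """Re-share a secret from one modular domain into another.

    The signed value must satisfy |v| < 2^value_bits; the dealer issues
    one mask shared in both domains, the source shares are opened under
    the mask plus a positivity offset (no modular wrap thanks to the
    slack headroom), and the public opening is re-shared in the target
    domain by subtracting the target-domain mask.  One round.
    """
    need = value_bits + slack_bits + 3
    if (1 << need) >= src.modulus or (1 << need) >= dst.modulus:
        raise DomainError(
            f"value_bits={value_bits} leaves no masking headroom in a "
            f"{min(src.bit_width, dst.bit_width)}-bit domain"
        )
    if x.domain != src:
        raise ShareError("input share is not in the declared source domain")
    offset = 1 << (value_bits + 1)
    r_src, r_dst = session.dealer.issue_cross_pair(
        x.shape, src, dst, value_bits + slack_bits + 2
    )
    masked = add_public(add_local(x, SharedTensor(r_src, src, session)), offset)
    [c] = session.open_payloads([masked.payloads], "masked:convert", src)
    out = add_public(neg_local(SharedTensor(r_dst, dst, session)), c % dst.modulus)
    return add_public(out, (-offset) % dst.modulus)
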