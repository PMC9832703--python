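"""Modular arithmetic domains and fixed-point encoding.

Secret-shared values live in a finite algebraic structure: either a prime
field ``Z_q`` (q prime) or the ring ``Z_{2^k}``.  Rings map directly onto
machine integers and are cheap, but lack modular inverses for even
elements, so protocols that need inversion are restricted to fields.
A Mersenne modulus ``q = 2^k - 1`` additionally admits a division-free
"fold and add" reduction, exposed here as :func:`mersenne_reduce`.

Real numbers enter the modular world through a fixed-point encoding:
``x`` is represented as ``round(x * 2^f) mod q`` with negatives embedded
in the upper half of the domain (two's-complement style), so that the
sign of a value is the "most significant bit" of its representative.

Tensors of elements are ``numpy`` arrays with ``dtype=object`` holding
Python integers: moduli here are 127-128 bits wide and do not fit any
fixed-width dtype.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DomainKind",
    "Reduction",
    "ModulusDomain",
    "FixedPointCodec",
    "DomainError",
    "mod_add",
    "mod_sub",
    "mod_mul",
    "mod_pow",
    "mod_inverse",
    "mersenne_reduce",
    "encode_fixed",
    "decode_fixed",
    "DEFAULT_FIELD",
    "DEFAULT_RING",
    "default_codec",
]


class DomainError(ValueError):
    """An operation was requested that the modular domain does not support."""


class DomainKind(enum.Enum):
    PRIME_FIELD = "prime_field"
    POWER_OF_TWO_RING = "power_of_two_ring"


class Reduction(enum.Enum):
    GENERIC = "generic"
    MERSENNE = "mersenne"


def _is_probable_prime(n: int) -> bool:
    """Deterministic Miller-Rabin for n < 3.3e24, strong probable test above."""
    if n < 2:
        return False
    small = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37)
    for p in small:
        if n % p == 0:
            return n == p
    d, r = n - 1, 0
    while d % 2 == 0:
        d //= 2
        r += 1
    for a in small:
        x = pow(a, d, n)
        if x in (1, n - 1):
            continue
        for _ in range(r - 1):
            x = x * x % n
            if x == n - 1:
                break
        else:
            return False
    return True


@dataclass(frozen=True)
class ModulusDomain:
    """A finite algebraic structure ``Z_q``, field or power-of-two ring.

    Parameters
    ----------
    kind
        ``PRIME_FIELD`` requires ``modulus`` prime; ``POWER_OF_TWO_RING``
        requires ``modulus == 2**bit_width`` exactly.
    modulus
        The positive integer q.  All elements lie in ``[0, q)``.
    bit_width
        k, the number of bits needed to represent any element.
    reduction
        ``MERSENNE`` selects the fold-and-add reduction and is only
        permitted when ``q == 2**bit_width - 1``.
    """

    kind: DomainKind
    modulus: int
    bit_width: int
    reduction: Reduction = Reduction.GENERIC

    def __post_init__(self) -> None:
        q = self.modulus
        if q <= 1:
            raise DomainError("modulus must exceed 1")
        if self.kind is DomainKind.POWER_OF_TWO_RING:
            if q != 1 << self.bit_width:
                raise DomainError("ring modulus must equal 2**bit_width")
        elif self.kind is DomainKind.PRIME_FIELD:
            if q.bit_length() > self.bit_width:
                raise DomainError("bit_width too small for modulus")
            if not _is_probable_prime(q):
                raise DomainError(f"field modulus {q} is not prime")
        if self.reduction is Reduction.MERSENNE and q != (1 << self.bit_width) - 1:
            raise DomainError("mersenne reduction requires q = 2**k - 1")

    # -- scalar helpers -------------------------------------------------

    @property
    def element_bytes(self) -> int:
        """Serialized width of one element: ceil(k / 8) bytes."""
        return (self.bit_width + 7) // 8

    def reduce(self, x):
        """Map integer(s) into [0, q), dispatching to the Mersenne fold."""
        if self.reduction is Reduction.MERSENNE:
            return mersenne_reduce(x, self)
        if isinstance(x, np.ndarray):
            return x % self.modulus
        return int(x) % self.modulus

    def rand_element(self, getrandbits) -> int:
        """One uniform element, via rejection sampling from ``getrandbits``."""
        while True:
            x = getrandbits(self.bit_width)
            if x < self.modulus:
                return x

    def rand_tensor(self, getrandbits, shape) -> np.ndarray:
        out = np.empty(shape, dtype=object)
        flat = out.reshape(-1)
        for i in range(flat.size):
            flat[i] = self.rand_element(getrandbits)
        return out


def as_tensor(x, domain: ModulusDomain | None = None) -> np.ndarray:
    """Coerce scalars / nested lists to an object-dtype tensor of ints."""
    arr = np.array(x, dtype=object)
    flat = arr.reshape(-1)
    for i in range(flat.size):
        flat[i] = int(flat[i])
    if domain is not None:
        arr = np.asarray(arr % domain.modulus, dtype=object)  # 0-d ops may drop to scalar
    return arr


def mod_add(a, b, d: ModulusDomain):
    return d.reduce(np.add(a, b) if isinstance(a, np.ndarray) or isinstance(b, np.ndarray) else a + b)


def mod_sub(a, b, d: ModulusDomain):
    return d.reduce(np.subtract(a, b) if isinstance(a, np.ndarray) or isinstance(b, np.ndarray) else a - b)


def mod_mul(a, b, d: ModulusDomain):
    return d.reduce(np.multiply(a, b) if isinstance(a, np.ndarray) or isinstance(b, np.ndarray) else a * b)


def mod_pow(a, e: int, d: ModulusDomain):
    if isinstance(a, np.ndarray):
        out = np.empty(a.shape, dtype=object)
        fo, fa = out.reshape(-1), a.reshape(-1)
        for i in range(fa.size):
            fo[i] = pow(int(fa[i]), e, d.modulus)
        return out
    return pow(int(a), e, d.modulus)


def mod_inverse(a: int, d: ModulusDomain) -> int:
    """Multiplicative inverse of ``a`` modulo q.

    Fields invert every non-zero element.  In ``Z_{2^k}`` only odd
    elements are units; even elements raise :class:`DomainError`,
    mirroring the fact that inverse-based protocols are unavailable in
    ring-based sharing.
    """
    a = int(a) % d.modulus
    if a == 0:
        raise DomainError("0 has no modular inverse")
    if d.kind is DomainKind.POWER_OF_TWO_RING and a % 2 == 0:
        raise DomainError("even elements are not invertible in Z_{2^k}")
    return pow(a, -1, d.modulus)


def _mersenne_reduce_int(x: int, q: int, k: int) -> int:
    while x >> k:
        x = (x >> k) + (x & q)
    return x - q if x >= q else x


def mersenne_reduce(x, d: ModulusDomain):
    """Reduce ``x`` (< q^2) modulo a Mersenne modulus q = 2^k - 1.

    Uses the identity ``2^k = 1 (mod q)``: the high bits fold onto the
    low bits by shift and mask, with no general division.
    """
    if d.reduction is not Reduction.MERSENNE:
        raise DomainError("domain is not configured for Mersenne reduction")
    q, k = d.modulus, d.bit_width
    if isinstance(x, np.ndarray):
        out = np.empty(x.shape, dtype=object)
        fo, fx = out.reshape(-1), x.reshape(-1)
        for i in range(fx.size):
            v = int(fx[i])
            fo[i] = _mersenne_reduce_int(v if v >= 0 else v % q, q, k)
        return out
    x = int(x)
    return _mersenne_reduce_int(x if x >= 0 else x % q, q, k)


@dataclass(frozen=True)
class FixedPointCodec:
    """Fixed-point embedding of reals into a modular domain.

    ``f`` fractional bits give resolution ``2^-f``; ``s`` slack bits
    reserve statistical-masking headroom so that one un-truncated product
    (scale ``2^{2f}``) still fits: ``2^(2f+s) < q`` is enforced.

    ``compare_bits`` bounds the magnitude (in encoded units) of values
    fed to the comparison protocol; it is a protocol parameter, not part
    of the encoding itself, but lives here because it must be consistent
    across all parties.
    """

    frac_bits: int
    domain: ModulusDomain
    slack_bits: int = 40
    compare_bits: int = 64

    def __post_init__(self) -> None:
        if self.frac_bits < 1 or self.slack_bits < 1:
            raise DomainError("frac_bits and slack_bits must be >= 1")
        if 1 << (2 * self.frac_bits + self.slack_bits) >= self.domain.modulus:
            raise DomainError("2^(2f+s) must be smaller than the modulus")

    @property
    def range_bits(self) -> int:
        """Encoded magnitudes must stay below 2^range_bits."""
        return self.domain.bit_width - self.slack_bits - 2

    @property
    def max_abs(self) -> float:
        """Largest representable |real| (leaves product headroom)."""
        return float(2 ** (self.range_bits - self.frac_bits - 1))

    def encode(self, x):
        return encode_fixed(x, self)

    def decode(self, e):
        return decode_fixed(e, self)


def encode_fixed(x, c: FixedPointCodec):
    """``round(x * 2^f)`` mapped into [0, q); negatives as ``q - |.|``."""
    q = c.domain.modulus
    scale = 1 << c.frac_bits
    bound = 1 << (c.range_bits - 1)

    def enc(v: float) -> int:
        r = round(float(v) * scale)
        if abs(r) >= bound:
            raise DomainError(f"value {v} overflows the fixed-point range")
        return r % q

    if isinstance(x, np.ndarray) or isinstance(x, (list, tuple)):
        arr = np.array(x, dtype=object)
        out = np.empty(arr.shape, dtype=object)
        fo, fa = out.reshape(-1), arr.reshape(-1)
        for i in range(fa.size):
            fo[i] = enc(fa[i])
        return out
    return enc(x)


def decode_fixed(e, c: FixedPointCodec):
    """Inverse of :func:`encode_fixed`; elements above q/2 decode negative."""
    q = c.domain.modulus
    half = q // 2
    scale = float(1 << c.frac_bits)

    def dec(v: int) -> float:
        v = int(v) % q
        if v > half:
            v -= q
        return v / scale

    if isinstance(e, np.ndarray):
        out = np.empty(e.shape, dtype=float)
        fo, fe = out.reshape(-1), e.reshape(-1)
        for i in range(fe.size):
            fo[i] = dec(fe[i])
        return out
    return dec(e)


#: Default prime field: the Mersenne prime 2^127 - 1 (fold-and-add reduction).
DEFAULT_FIELD = ModulusDomain(
    DomainKind.PRIME_FIELD, (1 << 127) - 1, 127, Reduction.MERSENNE
)

#: Default ring: Z_{2^128}.
DEFAULT_RING = ModulusDomain(DomainKind.POWER_OF_TWO_RING, 1 << 128, 128)


def default_codec(domain: ModulusDomain | None = None) -> FixedPointCodec:
    """A codec sized to the domain: 32 fractional / 40 slack bits on
    wide (>=100-bit) domains, scaled down proportionally on narrow ones
    so that one un-truncated product still fits."""
    domain = domain or DEFAULT_FIELD
    if domain.bit_width >= 100:
        return FixedPointCodec(32, domain, 40, 64)
    f = max(8, (domain.bit_width - 24) // 3)
    s = max(8, domain.bit_width - 2 * f - 8)
    m = max(16, domain.bit_width - s - 4)
    return FixedPointCodec(f, domain, s, m)
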