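"""Party session, message accounting, and the trusted dealer.

The toolkit follows the server-aided ("trusted dealer") model of
honest-but-curious MPC: ``n >= 2`` computing parties hold additive shares
of the data, and an auxiliary party 0 — the dealer — supplies correlated
randomness (multiplication triples, Beaver masks, truncation pairs,
shared random bits, cross-domain mask pairs) but never touches any
share- or secret-dependent message.

Execution model
---------------
A :class:`Session` is a centralized, single-process simulator: it holds
every party's state and routes explicit ``exchange`` calls between them.
Because all communication goes through one choke point, the simulator
counts communication rounds and per-link bytes *exactly*, keeps a
transcript digest per link, records the dealer's inbox for passivity
audits, and is bit-for-bit deterministic under a fixed seed.  A real
socket deployment is out of scope for this implementation
(``transport="sockets"`` raises), but every protocol is written against
the same narrow exchange interface a distributed transport would offer.

Round accounting follows the usual MPC convention: one round is one
synchronized exchange in which at least one message crosses a link
between two *computing* parties, regardless of how many tensors are
batched into it.  Dealer traffic is counted in bytes but never in
rounds.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field

import numpy as np

from .domains import (
    DomainKind,
    DomainError,
    ModulusDomain,
    FixedPointCodec,
    DEFAULT_FIELD,
    default_codec,
    mod_pow,
)

__all__ = [
    "PartyConfig",
    "ChannelMetrics",
    "RandomnessStream",
    "Session",
    "Dealer",
    "SessionError",
    "start_session",
    "serialize_tensor",
    "deserialize_tensor",
]

DEALER_ID = 0


class SessionError(RuntimeError):
    pass


@dataclass(frozen=True)
class PartyConfig:
    """One actor's identity: 0 is the trusted dealer, 1..n computing parties."""

    party_id: int
    endpoint: str = "in_process"
    n_parties: int = 2


def serialize_tensor(arr: np.ndarray, domain: ModulusDomain) -> bytes:
    """Fixed-width big-endian element encoding, width = ceil(k/8) bytes.

    Fixed-width serialization keeps byte counters reproducible across
    machines and makes transcript sizes independent of element values —
    a property the oblivious-access tests rely on.
    """
    w = domain.element_bytes
    flat = np.asarray(arr, dtype=object).reshape(-1)
    return b"".join(int(v).to_bytes(w, "big") for v in flat)


def deserialize_tensor(data: bytes, shape, domain: ModulusDomain) -> np.ndarray:
    w = domain.element_bytes
    n = len(data) // w
    out = np.empty(n, dtype=object)
    for i in range(n):
        out[i] = int.from_bytes(data[i * w : (i + 1) * w], "big")
    return out.reshape(shape)


class ChannelMetrics:
    """Monotone counters: rounds, per-link bytes and message counts."""

    def __init__(self) -> None:
        self.rounds: int = 0
        self.bytes_sent: dict[tuple[int, int], int] = {}
        self.messages: dict[tuple[int, int], int] = {}

    def record(self, src: int, dst: int, nbytes: int) -> None:
        link = (src, dst)
        self.bytes_sent[link] = self.bytes_sent.get(link, 0) + nbytes
        self.messages[link] = self.messages.get(link, 0) + 1

    @property
    def total_bytes(self) -> int:
        return sum(self.bytes_sent.values())

    def party_link_bytes(self) -> int:
        """Bytes crossing computing-party links only (dealer excluded)."""
        return sum(
            v for (s, d), v in self.bytes_sent.items() if s != DEALER_ID and d != DEALER_ID
        )

    def snapshot(self) -> tuple[int, int, int]:
        return (self.rounds, self.total_bytes, sum(self.messages.values()))

    def as_dict(self) -> dict:
        return {
            "rounds": self.rounds,
            "total_bytes": self.total_bytes,
            "party_link_bytes": self.party_link_bytes(),
            "messages": sum(self.messages.values()),
        }


class RandomnessStream:
    """A pairwise common PRG: both holders of (seed, counter) draw the
    same element sequence, so a dealer can 'send' pseudorandom shares for
    free."""

    def __init__(self, seed: bytes, owner_pair: tuple[int, int]) -> None:
        if len(seed) != 16:
            raise SessionError("stream seed must be 16 bytes")
        self.seed = seed
        self.owner_pair = owner_pair
        self.counter = 0
        self._rng = random.Random(int.from_bytes(seed, "big"))

    def getrandbits(self, k: int) -> int:
        self.counter += 1
        return self._rng.getrandbits(k)

    def rand_tensor(self, shape, domain: ModulusDomain) -> np.ndarray:
        return domain.rand_tensor(self.getrandbits, shape)

    def rand_int_below(self, bound: int):
        """Uniform integer in [0, bound), by rejection."""
        bits = (bound - 1).bit_length() if bound > 1 else 1
        while True:
            x = self.getrandbits(bits)
            if x < bound:
                return x


def _derive_seed(master: int, *tags) -> bytes:
    h = hashlib.blake2b(digest_size=16)
    h.update(str(master).encode())
    for t in tags:
        h.update(b"/" + str(t).encode())
    return h.digest()


class Dealer:
    """Correlated-randomness service (party 0).

    The dealer samples uniform values, registers Beaver masks so that
    later *monomial* requests can be answered consistently, and hands
    each computing party an additive share.  Wherever a share can be
    pseudorandom it is drawn from the pairwise :class:`RandomnessStream`
    (zero traffic); only the correlated share — the one that must equal
    ``value - sum(pseudorandom shares)`` — is transmitted, to the last
    party.

    ``inbox`` records every request the dealer receives.  Requests name
    a correlation kind and a shape, never a share or secret value; the
    privacy audit inspects this log.
    """

    def __init__(self, session: "Session") -> None:
        self.session = session
        self.inbox: list[dict] = []
        self.mask_registry: dict[int, np.ndarray] = {}
        self._mask_domain: dict[int, ModulusDomain] = {}
        self._next_mask_id = 0
        self.correlations_issued = 0

    # -- internals ------------------------------------------------------

    def _log(self, kind: str, **info) -> None:
        self.inbox.append({"kind": kind, **info})
        self.correlations_issued += 1

    def _pseudorandom_shares(self, shape, domain: ModulusDomain, parties) -> list[np.ndarray]:
        return [
            self.session.dealer_stream(p).rand_tensor(shape, domain) for p in parties
        ]

    def _share_known_value(self, value: np.ndarray, domain: ModulusDomain) -> list[np.ndarray]:
        """Additively share ``value``; only the last share costs traffic."""
        value = np.asarray(value, dtype=object)  # 0-d ops may drop to scalar
        n = self.session.n_parties
        shares = self._pseudorandom_shares(value.shape, domain, range(1, n))
        acc = np.zeros(value.shape, dtype=object)
        for s in shares:
            acc = acc + s
        last = (value - acc) % domain.modulus
        self.session._dealer_send(n, last, domain)
        shares.append(last)
        return shares

    def _fresh_shared_uniform(self, shape, domain: ModulusDomain):
        """Uniform value shared with *all* shares pseudorandom (free)."""
        n = self.session.n_parties
        shares = self._pseudorandom_shares(shape, domain, range(1, n + 1))
        value = np.zeros(shape, dtype=object)
        for s in shares:
            value = (value + s) % domain.modulus
        return value, shares

    # -- correlation requests ------------------------------------------

    def issue_mask(self, shape, domain: ModulusDomain) -> tuple[int, list[np.ndarray]]:
        """A fresh uniform Beaver mask [r]; registered for later monomials."""
        self._log("mask", shape=tuple(shape))
        value, shares = self._fresh_shared_uniform(shape, domain)
        mid = self._next_mask_id
        self._next_mask_id += 1
        self.mask_registry[mid] = value
        self._mask_domain[mid] = domain
        return mid, shares

    def _linear_mask_value(self, expr: dict[int, int]):
        """Evaluate a public linear combination of registered masks.

        Derived Beaver partitions (of sums, differences, public scalings)
        carry masks of the form ``sum_j c_j * r_j``; the dealer can compute
        any product of such combinations because it knows every r_j.
        """
        mid0 = next(iter(expr))
        domain = self._mask_domain[mid0]
        val = None
        for mid in sorted(expr):
            coeff = expr[mid] % domain.modulus
            term = (self.mask_registry[mid] * coeff) % domain.modulus
            val = term if val is None else (val + term) % domain.modulus
        return val, domain

    def issue_mask_product(self, terms, sum_result: bool = False) -> list[np.ndarray]:
        """Shares of ``prod_t (linear_t)^{p_t}`` elementwise over registered
        masks; with ``sum_result`` the elementwise product is summed to a
        scalar (the inner-product correlation)."""
        self._log(
            "mask_product",
            terms=[(tuple(sorted(e.items())), p) for e, p in terms],
            summed=sum_result,
        )
        value, domain = None, None
        for expr, power in terms:
            v, domain = self._linear_mask_value(expr)
            if power != 1:
                v = mod_pow(v, power, domain)
            value = v if value is None else (value * v) % domain.modulus
        if sum_result:
            value = np.array(int(np.sum(value)) % domain.modulus, dtype=object)
        return self._share_known_value(np.asarray(value, dtype=object), domain)

    def issue_monomial(self, powers: dict[int, int]) -> list[np.ndarray]:
        """Shares of ``prod_j r_j^{k_j}`` over registered masks (the
        correlations consumed by generalized Beaver polynomial evaluation)."""
        return self.issue_mask_product([({mid: 1}, p) for mid, p in powers.items()])

    def issue_mask_matmul(self, expr_a: dict[int, int], expr_b: dict[int, int]) -> list[np.ndarray]:
        """Shares of the matrix product ``R_A @ R_B`` of two (possibly
        derived) masks."""
        self._log(
            "mask_matmul",
            a=tuple(sorted(expr_a.items())),
            b=tuple(sorted(expr_b.items())),
        )
        va, domain = self._linear_mask_value(expr_a)
        vb, _ = self._linear_mask_value(expr_b)
        return self._share_known_value((va @ vb) % domain.modulus, domain)

    def issue_triple(self, shape, domain: ModulusDomain, matmul_shapes=None):
        """A classic Beaver triple ([a], [b], [c]) with c = a*b (elementwise)
        or c = a @ b when ``matmul_shapes=(shape_a, shape_b)`` is given."""
        if matmul_shapes is not None:
            sa, sb = matmul_shapes
            self._log("triple", shape=(tuple(sa), tuple(sb)), matmul=True)
            a, a_sh = self._fresh_shared_uniform(sa, domain)
            b, b_sh = self._fresh_shared_uniform(sb, domain)
            c = (a @ b) % domain.modulus
        else:
            self._log("triple", shape=tuple(shape), matmul=False)
            a, a_sh = self._fresh_shared_uniform(shape, domain)
            b, b_sh = self._fresh_shared_uniform(shape, domain)
            c = (a * b) % domain.modulus
        return a_sh, b_sh, self._share_known_value(c, domain)

    def issue_trunc_pair(self, shape, domain: ModulusDomain, mask_bits: int, f: int):
        """([r], [r >> f]) with r uniform in [0, 2^mask_bits)."""
        self._log("trunc_pair", shape=tuple(shape), mask_bits=mask_bits, f=f)
        r = np.empty(shape, dtype=object)
        stream = self.session.dealer_stream(0)  # dealer-private sampling
        flat = r.reshape(-1)
        for i in range(flat.size):
            flat[i] = stream.getrandbits(mask_bits)
        hi = np.empty(shape, dtype=object)
        fh, fr = hi.reshape(-1), r.reshape(-1)
        for i in range(fr.size):
            fh[i] = int(fr[i]) >> f
        return self._share_known_value(r % domain.modulus, domain), self._share_known_value(
            hi, domain
        )

    def issue_bits(self, shape, domain: ModulusDomain):
        """Shares of uniform bits (one bit per tensor element)."""
        self._log("bits", shape=tuple(shape))
        stream = self.session.dealer_stream(0)
        bits = np.empty(shape, dtype=object)
        flat = bits.reshape(-1)
        for i in range(flat.size):
            flat[i] = stream.getrandbits(1)
        return bits, self._share_known_value(bits, domain)

    def issue_cross_pair(self, shape, src: ModulusDomain, dst: ModulusDomain, mask_bits: int):
        """A mask r < 2^mask_bits shared in both domains (for conversion)."""
        self._log("cross_pair", shape=tuple(shape), mask_bits=mask_bits)
        stream = self.session.dealer_stream(0)
        r = np.empty(shape, dtype=object)
        flat = r.reshape(-1)
        for i in range(flat.size):
            flat[i] = stream.getrandbits(mask_bits)
        return (
            self._share_known_value(r % src.modulus, src),
            self._share_known_value(r % dst.modulus, dst),
            )


class Session:
    """A live MPC session: n computing parties + the trusted dealer,
    centrally simulated.

    Parameters
    ----------
    n_parties
        Number of computing parties (>= 2), dealer excluded.
    domain, codec
        Default modular domain and fixed-point codec for the session.
    seed
        Master seed; all pairwise randomness streams, input-sharing
        randomness and dealer sampling derive from it, so a fixed seed
        reproduces transcripts byte for byte.
    """

    def __init__(
        self,
        n_parties: int = 2,
        domain: ModulusDomain | None = None,
        codec: FixedPointCodec | None = None,
        seed: int = 0,
    ) -> None:
        if n_parties < 2:
            raise SessionError("at least two computing parties are required")
        self.n_parties = n_parties
        self.domain = domain or DEFAULT_FIELD
        try:
            self.codec = codec or default_codec(self.domain)
            if self.codec.domain is not self.domain:
                self.codec = FixedPointCodec(
                    self.codec.frac_bits, self.domain, self.codec.slack_bits,
                    self.codec.compare_bits,
                )
        except DomainError:
            # tiny domains (used for statistical share tests) carry no codec
            self.codec = None
        self.seed = seed
        self.metrics = ChannelMetrics()
        self._streams: dict[tuple[int, int], RandomnessStream] = {}
        self.input_rng = random.Random(int.from_bytes(_derive_seed(seed, "input"), "big"))
        self.dealer = Dealer(self)
        self._transcript = hashlib.blake2b(digest_size=16)
        self.open_log: list[dict] = []
        self.reveal_log: list[dict] = []
        self._next_handle = 0

    # -- plumbing -------------------------------------------------------

    def next_handle(self) -> int:
        self._next_handle += 1
        return self._next_handle

    def stream(self, a: int, b: int) -> RandomnessStream:
        pair = (min(a, b), max(a, b))
        if pair not in self._streams:
            self._streams[pair] = RandomnessStream(
                _derive_seed(self.seed, "pair", *pair), pair
            )
        return self._streams[pair]

    def dealer_stream(self, party: int) -> RandomnessStream:
        return self.stream(DEALER_ID, party)

    def _record_message(self, src: int, dst: int, payload: bytes) -> None:
        self.metrics.record(src, dst, len(payload))
        self._transcript.update(
            src.to_bytes(2, "big") + dst.to_bytes(2, "big") + len(payload).to_bytes(8, "big")
        )
        self._transcript.update(payload)

    def _dealer_send(self, dst: int, tensor: np.ndarray, domain: ModulusDomain) -> None:
        self._record_message(DEALER_ID, dst, serialize_tensor(tensor, domain))

    def transcript_digest(self) -> str:
        return self._transcript.hexdigest()

    # -- communication primitives --------------------------------------

    def exchange(self, payloads: dict[tuple[int, int], np.ndarray],
                 domain: ModulusDomain | None = None) -> dict[tuple[int, int], np.ndarray]:
        """Deliver per-(src, dst) tensors in one synchronized round.

        Exactly one round is counted per call in which any message
        crosses a computing-party link; an empty call costs nothing.
        """
        domain = domain or self.domain
        party_traffic = False
        for (src, dst), tensor in payloads.items():
            if src == dst:
                raise SessionError("a party cannot message itself")
            self._record_message(src, dst, serialize_tensor(tensor, domain))
            if src != DEALER_ID and dst != DEALER_ID:
                party_traffic = True
        if party_traffic:
            self.metrics.rounds += 1
        return dict(payloads)

    def open_payloads(
        self,
        payload_sets: list[list[np.ndarray]],
        label: str,
        domain: ModulusDomain | None = None,
    ) -> list[np.ndarray]:
        """All-to-all opening of one or more share sets, batched into a
        single round.  ``label`` must be namespaced ``"masked:..."`` for
        protocol-internal openings of uniformly masked values, or
        ``"output:..."`` for the documented outputs of a computation; the
        leakage audit distinguishes the two.
        """
        domain = domain or self.domain
        if not payload_sets:
            return []
        if not (label.startswith("masked:") or label.startswith("output:")):
            raise SessionError("open label must be namespaced masked:/output:")
        n = self.n_parties
        payloads = {}
        for i in range(1, n + 1):
            blob = np.concatenate(
                [np.asarray(ps[i - 1], dtype=object).reshape(-1) for ps in payload_sets]
            )
            for j in range(1, n + 1):
                if i != j:
                    payloads[(i, j)] = blob
        self.exchange(payloads, domain)
        results = []
        for ps in payload_sets:
            acc = np.zeros(np.asarray(ps[0]).shape, dtype=object)
            for s in ps:
                acc = np.asarray((acc + np.asarray(s, dtype=object)) % domain.modulus,
                                 dtype=object)
            results.append(acc)
        entry = {"label": label, "shapes": [tuple(np.asarray(r).shape) for r in results]}
        self.open_log.append(entry)
        if label.startswith("output:"):
            self.reveal_log.append(entry)
        return results


def start_session(
    configs: list[PartyConfig] | int,
    transport: str = "in_process",
    domain: ModulusDomain | None = None,
    codec: FixedPointCodec | None = None,
    seed: int = 0,
) -> Session:
    """Create a session from party configs (or a bare party count).

    Only the ``in_process`` transport is implemented; it simulates all
    actors inside one process with exact accounting.
    """
    if transport != "in_process":
        raise SessionError(
            f"transport {transport!r} is not available; use 'in_process'"
        )
    if isinstance(configs, int):
        n = configs
    else:
        ids = sorted(c.party_id for c in configs)
        computing = [i for i in ids if i != DEALER_ID]
        n = len(computing)
        if len(set(ids)) != len(ids) or computing != list(range(1, n + 1)):
            raise SessionError("party ids must be distinct and contiguous")
    if n < 2:
        raise SessionError("at least two computing parties are required")
    return Session(n_parties=n, domain=domain, codec=codec, seed=seed)
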