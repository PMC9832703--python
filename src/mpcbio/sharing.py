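"""Additive secret sharing and the communication-free algebra of shares.

A secret tensor ``x`` over ``Z_q`` is split into ``n`` uniformly random
payloads that sum to ``x`` elementwise mod q; any strict subset of the
payloads is uniform and carries no information.  Addition, subtraction,
and multiplication/addition by public constants act share-wise and cost
no communication; reconstruction (:func:`reveal`) costs exactly one
round.

:class:`SharedTensor` is the toolkit's working container: it tracks all
parties' payloads (the runtime is a centralized simulator), a stable
handle identifying the logical secret, and a version counter that is
bumped on every in-place mutation — the Beaver partition cache keys on
(handle, version) so a mutated secret can never be multiplied through a
stale partition.  :class:`AdditiveShare` is the single-party view used
for import/export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domains import ModulusDomain, as_tensor
from .runtime import Session

__all__ = [
    "AdditiveShare",
    "SharedTensor",
    "ShareError",
    "share_secret",
    "share_reals",
    "reveal",
    "reveal_reals",
    "add_local",
    "sub_local",
    "neg_local",
    "mul_public",
    "add_public",
    "matmul_public",
    "sum_axis",
    "export_shares_tsv",
    "import_shares_tsv",
]


class ShareError(ValueError):
    pass


@dataclass
class AdditiveShare:
    """One computing party's additive fragment of a secret tensor."""

    payload: np.ndarray
    party_id: int
    domain: ModulusDomain
    version: int = 0


class SharedTensor:
    """A logical secret: the full set of additive shares plus metadata."""

    def __init__(self, payloads: list[np.ndarray], domain: ModulusDomain,
                 session: Session, handle: int | None = None) -> None:
        shapes = {np.asarray(p).shape for p in payloads}
        if len(shapes) != 1:
            raise ShareError("share payloads disagree on shape")
        self.payloads = [np.asarray(p, dtype=object) for p in payloads]
        self.domain = domain
        self.session = session
        self.handle = handle if handle is not None else session.next_handle()
        self.version = 0

    @property
    def shape(self) -> tuple:
        return self.payloads[0].shape

    @property
    def n_parties(self) -> int:
        return len(self.payloads)

    def shares(self) -> list[AdditiveShare]:
        return [
            AdditiveShare(p, i + 1, self.domain, self.version)
            for i, p in enumerate(self.payloads)
        ]

    def key(self) -> tuple[int, int]:
        """Cache key: (handle, version)."""
        return (self.handle, self.version)

    # -- mutation (invalidates cached partitions via the version bump) --

    def assign(self, other: "SharedTensor") -> None:
        """In-place overwrite with another secret's shares."""
        self._check(other)
        self.payloads = [p.copy() for p in other.payloads]
        self.version += 1

    def iadd(self, other: "SharedTensor") -> None:
        """In-place ``self += other`` (local, but a mutation)."""
        self._check(other)
        q = self.domain.modulus
        self.payloads = [np.asarray((a + b) % q, dtype=object)
                         for a, b in zip(self.payloads, other.payloads)]
        self.version += 1

    def _check(self, other: "SharedTensor") -> None:
        if other.domain is not self.domain and other.domain != self.domain:
            raise ShareError("domain mismatch")
        if other.shape != self.shape:
            raise ShareError("shape mismatch")

    # -- local linear algebra ------------------------------------------

    def __add__(self, other):
        return add_local(self, other)

    def __sub__(self, other):
        return sub_local(self, other)

    def __neg__(self):
        return neg_local(self)

    def reshape(self, *shape) -> "SharedTensor":
        return SharedTensor([p.reshape(*shape) for p in self.payloads],
                            self.domain, self.session)

    def slice(self, idx) -> "SharedTensor":
        """A local view-copy of a sub-tensor (fresh handle)."""
        return SharedTensor([np.asarray(p[idx], dtype=object).reshape(
            np.asarray(self.payloads[0][idx]).shape) for p in self.payloads],
            self.domain, self.session)


def share_secret(x, session: Session, domain: ModulusDomain | None = None) -> SharedTensor:
    """Split a plaintext tensor into n additive shares.

    The first ``n-1`` payloads are uniform draws from the data
    provider's local randomness; the last is ``x - sum(others) mod q``.
    Sharing itself crosses no computing-party link (the provider hands
    each party its share out of band), so metrics are untouched.
    """
    domain = domain or session.domain
    x = as_tensor(x, domain)
    n = session.n_parties
    payloads = [domain.rand_tensor(session.input_rng.getrandbits, x.shape)
                for _ in range(n - 1)]
    acc = np.zeros(x.shape, dtype=object)
    for p in payloads:
        acc = acc + p
    payloads.append((x - acc) % domain.modulus)
    return SharedTensor(payloads, domain, session)


def share_reals(x, session: Session, codec=None) -> SharedTensor:
    """Fixed-point encode a real tensor, then share it."""
    codec = codec or session.codec
    return share_secret(codec.encode(np.asarray(x, dtype=float)), session, codec.domain)


def reveal(x, session: Session, label: str = "output:value") -> np.ndarray:
    """Reconstruct a secret; costs exactly one communication round.

    Accepts a :class:`SharedTensor` or a complete list of
    :class:`AdditiveShare` (whose versions must agree).
    """
    if isinstance(x, SharedTensor):
        payloads, domain = x.payloads, x.domain
    else:
        versions = {s.version for s in x}
        if len(versions) != 1:
            raise ShareError("stale share: versions do not match")
        payloads = [s.payload for s in sorted(x, key=lambda s: s.party_id)]
        domain = x[0].domain
    [out] = session.open_payloads([payloads], label, domain)
    return out


def reveal_reals(x: SharedTensor, session: Session, codec=None,
                 label: str = "output:value"):
    codec = codec or session.codec
    return codec.decode(reveal(x, session, label))


def add_local(a: SharedTensor, b: SharedTensor) -> SharedTensor:
    a._check(b)
    q = a.domain.modulus
    return SharedTensor([(x + y) % q for x, y in zip(a.payloads, b.payloads)],
                        a.domain, a.session)


def sub_local(a: SharedTensor, b: SharedTensor) -> SharedTensor:
    a._check(b)
    q = a.domain.modulus
    return SharedTensor([(x - y) % q for x, y in zip(a.payloads, b.payloads)],
                        a.domain, a.session)


def neg_local(a: SharedTensor) -> SharedTensor:
    q = a.domain.modulus
    return SharedTensor([(-x) % q for x in a.payloads], a.domain, a.session)


def mul_public(a: SharedTensor, c) -> SharedTensor:
    """Scale every party's share by a public constant (or tensor)."""
    q = a.domain.modulus
    c = as_tensor(c, a.domain)
    return SharedTensor([(p * c) % q for p in a.payloads], a.domain, a.session)


def add_public(a: SharedTensor, c) -> SharedTensor:
    """Add a public constant: applied by party 1 only (fixed protocol-wide)."""
    q = a.domain.modulus
    c = as_tensor(c, a.domain)
    payloads = [p.copy() for p in a.payloads]
    payloads[0] = (payloads[0] + c) % q
    return SharedTensor(payloads, a.domain, a.session)


def matmul_public(P, a: SharedTensor, right: bool = False) -> SharedTensor:
    """Public matrix times shared tensor (or shared @ public if right=True)."""
    q = a.domain.modulus
    P = as_tensor(P, a.domain)
    if right:
        return SharedTensor([(p @ P) % q for p in a.payloads], a.domain, a.session)
    return SharedTensor([(P @ p) % q for p in a.payloads], a.domain, a.session)


def sum_axis(a: SharedTensor, axis=None) -> SharedTensor:
    q = a.domain.modulus
    return SharedTensor(
        [np.asarray(p.sum(axis=axis), dtype=object).reshape(
            np.asarray(a.payloads[0].sum(axis=axis)).shape) % q
         for p in a.payloads],
        a.domain, a.session)


def export_shares_tsv(x: SharedTensor, path) -> None:
    """Debug/interchange dump: one row per (party_id, flat index, value)."""
    rows = []
    for i, p in enumerate(x.payloads):
        flat = p.reshape(-1)
        for j in range(flat.size):
            rows.append((i + 1, j, str(int(flat[j]))))
    pd.DataFrame(rows, columns=["party_id", "index", "value"]).to_csv(
        path, sep="\t", index=False
    )


def import_shares_tsv(path, shape, session: Session,
                      domain: ModulusDomain | None = None) -> SharedTensor:
    domain = domain or session.domain
    df = pd.read_csv(path, sep="\t", dtype={"value": str})
    payloads = []
    for pid in sorted(df["party_id"].unique()):
        sub = df[df["party_id"] == pid].sort_values("index")
        arr = np.array([int(v) for v in sub["value"]], dtype=object).reshape(shape)
        payloads.append(arr % domain.modulus)
    return SharedTensor(payloads, domain, session)
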