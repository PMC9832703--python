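"""Plain-text configuration (INI-style ``key = value`` with sections).

A config file fully determines a session: algebraic domain, fixed-point
codec, party count and seed.  Every key is optional; defaults reproduce
the standard 127-bit Mersenne-field setup with two computing parties.

Example::

    [domain]
    kind = prime_field        ; or power_of_two_ring
    bits = 127
    reduction = mersenne      ; or generic

    [fixed_point]
    frac_bits = 32
    slack_bits = 40
    compare_bits = 64

    [session]
    n_parties = 2
    seed = 0
"""

from __future__ import annotations

import configparser

from .domains import (
    DomainKind,
    FixedPointCodec,
    ModulusDomain,
    Reduction,
    DEFAULT_FIELD,
    default_codec,
)
from .runtime import Session

__all__ = ["ConfigError", "load_config", "session_from_config", "domain_for"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key."""


_DOMAIN_KEYS = {"kind", "bits", "modulus", "reduction"}
_FP_KEYS = {"frac_bits", "slack_bits", "compare_bits"}
_SESSION_KEYS = {"n_parties", "seed", "transport"}


def domain_for(kind: str, bits: int) -> ModulusDomain:
    """The toolkit's standard domain for a (kind, bit-width) request:
    Mersenne-prime fields (2^k - 1 prime) and power-of-two rings."""
    if kind in ("field", "prime_field"):
        mersenne = {61: 61, 64: 61, 89: 89, 107: 107, 127: 127, 128: 127}
        k = mersenne.get(bits)
        if k is None:
            raise ConfigError(f"domain.bits: no standard prime field for {bits} bits")
        return ModulusDomain(DomainKind.PRIME_FIELD, (1 << k) - 1, k, Reduction.MERSENNE)
    if kind in ("ring", "power_of_two_ring"):
        return ModulusDomain(DomainKind.POWER_OF_TWO_RING, 1 << bits, bits)
    raise ConfigError(f"domain.kind: unknown kind {kind!r}")


def load_config(path) -> dict:
    """Parse and validate a config file into a nested dict."""
    parser = configparser.ConfigParser(inline_comment_prefixes=(";", "#"))
    read = parser.read(path)
    if not read:
        raise ConfigError(f"config file not found: {path}")
    out: dict = {"domain": {}, "fixed_point": {}, "session": {}}
    for section in parser.sections():
        if section not in out:
            raise ConfigError(f"unknown config section [{section}]")
        allowed = {"domain": _DOMAIN_KEYS, "fixed_point": _FP_KEYS,
                   "session": _SESSION_KEYS}[section]
        for key, value in parser.items(section):
            if key not in allowed:
                raise ConfigError(f"unknown config key {section}.{key}")
            out[section][key] = value
    return out


def session_from_config(cfg: dict | None = None, seed: int | None = None) -> Session:
    """Build a live session from a parsed config (all keys optional)."""
    cfg = cfg or {}
    dom_cfg = cfg.get("domain", {})
    kind = dom_cfg.get("kind", "prime_field")
    try:
        bits = int(dom_cfg.get("bits", 127))
    except ValueError:
        raise ConfigError("domain.bits must be an integer") from None
    if "modulus" in dom_cfg:
        modulus = int(dom_cfg["modulus"])
        red = Reduction(dom_cfg.get("reduction", "generic"))
        dk = DomainKind(kind if kind in ("prime_field", "power_of_two_ring")
                        else "prime_field")
        domain = ModulusDomain(dk, modulus, bits, red)
    else:
        domain = domain_for(kind, bits)

    fp_cfg = cfg.get("fixed_point", {})
    if fp_cfg:
        base = default_codec(domain)
        try:
            codec = FixedPointCodec(
                int(fp_cfg.get("frac_bits", base.frac_bits)), domain,
                int(fp_cfg.get("slack_bits", base.slack_bits)),
                int(fp_cfg.get("compare_bits", base.compare_bits)),
            )
        except ValueError as e:
            raise ConfigError(f"fixed_point: {e}") from None
    else:
        codec = default_codec(domain)

    sess_cfg = cfg.get("session", {})
    n_parties = int(sess_cfg.get("n_parties", 2))
    if seed is None:
        seed = int(sess_cfg.get("seed", 0))
    if n_parties < 2:
        raise ConfigError("session.n_parties must be at least 2")
    return Session(n_parties=n_parties, domain=domain, codec=codec, seed=seed)
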