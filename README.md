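# mpcbio

Secure multiparty computation (MPC) for biomedical data analysis.

Genomic data cannot be de-identified — a leaked genome is compromised
forever, along with information about the donor's relatives — so
collaborating labs often cannot pool the raw data that their studies
need. Additive secret sharing sidesteps the problem: each data provider
splits every value `x` into random shares `x_1 + ... + x_n = x (mod q)`,
one per computing party, so that any strict subset of shares is
uniformly random. The parties then run joint protocols on the shares and
reveal only the agreed study outputs. `mpcbio` is a toolkit for building
and measuring such protocols, aimed at method developers who want exact
communication accounting and auditable leakage rather than a production
deployment.

## What is inside

* **Protocol core** — additive sharing over a prime field (default: the
  Mersenne prime `2^127 - 1`, with division-free fold-and-add reduction)
  or the ring `Z_{2^128}`, with a *trusted dealer* supplying correlated
  randomness under an honest-but-curious model.
* **Beaver-partition engine** — a multiplication of shared secrets
  costs one opening of the "partitions" `e = x - r`; partitions are
  cached and reused for as long as the variable is unchanged, propagate
  for free through linear operations, and whole polynomials

  `f(x_1..x_n) = Σ_i c_i Π_j x_j^{p_ij}`

  evaluate in a **single online round** by partitioning each variable
  once and letting the dealer supply shares of the mask monomials
  `Π_j r_j^{k_j}`.
* **Fixed-point protocols** — probabilistic truncation, exact oblivious
  comparison, Goldschmidt-style division and square root (the inverse
  square root falls out as a free by-product, so `a/√b` is a single
  extra multiplication), and field↔ring share conversion.
* **Expression optimizer** — arithmetic on secure handles builds a lazy
  hash-consed DAG; rewrite passes fuse `a/√b`, vectorize
  diagonal-matrix products, and collapse arithmetic subtrees into
  one-round polynomials under a degree cap, minimizing (rounds, dealer
  correlations).
* **Three demonstration pipelines**, each with a plaintext twin it is
  checked against: a mini genome-wide association study (quality
  control + regression scan), a hinge-loss SGD read-binning classifier,
  and oblivious interleaved-Bloom-filter read classification whose
  transcripts are independent of what is queried.
* **Synthetic data generators** for all of the above — no downloads,
  fully seed-deterministic.

The runtime simulates all parties and the dealer in one process with
exact per-link round/byte metrics, transcript digests, a dealer inbox,
and a reveal log, so every communication claim in the docs is asserted
by a test. See `docs/methods.md` for the protocol details and design
rationale.

## Worked example

```python
from mpcbio import Session, PartitionCache
from mpcbio.sharing import share_secret, reveal
from mpcbio.beaver import multiply, evaluate_polynomial, PolynomialSpec

s = Session(n_parties=2, seed=42)      # + trusted dealer, simulated
cache = PartitionCache()
x, y, z = (share_secret(v, s) for v in (6, 7, 3))

xy = multiply(x, y, s, cache)
print("x*y =", reveal(xy, s), "| rounds so far:", s.metrics.rounds)

xyz = evaluate_polynomial(PolynomialSpec([1], [[1, 1, 1]]), [x, y, z], s, cache)
print("x*y*z =", reveal(xyz, s), "| rounds so far:", s.metrics.rounds)
print("cache:", cache.counters())
```

prints

```
x*y = 42 | rounds so far: 2
x*y*z = 126 | rounds so far: 4
cache: {'hits': 2, 'misses': 3, 'invalidations': 0}
```

Reading the numbers: the multiplication opened the partitions of `x`
and `y` in one batched round, and its reveal cost the second round. The
degree-3 product `x·y·z` then needed only one more online round — `x`
and `y` were already partitioned (the two cache hits), so only `z`'s
partition was opened (the third miss) — plus one round for its reveal.
A mutated secret bumps its version and would show up as an
invalidation; a stale partition can never be consumed.

The same machinery from the command line:

```
$ mpcbio simulate gwas --seed 3
gwas: mask 46/50 pass, max|dbeta|=6.01e-07, rounds=196
self-check: ok

$ mpcbio bench innerprod --size 1000 --domain field --bits 128
{"task": "innerprod", "domain": "field", "bits": 128, "rounds": 2,
 "bytes_sent": 64048, "ok": true, "wall_time_s": 0.0062}
```

The GWAS line says: on a synthetic cohort of 100 individuals × 50 SNPs,
the securely computed quality-control mask (missing rate, minor-allele
frequency, Hardy-Weinberg chi-square — all evaluated as exact integer
comparisons under MPC) kept 46 SNPs and matched the plaintext filter
bit for bit, and the securely computed association statistics agreed
with the plaintext regression to 6×10⁻⁷, using 196 communication rounds
in total. The inner-product benchmark shows the round count is
independent of the vector length: one round for the batched partitions,
one for the reveal.

Other entry points: `mpcbio gen genotypes|reads|bench` (synthetic
inputs), `mpcbio gwas` (TSV in, per-SNP statistics out), `mpcbio
binning train|classify`, `mpcbio simulate gwas|binning|bloom`. All
commands accept `--config` (INI-style key = value) to select the
domain, fixed-point precision, party count, and seed.

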