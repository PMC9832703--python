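# Methods

## Security model and execution model

`mpcbio` implements additive secret sharing over a finite field or a
power-of-two ring, in the *server-aided* (trusted-dealer) model under an
honest-but-curious adversary: `n >= 2` computing parties follow the
protocol but may inspect everything they receive; an auxiliary party —
the dealer — samples correlated randomness (Beaver masks and triples,
mask monomials, truncation pairs, shared random bits, cross-domain mask
pairs) and never receives any share- or secret-dependent message. The
scheme tolerates arbitrary collusion as long as the dealer and one
computing party stay honest. Malicious security is out of scope.

The runtime is a **centralized single-process simulator**: one `Session`
object holds every party's share state and routes explicit `exchange`
calls between them. We chose this over per-party processes or threads
because the package's purpose is protocol-level correctness and
communication accounting, which the simulator measures *exactly*: one
round per synchronized exchange that crosses a computing-party link
(dealer traffic counts bytes, never rounds), fixed-width big-endian
serialization so byte counters are machine-independent, a per-link
transcript digest, a dealer inbox for passivity audits, and a reveal log
for leakage audits. With a fixed master seed every transcript is
bit-for-bit reproducible. The price is that no actual network boundary
exists; a socket transport would slot in behind the same exchange
interface but is not implemented.

Pairwise PRG streams derived from the master seed let the dealer "send"
pseudorandom shares for free: for every correlation only the one share
that must equal `value - sum(pseudorandom shares)` is transmitted (to
the last party). Fresh uniform masks cost no dealer traffic at all.

## Algebraic domains and fixed-point encoding

* Default field: the Mersenne prime `q = 2^127 - 1`, with fold-and-add
  reduction (`2^127 = 1 mod q`, so reduction is shift/mask/add — no
  general division). Default ring: `Z_{2^128}`. Both are configurable;
  61-bit Mersenne field and 64-bit ring are provided for narrow setups.
  Rings have no inverses for even elements, so every protocol here is
  inverse-free; the field is still preferred where statistical masking
  headroom matters.
* Fixed point: value `x` is stored as `round(x 2^f) mod q`, negatives in
  the upper half. Defaults `f = 32` fractional bits and `s = 40`
  statistical-slack bits satisfy `2^(2f+s) < q`, i.e. one un-truncated
  product plus masking headroom fits in the field. The resolution is
  `2^-32 ~ 2.3e-10`; representable magnitudes after one product are
  about `2^21` in real units, ample for the pipelines' statistics.

## Protocol layer

**Beaver partitions and caching.** A partition of `x` is `(e = x - r,
[r])` with `r` a fresh dealer mask and `e` opened to all parties. All
cold operands of an operation are opened in one batched exchange, so any
multiplication / inner product / matrix product / polynomial evaluation
costs exactly **one round when some operand is cold and zero when all
partitions are cached**. Partitions are keyed by (secret handle,
version); every in-place mutation bumps the version, so a stale
partition is structurally unreachable. Partitions propagate for free
through addition, subtraction, and public scaling; propagated masks are
linear combinations of registered dealer masks, which the dealer can
still multiply out for later correlations.

**Generalized polynomial evaluation.** `sum_i c_i prod_j x_j^{p_ij}`
with public integer coefficients is evaluated by expanding each
`prod_j (e_j + r_j)^{p_ij}` binomially; the dealer supplies one share
per distinct mask monomial (monomials that are a single mask at power
one reuse the partition's own mask share). Each variable is partitioned
at most once, so the whole polynomial costs one online round. The
number of dealer correlations grows exponentially with the degree,
hence a degree cap (default 4); expressions over the cap are split into
stages that lean on partition caching. Coefficients are restricted to
integers because monomials of different total degree carry different
fixed-point scales; real-coefficient expressions are executed as
truncated multiplication chains instead.

**Truncation** (rescaling by `2^-f` after a fixed-point product) is the
standard probabilistic dealer-pair method: offset into a positive
window, open `x + offset + r` under a uniform mask wide enough that no
modular wrap occurs, shift the public value, subtract `[r >> f]`. Error
is at most one unit in the last place; one round. Exact truncation was
rejected — it costs a comparison per call and the +-1-ulp noise is far
below the pipelines' 1e-3 tolerance.

**Comparison / sign extraction.** The sign of a shared value `d` with
`|d| < 2^M` (default `M = 64` encoded units) is recovered exactly: open
`d + 2^M + r` where the dealer shares `r`'s low bits individually;
the sign bit is then `c_hi - r_hi - borrow`, with the borrow computed
by a bitwise public-vs-shared comparison circuit — suffix products of
per-bit equality indicators evaluated as a balanced doubling tree of
batched secure multiplications. Round cost is `2 + ceil(log2 M) + 1`
(8 rounds at the default width): **fixed for a given configuration and
identical for every input**, which is what the pipelines'
transcript-obliviousness rests on, but logarithmic rather than constant
in the configured bit width. Truly width-independent alternatives need
either modular inverses (unavailable in rings) or correlation families
exponential in the width; we consider the log-depth circuit the right
trade at 64-128 bits. The same protocol runs unchanged in the ring.

**Division and square root** are Goldschmidt/Newton iterations with no
modular inverse anywhere. The operand is first normalized into
`[1/2, 1)`: either from a public order-of-magnitude hint, or securely —
one *batched* comparison of the operand against all powers of two in a
configured range yields a shared one-hot over octaves, and the scaling
factors (`sigma`, `sqrt(sigma)`) are public-weighted sums of those
bits. Reciprocal: `w <- w (2 - b w)` from the minimax affine seed
`48/17 - 32/17 b`; inverse square root: `y <- y (3 - b y^2) / 2` from
`3 - 2b`. Default 10 iterations, far past the `2^-32` quantization
floor; observed relative errors are ~1e-8, comfortably inside the
documented `2^(-f/2+2)` bound. The square-root routine returns the
inverse square root as a by-product, so `a / sqrt(b)` is one extra
multiplication (`a * invsqrt(b)`) — measured at ~42% fewer rounds than
a square root followed by a full division. Divisor signs are handled
obliviously (sign bit, multiply by +-1, re-apply).

**Domain conversion** re-shares a value between field and ring via a
dealer mask shared in both domains: open the offset, masked value in
the source (no wrap, by the slack headroom), re-share the public
opening in the target minus the target-domain mask. One round; the
caller must bound the value's magnitude (`value_bits`, default 80).

## Expression optimizer

Arithmetic on secure handles builds a hash-consed DAG lazily (zero
communication). Three passes reproduce the protocol-level optimizations
automatically:

1. rewrites — `a / sqrt(b) -> a * invsqrt(b)`; products against
   diagonal-tagged matrices become elementwise row/column scalings
   (`O(n^2)` instead of `O(n^3)` scalar products; diagonal structure is
   a *user tag*, never inferred from secret data, which would leak);
   powers above the degree cap split into balanced product chains.
2. polynomial collapsing — maximal integer arithmetic subtrees under
   the degree cap become single generalized-polynomial steps.
3. planning — per subtree, polynomial route vs cached-multiply chain,
   minimizing (rounds, then dealer correlations) lexicographically;
   ties prefer the multiply chain (fewer correlations). The search is
   exhaustive up to 10 internal nodes and greedy
   (largest-expandable-subtree) beyond. Each secret leaf enters the
   partition schedule at most once.

Integer-mode plans predict round counts exactly and execution verifies
prediction against observed metrics; fixed-point plans use per-primitive
round costs measured once on a probe session, which are upper bounds
(an operand that happens to be warm inside a compound primitive can only
save rounds), so there the check is `observed <= predicted`.

## Pipelines

**Mini-GWAS.** Genotypes are shared as one-hot class indicators
(hom-ref / het / hom-alt / missing), so QC counts are local column sums
and the missing sentinel is never compared under MPC. All three QC
filters are integer comparisons with denominators cleared as exact
rationals — in particular the Hardy-Weinberg chi-square is tested via
the monotone-equivalent polynomial inequality
`a^2(4m o0 - A^2)^2 + 2aA(2m o1 - aA)^2 + A^2(4m o2 - a^2)^2
<= T * 4 m a^2 A^2` (a/A alt/ref allele counts, m genotyped count), so
the secure mask agrees bit-for-bit with the exact-rational plaintext
filter. Monomorphic SNPs make both sides zero and are defined to pass
HWE (they fail the MAF filter anyway). The association scan computes
per-SNP regression slope and squared correlation from shared sums,
vectorized across SNPs; the correlation denominator uses
`num * invsqrt(var_g * var_y)`. Zero-variance SNPs are detected
obliviously and forced to statistic 0. Missing entries enter the scan
as dosage 0 (the plaintext twin uses the same convention). Only the QC
mask and the per-SNP statistics are revealed — aggregate, low-leakage
outputs; per-individual values never are. Population-structure
correction (PCA) is out of scope; the scan is univariate on a
provider-standardized phenotype.

**Oblivious Bloom-filter binning.** The interleaved Bloom filter (one
bit row per reference bin; blake2b-based positions) is public at the
computing parties — the reference owner is one of them; what stays
secret is *which positions a read probes*. Each probe is a one-hot
vector shared by the read owner and contracted against the public bit
matrix locally; the AND across a k-mer's h probes is a chain of secure
bit products; the winning bin is a secure argmax tournament (strict
comparisons, ties to the lower index — mirrored exactly in the
plaintext twin). All shapes are fixed, so transcripts are identical
across queries — the oblivious-access property. Defaults: 1024-bit
filters, 3 hash functions, k = 16, 20 evenly spaced k-mers per read
(sized so the per-bin filters stay ~50-60% loaded on the synthetic
references; a saturated filter classifies nothing).

**Hinge-loss SGD.** Per step, the margin `y (w.x + b)` is compared to 1
obliviously and the subgradient indicator gates the update by secure
multiplication, so support-vector identity never leaks. Sample order
comes from a public seed. Defaults lr = 0.1, 5 epochs. The plaintext
twin replays the identical visiting order in the same fixed-point
integer arithmetic with exact floors; the secure trajectory can deviate
only by accumulated +-1-ulp truncation noise (measured ~3e-9 per weight
after 100 steps, versus the 1e-3 documented tolerance). Multiclass is
one-vs-rest with a secure argmax at inference.

## Synthetic data: what it does and does not emulate

Generators are seed-deterministic (same seed, byte-identical output)
and every truth table suffices to recompute the expected pipeline output
in plaintext.

* Genotypes: per-SNP binomial sampling at Hardy-Weinberg with MAF ~
  Uniform(0.05, 0.5); designated violator SNPs get an inbreeding-style
  heterozygote deficit (F = 0.8-1.0), the signature the HWE filter is
  meant to catch; missingness is i.i.d. Bernoulli. The phenotype is a
  linear model on standardized causal genotypes plus unit Gaussian
  noise. Causal variants are restricted to common SNPs (MAF >= 0.2)
  with standardized effect 1.0 — sized by a power calculation so that
  at the desk-scale cohort (100 individuals x 50 SNPs, 5 causal) the
  planted signals rank in the top quantile of the association statistics
  in ~99% of simulated cohorts; smaller effects make the recovery check
  a coin flip at this n, which would test luck rather than the
  pipeline. *Not* emulated: linkage disequilibrium, population
  structure, genotyping-error models beyond the HWE distortion, case /
  control ascertainment. Passing tests therefore certify the secure
  computation against its plaintext twin and parameter recovery under
  an idealized architecture — not calibration on real cohorts.
* Reads: one random 300 bp reference per bin, 65 bp reads with i.i.d.
  point substitutions (default 2%). No indels, no quality model, no
  shared sequence between bins (real genomes overlap; classification
  here is easier than reality).
* Features: two Gaussian clouds separated by a corridor of configurable
  margin — exactly separable by construction, as the SGD accuracy check
  requires.

## Numerical and degenerate-input choices

* Probabilistic truncation: +-1 ulp, one round (exactness rejected for
  round cost).
* Comparison width `compare_bits = 64` by default: inputs must satisfy
  `|encoded value| < 2^64`; the GWAS integer comparisons peak near
  `2^61` at the default cohort scale.
* Normalization ranges for divide / sqrt are per-call parameters
  (`lo`, `hi` octaves); values outside clamp to the extreme octave and
  converge more slowly. The association scan passes explicit bounds
  sized to its statistics.
* Argmax and classification ties break toward the lower index in both
  the secure and the plaintext route, so agreement checks are exact.
* Public constant addition is applied by party 1 (any fixed designated
  party works; it must be protocol-wide).
* Zero-variance SNPs: statistic defined as 0, detected obliviously.

## Known limitations

* Single-process simulator: no real network, no TLS, no fault
  tolerance; honest-but-curious only.
* Comparison rounds grow with log of the configured width (see above).
* The fully-shared Bloom-index mode (index secret from the computing
  parties) is not implemented; the index is public at the parties.
* Polynomial evaluation requires integer coefficients; fixed-point
  expressions fall back to multiplication chains.
* Object-dtype big-integer tensors put desk-scale ceilings on problem
  sizes (hundreds of individuals / SNPs, thousands of SGD steps); the
  protocols themselves are scale-free.
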