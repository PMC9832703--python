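"""Seed-deterministic generators for pipeline inputs.

Every test and demo runs on synthetic data with the statistical
structure each pipeline assumes:

* genotype matrices drawn at Hardy-Weinberg equilibrium with uniform
  minor-allele frequencies, optional HWE violators (via an inbreeding
  coefficient), missingness, and a quantitative phenotype built from a
  handful of causal variants plus Gaussian noise;
* metagenomic reads sampled from random per-bin reference sequences
  with point mutations;
* micro-benchmark inputs (mult3 / innerprod / xtabs) with their
  plaintext expected outputs.

Each generator also returns a truth table sufficient to recompute the
corresponding pipeline's expected output in plaintext.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenotypeData",
    "ReadData",
    "gen_genotypes",
    "gen_reads",
    "gen_benchmark_inputs",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_reads_fasta",
    "read_reads_fasta",
]

MISSING = -1


@dataclass
class GenotypeData:
    """Genotypes (0/1/2, -1 missing), phenotype, and the ground truth."""

    genotypes: np.ndarray          # individuals x SNPs, int
    phenotype: np.ndarray          # individuals, float
    snp_ids: list[str]
    maf: np.ndarray                # per-SNP simulated allele frequency
    causal: np.ndarray             # causal SNP indices
    effects: np.ndarray            # per-causal effect sizes
    hwe_violators: np.ndarray      # indices simulated off-equilibrium
    inbreeding: float

    def truth_table(self) -> pd.DataFrame:
        m = self.genotypes.shape[1]
        return pd.DataFrame({
            "snp": self.snp_ids,
            "maf": self.maf,
            "causal": np.isin(np.arange(m), self.causal).astype(int),
            "effect": [
                float(self.effects[list(self.causal).index(j)]) if j in self.causal else 0.0
                for j in range(m)
            ],
            "hwe_violator": np.isin(np.arange(m), self.hwe_violators).astype(int),
        })


def gen_genotypes(
    n_individuals: int = 100,
    n_snps: int = 50,
    maf_range: tuple[float, float] = (0.05, 0.5),
    miss_rate: float = 0.02,
    n_causal: int = 5,
    effect_size: float = 1.0,
    hwe_violators: int = 3,
    inbreeding: float = 0.8,
    noise_sd: float = 1.0,
    causal_maf_min: float = 0.2,
    seed: int = 0,
) -> GenotypeData:
    """Simulate a GWAS cohort.

    Genotypes at SNP j are Binomial(2, p_j) (i.e., Hardy-Weinberg) with
    p_j ~ Uniform(maf_range), except for ``hwe_violators`` SNPs whose
    genotype distribution is distorted by inbreeding coefficient F
    (heterozygote deficit, the classic signature of genotyping error).
    The quantitative phenotype is a linear combination of standardized
    causal genotypes plus N(0, noise_sd^2) noise; missing entries are
    introduced last, so the phenotype reflects the true genotypes.

    Causal variants are drawn among common SNPs (MAF >= causal_maf_min)
    and carry standardized effects of magnitude ``effect_size``; the
    defaults are sized by a power calculation so that at the desk-scale
    cohort (100 x 50) the planted signals are recoverable from the
    association ranking with >= 99% probability.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie inside (0, 0.5]")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_snps)
    G = np.empty((n_individuals, n_snps), dtype=int)
    violators = rng.choice(n_snps, size=min(hwe_violators, n_snps), replace=False)
    violators.sort()
    for j in range(n_snps):
        p = maf[j]
        if j in violators:
            f = inbreeding
            probs = [
                (1 - p) ** 2 + f * p * (1 - p),
                2 * p * (1 - p) * (1 - f),
                p ** 2 + f * p * (1 - p),
            ]
            G[:, j] = rng.choice(3, size=n_individuals, p=probs)
        else:
            G[:, j] = rng.binomial(2, p, size=n_individuals)

    eligible = np.setdiff1d(np.flatnonzero(maf >= causal_maf_min), violators)
    if len(eligible) < n_causal:
        eligible = np.setdiff1d(np.arange(n_snps), violators)
    causal = rng.choice(eligible, size=min(n_causal, len(eligible)),
                        replace=False)
    causal.sort()
    effects = effect_size * rng.choice([-1.0, 1.0], size=len(causal))
    y = rng.normal(0.0, noise_sd, size=n_individuals)
    for e, j in zip(effects, causal):
        p = maf[j]
        sd = np.sqrt(2 * p * (1 - p))
        y = y + e * (G[:, j] - 2 * p) / sd

    if miss_rate > 0:
        mask = rng.random((n_individuals, n_snps)) < miss_rate
        G = np.where(mask, MISSING, G)

    snp_ids = [f"snp{j:04d}" for j in range(n_snps)]
    return GenotypeData(G, y, snp_ids, maf, causal, effects, violators,
                        inbreeding if hwe_violators else 0.0)


@dataclass
class ReadData:
    """Reads, bin labels, and the per-bin reference k-mer sets."""

    reads: list[str]
    labels: np.ndarray
    references: list[str]
    kmer_sets: list[set]
    k: int
    read_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.read_ids:
            self.read_ids = [f"read{i:05d}" for i in range(len(self.reads))]


_BASES = np.array(list("ACGT"))


def gen_reads(
    n_bins: int = 5,
    n_reads: int = 200,
    read_len: int = 65,
    mutation_rate: float = 0.02,
    k: int = 16,
    ref_len: int = 300,
    seed: int = 0,
) -> ReadData:
    """Simulate a metagenomic classification task at desk scale.

    One random reference sequence per bin; each read is a substring of
    a uniformly chosen reference with independent point substitutions.
    Returns the per-bin reference k-mer sets used to build the Bloom
    index, and the true bin label per read.
    """
    if read_len < k:
        raise ValueError("read_len must be at least the k-mer size")
    rng = np.random.default_rng(seed)
    refs = ["".join(rng.choice(_BASES, size=ref_len)) for _ in range(n_bins)]
    kmer_sets = [
        {ref[i: i + k] for i in range(len(ref) - k + 1)} for ref in refs
    ]
    reads, labels = [], np.empty(n_reads, dtype=int)
    for i in range(n_reads):
        b = rng.integers(n_bins)
        start = rng.integers(ref_len - read_len + 1)
        read = list(refs[b][start: start + read_len])
        for pos in range(read_len):
            if rng.random() < mutation_rate:
                read[pos] = rng.choice([c for c in "ACGT" if c != read[pos]])
        reads.append("".join(read))
        labels[i] = b
    return ReadData(reads, labels, refs, kmer_sets, k)


def gen_linear_features(
    n: int = 200,
    dim: int = 2,
    margin: float = 1.0,
    spread: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly separable labelled features for margin-classifier tests.

    Each point's signed distance from a random hyperplane is
    ``y * (margin/2 + |N(0, spread)|)``, so the two classes are
    separated by a corridor of width ``margin`` by construction; the
    components orthogonal to the normal are free Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    normal = rng.normal(size=dim)
    normal /= np.linalg.norm(normal)
    y = rng.choice([-1, 1], size=n)
    X = rng.normal(scale=spread, size=(n, dim))
    perp = X - np.outer(X @ normal, normal)
    dist = margin / 2 + np.abs(rng.normal(scale=spread, size=n))
    X = perp + np.outer(y * dist, normal)
    return X, y


def write_features_tsv(X: np.ndarray, y: np.ndarray, path) -> None:
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
    df.insert(0, "label", y)
    df.to_csv(path, sep="\t", index=False)


def read_features_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    feats = [c for c in df.columns if c != "label"]
    return df[feats].to_numpy(dtype=float), df["label"].to_numpy(dtype=int)


def gen_benchmark_inputs(task: str, size: int = 1, seed: int = 0) -> dict:
    """Inputs + plaintext expected output for the micro-benchmarks."""
    rng = np.random.default_rng(seed)
    if task == "mult3":
        x = rng.integers(1, 1000, size=3)
        return {"inputs": [int(v) for v in x], "expected": int(np.prod(x))}
    if task == "innerprod":
        a = rng.integers(0, 1000, size=size)
        b = rng.integers(0, 1000, size=size)
        return {"inputs": [a.tolist(), b.tolist()], "expected": int(a @ b)}
    if task == "xtabs":
        n_cat = max(2, min(size, 10))
        cats = rng.integers(0, n_cat, size=size)
        vals = rng.integers(0, 1000, size=size)
        sums = [int(vals[cats == c].sum()) for c in range(n_cat)]
        return {"inputs": [cats.tolist(), vals.tolist()], "expected": sums,
                "n_categories": n_cat}
    raise ValueError(f"unknown benchmark task {task!r}")


# ---------------------------------------------------------------------------
# plain-text file dialects (TSV / FASTA)

def write_genotypes_tsv(data: GenotypeData, path) -> None:
    df = pd.DataFrame(data.genotypes, columns=data.snp_ids)
    df.insert(0, "id", [f"ind{i:05d}" for i in range(len(df))])
    df.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t")
    ids = df["id"].tolist()
    snps = [c for c in df.columns if c != "id"]
    return df[snps].to_numpy(dtype=int), snps, ids


def write_phenotypes_tsv(phenotype: np.ndarray, path, ids=None) -> None:
    ids = ids or [f"ind{i:05d}" for i in range(len(phenotype))]
    pd.DataFrame({"id": ids, "value": phenotype}).to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["value"].to_numpy(dtype=float)


def write_reads_fasta(data: ReadData, path) -> None:
    records = [
        SeqRecord(Seq(r), id=rid, description=f"bin={b}")
        for r, rid, b in zip(data.reads, data.read_ids, data.labels)
    ]
    SeqIO.write(records, path, "fasta")


def read_reads_fasta(path) -> tuple[list[str], list[str]]:
    records = list(SeqIO.parse(path, "fasta"))
    return [str(r.seq) for r in records], [r.id for r in records]
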