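"""Pairwise average nucleotide identity (ANI) estimation.

ANI is estimated from bottom-s MinHash sketches of canonical k-mers, the
standard Mash-style approach used by genome dereplication tools. Exact
oracles (per-site Hamming identity for equal-length genomes, and full-set
k-mer Jaccard) are provided for validation: at default settings the sketch
estimator tracks the Hamming oracle to within ~0.01 for pairs above the 95%
species boundary. Below it the agreement degrades gracefully (~0.005-0.02 at
ANI 0.89 for 20 kb genomes) because the fraction of mutation-free k-mer
windows itself fluctuates around its expectation — an inherent property of
k-mer identity estimation at finite genome length, not of sketching; the
exact full-set Jaccard shows the same spread.

The Jaccard → ANI mapping uses the Mash distance
``D = -(1/k) * ln(2j / (1 + j))`` and reports ``ANI = exp(-D)``. For
divergence produced by independent per-site substitutions at rate ``d``,
``2j/(1+j)`` estimates ``(1-d)^k``, so ``exp(-D) = 1 - d`` exactly in
expectation; the common first-order form ``1 - D`` is biased low by ``d²/2``
which is material (~0.005) at species-boundary distances.

Non-ACGT characters never contribute: every k-mer window containing one is
skipped. Canonical k-mers (min of a k-mer and its reverse complement under
the 2-bit encoding) make sketches strand-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._hash import splitmix64

DEFAULT_K = 21
#: Default sketch size (standard Mash regime). Per-pair sampling error of the
#: ANI estimate is sd ≈ exp(-D)/(k√s) · √(j(1-j))/(j(1+j)): ≲ 0.001 for pairs
#: above the 95% species boundary, ~0.006 at ANI 0.89 — ample for threshold
#: clustering, where only the separation between the within-unit, between-unit
#: and between-species bands matters.
DEFAULT_SKETCH_SIZE = 1_000

# 2-bit base encoding; anything else is invalid (-1) and voids its windows.
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


@dataclass(frozen=True)
class Sketch:
    """Bottom-s sketch of a genome's canonical k-mer hashes.

    ``hashes`` holds the s smallest distinct hash values, strictly increasing.
    """

    genome_id: str
    k: int
    s: int
    hashes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        h = np.asarray(self.hashes, dtype=np.uint64)
        if h.size > 1 and not np.all(h[1:] > h[:-1]):
            raise ValueError("sketch hashes must be strictly increasing")
        if h.size > self.s:
            raise ValueError("sketch holds more than s hashes")
        object.__setattr__(self, "hashes", h)


@dataclass
class ANIMatrix:
    """Symmetric pairwise ANI estimates over an ordered genome collection."""

    ids: list[str]
    values: np.ndarray
    method: str = "sketch"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("ANI matrix shape does not match id count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("ANI matrix must be symmetric")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("ANI values must lie in [0, 1]")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def get(self, a: str, b: str) -> float:
        ia, ib = self.ids.index(a), self.ids.index(b)
        return float(self.values[ia, ib])

    def submatrix(self, ids: Sequence[str]) -> "ANIMatrix":
        idx = [self.ids.index(i) for i in ids]
        return ANIMatrix(list(ids), self.values[np.ix_(idx, idx)], self.method)


def _canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit encode all valid k-mer windows of ``seq`` canonically.

    Returns a uint64 array (one entry per valid window, duplicates kept);
    canonical code = min(forward code, reverse-complement code).
    """
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    invalid = codes < 0
    # window is valid iff it contains no invalid base
    bad = np.convolve(invalid.astype(np.int32), np.ones(k, dtype=np.int32), "valid") > 0
    c = np.where(invalid, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    three = np.uint64(3)
    for t in range(k):
        fwd |= c[t : t + n] << np.uint64(2 * (k - 1 - t))
        rev |= (three - c[t : t + n]) << np.uint64(2 * t)
    canon = np.minimum(fwd, rev)
    return canon[~bad]


def sketch(
    sequences: str | Iterable[str],
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    genome_id: str = "",
) -> Sketch:
    """Bottom-s MinHash sketch of one genome (contigs pooled).

    Raises ``ValueError`` if no contig reaches length k.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    parts = [_canonical_kmer_codes(seq, k) for seq in sequences]
    kmers = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
    if kmers.size == 0:
        raise ValueError(f"no k-mer of length {k} in genome {genome_id!r}")
    hashes = np.unique(splitmix64(kmers))  # sorted distinct
    return Sketch(genome_id=genome_id, k=k, s=s, hashes=hashes[:s])


def jaccard(a: Sketch, b: Sketch) -> float:
    """Mash-style merged bottom-s Jaccard estimate between two sketches.

    Takes the s smallest hashes of the union (fewer when the union is small)
    and counts how many occur in both genomes.
    """
    if a.k != b.k:
        raise ValueError(f"sketch k mismatch: {a.k} != {b.k}")
    s = min(a.s, b.s)
    union = np.union1d(a.hashes, b.hashes)[:s]
    if union.size == 0:
        raise ValueError("empty sketches")
    shared = np.isin(union, a.hashes, assume_unique=True) & np.isin(
        union, b.hashes, assume_unique=True
    )
    return float(shared.sum() / union.size)


def mash_ani(j: float, k: int = DEFAULT_K) -> float:
    """Map a Jaccard estimate to ANI via the Mash distance.

    ``D = -(1/k) ln(2j/(1+j))``, ``ANI = exp(-D)``, clamped to [0, 1];
    ``j = 0`` maps to 0 (no detectable similarity).
    """
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"jaccard estimate {j} outside [0, 1]")
    if j == 0.0:
        return 0.0
    d = -(1.0 / k) * np.log(2.0 * j / (1.0 + j))
    return float(min(1.0, max(0.0, np.exp(-d))))


def exact_ani(
    seq_a: str | Sequence[str],
    seq_b: str | Sequence[str],
    method: str = "hamming",
    k: int = DEFAULT_K,
) -> float:
    """Exact ANI oracle.

    ``hamming``: 1 - mismatches/L on equal-length single sequences (valid for
    the indel-free generator). ``jaccard``: full-set canonical k-mer Jaccard
    passed through the same Mash mapping as the sketch estimator.
    """
    if method == "hamming":
        if not isinstance(seq_a, str) or not isinstance(seq_b, str):
            raise ValueError("hamming ANI requires single sequences")
        if len(seq_a) != len(seq_b):
            raise ValueError(
                f"hamming ANI requires equal lengths ({len(seq_a)} != {len(seq_b)})"
            )
        a = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)
        b = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)
        return float(1.0 - np.count_nonzero(a != b) / a.size)
    if method == "jaccard":
        if isinstance(seq_a, str):
            seq_a = [seq_a]
        if isinstance(seq_b, str):
            seq_b = [seq_b]
        ka = np.unique(np.concatenate([_canonical_kmer_codes(s, k) for s in seq_a]))
        kb = np.unique(np.concatenate([_canonical_kmer_codes(s, k) for s in seq_b]))
        inter = np.intersect1d(ka, kb, assume_unique=True).size
        union = ka.size + kb.size - inter
        return mash_ani(inter / union if union else 0.0, k)
    raise ValueError(f"unknown exact ANI method {method!r}")


def _hamming_matrix(seqs: list[str]) -> np.ndarray:
    """Pairwise per-site identity over equal-length sequences.

    Uses one-hot base indicators and BLAS: matches(i,j) = Σ_b A_b A_bᵀ, so a
    site matches only when both genomes carry the same unambiguous base.
    """
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("exact_hamming requires equal-length genomes")
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), L
    )
    matches = np.zeros((len(seqs), len(seqs)), dtype=np.float64)
    for base in b"ACGT":
        onehot = (arr == base).astype(np.float32)
        matches += (onehot @ onehot.T).astype(np.float64)
    out = matches / L
    np.fill_diagonal(out, 1.0)
    return np.clip((out + out.T) / 2.0, 0.0, 1.0)


def pairwise_ani_matrix(
    genomes: Mapping[str, str | Sequence[str]],
    method: str = "sketch",
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
) -> ANIMatrix:
    """Symmetric ANI matrix over a genome collection, ids in sorted order.

    ``method`` is one of ``sketch`` (default), ``exact_hamming`` or
    ``exact_jaccard``. Pairs with no shared k-mers get ANI 0.
    """
    if len(genomes) == 0:
        raise ValueError("empty genome collection")
    ids = sorted(genomes)
    n = len(ids)
    if method == "exact_hamming":
        seqs = []
        for gid in ids:
            g = genomes[gid]
            if not isinstance(g, str):
                if len(g) != 1:
                    raise ValueError("exact_hamming requires single-contig genomes")
                g = g[0]
            seqs.append(g)
        return ANIMatrix(ids, _hamming_matrix(seqs), "exact_hamming")

    mat = np.ones((n, n))
    if method == "sketch":
        sketches = [sketch(genomes[gid], k=k, s=s, genome_id=gid) for gid in ids]
        for i in range(n):
            for jdx in range(i + 1, n):
                a = mash_ani(jaccard(sketches[i], sketches[jdx]), k)
                mat[i, jdx] = mat[jdx, i] = a
    elif method == "exact_jaccard":
        kmer_sets = []
        for gid in ids:
            g = genomes[gid]
            contigs = [g] if isinstance(g, str) else list(g)
            kmer_sets.append(
                np.unique(np.concatenate([_canonical_kmer_codes(c, k) for c in contigs]))
            )
        for i in range(n):
            for jdx in range(i + 1, n):
                inter = np.intersect1d(
                    kmer_sets[i], kmer_sets[jdx], assume_unique=True
                ).size
                union = kmer_sets[i].size + kmer_sets[jdx].size - inter
                a = mash_ani(inter / union if union else 0.0, k)
                mat[i, jdx] = mat[jdx, i] = a
    else:
        raise ValueError(f"unknown ANI method {method!r}")
    return ANIMatrix(ids, mat, method)


def write_sketches(sketches: Iterable[Sketch], path: str | Path) -> None:
    """Serialize sketches to TSV: genome_id, k, s, comma-joined hash list."""
    rows = [
        {
            "genome_id": sk.genome_id,
            "k": sk.k,
            "s": sk.s,
            "hashes": ",".join(str(h) for h in sk.hashes),
        }
        for sk in sketches
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sketches(path: str | Path) -> list[Sketch]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    return [
        Sketch(
            genome_id=r.genome_id,
            k=int(r.k),
            s=int(r.s),
            hashes=np.array([int(x) for x in str(r.hashes).split(",")], dtype=np.uint64),
        )
        for r in df.itertuples()
    ]
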