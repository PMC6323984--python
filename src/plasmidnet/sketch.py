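"""MinHash sketching and Mash-style distances between plasmid sequences.

A sequence is reduced to a *bottom sketch*: the ``s`` smallest 64-bit hash
values over its canonical k-mers (the lexicographic minimum of each k-mer
and its reverse complement, so strand does not matter).  Comparing the
bottom sketches of two sequences yields an estimate ``j`` of the Jaccard
index of their full k-mer sets, from which the Mash distance

    d = -(1/k) * ln(2j / (1 + j))

is derived -- an evolutionary-distance-like quantity that approximates the
per-base substitution rate separating the two sequences under a simple
Poisson mutation model.  A binomial null model gives a p-value for the
observed number of shared hashes arising by chance between unrelated
sequences.

Defaults are k=21 and s=1000, the parameters used to build the plasmid
relatedness network, where linked pairs (d < 0.1) correspond roughly to
average nucleotide identity above 90%.

Hashing is a seeded splitmix64 finalizer applied to the 2-bit integer
encoding of each canonical k-mer.  It is fixed and platform-independent, so
sketches are reproducible bit for bit; compatibility with the Mash binary's
MurmurHash sketches is deliberately not a goal (sketches from different
tools are never mixed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import binom

__all__ = [
    "SketchParams",
    "SketchProfile",
    "DistanceEdge",
    "canonical_kmers",
    "canonical_kmer_codes",
    "bottom_sketch",
    "sketch_sequence",
    "mash_jaccard",
    "mash_distance",
    "edge_p_value",
    "distance_edge",
    "save_sketches",
    "load_sketches",
]

#: Default hash seed; any fixed integer works, 42 is kept as a nod to
#: common sketching practice.
DEFAULT_HASH_SEED = 42

_MAX_K = 32  # canonical k-mers are packed 2 bits/base into a uint64

# base -> 2-bit code; A<C<G<T so integer order on packed k-mers equals
# lexicographic order on the strings, and complement(b) == 3 - b.
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_CODE_BASE = "ACGT"


@dataclass(frozen=True)
class SketchParams:
    """Sketching parameters: k-mer length, sketch size, hash seed."""

    k: int = 21
    s: int = 1000
    hash_seed: int = DEFAULT_HASH_SEED

    def __post_init__(self) -> None:
        if not 1 <= self.k <= _MAX_K:
            raise ValueError(f"k must be in 1..{_MAX_K}, got {self.k}")
        if self.s < 1:
            raise ValueError(f"sketch size must be >= 1, got {self.s}")


@dataclass
class SketchProfile:
    """Bottom-s sketch of one sequence.

    ``hashes`` is a sorted uint64 array of the ``min(s, n_kmers)`` smallest
    hash values; ``n_kmers`` counts distinct canonical k-mers in the source.
    """

    accession: str
    hashes: np.ndarray
    n_kmers: int
    params: SketchParams = field(default_factory=SketchParams)

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SketchProfile):
            return NotImplemented
        return (
            self.accession == other.accession
            and self.n_kmers == other.n_kmers
            and self.params == other.params
            and np.array_equal(self.hashes, other.hashes)
        )


@dataclass(frozen=True)
class DistanceEdge:
    """A plasmid pair with shared-hash count, Jaccard estimate, distance, p-value."""

    accession_a: str
    accession_b: str
    x: int
    j: float
    d: float
    p: float


def _encode_bases(sequence: str) -> np.ndarray:
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def canonical_kmer_codes(sequence: str, k: int) -> np.ndarray:
    """Distinct canonical k-mers of ``sequence`` as sorted packed uint64 codes.

    Windows containing any character outside A/C/G/T are skipped.  The
    canonical form is the smaller of the forward and reverse-complement
    encodings, which (with the A=0..T=3 code) is also the lexicographically
    smaller string.
    """
    if not 1 <= k <= _MAX_K:
        raise ValueError(f"k must be in 1..{_MAX_K}, got {k}")
    codes = _encode_bases(sequence.upper())
    if codes.size < k:
        return np.empty(0, dtype=np.uint64)
    windows = sliding_window_view(codes, k)
    good = windows[~(windows > 3).any(axis=1)].astype(np.uint64)
    if good.size == 0:
        return np.empty(0, dtype=np.uint64)
    weights = np.uint64(4) ** np.arange(k, dtype=np.uint64)[::-1]
    fwd = (good * weights).sum(axis=1, dtype=np.uint64)
    rev = ((np.uint64(3) - good)[:, ::-1] * weights).sum(axis=1, dtype=np.uint64)
    return np.unique(np.minimum(fwd, rev))


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_CODE_BASE[code & 3])
        code >>= 2
    return "".join(reversed(out))


def canonical_kmers(sequence: str, k: int) -> set[str]:
    """Set of canonical k-mer strings of ``sequence`` (strand-independent)."""
    return {_decode_kmer(int(c), k) for c in canonical_kmer_codes(sequence, k)}


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


def hash_kmer_codes(codes: np.ndarray, seed: int) -> np.ndarray:
    """Seeded 64-bit hash of packed k-mer codes (vectorized splitmix64)."""
    codes = np.asarray(codes, dtype=np.uint64)
    seed_mix = _splitmix64(np.array([seed], dtype=np.uint64))[0]
    with np.errstate(over="ignore"):
        return _splitmix64(codes ^ seed_mix)


def _encode_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer:
        b = _BASE_CODE[ord(ch)]
        if b > 3:
            raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
        code = (code << 2) | int(b)
    return code


def bottom_sketch(
    kmers: Iterable[str] | np.ndarray,
    params: SketchParams,
    accession: str = "",
) -> SketchProfile:
    """Bottom-s sketch of a k-mer set.

    Accepts either canonical k-mer strings or packed uint64 codes (the
    output of :func:`canonical_kmer_codes`).  An empty k-mer set yields an
    empty sketch; distances to an empty sketch are undefined and rejected
    by :func:`mash_jaccard`.
    """
    if isinstance(kmers, np.ndarray):
        codes = np.asarray(kmers, dtype=np.uint64)
    else:
        codes = np.fromiter(
            (_encode_kmer(k) for k in kmers), dtype=np.uint64
        )
    codes = np.unique(codes)
    hashes = np.unique(hash_kmer_codes(codes, params.hash_seed))
    return SketchProfile(
        accession=accession,
        hashes=hashes[: params.s],
        n_kmers=int(codes.size),
        params=params,
    )


def sketch_sequence(
    sequence: str, params: SketchParams, accession: str = ""
) -> SketchProfile:
    """Sketch a nucleotide sequence directly (canonicalize, hash, keep bottom s)."""
    return bottom_sketch(
        canonical_kmer_codes(sequence, params.k), params, accession=accession
    )


def mash_jaccard(a: SketchProfile, b: SketchProfile) -> tuple[int, float]:
    """Shared-hash count ``x`` and Jaccard estimate ``j`` from two sketches.

    The estimate is taken over the merged bottom sketch: the ``s`` smallest
    values of the union of both hash sets, of which ``x`` occur in both.
    """
    if a.params != b.params:
        raise ValueError(
            f"sketch parameter mismatch: {a.params} vs {b.params}"
        )
    if a.hashes.size == 0 or b.hashes.size == 0:
        empty = a.accession if a.hashes.size == 0 else b.accession
        raise ValueError(f"cannot compare empty sketch ({empty!r})")
    merged = np.union1d(a.hashes, b.hashes)[: a.params.s]
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    x = int(np.isin(merged, shared, assume_unique=True).sum())
    return x, x / merged.size


def mash_distance(j: float, k: int) -> float:
    """Mash distance from a Jaccard estimate; capped at 1, and 1 when j == 0."""
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"Jaccard estimate outside [0, 1]: {j}")
    if j == 0.0:
        return 1.0
    return min(1.0, -(1.0 / k) * math.log(2.0 * j / (1.0 + j)))


def edge_p_value(
    x: int, n_kmers_a: int, n_kmers_b: int, params: SketchParams
) -> float:
    """P(X >= x) under the chance-sharing null model.

    The probability r that a random hash drawn into the merged sketch is
    shared by chance comes from the k-mer space size 4^k and the two
    genomes' distinct k-mer counts; X ~ Binomial(s, r).
    """
    if x < 0:
        raise ValueError(f"shared-hash count must be >= 0, got {x}")
    if x > params.s:
        raise ValueError(f"shared-hash count {x} exceeds sketch size {params.s}")
    if n_kmers_a < 1 or n_kmers_b < 1:
        raise ValueError("k-mer counts must be >= 1")
    if x == 0:
        return 1.0
    kmer_space = 4.0 ** params.k
    p_a = n_kmers_a / (n_kmers_a + kmer_space)
    p_b = n_kmers_b / (n_kmers_b + kmer_space)
    r = (p_a * p_b) / (p_a + p_b - p_a * p_b)
    return float(binom.sf(x - 1, params.s, r))


def distance_edge(a: SketchProfile, b: SketchProfile) -> DistanceEdge:
    """Full pairwise comparison of two sketches (x, j, d, p) as one edge."""
    if a.accession == b.accession:
        raise ValueError(f"self-pair for accession {a.accession!r}")
    x, j = mash_jaccard(a, b)
    d = mash_distance(j, a.params.k)
    p = edge_p_value(x, a.n_kmers, b.n_kmers, a.params)
    return DistanceEdge(a.accession, b.accession, x, j, d, p)


def _sketch_to_dict(profile: SketchProfile) -> dict:
    return {
        "accession": profile.accession,
        "k": profile.params.k,
        "s": profile.params.s,
        "hash_seed": profile.params.hash_seed,
        "n_kmers": profile.n_kmers,
        "hashes": [int(h) for h in profile.hashes],
    }


def _sketch_from_dict(doc: dict) -> SketchProfile:
    params = SketchParams(k=doc["k"], s=doc["s"], hash_seed=doc["hash_seed"])
    return SketchProfile(
        accession=doc["accession"],
        hashes=np.array(doc["hashes"], dtype=np.uint64),
        n_kmers=doc["n_kmers"],
        params=params,
    )


def save_sketches(profiles: Iterable[SketchProfile], path: str | Path) -> None:
    doc = {"sketches": [_sketch_to_dict(p) for p in profiles]}
    Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")))


def load_sketches(path: str | Path) -> list[SketchProfile]:
    doc = json.loads(Path(path).read_text())
    return [_sketch_from_dict(d) for d in doc["sketches"]]
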