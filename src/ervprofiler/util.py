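"""Small shared helpers: sequence encoding, reverse complement, k-mer counts
and the per-read RNG stream used for multi-mapper resolution."""

from __future__ import annotations

import zlib
from collections import Counter
from collections.abc import Iterable

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# A,C,G,T -> 0..3; anything else (incl. N) -> 4, which never matches itself
# across read/reference, so ambiguous bases count as mismatches.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_counts(sequences: Iterable, k: int) -> Counter:
    """Count every k-mer on the forward strand of the given sequences.

    ``sequences`` holds objects with ``.sequence`` (GenomeSequence) or plain
    strings.  Reverse-strand occurrences are resolved at query time via
    :func:`kmer_occurrences` so palindromic k-mers are not double counted.
    """
    counts: Counter = Counter()
    for rec in sequences:
        seq = getattr(rec, "sequence", rec)
        counts.update(seq[i : i + k] for i in range(len(seq) - k + 1))
    return counts


def kmer_occurrences(counts: Counter, kmer: str) -> int:
    """Occurrences of ``kmer`` in the counted genome, either strand."""
    rc = reverse_complement(kmer)
    n = counts.get(kmer, 0)
    if rc != kmer:
        n += counts.get(rc, 0)
    return n


def rng_for_read(seed: int, read_id: str) -> np.random.Generator:
    """A dedicated RNG stream keyed by (seed, read id).

    Keying the stream on the read identifier makes multi-mapper selection
    independent of the order in which reads are presented.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(read_id.encode())])


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a top-level seed."""
    state = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]
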