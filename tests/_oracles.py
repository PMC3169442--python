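"""Independent brute-force oracles used by the test suite.

Each function here recomputes a pipeline quantity by direct enumeration —
per-position loops and string comparisons — deliberately avoiding the
vectorized code paths of the package so agreement is meaningful.
"""

from __future__ import annotations

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def scan_alignments(read: str, genomes, max_mismatches: int):
    """All placements of ``read`` on either strand with <= max_mismatches,
    then restricted to the minimum-distance set.

    Returns a sorted list of (chrom, pos, strand, distance).
    """
    hits = []
    rc = revcomp(read)
    k = len(read)
    for g in genomes:
        seq = g.sequence
        for pos in range(len(seq) - k + 1):
            window = seq[pos : pos + k]
            d = hamming(read, window)
            if d <= max_mismatches:
                hits.append((g.name, pos, "+", d))
            d = hamming(rc, window)
            if d <= max_mismatches:
                hits.append((g.name, pos, "-", d))
    if not hits:
        return []
    dmin = min(h[3] for h in hits)
    return sorted(h for h in hits if h[3] == dmin)


def footprint(read, extension: int):
    """(start, end) of the directionally extended read, clipped at 0."""
    if read.strand == "+":
        return read.start, read.start + read.read_length + extension
    end = read.start + read.read_length
    return max(0, end - (read.read_length + extension)), end


def pileup_depth(placements, length: int, extension: int):
    """Per-position count of extended footprints overlapping each position."""
    depth = [0] * length
    for read in placements:
        start, end = footprint(read, extension)
        for pos in range(max(0, start), min(length, end)):
            depth[pos] += 1
    return depth


def flank_counts(reads, elements, flank_size: int, extension: int,
                 flip_minus: bool = True):
    """Per-relative-position footprint counts agglomerated over elements.

    Index i of the returned list corresponds to relative position
    i - flank_size (negative = biological 5' flank).
    """
    counts = [0] * (2 * flank_size)
    spans = [footprint(r, extension) for r in reads]
    chroms = [r.chrom for r in reads]
    for element in elements:
        iv = element.interval
        flipped = flip_minus and iv.strand == "-"
        for i in range(2 * flank_size):
            rel = i - flank_size
            if not flipped:
                g = iv.start + rel if rel < 0 else iv.end + rel
            else:
                # 5' flank of a minus element is genomically right of it
                g = iv.end - 1 - rel if rel < 0 else iv.start - 1 - rel
            for (s, e), chrom in zip(spans, chroms):
                if chrom == iv.chrom and s <= g < e:
                    counts[i] += 1
    return counts


def mappability_track(genome, k: int):
    """1 if the k-mer starting at each position occurs exactly once in the
    genome over both strands, else 0."""
    seq = genome.sequence
    n = len(seq) - k + 1
    track = []
    for p in range(n):
        kmer = seq[p : p + k]
        rc = revcomp(kmer)
        occ = 0
        for q in range(n):
            window = seq[q : q + k]
            if window == kmer:
                occ += 1
            if rc != kmer and window == rc:
                occ += 1
        track.append(1 if occ == 1 else 0)
    return track


def pcr_products(genome, forward: str, reverse: str, max_product: int,
                 max_mismatches: int):
    """All products of the primer pair by double-loop scan, as a sorted set
    of (chrom, start, end, strand)."""
    seq = genome.sequence
    products = set()
    for left, right, strand in (
        (forward, revcomp(reverse), "+"),
        (reverse, revcomp(forward), "-"),
    ):
        for i in range(len(seq) - len(left) + 1):
            if hamming(left, seq[i : i + len(left)]) > max_mismatches:
                continue
            for j in range(i, min(i + max_product - len(right), len(seq) - len(right)) + 1):
                if j + len(right) - i > max_product:
                    continue
                if hamming(right, seq[j : j + len(right)]) <= max_mismatches:
                    products.add((genome.name, i, j + len(right), strand))
    return sorted(products)


def permutation_ttest_p(a, b):
    """Exact two-sided permutation p-value for the difference of means over
    all label assignments (for small groups)."""
    from itertools import combinations

    pooled = list(a) + list(b)
    na = len(a)
    observed = abs(sum(a) / na - sum(b) / len(b))
    count = total = 0
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        diff = abs(sum(ga) / len(ga) - sum(gb) / len(gb))
        if diff >= observed - 1e-12:
            count += 1
        total += 1
    return count / total
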