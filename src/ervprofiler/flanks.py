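"""Agglomerated read density in the genomic flanks of intact repeat elements.

Heterochromatic marks deposited on an ERV spread into the adjacent genome;
the agglomerated flank profile measures that spreading by pooling, across
all intact copies of a family, the density of (quality-filtered, unique,
positionally deduplicated, extended) reads in the +/- ``flank_size`` windows
around each element, expressed in element-relative coordinates.  Densities
are double-normalized: by the number of included elements and by the total
number of genome-aligned reads (per million).

A k-mer mappability check is provided so non-uniform alignability of the
flank windows can be ruled out as a confounder.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from collections.abc import Sequence
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .consensus import DEFAULT_EXTENSION, extend_read
from .errors import ParameterError
from .records import AlignedRead, ElementAnnotation, GenomicInterval
from .util import kmer_counts, kmer_occurrences

log = logging.getLogger(__name__)

DEFAULT_FLANK_SIZE = 7000
DEFAULT_MIN_QUALITY = 7


def select_intact_elements(
    annotations: Sequence[ElementAnnotation],
    min_length: int,
    max_divergence: float,
) -> list[ElementAnnotation]:
    """Keep elements with length >= ``min_length`` and divergence <= ``max_divergence``.

    The exact intactness thresholds are user parameters.  Idempotent.
    """
    selected = [
        replace(a, intact=True)
        for a in annotations
        if len(a.interval) >= min_length and a.divergence <= max_divergence
    ]
    log.info(
        "select_intact_elements: %d of %d elements pass (min_length=%d, "
        "max_divergence=%g)", len(selected), len(annotations), min_length,
        max_divergence,
    )
    return selected


def filter_flank_reads(
    reads: Sequence[AlignedRead], min_quality: int = DEFAULT_MIN_QUALITY
) -> list[AlignedRead]:
    """Keep uniquely aligned reads with map quality strictly above the threshold.

    Both conditions come from the read-counting rules of the flank analysis:
    quality must exceed (not equal) ``min_quality``, and only reads with a
    single best alignment location are kept.
    """
    kept: list[AlignedRead] = []
    n_quality = 0
    n_multi = 0
    for r in reads:
        if r.map_quality <= min_quality:
            n_quality += 1
        elif not r.is_unique:
            n_multi += 1
        else:
            kept.append(r)
    log.info(
        "filter_flank_reads: kept %d, removed %d (quality <= %d) and %d (multi-mapped)",
        len(kept), n_quality, min_quality, n_multi,
    )
    return kept


def dedup_reads(reads: Sequence[AlignedRead]) -> list[AlignedRead]:
    """Collapse reads mapped to the same location to a single copy.

    Location is ``(chrom, start, strand)`` — the strand is part of the key,
    so coincident reads on opposite strands both survive.  Output is sorted
    by location; the operation is idempotent.
    """
    seen: dict[tuple[str, int, str], AlignedRead] = {}
    for r in reads:
        key = (r.chrom, r.start, r.strand)
        held = seen.get(key)
        # deterministic representative regardless of input order: highest
        # quality, then fewest hits, then smallest id
        if held is None or (
            (-r.map_quality, r.n_hits, r.read_id or "")
            < (-held.map_quality, held.n_hits, held.read_id or "")
        ):
            seen[key] = r
    n_dup = len(reads) - len(seen)
    if n_dup:
        log.info("dedup_reads: collapsed %d duplicate placements", n_dup)
    return [seen[k] for k in sorted(seen)]


@dataclass
class FlankProfile:
    """Element-relative read density over the +/- flank windows.

    ``density`` has ``2 * flank_size`` entries: index ``i`` corresponds to
    relative position ``i - flank_size``, where negative positions are the
    biological 5' (upstream) flank (-1 adjacent to the element) and
    non-negative positions the 3' flank (0 adjacent).
    """

    family: str
    flank_size: int
    counts: np.ndarray
    density: np.ndarray
    n_elements: int
    library_size: int

    @property
    def relative_positions(self) -> np.ndarray:
        return np.arange(-self.flank_size, self.flank_size)

    def distance_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean of the 5' and 3' tracks as a function of boundary distance."""
        F = self.flank_size
        d = np.arange(F)
        five = self.density[F - 1 - d]
        three = self.density[F + d]
        return d, (five + three) / 2.0


def agglomerate_flanks(
    reads: Sequence[AlignedRead],
    elements: Sequence[ElementAnnotation],
    library_size: int,
    flank_size: int = DEFAULT_FLANK_SIZE,
    extension: int = DEFAULT_EXTENSION,
    count_mode: str = "footprint",
    flip_minus: bool = True,
) -> FlankProfile:
    """Pool extended-read coverage in the flanks of all elements.

    For each element, read footprints overlapping ``[start - flank_size,
    start)`` or ``[end, end + flank_size)`` contribute their in-flank
    overlap positions (``count_mode='footprint'``) or just their start
    position (``count_mode='start'``).  Minus-strand elements are
    orientation-flipped (configurable) so "5' flank" is biologically
    upstream.  Density = counts / n_elements / (library_size / 1e6).
    """
    if not elements:
        raise ParameterError("elements must be non-empty")
    if library_size <= 0:
        raise ParameterError("library_size must be positive")
    if count_mode not in ("footprint", "start"):
        raise ParameterError(f"unknown count_mode {count_mode!r}")

    F = flank_size
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for r in reads:
        if count_mode == "start":
            by_chrom[r.chrom].append((r.start, r.start + 1))
        else:
            iv = extend_read(r, extension)
            by_chrom[r.chrom].append((iv.start, iv.end))
    footprints = {
        chrom: (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
        for chrom, ivs in by_chrom.items()
    }

    counts = np.zeros(2 * F, dtype=np.int64)
    for element in elements:
        iv = element.interval
        if iv.chrom not in footprints:
            continue
        fs, fe = footprints[iv.chrom]
        flipped = flip_minus and iv.strand == "-"
        for window_start, upstream_window in (
            (iv.start - F, True),   # genomic left window
            (iv.end, False),        # genomic right window
        ):
            local = _window_coverage(fs, fe, window_start, F)
            if flipped:
                # genomic right window is the biological 5' flank, reversed
                if upstream_window:
                    counts[F:] += local[::-1]
                else:
                    counts[:F] += local[::-1]
            else:
                if upstream_window:
                    counts[:F] += local
                else:
                    counts[F:] += local

    density = counts / len(elements) / (library_size / 1e6)
    families = sorted({e.family for e in elements})
    return FlankProfile(
        family=",".join(families),
        flank_size=F,
        counts=counts,
        density=density,
        n_elements=len(elements),
        library_size=library_size,
    )


def _window_coverage(fs: np.ndarray, fe: np.ndarray, window_start: int, width: int) -> np.ndarray:
    """Per-position footprint coverage inside ``[window_start, window_start+width)``."""
    os = np.maximum(fs, max(window_start, 0)) - window_start
    oe = np.minimum(fe, window_start + width) - window_start
    mask = oe > os
    diff = np.zeros(width + 1, dtype=np.int64)
    np.add.at(diff, os[mask], 1)
    np.add.at(diff, oe[mask], -1)
    return np.cumsum(diff[:width])


@dataclass
class FlankDecayFit:
    """Least-squares fit of density(d) = amplitude * exp(-d/scale) + background."""

    scale: float
    amplitude: float
    background: float
    bin_centers: np.ndarray
    bin_means: np.ndarray


def fit_flank_decay(
    profile: FlankProfile, bin_width: int = 250, min_distance: int = 0
) -> FlankDecayFit:
    """Fit an exponential decay to the distance-binned mean flank density.

    ``min_distance`` excludes the bins closest to the element boundary from
    the fit (the full binned profile is still returned).  With footprint
    coverage, positions within one fragment length of the boundary mix in
    fragments starting inside the element body and smear the decay, so
    passing the fragment length there makes the estimator see the pure
    exponential regime.
    """
    distances, density = profile.distance_profile()
    n_bins = profile.flank_size // bin_width
    usable = n_bins * bin_width
    means = density[:usable].reshape(n_bins, bin_width).mean(axis=1)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    keep = centers >= min_distance
    if keep.sum() < 3:
        raise ParameterError("too few bins for a 3-parameter decay fit")

    def model(d, amplitude, scale, background):
        return amplitude * np.exp(-d / scale) + background

    x, y = centers[keep], means[keep]
    span = max(y.max() - y.min(), 1e-12)
    p0 = [span, profile.flank_size / 5.0, max(y.min(), 0.0)]
    popt, _ = curve_fit(
        model, x, y, p0=p0,
        bounds=([0.0, 1.0, 0.0], [np.inf, np.inf, np.inf]), maxfev=20000,
    )
    return FlankDecayFit(
        scale=float(popt[1]), amplitude=float(popt[0]), background=float(popt[2]),
        bin_centers=centers, bin_means=means,
    )


def genome_mappability(genomes, read_length: int) -> dict[str, np.ndarray]:
    """Per-position k-mer uniqueness (1 if the k-mer occurs once genome-wide,
    either strand, else 0) for every sequence in ``genomes``."""
    from .records import GenomeSequence

    if isinstance(genomes, GenomeSequence):
        genomes = [genomes]
    genomes = list(genomes)
    counts = kmer_counts(genomes, read_length)
    tracks: dict[str, np.ndarray] = {}
    for g in genomes:
        seq = g.sequence
        n = len(seq) - read_length + 1
        track = np.zeros(max(n, 0), dtype=np.int8)
        for p in range(max(n, 0)):
            kmer = seq[p : p + read_length]
            track[p] = 1 if kmer_occurrences(counts, kmer) == 1 else 0
        tracks[g.name] = track
    return tracks


def mappability_profile(
    genomes, read_length: int, windows: Sequence[GenomicInterval]
) -> np.ndarray:
    """Mean mappability of ``read_length``-mers per window, each in [0, 1]."""
    tracks = genome_mappability(genomes, read_length)
    means = np.full(len(windows), np.nan)
    for i, w in enumerate(windows):
        if w.chrom not in tracks:
            raise ParameterError(f"window chrom {w.chrom!r} not in genome")
        track = tracks[w.chrom]
        lo = max(w.start, 0)
        hi = min(w.end, len(track))
        if hi > lo:
            means[i] = float(track[lo:hi].mean())
    return means
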