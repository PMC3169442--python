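"""ChIP-seq metaprofiles along a repeat consensus sequence.

The metaprofile answers "how is the mark distributed along an average copy
of this ERV family?": reads (multi-mapper resolved) are directionally
extended by a fixed fragment extension, piled up along the consensus, and
normalized to RPKM using the number of reads uniquely mapped to the genome
as the library-size denominator.

RPKM convention for a bin of width w: mean per-base depth in the bin
x 10^9 / library_size (equivalently reads-per-kilobase-per-million for a
1 bp bin).  The convention is fixed here and recorded in profile metadata.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .records import AlignedRead, GenomicInterval
from .util import rng_for_read

DEFAULT_EXTENSION = 150  # bp, applied to the 3' end of each read


def assign_multimappers(
    groups: Mapping[str, Sequence[AlignedRead]], seed: int
) -> list[AlignedRead]:
    """Retain exactly one placement per read, uniformly among its ties.

    Unique reads pass through unchanged.  Selection uses a per-read RNG
    stream keyed by ``(seed, read_id)``, so the output is deterministic for
    a fixed seed and invariant to the order of ``groups``.  Output is sorted
    by read id.
    """
    chosen: list[AlignedRead] = []
    for rid in sorted(groups):
        group = list(groups[rid])
        if not group:
            raise ParameterError(f"empty placement group for read {rid!r}")
        if len(group) == 1:
            chosen.append(group[0])
        else:
            idx = int(rng_for_read(seed, rid).integers(len(group)))
            chosen.append(group[idx])
    return chosen


def extend_read(read: AlignedRead, extension: int = DEFAULT_EXTENSION) -> GenomicInterval:
    """Directionally extend a read's 3' end by ``extension`` bp.

    '+' reads extend rightwards, '-' reads leftwards; the footprint is
    ``read_length + extension`` bp except where clipped at position 0.
    """
    if extension < 0:
        raise ParameterError("extension must be >= 0")
    if read.strand == "+":
        start = read.start
        end = read.start + read.read_length + extension
    else:
        end = read.start + read.read_length
        start = end - (read.read_length + extension)
    return GenomicInterval(read.chrom, max(0, start), end, read.strand)


@dataclass
class ConsensusProfile:
    """Per-bin RPKM along a consensus plus the per-base raw depth."""

    consensus_name: str
    length: int
    bin_width: int
    values: np.ndarray            # per-bin RPKM
    raw_depth: np.ndarray         # per-base footprint depth (len == length)
    n_reads_used: int
    library_size: int
    extension: int

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.bin_width

    def rescaled(self, library_size: int) -> "ConsensusProfile":
        """The same profile under a different normalization denominator."""
        if library_size <= 0:
            raise ParameterError("library_size must be positive")
        factor = self.library_size / library_size
        return ConsensusProfile(
            self.consensus_name, self.length, self.bin_width,
            self.values * factor, self.raw_depth, self.n_reads_used,
            library_size, self.extension,
        )


def profile_consensus(
    placements: Sequence[AlignedRead],
    consensus_length: int,
    library_size: int,
    extension: int = DEFAULT_EXTENSION,
    bin_width: int = 1,
    consensus_name: str = "consensus",
) -> ConsensusProfile:
    """Pile up extended reads along the consensus and normalize to RPKM.

    ``placements`` must already be multi-mapper resolved (one record per
    read).  Footprints extending past either end of the consensus are
    clipped, not wrapped.
    """
    if library_size <= 0:
        raise ParameterError("library_size must be positive")
    if bin_width < 1 or consensus_length < 1:
        raise ParameterError("bin_width and consensus_length must be >= 1")
    diff = np.zeros(consensus_length + 1, dtype=np.int64)
    n_used = 0
    for read in placements:
        iv = extend_read(read, extension)
        start = max(0, iv.start)
        end = min(consensus_length, iv.end)
        if end > start:
            diff[start] += 1
            diff[end] -= 1
            n_used += 1
    depth = np.cumsum(diff[:consensus_length])
    n_bins = -(-consensus_length // bin_width)
    padded = np.zeros(n_bins * bin_width, dtype=np.float64)
    padded[:consensus_length] = depth
    mean_depth = padded.reshape(n_bins, bin_width).sum(axis=1) / bin_width
    values = mean_depth * 1e9 / library_size
    return ConsensusProfile(
        consensus_name, consensus_length, bin_width, values,
        depth.astype(np.int64), n_used, library_size, extension,
    )


@dataclass
class ConditionComparison:
    """Per-bin wt/KO ratio and mean-signal summary for two profiles."""

    ratio: np.ndarray
    mean_a: float
    mean_b: float
    mean_ratio: float
    pseudocount: float


def compare_conditions(
    profile_a: ConsensusProfile, profile_b: ConsensusProfile
) -> ConditionComparison:
    """Elementwise a/b ratio with a pseudocount, plus mean-signal summary.

    The pseudocount is 1e-6 x the larger profile maximum, recorded in the
    result so downstream reports can state it.
    """
    if (
        profile_a.length != profile_b.length
        or profile_a.bin_width != profile_b.bin_width
    ):
        raise ParameterError("profiles differ in consensus length or bin width")
    top = max(float(profile_a.values.max(initial=0.0)),
              float(profile_b.values.max(initial=0.0)))
    eps = 1e-6 * top if top > 0 else 1e-6
    ratio = (profile_a.values + eps) / (profile_b.values + eps)
    mean_a = float(profile_a.values.mean())
    mean_b = float(profile_b.values.mean())
    return ConditionComparison(
        ratio=ratio,
        mean_a=mean_a,
        mean_b=mean_b,
        mean_ratio=(mean_a + eps) / (mean_b + eps),
        pseudocount=eps,
    )


def write_profile(profile: ConsensusProfile, path) -> None:
    """Write the profile as TSV (bin_start, rpkm) with a JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("bin_start\trpkm\n")
        for start, value in zip(profile.bin_starts, profile.values):
            fh.write(f"{start}\t{value:.6g}\n")
    sidecar = {
        "consensus_name": profile.consensus_name,
        "length": profile.length,
        "bin_width": profile.bin_width,
        "extension": profile.extension,
        "n_reads_used": profile.n_reads_used,
        "library_size": profile.library_size,
        "rpkm_convention": "mean per-base depth * 1e9 / library_size",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
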