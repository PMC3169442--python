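"""Bisulphite clone methylation calling, conversion QC and four-bin reporting.

Bisulphite treatment converts unmethylated cytosines to uracil (read as T),
while methylated CpG cytosines resist.  Each sequenced clone is one DNA
molecule: comparing it to the unconverted reference at every CpG yields a
per-molecule methylation call, and the fraction of *non*-CpG reference
cytosines read as T is the per-clone conversion rate used for quality
control (clones with rate strictly above 98% are retained by default).

Clones are assumed to represent the converted plus strand of the amplicon
(C->T space); apparent G->A conversion triggers a strand error.  Alignment
is end-gap-free with mismatches only: clones of a different length than
the reference are rejected rather than risking a shifted CpG register.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, DegenerateInputError, ParameterError, StrandError
from .records import GenomeSequence, GenomicInterval
from .util import encode_sequence, reverse_complement

log = logging.getLogger(__name__)

DEFAULT_MIN_CONVERSION = 0.98
DEFAULT_BIN_EDGES = (0.25, 0.5, 0.75)

METHYLATED, UNMETHYLATED, MISSING = 1, 0, -1


def cpg_positions(reference: GenomeSequence) -> np.ndarray:
    """0-based positions of the C of every CpG dinucleotide in the reference."""
    seq = reference.sequence
    return np.array(
        [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"],
        dtype=np.int64,
    )


@dataclass
class BisulfiteClone:
    """Per-CpG methylation calls and conversion QC for one sequenced molecule."""

    clone_id: str
    calls: np.ndarray             # int8 per CpG: 1 meth, 0 unmeth, -1 missing
    conversion_rate: float        # NaN when no informative non-CpG C exists
    n_cpg: int
    cpg_sites: np.ndarray         # reference positions of the CpG cytosines

    @property
    def methylated_fraction(self) -> float:
        """methylated / (methylated + unmethylated); NaN if nothing was called."""
        called = self.calls >= 0
        if not called.any():
            return float("nan")
        return float(self.calls[called].mean())


def call_clone(
    clone_seq: str,
    reference: GenomeSequence,
    clone_id: str = "clone",
    strand_check: bool = True,
) -> BisulfiteClone:
    """Call per-CpG methylation for one clone against the unconverted reference.

    At each reference CpG: clone C -> methylated, T -> unmethylated, any
    other base -> missing.  The conversion rate is computed over non-CpG
    reference C positions with an unambiguous (C or T) clone base.
    """
    clone = clone_seq.upper()
    ref = reference.sequence
    if len(clone) != len(ref):
        raise AlignmentError(
            f"clone {clone_id!r} length {len(clone)} != reference length {len(ref)}; "
            "end-gap-free alignment requires equal lengths (indels unsupported)"
        )
    sites = cpg_positions(reference)
    if sites.size == 0:
        raise DegenerateInputError("reference contains no CpG site")

    if strand_check:
        g_positions = [i for i, b in enumerate(ref) if b == "G"]
        informative = [i for i in g_positions if clone[i] in "GA"]
        if len(informative) >= 5:
            frac_a = sum(clone[i] == "A" for i in informative) / len(informative)
            if frac_a > 0.5:
                raise StrandError(
                    f"clone {clone_id!r}: {frac_a:.0%} of reference Gs read as A; "
                    "this looks like the G->A converted strand, which is unsupported"
                )

    cpg_set = set(int(i) for i in sites)
    calls = np.full(sites.size, MISSING, dtype=np.int8)
    for k, i in enumerate(sites):
        base = clone[i]
        if base == "C":
            calls[k] = METHYLATED
        elif base == "T":
            calls[k] = UNMETHYLATED

    converted = informative_c = 0
    for i, b in enumerate(ref):
        if b == "C" and i not in cpg_set:
            base = clone[i]
            if base in "CT":
                informative_c += 1
                if base == "T":
                    converted += 1
    rate = converted / informative_c if informative_c else float("nan")
    return BisulfiteClone(clone_id, calls, rate, int(sites.size), sites)


def filter_clones(
    clones: Sequence[BisulfiteClone],
    min_conversion: float = DEFAULT_MIN_CONVERSION,
) -> list[BisulfiteClone]:
    """Keep clones with conversion rate strictly above ``min_conversion``.

    A NaN conversion rate (no informative non-CpG C) never passes.
    """
    kept = [c for c in clones if c.conversion_rate > min_conversion]
    if len(kept) != len(clones):
        log.info(
            "filter_clones: removed %d of %d clones (conversion <= %g)",
            len(clones) - len(kept), len(clones), min_conversion,
        )
    return kept


@dataclass
class MethylationBinning:
    """Percentage of clones per methylation bin per sample."""

    bin_edges: tuple[float, ...]
    labels: tuple[str, ...]
    percentages: pd.DataFrame     # index: sample, columns: labels
    n_clones: dict[str, int]
    n_excluded: dict[str, int]


def bin_clones(
    samples: Mapping[str, Sequence[BisulfiteClone]],
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> MethylationBinning:
    """Bin clones by methylated-CpG fraction and report per-sample percentages.

    With the default edges the four categories are the equal-width quartiles
    [0, 0.25], (0.25, 0.5], (0.5, 0.75], (0.75, 1].  Clones with no called
    CpG are excluded with a logged warning.  Percentages per sample sum to
    100 and the result is invariant to clone order.
    """
    edges = tuple(float(e) for e in bin_edges)
    if list(edges) != sorted(set(edges)) or not edges or edges[0] <= 0 or edges[-1] >= 1:
        raise ParameterError("bin_edges must be strictly increasing within (0, 1)")
    bounds = (0.0,) + edges + (1.0,)
    labels = tuple(
        f"{bounds[i]:g}-{bounds[i + 1]:g}" for i in range(len(bounds) - 1)
    )
    edge_arr = np.array(edges)
    rows = {}
    n_clones: dict[str, int] = {}
    n_excluded: dict[str, int] = {}
    for sample, clones in samples.items():
        scores = np.array([c.methylated_fraction for c in clones], dtype=float)
        valid = ~np.isnan(scores)
        n_excluded[sample] = int((~valid).sum())
        if n_excluded[sample]:
            log.warning(
                "bin_clones: sample %r: excluded %d clone(s) with zero called CpGs",
                sample, n_excluded[sample],
            )
        scores = scores[valid]
        if scores.size == 0:
            raise DataError(f"sample {sample!r} has no clone with called CpGs")
        idx = np.searchsorted(edge_arr, scores, side="left")
        histogram = np.bincount(idx, minlength=len(labels)).astype(float)
        rows[sample] = histogram / scores.size * 100.0
        n_clones[sample] = int(scores.size)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(labels))
    return MethylationBinning(edges, labels, frame, n_clones, n_excluded)


def methylation_matrix(clones: Sequence[BisulfiteClone]) -> pd.DataFrame:
    """Lollipop-style clone x CpG-position matrix (1 meth, 0 unmeth, NA missing)."""
    if not clones:
        return pd.DataFrame()
    columns = [int(p) for p in clones[0].cpg_sites]
    data = {}
    for c in clones:
        vals = c.calls.astype(float)
        vals[vals < 0] = np.nan
        data[c.clone_id] = vals
    return pd.DataFrame.from_dict(data, orient="index", columns=columns)


# ---------------------------------------------------------------------------
# In-silico PCR


def insilico_pcr(
    genome,
    forward_primer: str,
    reverse_primer: str,
    max_product: int,
    max_mismatches: int = 0,
) -> list[GenomicInterval]:
    """Enumerate PCR products a primer pair would amplify from the genome.

    A product exists wherever one primer matches one strand and the other
    primer's reverse complement matches downstream on the same strand within
    ``max_product`` bases, each with at most ``max_mismatches`` mismatches.
    Both orientations are scanned; product intervals are deduplicated and
    sorted.
    """
    if isinstance(genome, GenomeSequence):
        genome = [genome]
    genomes = list(genome)
    fwd = forward_primer.upper()
    rev = reverse_primer.upper()
    if min(len(fwd), len(rev)) < 15:
        raise ParameterError("primers must be at least 15 nt")
    if max_product <= max(len(fwd), len(rev)):
        raise ParameterError("max_product must exceed the primer lengths")

    products: set[tuple[str, int, int, str]] = set()
    for g in genomes:
        enc = encode_sequence(g.sequence)
        pos = {
            primer: _match_positions(enc, primer, max_mismatches)
            for primer in {fwd, rev, reverse_complement(fwd), reverse_complement(rev)}
        }
        # plus orientation: forward anneals left, reverse-complement(reverse) right
        for left, right, strand in (
            (fwd, reverse_complement(rev), "+"),
            (rev, reverse_complement(fwd), "-"),
        ):
            rlen = len(right)
            right_pos = pos[right]
            for i in pos[left]:
                lo = np.searchsorted(right_pos, i)
                hi = np.searchsorted(right_pos, i + max_product - rlen, side="right")
                for j in right_pos[lo:hi]:
                    products.add((g.name, int(i), int(j) + rlen, strand))
    return sorted(
        (GenomicInterval(c, s, e, st) for c, s, e, st in products),
        key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand),
    )


def _match_positions(enc: np.ndarray, primer: str, max_mismatches: int) -> np.ndarray:
    k = len(primer)
    if len(enc) < k:
        return np.array([], dtype=np.int64)
    from numpy.lib.stride_tricks import sliding_window_view

    windows = sliding_window_view(enc, k)
    mism = (windows != encode_sequence(primer)[None, :]).sum(axis=1)
    return np.nonzero(mism <= max_mismatches)[0].astype(np.int64)
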