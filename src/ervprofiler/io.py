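"""Readers/writers for the text formats the pipeline touches, plus a minimal
deterministic read aligner for desk-scale genomes.

Formats: multi-record FASTA, a strict SAM subset (header optional, the 11
mandatory columns, M/=/X-only CIGARs), BED6 element annotations and a simple
TSV alignment dialect (``chrom start strand read_length map_quality n_hits``
with an optional leading ``read_id`` column).

The aligner enumerates every placement of each read on both strands with
Hamming distance <= ``max_mismatches`` (no gaps).  An exact pigeonhole seed
prefilter (``max_mismatches + 1`` disjoint exact seeds) skips reads that
cannot match anywhere; it is lossless.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Sequence
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqIO import write as _seqio_write
from Bio.SeqRecord import SeqRecord
from numpy.lib.stride_tricks import sliding_window_view

from .errors import FormatError, ParameterError
from .records import AlignedRead, ElementAnnotation, GenomeSequence, GenomicInterval
from .util import encode_sequence, reverse_complement, rng_for_read

log = logging.getLogger(__name__)

_ALPHABET = frozenset("ACGTN")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHPX=])")

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[GenomeSequence]:
    """Parse a FASTA file into a list of :class:`GenomeSequence`.

    Sequences are uppercased on ingest.  Malformed headers and illegal
    characters raise :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    records: list[GenomeSequence] = []
    name: str | None = None
    name_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}:{name_line}: record '{name}' has no sequence")
        records.append(GenomeSequence(name, seq))

    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}:{ln}: empty FASTA header")
                name = header.split()[0]
                name_line = ln
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}:{ln}: sequence data before any '>' header"
                    )
                bad = set(line.upper()) - _ALPHABET
                if bad:
                    raise FormatError(
                        f"{path}:{ln}: illegal character(s) {sorted(bad)} in sequence"
                    )
                chunks.append(line.upper())
    _flush()
    return records


def write_fasta(records: Sequence[GenomeSequence], path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.name, description="") for r in records
    ]
    with open(path, "w") as fh:
        _seqio_write(seqrecords, fh, "fasta")


# ---------------------------------------------------------------------------
# Alignments: SAM subset and TSV dialect


def read_alignments(path, dialect: str = "sam") -> list[AlignedRead]:
    """Read placements from ``path`` in the named dialect (``sam`` or ``tsv``).

    SAM: header optional, 11 mandatory columns required per line; POS is
    converted 1-based -> 0-based; FLAG bit 16 sets strand '-'; unmapped
    (FLAG bit 4) and non-primary (bits 0x100/0x800) records are skipped with
    a logged count; the hit count is taken from an ``NH:i:`` tag when
    present, else 1.  CIGARs with operations other than M/=/X are rejected.
    """
    if dialect == "sam":
        return _read_sam(Path(path))
    if dialect == "tsv":
        return _read_tsv(Path(path))
    raise ParameterError(f"unknown alignment dialect {dialect!r}")


def _read_sam(path: Path) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    n_unmapped = 0
    n_secondary = 0
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("@"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise FormatError(
                    f"{path}:{ln}: SAM line has {len(fields)} fields; 11 required"
                )
            qname = fields[0]
            try:
                flag = int(fields[1])
                pos = int(fields[3])
                mapq = int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer FLAG/POS/MAPQ") from exc
            if flag & 0x4 or fields[2] == "*":
                n_unmapped += 1
                continue
            if flag & 0x900:
                n_secondary += 1
                continue
            if pos < 1:
                raise FormatError(f"{path}:{ln}: non-positive POS {pos} for mapped read")
            read_length = _cigar_reference_length(fields[5], path, ln)
            n_hits = 1
            for tag in fields[11:]:
                if tag.startswith("NH:i:"):
                    n_hits = int(tag[5:])
                    break
            reads.append(
                AlignedRead(
                    chrom=fields[2],
                    start=pos - 1,
                    strand="-" if flag & 0x10 else "+",
                    read_length=read_length,
                    map_quality=mapq,
                    n_hits=n_hits,
                    read_id=qname,
                )
            )
    if n_unmapped or n_secondary:
        log.info(
            "%s: skipped %d unmapped and %d non-primary records",
            path,
            n_unmapped,
            n_secondary,
        )
    return reads


def _cigar_reference_length(cigar: str, path: Path, ln: int) -> int:
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise FormatError(f"{path}:{ln}: malformed CIGAR {cigar!r}")
    length = 0
    for n, op in ops:
        if op not in "M=X":
            raise FormatError(
                f"{path}:{ln}: unsupported CIGAR operation {op!r} "
                "(only M/=/X are accepted in this subset)"
            )
        length += int(n)
    return length


_TSV_COLUMNS = ("chrom", "start", "strand", "read_length", "map_quality", "n_hits")


def _read_tsv(path: Path) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fields[0] in ("chrom", "read_id"):
                continue  # header row
            if len(fields) == 7:
                read_id, rest = fields[0], fields[1:]
            elif len(fields) == 6:
                read_id, rest = None, fields
            else:
                raise FormatError(
                    f"{path}:{ln}: expected 6 or 7 columns, found {len(fields)}"
                )
            chrom, start, strand, rl, mapq, nh = rest
            try:
                start_i, rl_i, mapq_i, nh_i = int(start), int(rl), int(mapq), int(nh)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer numeric column") from exc
            if start_i < 0:
                raise FormatError(f"{path}:{ln}: negative start position {start_i}")
            reads.append(
                AlignedRead(
                    chrom=chrom,
                    start=start_i,
                    strand=strand,
                    read_length=rl_i,
                    map_quality=mapq_i,
                    n_hits=nh_i,
                    read_id=read_id,
                )
            )
    return reads


def write_alignments_tsv(reads: Sequence[AlignedRead], path) -> None:
    with_ids = any(r.read_id is not None for r in reads)
    with open(path, "w") as fh:
        header = _TSV_COLUMNS if not with_ids else ("read_id",) + _TSV_COLUMNS
        fh.write("\t".join(header) + "\n")
        for r in reads:
            row = [r.chrom, str(r.start), r.strand, str(r.read_length),
                   str(r.map_quality), str(r.n_hits)]
            if with_ids:
                row.insert(0, r.read_id if r.read_id is not None else ".")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# BED6 annotations (chrom, start, end, name=family, score=divergence, strand)


def read_bed(path) -> list[ElementAnnotation]:
    path = Path(path)
    annotations: list[ElementAnnotation] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{ln}: BED6 requires 6 columns, found {len(fields)}"
                )
            chrom, start, end, name, score, strand = fields[:6]
            try:
                interval = GenomicInterval(chrom, int(start), int(end), strand)
                divergence = 0.0 if score == "." else float(score)
            except (ValueError, ParameterError) as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
            annotations.append(
                ElementAnnotation(interval, family=name, divergence=divergence)
            )
    return annotations


def write_bed(annotations: Sequence[ElementAnnotation], path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            iv = a.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{a.family}\t"
                f"{a.divergence:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Minimal Hamming aligner


def _as_genome_list(genome) -> list[GenomeSequence]:
    if isinstance(genome, GenomeSequence):
        return [genome]
    return list(genome)


def _seed_kmer_set(genomes: list[GenomeSequence], k: int) -> set[str]:
    kmers: set[str] = set()
    for g in genomes:
        seq = g.sequence
        rc = reverse_complement(seq)
        for s in (seq, rc):
            kmers.update(s[i : i + k] for i in range(len(s) - k + 1))
    return kmers


def enumerate_placements(
    read_seqs: Sequence[str],
    genome,
    max_mismatches: int = 0,
    read_ids: Sequence[str] | None = None,
    prefilter: bool = True,
) -> tuple[dict[str, list[AlignedRead]], list[str]]:
    """Enumerate all minimum-distance placements of each read.

    Returns ``(groups, unmapped_ids)`` where ``groups`` maps each placed
    read's id to the list of its tied best placements (each carrying
    ``n_hits`` equal to the tie count) and ``unmapped_ids`` lists reads with
    no placement at <= ``max_mismatches`` mismatches.  Both strands are
    scanned; a '-' placement means the reference matches the reverse
    complement of the read.
    """
    if max_mismatches < 0 or max_mismatches > 3:
        raise ParameterError("max_mismatches must be in 0..3")
    genomes = _as_genome_list(genome)
    if not genomes:
        raise ParameterError("empty genome")
    shortest = min(len(g) for g in genomes)
    if read_ids is None:
        read_ids = [f"r{i:07d}" for i in range(len(read_seqs))]
    if len(read_ids) != len(read_seqs):
        raise ParameterError("read_ids and read_seqs length mismatch")

    # Group identical sequences so each distinct sequence is scanned once.
    by_seq: dict[str, list[str]] = {}
    for rid, seq in zip(read_ids, read_seqs):
        seq = seq.upper()
        if len(seq) > shortest:
            raise ParameterError(
                f"read {rid} longer ({len(seq)}) than shortest target ({shortest})"
            )
        by_seq.setdefault(seq, []).append(rid)

    encoded = {g.name: encode_sequence(g.sequence) for g in genomes}
    groups: dict[str, list[AlignedRead]] = {}
    unmapped: list[str] = []

    by_length: dict[int, list[str]] = {}
    for seq in by_seq:
        by_length.setdefault(len(seq), []).append(seq)

    for rl, seqs in by_length.items():
        seed_len = rl // (max_mismatches + 1)
        kmer_set: set[str] | None = None
        if prefilter and seed_len >= 8:
            kmer_set = _seed_kmer_set(genomes, seed_len)

        candidates: list[str] = []
        for seq in seqs:
            if kmer_set is not None:
                parts = [
                    seq[i * seed_len : (i + 1) * seed_len]
                    for i in range(max_mismatches + 1)
                ]
                if not any(p in kmer_set for p in parts):
                    unmapped.extend(by_seq[seq])
                    continue
            candidates.append(seq)

        windows = {
            name: sliding_window_view(enc, rl)
            for name, enc in encoded.items()
            if len(enc) >= rl
        }
        n_positions = sum(w.shape[0] for w in windows.values())
        chunk = max(1, int(32e6 / max(1, n_positions * rl)))
        for lo in range(0, len(candidates), chunk):
            batch = candidates[lo : lo + chunk]
            fwd = np.stack([encode_sequence(s) for s in batch])
            rev = np.stack([encode_sequence(reverse_complement(s)) for s in batch])
            # hits[i] collects (chrom, pos, strand, distance) for batch read i
            hits: list[list[tuple[str, int, str, int]]] = [[] for _ in batch]
            for name, win in windows.items():
                for arr, strand in ((fwd, "+"), (rev, "-")):
                    mism = (arr[:, None, :] != win[None, :, :]).sum(
                        axis=2, dtype=np.int32
                    )
                    rows, cols = np.nonzero(mism <= max_mismatches)
                    for i, pos in zip(rows, cols):
                        hits[i].append((name, int(pos), strand, int(mism[i, pos])))
            for seq, seq_hits in zip(batch, hits):
                if not seq_hits:
                    unmapped.extend(by_seq[seq])
                    continue
                dmin = min(h[3] for h in seq_hits)
                ties = sorted(
                    (h for h in seq_hits if h[3] == dmin), key=lambda h: (h[0], h[1], h[2])
                )
                for rid in by_seq[seq]:
                    groups[rid] = [
                        AlignedRead(
                            chrom=c,
                            start=p,
                            strand=s,
                            read_length=rl,
                            map_quality=37 if len(ties) == 1 else 0,
                            n_hits=len(ties),
                            read_id=rid,
                        )
                        for c, p, s, _ in ties
                    ]
    return groups, unmapped


def align_reads_minimal(
    read_seqs: Sequence[str],
    genome,
    max_mismatches: int = 0,
    seed: int = 0,
    read_ids: Sequence[str] | None = None,
    prefilter: bool = True,
) -> list[AlignedRead]:
    """Place each read once, choosing uniformly among tied best placements.

    Reads with no placement are omitted (their count is logged).  The
    returned list follows the input read order; the choice among ties uses a
    per-read RNG stream keyed by ``(seed, read_id)`` so it is independent of
    input order.
    """
    if read_ids is None:
        read_ids = [f"r{i:07d}" for i in range(len(read_seqs))]
    groups, unmapped = enumerate_placements(
        read_seqs, genome, max_mismatches, read_ids, prefilter
    )
    if unmapped:
        log.info("align_reads_minimal: %d reads had no placement", len(unmapped))
    placed: list[AlignedRead] = []
    for rid in read_ids:
        group = groups.get(rid)
        if group is None:
            continue
        idx = 0 if len(group) == 1 else int(rng_for_read(seed, rid).integers(len(group)))
        placed.append(group[idx])
    return placed
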