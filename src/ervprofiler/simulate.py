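"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study design the pipeline was built for: native
ChIP-seq of a repressive histone mark over endogenous retrovirus (ERV)
copies in wild-type cells and in a knockout of the depositing enzyme, plus
bisulphite clone sequencing and replicate qPCR Ct tables.

The read simulator draws single-end, fixed-length, error-free reads from a
per-base fragment-start weight field:

* uniform ``background_rate`` everywhere,
* ``enrichment_fold x body_profile`` inside element copies (consensus
  coordinates mapped linearly through each copy; minus-strand copies are
  reversed),
* ``enrichment_fold x exp(-d / flank_decay_scale)`` at distance ``d`` from
  the nearest element boundary,

with the element and flank terms multiplied by ``ko_attenuation`` for the
"ko" condition.  Each fragment of length ``read_length +
fragment_extension`` yields one read from its 5' end on a uniformly chosen
strand, so directional 3'-extension by ``fragment_extension`` downstream
reconstructs the fragment.  All generators are bit-reproducible for a fixed
seed and return their ground truth alongside the outputs.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError, PlacementError
from .records import AlignedRead, ElementAnnotation, GenomeSequence, GenomicInterval
from .util import kmer_counts, kmer_occurrences, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def smooth_body_profile(length: int, amplitude: float = 0.8) -> np.ndarray:
    """A smooth nonuniform enrichment profile (mean 1, peaked mid-element).

    One raised-cosine period across the element: relative weight
    ``1 + amplitude`` at the centre, ``1 - amplitude`` at the ends.
    """
    x = np.arange(length)
    return 1.0 + amplitude * np.cos(2.0 * np.pi * (x - length / 2.0) / length)


def ltr_consensus(
    rng: np.random.Generator,
    internal_length: int = 1300,
    ltr_length: int = 350,
    name: str = "ERV_consensus",
) -> GenomeSequence:
    """A provirus-like consensus: identical LTRs flanking an internal region.

    The repeated LTRs reproduce the within-element multi-mapping that real
    proviruses cause.
    """
    ltr = random_sequence(rng, ltr_length)
    internal = random_sequence(rng, internal_length)
    return GenomeSequence(name, ltr + internal + ltr)


@dataclass
class ERVFamilyModel:
    """An ERV family: consensus, enrichment shape and copy parameters."""

    consensus: GenomeSequence
    name: str = "ERV1"
    ltr_length: int = 350
    body_profile: np.ndarray | None = None
    flank_decay_scale: float = 2000.0
    copies: int = 3
    per_copy_divergence: float = 0.02

    def __post_init__(self) -> None:
        if self.body_profile is None:
            self.body_profile = smooth_body_profile(len(self.consensus))
        self.body_profile = np.asarray(self.body_profile, dtype=float)
        if self.body_profile.shape != (len(self.consensus),):
            raise ParameterError("body_profile length must equal consensus length")
        if (self.body_profile < 0).any() or not (self.body_profile > 0).any():
            raise ParameterError("body_profile must be non-negative with a positive entry")
        if not (0.0 <= self.per_copy_divergence < 0.2):
            raise ParameterError("per_copy_divergence must be in [0, 0.2)")
        if self.flank_decay_scale <= 0:
            raise ParameterError("flank_decay_scale must be positive")
        if self.copies < 1:
            raise ParameterError("copies must be >= 1")


@dataclass
class LibraryModel:
    """One sequencing library's depth, fragment geometry and enrichment."""

    n_reads: int = 200_000
    read_length: int = 50
    fragment_extension: int = 150
    background_rate: float = 1.0
    enrichment_fold: float = 10.0
    ko_attenuation: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ParameterError("n_reads must be positive")
        if self.enrichment_fold < 1:
            raise ParameterError("enrichment_fold must be >= 1")
        if not (0 < self.ko_attenuation <= 1):
            raise ParameterError("ko_attenuation must be in (0, 1]")
        if self.background_rate < 0:
            raise ParameterError("background_rate must be >= 0")

    @property
    def fragment_length(self) -> int:
        return self.read_length + self.fragment_extension


@dataclass
class MethylationModel:
    """Bisulphite clone generator parameters."""

    reference: GenomeSequence
    per_cpg_meth_prob: float = 0.9
    conversion_rate: float = 0.995
    n_clones: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.per_cpg_meth_prob, self.conversion_rate):
            if not (0.0 <= p <= 1.0):
                raise ParameterError("probabilities must be in [0, 1]")
        if self.n_clones < 1:
            raise ParameterError("n_clones must be >= 1")


# ---------------------------------------------------------------------------
# Genome construction


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    if rate <= 0:
        return sequence
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


def build_genome(
    families: Sequence[ERVFamilyModel],
    genome_length: int,
    seed: int,
    chrom_name: str = "chr1",
    min_separation: int = 0,
    max_tries: int = 2000,
) -> tuple[GenomeSequence, list[ElementAnnotation]]:
    """A random background genome with mutated element copies planted in it.

    Each copy of each family consensus is substituted (never inserted, so
    the genome length is exact) at a random non-overlapping position on a
    random strand, after per-base mutation at the family's divergence rate.
    Deterministic for a fixed seed.
    """
    total = sum(len(f.consensus) * f.copies for f in families)
    if total >= genome_length / 2:
        raise ParameterError("total planted element length must be < genome_length / 2")
    rng = np.random.default_rng(seed)
    genome = np.frombuffer(
        random_sequence(rng, genome_length).encode("ascii"), dtype=np.uint8
    ).copy()

    placed: list[tuple[int, int]] = []
    annotations: list[ElementAnnotation] = []
    for family in families:
        length = len(family.consensus)
        for _ in range(family.copies):
            for _try in range(max_tries):
                start = int(rng.integers(0, genome_length - length + 1))
                end = start + length
                if all(
                    end + min_separation <= s or e + min_separation <= start
                    for s, e in placed
                ):
                    break
            else:
                raise PlacementError(
                    f"could not place a copy of {family.name} without overlap "
                    f"after {max_tries} tries"
                )
            placed.append((start, end))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            copy_seq = _mutate(rng, family.consensus.sequence, family.per_copy_divergence)
            if strand == "-":
                copy_seq = reverse_complement(copy_seq)
            genome[start:end] = np.frombuffer(copy_seq.encode("ascii"), dtype=np.uint8)
            annotations.append(
                ElementAnnotation(
                    GenomicInterval(chrom_name, start, end, strand),
                    family=family.name,
                    intact=True,
                    divergence=family.per_copy_divergence,
                )
            )
    annotations.sort(key=lambda a: a.interval.start)
    return GenomeSequence(chrom_name, genome.tobytes().decode("ascii")), annotations


# ---------------------------------------------------------------------------
# ChIP read simulation


def condition_weights(
    genome_length: int,
    annotations: Sequence[ElementAnnotation],
    family: ERVFamilyModel,
    library: LibraryModel,
    condition: str,
) -> np.ndarray:
    """The per-base fragment-start weight field for one condition."""
    if condition not in ("wt", "ko"):
        raise ParameterError(f"condition must be 'wt' or 'ko', got {condition!r}")
    atten = library.ko_attenuation if condition == "ko" else 1.0
    weights = np.full(genome_length, float(library.background_rate))
    in_element = np.zeros(genome_length, dtype=bool)
    members = [a for a in annotations if a.family == family.name]
    for a in members:
        s, e = a.interval.start, a.interval.end
        profile = family.body_profile
        if a.interval.strand == "-":
            profile = profile[::-1]
        weights[s:e] += library.enrichment_fold * atten * profile
        in_element[s:e] = True
    cutoff = int(min(8 * family.flank_decay_scale, genome_length))
    distance = np.full(genome_length, np.inf)
    for a in members:
        s, e = a.interval.start, a.interval.end
        lo = max(0, s - cutoff)
        if lo < s:
            distance[lo:s] = np.minimum(distance[lo:s], s - np.arange(lo, s))
        hi = min(genome_length, e + cutoff)
        if e < hi:
            distance[e:hi] = np.minimum(distance[e:hi], np.arange(e, hi) - e + 1)
    distance[in_element] = np.inf
    mask = np.isfinite(distance)
    weights[mask] += (
        library.enrichment_fold * atten * np.exp(-distance[mask] / family.flank_decay_scale)
    )
    return weights


@dataclass
class ChipReadSet:
    """Simulated reads plus their ground truth and true-position alignments.

    ``alignments`` carries one record per read at its true genomic position
    with ``n_hits`` equal to the read sequence's exact occurrence count in
    the genome (either strand) and map quality 37 for unique reads, 0
    otherwise.
    """

    condition: str
    sequences: list[str]
    read_ids: list[str]
    truth: pd.DataFrame
    alignments: list[AlignedRead]

    @property
    def n_unique(self) -> int:
        return sum(1 for r in self.alignments if r.is_unique)


def simulate_chip_reads(
    genome: GenomeSequence,
    annotations: Sequence[ElementAnnotation],
    family: ERVFamilyModel,
    library: LibraryModel,
    condition: str = "wt",
) -> ChipReadSet:
    """Draw a ChIP library from the condition's fragment-start weight field.

    The truth table records, for every read, the fragment start, the read's
    own leftmost coordinate, its strand, and its origin ("element_<i>",
    "flank_<i>" within 7 kb of copy i, or "background").
    """
    L = len(genome)
    rl = library.read_length
    frag = library.fragment_length
    if frag > L:
        raise ParameterError("fragment length exceeds genome length")
    rng = np.random.default_rng([int(library.seed), 0 if condition == "wt" else 1])
    weights = condition_weights(L, annotations, family, library, condition)
    w = weights[: L - frag + 1]
    p = w / w.sum()
    frag_starts = rng.choice(w.size, size=library.n_reads, p=p)
    minus = rng.integers(0, 2, size=library.n_reads).astype(bool)

    members = [a for a in annotations if a.family == family.name]
    origin_label = np.full(L, -1, dtype=np.int32)  # -1 background
    for i, a in enumerate(members):
        s, e = a.interval.start, a.interval.end
        lo, hi = max(0, s - 7000), min(L, e + 7000)
        flank_code = 2 * i + 1
        region = origin_label[lo:hi]
        region[region == -1] = flank_code
        origin_label[lo:hi] = region
    for i, a in enumerate(members):
        s, e = a.interval.start, a.interval.end
        origin_label[s:e] = 2 * i

    seq = genome.sequence
    counts = kmer_counts([genome], rl)
    sequences: list[str] = []
    read_ids: list[str] = []
    alignments: list[AlignedRead] = []
    origins: list[str] = []
    read_starts = np.where(minus, frag_starts + frag - rl, frag_starts)
    for i in range(library.n_reads):
        fs = int(frag_starts[i])
        rs = int(read_starts[i])
        rid = f"r{i:07d}"
        if minus[i]:
            read_seq = reverse_complement(seq[rs : rs + rl])
            strand = "-"
        else:
            read_seq = seq[rs : rs + rl]
            strand = "+"
        occ = kmer_occurrences(counts, read_seq)
        code = int(origin_label[fs])
        if code == -1:
            origin = "background"
        elif code % 2 == 0:
            origin = f"element_{code // 2}"
        else:
            origin = f"flank_{code // 2}"
        sequences.append(read_seq)
        read_ids.append(rid)
        origins.append(origin)
        alignments.append(
            AlignedRead(
                chrom=genome.name,
                start=rs,
                strand=strand,
                read_length=rl,
                map_quality=37 if occ == 1 else 0,
                n_hits=max(occ, 1),
                read_id=rid,
            )
        )
    truth = pd.DataFrame(
        {
            "read_id": read_ids,
            "frag_start": frag_starts.astype(np.int64),
            "read_start": read_starts.astype(np.int64),
            "strand": np.where(minus, "-", "+"),
            "origin": origins,
        }
    )
    return ChipReadSet(condition, sequences, read_ids, truth, alignments)


def expected_body_ratio(
    genome_length: int,
    annotations: Sequence[ElementAnnotation],
    family: ERVFamilyModel,
    library: LibraryModel,
) -> float:
    """Closed-form wt/ko expectation for the mean element-body signal ratio.

    Computed exactly from the two weight fields: the expected share of reads
    whose read (not fragment) lies entirely inside an element body, wt over
    ko.  This is the quantity the consensus metaprofile comparison estimates.
    """
    rl = library.read_length
    frag = library.fragment_length
    members = [a for a in annotations if a.family == family.name]
    ok_plus = np.zeros(genome_length, dtype=bool)
    for a in members:
        s, e = a.interval.start, a.interval.end
        if e - s >= rl:
            ok_plus[s : e - rl + 1] = True
    n_frag = genome_length - frag + 1
    p = np.arange(n_frag)
    q = 0.5 * ok_plus[p] + 0.5 * ok_plus[p + frag - rl]

    shares = {}
    for condition in ("wt", "ko"):
        w = condition_weights(genome_length, annotations, family, library, condition)[:n_frag]
        shares[condition] = float((w * q).sum() / w.sum())
    return shares["wt"] / shares["ko"]


# ---------------------------------------------------------------------------
# Bisulphite clones


@dataclass
class BisulfiteCloneSet:
    clones: list[GenomeSequence]
    truth: pd.DataFrame           # clones x CpG positions, True = methylated
    cpg_sites: np.ndarray


def simulate_bisulfite_clones(model: MethylationModel) -> BisulfiteCloneSet:
    """Simulate bisulphite-converted clone sequences with known methylation.

    Each CpG cytosine is methylated with ``per_cpg_meth_prob`` and then
    protected from conversion; every other cytosine converts to T with
    probability ``conversion_rate`` (incomplete conversion leaves a C).
    """
    ref = model.reference.sequence
    sites = [
        i for i in range(len(ref) - 1) if ref[i] == "C" and ref[i + 1] == "G"
    ]
    if not sites:
        raise DegenerateInputError("reference contains no CpG site")
    site_arr = np.array(sites, dtype=np.int64)
    c_positions = np.array([i for i, b in enumerate(ref) if b == "C"], dtype=np.int64)
    site_set = set(sites)
    rng = np.random.default_rng(model.seed)

    clones: list[GenomeSequence] = []
    truth_rows = np.zeros((model.n_clones, site_arr.size), dtype=bool)
    for k in range(model.n_clones):
        methylated = rng.random(site_arr.size) < model.per_cpg_meth_prob
        truth_rows[k] = methylated
        protected = {int(site_arr[j]) for j in np.nonzero(methylated)[0]}
        arr = np.frombuffer(ref.encode("ascii"), dtype=np.uint8).copy()
        convert = rng.random(c_positions.size) < model.conversion_rate
        for pos, conv in zip(c_positions, convert):
            pos = int(pos)
            if pos in protected:
                continue
            if conv:
                arr[pos] = ord("T")
        clones.append(
            GenomeSequence(f"clone_{k:03d}", arr.tobytes().decode("ascii"))
        )
    truth = pd.DataFrame(
        truth_rows,
        index=[c.name for c in clones],
        columns=[int(s) for s in site_arr],
    )
    return BisulfiteCloneSet(clones, truth, site_arr)


# ---------------------------------------------------------------------------
# qPCR Ct tables


def simulate_ct_table(
    true_folds: Mapping[str, float],
    replicates: int = 3,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    target: str = "target",
    reference_gene: str = "Actb",
    target_baseline_ct: float = 24.0,
    reference_ct: float = 16.0,
) -> pd.DataFrame:
    """Replicate Ct values for a target and a reference gene per sample.

    Target Ct = baseline - log2(fold) + Gaussian noise; the reference gene
    sits at a constant Ct (+ noise).  The sample whose fold is 1 plays the
    control in downstream ddCt analysis.  Deterministic given the seed.
    """
    if replicates < 2:
        raise ParameterError("replicates must be >= 2")
    if any(f <= 0 for f in true_folds.values()):
        raise ParameterError("folds must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, fold in true_folds.items():
        for gene, base in (
            (target, target_baseline_ct - float(np.log2(fold))),
            (reference_gene, reference_ct),
        ):
            noise = rng.normal(0.0, ct_noise_sd, size=replicates) if ct_noise_sd > 0 else np.zeros(replicates)
            for rep in range(replicates):
                rows.append(
                    {"sample": sample, "target": gene, "replicate": rep + 1,
                     "ct": base + float(noise[rep])}
                )
    return pd.DataFrame(rows)
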