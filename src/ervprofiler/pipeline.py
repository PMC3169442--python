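"""End-to-end synthetic studies: genome -> reads -> profiles -> summaries.

These functions wire the generators and the analysis stages together under
a single top-level seed and return everything a report needs.  They are the
package's reference workflows; the examples and the acceptance script are
thin wrappers around them.

Two ChIP studies are provided because the two analyses live in different
coverage regimes (scales discussed in docs/methods.md):

* :func:`consensus_study` — a compact genome (80 kb) so that element-derived
  reads dominate and the consensus metaprofile is well determined at the
  default depth;
* :func:`flank_study` — a large genome (4 Mb) so that per-position read
  multiplicity stays low and the positional deduplication step of the flank
  analysis operates in its intended regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .bisulfite import bin_clones, call_clone, filter_clones, MethylationBinning
from .consensus import (
    ConditionComparison,
    ConsensusProfile,
    assign_multimappers,
    compare_conditions,
    profile_consensus,
)
from .flanks import (
    FlankDecayFit,
    FlankProfile,
    agglomerate_flanks,
    dedup_reads,
    filter_flank_reads,
    fit_flank_decay,
    mappability_profile,
    select_intact_elements,
)
from .io import enumerate_placements
from .records import ElementAnnotation, GenomeSequence, GenomicInterval
from .simulate import (
    ChipReadSet,
    ERVFamilyModel,
    LibraryModel,
    MethylationModel,
    build_genome,
    expected_body_ratio,
    ltr_consensus,
    random_sequence,
    simulate_bisulfite_clones,
    simulate_chip_reads,
    simulate_ct_table,
)
from .qpcr import delta_delta_ct
from .util import child_seeds


@dataclass
class ConsensusStudy:
    family: ERVFamilyModel
    genome: GenomeSequence
    annotations: list[ElementAnnotation]
    readsets: dict[str, ChipReadSet]
    profiles: dict[str, ConsensusProfile]
    comparison: ConditionComparison
    expected_ratio: float
    shape_correlation: float


def consensus_study(
    seed: int,
    n_reads: int = 200_000,
    genome_length: int = 80_000,
    internal_length: int = 1_300,
    ltr_length: int = 350,
    copies: int = 3,
    divergence: float = 0.02,
    enrichment_fold: float = 10.0,
    ko_attenuation: float = 0.1,
    extension: int = 150,
    bin_width: int = 10,
    max_mismatches: int = 2,
) -> ConsensusStudy:
    """Simulate wt and ko libraries, align reads to the family consensus with
    the minimal aligner, resolve multi-mappers, and build both metaprofiles.

    ``shape_correlation`` is the Pearson correlation between the wt profile
    and the planted body profile (both averaged per bin);
    ``expected_ratio`` is the generator's closed-form wt/ko expectation for
    the mean body signal.
    """
    seeds = child_seeds(seed, 6)
    rng = np.random.default_rng(seeds[0])
    consensus = ltr_consensus(rng, internal_length, ltr_length)
    family = ERVFamilyModel(
        consensus=consensus, ltr_length=ltr_length, copies=copies,
        per_copy_divergence=divergence,
    )
    genome, annotations = build_genome(
        [family], genome_length, seed=seeds[1], min_separation=500
    )
    library = LibraryModel(
        n_reads=n_reads, fragment_extension=extension,
        enrichment_fold=enrichment_fold, ko_attenuation=ko_attenuation,
        seed=seeds[2],
    )

    readsets: dict[str, ChipReadSet] = {}
    profiles: dict[str, ConsensusProfile] = {}
    for condition in ("wt", "ko"):
        rs = simulate_chip_reads(genome, annotations, family, library, condition)
        groups, _unmapped = enumerate_placements(
            rs.sequences, consensus, max_mismatches=max_mismatches,
            read_ids=rs.read_ids,
        )
        placements = assign_multimappers(groups, seed=seeds[3])
        profiles[condition] = profile_consensus(
            placements, len(consensus), library_size=rs.n_unique,
            extension=extension, bin_width=bin_width,
            consensus_name=consensus.name,
        )
        readsets[condition] = rs

    comparison = compare_conditions(profiles["wt"], profiles["ko"])
    expected = expected_body_ratio(genome_length, annotations, family, library)

    planted = family.body_profile
    n_bins = len(profiles["wt"].values)
    padded = np.zeros(n_bins * bin_width)
    padded[: planted.size] = planted
    planted_binned = padded.reshape(n_bins, bin_width).mean(axis=1)
    shape_corr = float(np.corrcoef(planted_binned, profiles["wt"].values)[0, 1])

    return ConsensusStudy(
        family=family, genome=genome, annotations=annotations,
        readsets=readsets, profiles=profiles, comparison=comparison,
        expected_ratio=expected, shape_correlation=shape_corr,
    )


@dataclass
class FlankStudy:
    family: ERVFamilyModel
    genome: GenomeSequence
    annotations: list[ElementAnnotation]
    elements: list[ElementAnnotation]
    profiles: dict[str, FlankProfile]
    fit: FlankDecayFit
    binned: dict[str, np.ndarray]
    bin_centers: np.ndarray
    spearman: float
    mappability_mean: float


def flank_study(
    seed: int,
    n_reads: int = 200_000,
    genome_length: int = 4_000_000,
    internal_length: int = 1_300,
    ltr_length: int = 350,
    copies: int = 12,
    divergence: float = 0.02,
    enrichment_fold: float = 10.0,
    ko_attenuation: float = 0.1,
    flank_decay_scale: float = 2_000.0,
    flank_size: int = 7_000,
    min_quality: int = 7,
    extension: int = 150,
    bin_width: int = 250,
    check_mappability: bool = True,
) -> FlankStudy:
    """Simulate wt and ko libraries on a large genome and run the full flank
    pipeline: quality/uniqueness filter -> positional dedup -> intact-element
    selection -> agglomeration -> exponential decay fit.

    The genome-wide alignments come from the generator's true-position
    records (exact-occurrence ``n_hits``), standing in for a genome-scale
    aligner run.
    """
    seeds = child_seeds(seed, 6)
    rng = np.random.default_rng(seeds[0])
    consensus = ltr_consensus(rng, internal_length, ltr_length)
    family = ERVFamilyModel(
        consensus=consensus, ltr_length=ltr_length, copies=copies,
        per_copy_divergence=divergence, flank_decay_scale=flank_decay_scale,
    )
    genome, annotations = build_genome(
        [family], genome_length, seed=seeds[1],
        min_separation=2 * flank_size + 2_000,
    )
    library = LibraryModel(
        n_reads=n_reads, fragment_extension=extension,
        enrichment_fold=enrichment_fold, ko_attenuation=ko_attenuation,
        seed=seeds[2],
    )
    elements = select_intact_elements(
        annotations, min_length=len(consensus) // 2, max_divergence=0.1
    )

    profiles: dict[str, FlankProfile] = {}
    binned: dict[str, np.ndarray] = {}
    for condition in ("wt", "ko"):
        rs = simulate_chip_reads(genome, annotations, family, library, condition)
        reads = filter_flank_reads(rs.alignments, min_quality=min_quality)
        reads = dedup_reads(reads)
        profile = agglomerate_flanks(
            reads, elements, library_size=len(rs.alignments),
            flank_size=flank_size, extension=extension,
        )
        profiles[condition] = profile
        _, density = profile.distance_profile()
        n_bins = flank_size // bin_width
        binned[condition] = (
            density[: n_bins * bin_width].reshape(n_bins, bin_width).mean(axis=1)
        )

    fit = fit_flank_decay(
        profiles["wt"], bin_width=bin_width,
        min_distance=library.fragment_length,
    )
    rho = float(
        _stats.spearmanr(fit.bin_centers, binned["wt"]).statistic
    )
    mean_mappability = float("nan")
    if check_mappability:
        windows = []
        for e in elements:
            iv = e.interval
            windows.append(
                GenomicInterval(iv.chrom, max(0, iv.start - flank_size), iv.start)
            )
            windows.append(GenomicInterval(iv.chrom, iv.end, iv.end + flank_size))
        mean_mappability = float(
            np.nanmean(mappability_profile(genome, library.read_length, windows))
        )
    return FlankStudy(
        family=family, genome=genome, annotations=annotations,
        elements=elements, profiles=profiles, fit=fit, binned=binned,
        bin_centers=fit.bin_centers, spearman=rho,
        mappability_mean=mean_mappability,
    )


@dataclass
class MethylationStudy:
    reference: GenomeSequence
    binning: MethylationBinning
    n_clones: dict[str, int]
    qc_total: int
    qc_removed: int


def methylation_study(
    seed: int,
    n_clones: int = 100,
    reference_length: int = 600,
    meth_probs: dict[str, float] | None = None,
    conversion_rate: float = 0.995,
    qc_conversion_rate: float = 0.95,
    qc_n_clones: int = 200,
) -> MethylationStudy:
    """Bisulphite workflow on two simulated cell lines plus a conversion-QC run.

    ``meth_probs`` defaults to a densely methylated wild type (0.9) versus a
    partially demethylated knockout line (0.6).  The QC run simulates a
    poorly converted batch and reports how many clones the strict >98%
    conversion filter removes.
    """
    if meth_probs is None:
        meth_probs = {"wt": 0.9, "hp1a_ko": 0.6}
    seeds = child_seeds(seed, 4 + len(meth_probs))
    rng = np.random.default_rng(seeds[0])
    while True:
        reference = GenomeSequence("amplicon", random_sequence(rng, reference_length))
        n_cpg = sum(
            1
            for i in range(reference_length - 1)
            if reference.sequence[i] == "C" and reference.sequence[i + 1] == "G"
        )
        if n_cpg >= 10:
            break

    samples = {}
    for k, (name, prob) in enumerate(meth_probs.items()):
        model = MethylationModel(
            reference=reference, per_cpg_meth_prob=prob,
            conversion_rate=conversion_rate, n_clones=n_clones, seed=seeds[2 + k],
        )
        clone_set = simulate_bisulfite_clones(model)
        called = [
            call_clone(c.sequence, reference, clone_id=c.name)
            for c in clone_set.clones
        ]
        samples[name] = filter_clones(called)

    binning = bin_clones(samples)

    qc_model = MethylationModel(
        reference=reference, per_cpg_meth_prob=0.5,
        conversion_rate=qc_conversion_rate, n_clones=qc_n_clones, seed=seeds[1],
    )
    qc_set = simulate_bisulfite_clones(qc_model)
    qc_called = [
        call_clone(c.sequence, reference, clone_id=c.name) for c in qc_set.clones
    ]
    qc_kept = filter_clones(qc_called)
    return MethylationStudy(
        reference=reference, binning=binning,
        n_clones={k: len(v) for k, v in samples.items()},
        qc_total=qc_n_clones, qc_removed=qc_n_clones - len(qc_kept),
    )


@dataclass
class QpcrStudy:
    noiseless: pd.DataFrame
    noisy: pd.DataFrame
    fold_noiseless: float
    fold_noisy: float


def qpcr_study(
    seed: int,
    noiseless_fold: float = 8.0,
    noisy_fold: float = 47.0,
    ct_noise_sd: float = 0.05,
    replicates: int = 3,
) -> QpcrStudy:
    """Recover planted expression folds through the ddCt analysis.

    The noiseless run plants an 8-fold upregulation (exactly 3 Ct cycles);
    the noisy run plants a 47-fold upregulation — the magnitude reported for
    the most strongly derepressed ERV family in the enzyme knockout — with
    replicate Ct noise.
    """
    seeds = child_seeds(seed, 2)
    table0 = simulate_ct_table(
        {"wt": 1.0, "setdb1_ko": noiseless_fold}, replicates=replicates,
        ct_noise_sd=0.0, seed=seeds[0],
    )
    result0 = delta_delta_ct(table0, "target", "Actb", "wt")
    table1 = simulate_ct_table(
        {"wt": 1.0, "setdb1_ko": noisy_fold}, replicates=replicates,
        ct_noise_sd=ct_noise_sd, seed=seeds[1],
    )
    result1 = delta_delta_ct(table1, "target", "Actb", "wt")
    fold0 = float(result0.loc[result0["sample"] == "setdb1_ko", "fold"].iloc[0])
    fold1 = float(result1.loc[result1["sample"] == "setdb1_ko", "fold"].iloc[0])
    return QpcrStudy(
        noiseless=result0, noisy=result1,
        fold_noiseless=fold0, fold_noisy=fold1,
    )
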