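import numpy as np
import pytest

from ervprofiler import (
    AlignmentError,
    DataError,
    DegenerateInputError,
    GenomeSequence,
    MethylationModel,
    ParameterError,
    StrandError,
    bin_clones,
    call_clone,
    cpg_positions,
    filter_clones,
    insilico_pcr,
    methylation_matrix,
    simulate_bisulfite_clones,
)
from ervprofiler.simulate import random_sequence
from ervprofiler.util import reverse_complement

from _oracles import pcr_products


REF = GenomeSequence("amp", "TTCGATCCATCGGACGTACCTT")
# CpGs at 2, 10, 14; non-CpG Cs at 6, 7, 18, 19


def _bisulfite_image(meth_sites=(), unconverted=()):
    """The fully converted clone of REF except methylated/unconverted Cs."""
    seq = list(REF.sequence)
    for i, b in enumerate(seq):
        if b == "C" and i not in meth_sites and i not in unconverted:
            seq[i] = "T"
    return "".join(seq)


class TestCallClone:
    def test_reference_cpg_positions(self):
        assert cpg_positions(REF).tolist() == [2, 10, 14]

    def test_fully_converted_clone_is_unmethylated(self):
        clone = call_clone(_bisulfite_image(), REF)
        assert clone.calls.tolist() == [0, 0, 0]
        assert clone.conversion_rate == 1.0

    def test_unconverted_clone_is_fully_methylated_with_zero_conversion(self):
        clone = call_clone(REF.sequence, REF)
        assert clone.calls.tolist() == [1, 1, 1]
        assert clone.conversion_rate == 0.0

    def test_mixed_calls_and_partial_conversion(self):
        seq = _bisulfite_image(meth_sites=(2, 14), unconverted=(6,))
        clone = call_clone(seq, REF)
        assert clone.calls.tolist() == [1, 0, 1]
        assert clone.conversion_rate == pytest.approx(3 / 4)

    def test_ambiguous_base_at_cpg_is_missing(self):
        seq = list(_bisulfite_image())
        seq[10] = "N"
        clone = call_clone("".join(seq), REF)
        assert clone.calls.tolist() == [0, -1, 0]
        assert clone.methylated_fraction == 0.0

    def test_length_mismatch_is_an_alignment_error(self):
        with pytest.raises(AlignmentError):
            call_clone(REF.sequence[:-1], REF)

    def test_reference_without_cpg_is_degenerate(self):
        ref = GenomeSequence("flat", "ATATCATTACAT")
        with pytest.raises(DegenerateInputError):
            call_clone(ref.sequence, ref)

    def test_opposite_strand_clone_is_rejected(self):
        rng = np.random.default_rng(0)
        ref = GenomeSequence("amp2", random_sequence(rng, 200))
        minus = reverse_complement(ref.sequence)
        converted_minus = minus.replace("C", "T")  # bisulfite of the - strand
        image = reverse_complement(converted_minus)  # G->A in + coordinates
        with pytest.raises(StrandError):
            call_clone(image, ref)

    def test_simulated_clones_recover_the_planted_methylation_level(self):
        rng = np.random.default_rng(1)
        ref = GenomeSequence("amp3", random_sequence(rng, 500))
        model = MethylationModel(ref, 0.5, 1.0, n_clones=200, seed=2)
        result = simulate_bisulfite_clones(model)
        clones = [call_clone(c.sequence, ref, c.name) for c in result.clones]
        fractions = [c.methylated_fraction for c in clones]
        n_cpg = clones[0].n_cpg
        sd = np.sqrt(0.25 / (n_cpg * len(clones)))
        assert abs(np.mean(fractions) - 0.5) < 3 * sd
        # calls must agree with the generator's truth matrix exactly
        called = np.array([c.calls for c in clones])
        assert np.array_equal(called == 1, result.truth.to_numpy())


class TestFilterClones:
    def _clone(self, rate):
        clone = call_clone(_bisulfite_image(), REF)
        clone.conversion_rate = rate
        return clone

    def test_threshold_is_strict(self):
        assert filter_clones([self._clone(0.98)], 0.98) == []

    def test_above_threshold_is_kept(self):
        clone = self._clone(0.995)
        assert filter_clones([clone], 0.98) == [clone]

    def test_nan_conversion_never_passes(self):
        assert filter_clones([self._clone(float("nan"))], 0.98) == []


class TestBinClones:
    def _clone_with_fraction(self, frac, n_cpg=10):
        clone = call_clone(_bisulfite_image(), REF)
        n_meth = round(frac * n_cpg)
        clone.calls = np.array([1] * n_meth + [0] * (n_cpg - n_meth), dtype=np.int8)
        clone.n_cpg = n_cpg
        return clone

    def test_fully_methylated_sample_lands_in_the_top_bin(self):
        binning = bin_clones({"wt": [self._clone_with_fraction(1.0)] * 5})
        assert binning.percentages.loc["wt"].tolist() == [0, 0, 0, 100]

    def test_one_clone_per_quartile(self):
        clones = [self._clone_with_fraction(f) for f in (0.1, 0.3, 0.6, 0.9)]
        binning = bin_clones({"s": clones})
        assert binning.percentages.loc["s"].tolist() == [25, 25, 25, 25]

    def test_boundary_fraction_goes_to_the_lower_bin(self):
        # bins are [0,.25], (.25,.5], ... : a score of exactly 0.25 is bin 1
        clones = [self._clone_with_fraction(0.25, n_cpg=4)]
        binning = bin_clones({"s": clones})
        assert binning.percentages.loc["s"].tolist() == [100, 0, 0, 0]

    def test_percentages_sum_to_100_and_are_order_invariant(self, rng):
        clones = [
            self._clone_with_fraction(float(rng.integers(0, 11)) / 10)
            for _ in range(57)
        ]
        a = bin_clones({"s": clones}).percentages
        b = bin_clones({"s": clones[::-1]}).percentages
        assert a.loc["s"].sum() == pytest.approx(100.0)
        assert a.equals(b)

    def test_zero_called_clone_is_excluded_with_warning(self, caplog):
        good = self._clone_with_fraction(0.9)
        empty = self._clone_with_fraction(0.0)
        empty.calls = np.full(3, -1, dtype=np.int8)
        binning = bin_clones({"s": [good, empty]})
        assert binning.n_excluded["s"] == 1
        assert binning.n_clones["s"] == 1

    def test_invalid_edges_are_rejected(self):
        with pytest.raises(ParameterError):
            bin_clones({"s": [self._clone_with_fraction(0.5)]}, bin_edges=(0.5, 0.25))

    def test_matrix_export_shape(self):
        clones = [self._clone_with_fraction(f) for f in (0.0, 1.0)]
        for i, c in enumerate(clones):
            c.clone_id = f"c{i}"
            c.calls = np.array([1, -1, 0], dtype=np.int8)
        matrix = methylation_matrix(clones)
        assert matrix.shape == (2, 3)
        assert np.isnan(matrix.iloc[0, 1])


class TestInsilicoPcr:
    def _planted_genome(self, spacings, seed=0):
        rng = np.random.default_rng(seed)
        fwd = random_sequence(rng, 20)
        rev = random_sequence(rng, 20)
        parts = [random_sequence(rng, 200)]
        sites = []
        pos = 200
        for gap in spacings:
            insert = fwd + random_sequence(rng, gap) + reverse_complement(rev)
            parts.append(insert)
            sites.append((pos, pos + len(insert)))
            pos += len(insert)
            filler = random_sequence(rng, 300)
            parts.append(filler)
            pos += 300
        return GenomeSequence("g", "".join(parts)), fwd, rev, sites

    def test_three_planted_sites_are_found_exactly(self):
        genome, fwd, rev, sites = self._planted_genome([100, 150, 200])
        products = insilico_pcr(genome, fwd, rev, max_product=400)
        assert [(p.start, p.end) for p in products] == sites
        assert all(p.strand == "+" for p in products)

    def test_products_longer_than_max_product_are_not_reported(self):
        genome, fwd, rev, _ = self._planted_genome([300])
        assert insilico_pcr(genome, fwd, rev, max_product=200) == []

    def test_minus_strand_products_are_detected(self):
        genome, fwd, rev, sites = self._planted_genome([120], seed=3)
        flipped = genome.reverse_complement()
        products = insilico_pcr(flipped, fwd, rev, max_product=400)
        (site,) = sites
        L = len(genome)
        assert [(p.start, p.end, p.strand) for p in products] == [
            (L - site[1], L - site[0], "-")
        ]

    def test_short_primers_are_rejected(self):
        genome = GenomeSequence("g", "A" * 100)
        with pytest.raises(ParameterError):
            insilico_pcr(genome, "ACGTACGT", "ACGTACGTACGTACG", 50)

    @pytest.mark.parametrize("max_mismatches", [0, 1])
    def test_matches_brute_force_double_loop(self, max_mismatches):
        for seed in range(8):
            genome, fwd, rev, _ = self._planted_genome([80, 140], seed=seed)
            products = insilico_pcr(
                genome, fwd, rev, max_product=300, max_mismatches=max_mismatches
            )
            got = [(p.chrom, p.start, p.end, p.strand) for p in products]
            assert got == pcr_products(genome, fwd, rev, 300, max_mismatches)
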