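import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dolphin.alignment_io import AlignedSequence, DomainAlignment, TaxonomyMap
from dolphin.alphabet import AA_INDEX, AMINO_ACIDS
from dolphin.errors import (
    BackgroundError,
    OutOfRangeError,
    ParameterError,
    UnsupportedResidueError,
)
from dolphin.scoring import (
    CountMatrix,
    build_domain_matrix,
    build_matrix,
    corrected_frequency,
    count_matrix,
    load_matrix,
    relative_frequency,
    save_matrix,
    score_matrix,
    substitution_scores,
)

from .conftest import random_alignment
from .oracle import brute_delta, brute_scores


def column_alignment(chars: str) -> DomainAlignment:
    """One-column alignment from a string of per-row characters."""
    return DomainAlignment(
        "COL", tuple(AlignedSequence(f"r{i}", ch) for i, ch in enumerate(chars))
    )


class TestCountMatrix:
    def test_pure_column_with_gaps(self):
        aln = column_alignment("C" * 10 + "--")
        C = count_matrix(aln)
        assert C.counts[0, AA_INDEX["C"]] == 10
        assert C.counts[0].sum() == 10  # gaps nowhere

    def test_all_gap_column_is_zero(self):
        C = count_matrix(column_alignment("----"))
        assert C.counts.sum() == 0

    def test_ambiguity_codes_count_nowhere(self):
        C = count_matrix(column_alignment("AXBZ"))
        assert C.counts[0].sum() == 1  # only the 'A'

    def test_matches_nested_loop_tally(self, toy_alignment):
        C = count_matrix(toy_alignment)
        rows = [s.residues for s in toy_alignment.sequences]
        expected = brute_counts_matrix(rows)
        assert (C.counts == expected).all()


def brute_counts_matrix(rows):
    out = np.zeros((len(rows[0]), 20), dtype=int)
    for row in rows:
        for p, ch in enumerate(row):
            if ch in AA_INDEX:
                out[p, AA_INDEX[ch]] += 1
    return out


class TestCorrectedFrequency:
    def test_all_gap_column_collapses_to_background(self, bg):
        C = count_matrix(column_alignment("---"))
        Fp = corrected_frequency(C, bg, 1.0)
        assert np.allclose(Fp[0], bg.as_vector(), atol=0, rtol=0)

    def test_hand_plugged_formula(self, bg):
        """C(p,'A')=10 others 0, c=1: F'A=(10+fA)/11, F'l=fl/11."""
        C = count_matrix(column_alignment("A" * 10))
        Fp = corrected_frequency(C, bg, 1.0)
        f = bg.as_vector()
        iA = AA_INDEX["A"]
        assert Fp[0, iA] == pytest.approx((10 + f[iA]) / 11, abs=1e-15)
        for i in range(20):
            if i != iA:
                assert Fp[0, i] == pytest.approx(f[i] / 11, abs=1e-15)

    def test_rows_sum_to_one(self, bg):
        rng = np.random.default_rng(5)
        aln = random_alignment(rng, n=7, length=12)
        Fp = corrected_frequency(count_matrix(aln), bg, 1.0)
        assert np.allclose(Fp.sum(axis=1), 1.0, atol=1e-9)

    def test_rejects_nonpositive_pseudocount(self, bg):
        C = count_matrix(column_alignment("A"))
        with pytest.raises(ParameterError):
            corrected_frequency(C, bg, 0.0)


class TestRelativeFrequency:
    def test_all_gap_column_is_one(self, bg):
        C = count_matrix(column_alignment("--"))
        Fs = relative_frequency(corrected_frequency(C, bg, 1.0), bg)
        assert np.allclose(Fs[0], 1.0, atol=1e-12)

    def test_ratio_definition(self, bg):
        Fp = 2.0 * bg.as_vector()[None, :]
        Fs = relative_frequency(Fp, bg)
        assert np.allclose(Fs, 2.0, atol=1e-12)

    def test_elementwise_hand_division(self, bg, toy_alignment):
        Fp = corrected_frequency(count_matrix(toy_alignment), bg, 1.0)
        Fs = relative_frequency(Fp, bg)
        f = bg.as_vector()
        for p in range(toy_alignment.length):
            for i in range(20):
                assert Fs[p, i] == pytest.approx(Fp[p, i] / f[i], rel=1e-15)

    def test_background_mismatch_rejected(self, bg, uniform_bg):
        Fp = corrected_frequency(count_matrix(column_alignment("A")), bg, 1.0)
        with pytest.raises(BackgroundError):
            relative_frequency(Fp, uniform_bg, built_with=bg.source)


class TestScoreMatrix:
    def test_all_gap_column_scores_zero(self, bg):
        M = build_matrix(column_alignment("---"), bg)
        assert np.allclose(M.scores[0], 0.0, atol=1e-12)

    def test_log_of_e_is_one(self, bg):
        Fs = np.full((1, 20), math.e)
        M = score_matrix(Fs, background_source=bg.source)
        assert np.allclose(M.scores, 1.0, atol=1e-15)

    def test_conserved_column_closed_form(self, bg):
        """10-row pure-C column: M(p,C) = ln(((10+fC)/11)/fC) with the
        pinned background, evaluated independently here."""
        M = build_matrix(column_alignment("C" * 10), bg)
        fC = bg["C"]
        expected = math.log(((10 + fC) / 11) / fC)
        assert M.score(1, "C") == pytest.approx(expected, abs=1e-12)
        # and any unseen letter is penalized: ln((f_l/11)/f_l) = ln(1/11)
        assert M.score(1, "Y") == pytest.approx(math.log(1 / 11), abs=1e-12)

    def test_sign_matches_enrichment(self, bg):
        M = build_matrix(column_alignment("CCCCA"), bg)
        assert M.score(1, "C") > 0  # enriched over background
        assert M.score(1, "W") < 0  # depleted


class TestSubstitutionScores:
    def test_wt_equals_mut_gives_zero_delta(self, bg, toy_alignment):
        M = build_matrix(toy_alignment, bg)
        s = substitution_scores(M, 2, "C", "C")
        assert s.delta == 0.0

    def test_all_gap_column_all_zero(self, bg):
        M = build_matrix(column_alignment("--"), bg)
        s = substitution_scores(M, 1, "C", "Y")
        assert s.wt_score == s.mut_score == s.delta == 0.0

    def test_conserved_column_strong_negative_delta(self, bg):
        M = build_matrix(column_alignment("C" * 10), bg)
        s = substitution_scores(M, 1, "C", "Y")
        fC = bg["C"]
        assert s.wt_score == pytest.approx(math.log(((10 + fC) / 11) / fC), abs=1e-12)
        assert s.mut_score == pytest.approx(math.log(1 / 11), abs=1e-12)
        assert s.wt_score > 0 > s.mut_score
        assert s.delta == pytest.approx(s.mut_score - s.wt_score, abs=0)

    def test_rejects_bad_letters_and_columns(self, bg, toy_alignment):
        M = build_matrix(toy_alignment, bg)
        with pytest.raises(UnsupportedResidueError):
            substitution_scores(M, 1, "X", "A")
        with pytest.raises(UnsupportedResidueError):
            substitution_scores(M, 1, "A", "*")
        with pytest.raises(OutOfRangeError):
            substitution_scores(M, 99, "A", "C")


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_all_four_matrices_and_delta(self, bg, seed):
        """Package vs independent loop implementation on random 5x8
        alignments, exact to 1e-12."""
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n=5, length=8)
        rows = [s.residues for s in aln.sequences]
        bgd = {aa: bg[aa] for aa in AMINO_ACIDS}
        oc, ofp, ofs, om = brute_scores(rows, AMINO_ACIDS, bgd, 1.0)
        C = count_matrix(aln)
        M = build_matrix(aln, bg)
        for p in range(aln.length):
            for aa in AMINO_ACIDS:
                i = AA_INDEX[aa]
                assert C.counts[p, i] == oc[p][aa]
                assert M.corrected_freq[p, i] == pytest.approx(ofp[p][aa], abs=1e-12)
                assert M.relative_freq[p, i] == pytest.approx(ofs[p][aa], abs=1e-12)
                assert M.scores[p, i] == pytest.approx(om[p][aa], abs=1e-12)
        s = substitution_scores(M, 3, "A", "W")
        assert s.delta == pytest.approx(brute_delta(om, 2, "A", "W"), abs=1e-12)


class TestProperties:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_delta_antisymmetry(self, bg, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n=6, length=5)
        M = build_matrix(aln, bg)
        p = 1 + int(rng.integers(aln.length))
        wt, mut = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
        fwd = substitution_scores(M, p, str(wt), str(mut)).delta
        rev = substitution_scores(M, p, str(mut), str(wt)).delta
        assert fwd == pytest.approx(-rev, abs=1e-15)

    def test_monotonicity_in_counts(self, bg):
        """One more observation of l at p raises M(p,l), lowers others."""
        base = count_matrix(column_alignment("ACDE"))
        bumped = CountMatrix(
            counts=base.counts + np.eye(1, 20, AA_INDEX["C"], dtype=np.int64),
            n_rows=base.n_rows + 1,
        )
        M0 = score_matrix(relative_frequency(corrected_frequency(base, bg), bg))
        M1 = score_matrix(relative_frequency(corrected_frequency(bumped, bg), bg))
        iC = AA_INDEX["C"]
        assert M1.scores[0, iC] > M0.scores[0, iC]
        others = [i for i in range(20) if i != iC]
        assert (M1.scores[0, others] < M0.scores[0, others]).all()

    def test_pseudo_count_limit(self, bg):
        """Large counts with fixed composition: M -> ln(fraction/f_l)."""
        n = 10_000
        comp = {"A": 0.5, "C": 0.3, "W": 0.2}
        counts = np.zeros((1, 20), dtype=np.int64)
        for aa, frac in comp.items():
            counts[0, AA_INDEX[aa]] = int(n * frac)
        C = CountMatrix(counts=counts, n_rows=n)
        M = score_matrix(relative_frequency(corrected_frequency(C, bg), bg))
        for aa, frac in comp.items():
            limit = math.log(frac / bg[aa])
            assert M.scores[0, AA_INDEX[aa]] == pytest.approx(limit, abs=1e-3)


class TestPipelineAndPersistence:
    def test_build_domain_matrix_equals_manual_composition(self, tmp_path, bg, toy_alignment, toy_taxonomy):
        from dolphin.alignment_io import filter_taxa, write_stockholm

        path = tmp_path / "toy.sto"
        write_stockholm(toy_alignment, path)
        M = build_domain_matrix(path, toy_taxonomy, bg, keep="eukaryota")
        manual = build_matrix(filter_taxa(toy_alignment, toy_taxonomy, "eukaryota"), bg)
        assert np.array_equal(M.scores, manual.scores)

    def test_taxon_filter_changes_matrix(self, tmp_path, bg, toy_alignment, toy_taxonomy):
        from dolphin.alignment_io import write_stockholm

        path = tmp_path / "toy.sto"
        write_stockholm(toy_alignment, path)
        filtered = build_domain_matrix(path, toy_taxonomy, bg, keep="eukaryota")
        unfiltered = build_domain_matrix(path, toy_taxonomy, bg, keep=None)
        assert not np.array_equal(filtered.scores, unfiltered.scores)
        # per-stage oracle on the unfiltered alignment
        rows = [s.residues for s in toy_alignment.sequences]
        bgd = {aa: bg[aa] for aa in AMINO_ACIDS}
        _, _, _, om = brute_scores(rows, AMINO_ACIDS, bgd, 1.0)
        for p in range(toy_alignment.length):
            for aa in AMINO_ACIDS:
                assert unfiltered.scores[p, AA_INDEX[aa]] == pytest.approx(
                    om[p][aa], abs=1e-12
                )

    def test_matrix_round_trip(self, tmp_path, bg, toy_alignment):
        M = build_matrix(toy_alignment, bg)
        path = tmp_path / "m.tsv"
        save_matrix(M, path)
        again = load_matrix(path)
        assert again.domain_id == M.domain_id
        assert again.pseudo_count == M.pseudo_count
        assert again.background_source == M.background_source
        assert np.array_equal(again.scores, M.scores)
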