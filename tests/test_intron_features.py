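"""Intron characteristics: AU content, borders, PWM scores, comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicescape.annotation_model import Intron
from splicescape.genome import DictGenome
from splicescape.intron_features import (
    ACCEPTOR_WINDOW,
    DONOR_WINDOW,
    au_richness,
    border_dinucleotides,
    compare_groups,
    compute_intron_features,
    gc_fraction,
    score_sequence,
    splice_site_score,
    summarize_introns,
    train_pwm,
)


class TestAuRichness:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATAT", 1.0), ("GCGC", 0.0), ("GTAG", 0.5), ("AUAU", 1.0), ("ANT", 1.0)],
    )
    def test_values(self, seq, expected):
        assert au_richness(seq) == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            au_richness("")

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=200))
    def test_au_plus_gc_is_one_for_n_free_sequence(self, seq):
        assert au_richness(seq) + gc_fraction(seq) == pytest.approx(1.0)


class TestBorderDinucleotides:
    def test_plus_strand_reads_forward(self):
        genome = DictGenome({"c": "NNNN" + "GT" + "CCCCCC" + "AG" + "NNNN"})
        intron = Intron("c", "+", 4, 14)
        assert border_dinucleotides(intron, genome) == ("GT", "AG")

    def test_minus_strand_reverse_complements(self):
        # genomic forward CT...AC is a canonical intron on the minus strand
        genome = DictGenome({"c": "NNNN" + "CT" + "CCCCCC" + "AC" + "NNNN"})
        intron = Intron("c", "-", 4, 14)
        assert border_dinucleotides(intron, genome) == ("GT", "AG")

    def test_minor_class_passes_through(self):
        genome = DictGenome({"c": "NNNN" + "GC" + "CCCCCC" + "AG" + "NNNN"})
        intron = Intron("c", "+", 4, 14)
        assert border_dinucleotides(intron, genome) == ("GC", "AG")

    def test_tiny_intron_rejected(self):
        genome = DictGenome({"c": "ACGTACGT"})
        with pytest.raises(ValueError):
            border_dinucleotides(Intron("c", "+", 2, 5), genome)


def _regular_introns(seq_len, intron_len=60, spacing=120, chrom="c"):
    out = []
    pos = 30
    while pos + intron_len + 30 < seq_len:
        out.append(Intron(chrom, "+", pos, pos + intron_len))
        pos += spacing
    return out


class TestPWM:
    def test_identical_training_sites_give_pseudocount_frequencies(self):
        # one repeated site: consensus base frequency (n+1)/(n+4) after
        # pseudocount 1, other bases 1/(n+4)
        exon = "A" * 30
        intron_seq = "GTAAGT" + "C" * 34 + "T" * 17 + "CAG"  # 60 nt
        unit = exon + intron_seq
        genome = DictGenome({"c": unit * 20 + exon})
        introns = [
            Intron("c", "+", i * len(unit) + 30, (i + 1) * len(unit))
            for i in range(20)
        ]
        pwm = train_pwm(introns, genome)
        n = pwm.n_training
        col = pwm.donor_matrix[:, 3]  # first intronic position: G for all
        g_idx = "ACGT".index("G")
        assert col[g_idx] == pytest.approx((n + 1) / (n + 4))
        assert sum(col) == pytest.approx(1.0)

    def test_uniform_random_sites_give_flat_frequencies(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=1_300_000))
        genome = DictGenome({"c": seq})
        introns = _regular_introns(len(seq))[:10_000]
        assert len(introns) == 10_000
        pwm = train_pwm(introns, genome)
        assert np.abs(pwm.donor_matrix - 0.25).max() < 0.02
        assert np.abs(pwm.acceptor_matrix - 0.25).max() < 0.02

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_pwm([], DictGenome({"c": "ACGT" * 100}))

    def test_frequencies_positive_and_normalized(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=40_000))
        genome = DictGenome({"c": seq})
        pwm = train_pwm(_regular_introns(len(seq))[:100], genome)
        for m in (pwm.donor_matrix, pwm.acceptor_matrix):
            assert (m > 0).all()
            assert np.allclose(m.sum(axis=0), 1.0)


class TestSiteScore:
    def test_background_pwm_scores_zero(self):
        matrix = np.full((4, 9), 0.25)
        background = np.full(4, 0.25)
        score, skipped = score_sequence("ACGTACGTA", matrix, background)
        assert score == pytest.approx(0.0)
        assert skipped == 0

    def test_two_position_toy_pwm_scores_two_bits(self):
        # p(favored)=0.5 vs background 0.25 at both positions: 2*log2(2) = 2
        matrix = np.array(
            [[0.5, 0.5], [1 / 6, 1 / 6], [1 / 6, 1 / 6], [1 / 6, 1 / 6]]
        )
        background = np.full(4, 0.25)
        score, _ = score_sequence("AA", matrix, background)
        assert score == pytest.approx(2.0)

    def test_consensus_sequence_attains_maximal_score(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=60_000))
        genome = DictGenome({"c": seq})
        pwm = train_pwm(_regular_introns(len(seq))[:200], genome)
        consensus = "".join(
            "ACGT"[i] for i in pwm.donor_matrix.argmax(axis=0)
        )
        best, _ = score_sequence(consensus, pwm.donor_matrix, pwm.background)
        for _ in range(50):
            other = "".join(rng.choice(list("ACGT"), size=9))
            assert score_sequence(other, pwm.donor_matrix, pwm.background)[0] <= best

    def test_n_positions_skipped_and_counted(self):
        matrix = np.full((4, 9), 0.25)
        background = np.full(4, 0.25)
        score, skipped = score_sequence("ACGTNNGTA", matrix, background)
        assert skipped == 2

    def test_window_geometry(self):
        assert sum(DONOR_WINDOW) == 9
        assert sum(ACCEPTOR_WINDOW) == 23


class TestCompareGroups:
    def test_fully_separated_small_samples_exact_p(self):
        # all 20 rank assignments enumerable; both extremes -> p = 2/20
        _, p = compare_groups([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = compare_groups([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_shifted_normals_detected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        _, p = compare_groups(a, b)
        assert p < 0.001

    def test_constant_pooled_input_warns_p_one(self):
        with pytest.warns(UserWarning):
            _, p = compare_groups([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestSummaries:
    def test_enormous_intron_threshold(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "length": [10, 60_000],
                "au_fraction": [0.5, 0.5],
                "donor_dinucleotide": ["GT", "GT"],
                "acceptor_dinucleotide": ["AG", "AG"],
                "site_score": [1.0, 2.0],
            }
        )
        out = summarize_introns(df)
        assert out.iloc[0]["n_enormous"] == 1
        assert out.iloc[0]["gt_ag_fraction"] == 1.0

    def test_empty_table_warns(self):
        import pandas as pd

        with pytest.warns(UserWarning):
            out = summarize_introns(pd.DataFrame())
        assert out.empty

    def test_feature_table_on_simulated_genome(self, sim_small):
        _, ann, _ = sim_small
        from splicescape.annotation_model import intron_table

        introns = intron_table(ann.genes)
        df = compute_intron_features(introns, ann.genome)
        assert len(df) == len(introns)
        assert df["au_fraction"].between(0, 1).all()
        assert (df["length"] >= 1).all()
        # planted canonical borders dominate
        gt_ag = (
            (df["donor_dinucleotide"] == "GT") & (df["acceptor_dinucleotide"] == "AG")
        ).mean()
        assert gt_ag > 0.9
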