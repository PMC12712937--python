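"""Unit and property tests for the di-motif scanner and motif matrices."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimotif import (
    DiMotifConfig,
    PSPM,
    Sequence,
    assign_qvalues,
    best_match,
    build_count_matrix,
    enumerate_configs,
    find_perfect_pre,
    match_pvalue,
    mismatch_category,
    mismatches,
    pspm_to_psam,
    read_meme,
    revcomp,
    scan_dimotifs,
    write_meme,
)
from conftest import random_dna

FNAB_60MER = "GAGTAAAAGAATTTTGTGTTTCAGGGTGAAACAGATCTGAAACACAAGAGCTTATGCATT"

dna = st.text(alphabet="ACGTN", min_size=1, max_size=60)


def brute_force_scan(seq, configs, max_mm):
    """Independent oracle: direct Hamming comparison at every placement."""
    hits = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for cfg in configs:
            if cfg.orientation != "HT" and strand == "-":
                continue
            up, dn = cfg.slots
            width = 14 + cfg.spacing
            for i in range(len(s) - width + 1):
                m1 = sum(a != b or a == "N" for a, b in zip(s[i:i + 7], up))
                m2 = sum(
                    a != b or a == "N"
                    for a, b in zip(s[i + 7 + cfg.spacing:i + width], dn)
                )
                if m1 <= max_mm and m2 <= max_mm:
                    hits.append((strand, cfg.orientation, cfg.spacing, i, m1, m2))
    return sorted(hits)


class TestRevcomp:
    def test_pre_maps_to_its_complementary_7mer(self):
        assert revcomp("TGAAACA") == "TGTTTCA"

    def test_n_is_preserved(self):
        assert revcomp("ACGTN") == "NACGT"

    @settings(max_examples=50, derandomize=True)
    @given(dna)
    def test_involution(self, s):
        assert revcomp(revcomp(s)) == s

    def test_sequence_objects_round_trip(self):
        s = Sequence("x", "ACGT")
        assert revcomp(s) == Sequence("x", "ACGT")


class TestEnumerateConfigs:
    @pytest.mark.parametrize("max_spacing,n", [(100, 303), (0, 3), (1, 6)])
    def test_counts(self, max_spacing, n):
        assert len(enumerate_configs(max_spacing)) == n

    def test_deterministic_order(self):
        cfgs = enumerate_configs(1)
        assert [(c.orientation, c.spacing) for c in cfgs] == [
            ("HH", 0), ("HH", 1), ("HT", 0), ("HT", 1), ("TT", 0), ("TT", 1)
        ]

    def test_negative_spacing_rejected(self):
        with pytest.raises(ValueError):
            enumerate_configs(-1)


class TestMismatches:
    @pytest.mark.parametrize(
        "window,expected,n",
        [
            ("TCAAACA", "TGAAACA", 1),   # KAR3 upstream PRE
            ("CAAAACA", "TGAAACA", 2),   # KAR3 downstream PRE
            ("TGANACA", "TGAAACA", 1),   # N counts as mismatch
            ("TGAAACA", "TGAAACA", 0),
        ],
    )
    def test_hamming(self, window, expected, n):
        assert mismatches(window, expected) == n

    def test_length_enforced(self):
        with pytest.raises(ValueError):
            mismatches("TGAAAC", "TGAAACA")


class TestScanDimotifs:
    def test_alphafold_input_contains_perfect_ht4(self):
        seq = Sequence("af3", "AGATGATGAAACAAACATGAAACATCTGC")
        ms = scan_dimotifs(seq, enumerate_configs(100))
        assert any(
            m.config == DiMotifConfig("HT", 4)
            and (m.m1, m.m2, m.start, m.strand) == (0, 0, 6, "+")
            for m in ms
        )

    def test_fig1_fragment_best_is_suboptimal_ht4(self):
        seq = Sequence("fig1", "TGACACATACATGAAACC")
        ms = assign_qvalues(scan_dimotifs(seq, enumerate_configs(100)))
        best = best_match(ms)
        assert best.config == DiMotifConfig("HT", 4)
        assert (best.m1, best.m2) == (1, 1)

    def test_dna_model_60mer_zero_mismatch_matches(self):
        ms = scan_dimotifs(Sequence("fnab", FNAB_60MER), enumerate_configs(100))
        perfect = {
            (m.config.orientation, m.config.spacing)
            for m in ms if m.total_mm == 0
        }
        assert perfect == {("HT", 4), ("TT", 3), ("TT", 14)}

    def test_matches_brute_force_on_random_sequences(self, rng):
        configs = enumerate_configs(20)
        for _ in range(15):
            s = random_dna(rng, int(rng.integers(20, 120)))
            got = sorted(
                (m.strand, m.config.orientation, m.config.spacing, m.start,
                 m.m1, m.m2)
                for m in scan_dimotifs(Sequence("r", s), configs)
            )
            assert got == brute_force_scan(s, configs, 2)

    def test_strand_symmetry(self, rng):
        configs = enumerate_configs(10)
        s = random_dna(rng, 150)
        fwd = scan_dimotifs(Sequence("f", s), configs)
        rev = scan_dimotifs(Sequence("r", revcomp(s)), configs)

        def canonical(matches, L):
            out = set()
            for m in matches:
                width = m.config.width
                # map every match to top-strand-of-f coordinates
                if m.region_id == "f":
                    start = m.start if m.strand == "+" else L - m.start - width
                    strand = m.strand
                else:
                    start = (L - m.start - width) if m.strand == "+" else m.start
                    strand = {"+": "-", "-": "+"}[m.strand]
                if m.config.orientation in ("HH", "TT"):
                    strand = "+"  # palindromic templates: strand is notional
                    out.add((m.config, start, m.m1, m.m2))
                else:
                    out.add((m.config, start, strand, m.m1, m.m2))
            return out

        got_f = canonical(fwd, len(s))
        got_r = canonical(rev, len(s))
        # HH/TT matches map onto themselves with slots swapped; compare HT
        ht_f = {t for t in got_f if t[0].orientation == "HT"}
        ht_r = {t for t in got_r if t[0].orientation == "HT"}
        assert ht_f == ht_r
        sym_f = {t[:2] for t in got_f if t[0].orientation != "HT"}
        sym_r = {t[:2] for t in got_r if t[0].orientation != "HT"}
        assert sym_f == sym_r

    def test_input_validation(self):
        with pytest.raises(ValueError):
            scan_dimotifs(Sequence("x", "ACGT"), enumerate_configs(0))
        with pytest.raises(ValueError):
            scan_dimotifs(Sequence("x", "A" * 20), [])
        with pytest.raises(ValueError):
            scan_dimotifs(Sequence("x", "A" * 20), enumerate_configs(0),
                          max_mm_per_pre=4)


class TestMatchPvalue:
    def test_uniform_background_closed_forms(self):
        assert match_pvalue(0, 0) == pytest.approx(0.25 ** 14, rel=1e-12)
        binom1 = 14 * (0.25 ** 13) * 0.75 + 0.25 ** 14
        assert match_pvalue(1, 0) == pytest.approx(binom1, rel=1e-12)
        assert match_pvalue(7, 7) == pytest.approx(1.0)

    def test_exhaustive_enumeration_small_template(self):
        # all 4^6 sequences against a width-6 template, biased background
        template = "TGAAAC"
        bg = {"A": 0.4, "C": 0.1, "G": 0.2, "T": 0.3}
        for total_mm in (0, 1, 3):
            want = 0.0
            for word in itertools.product("ACGT", repeat=6):
                matches = sum(a == b for a, b in zip(word, template))
                if matches >= 6 - total_mm:
                    want += math.prod(bg[c] for c in word)
            got = match_pvalue(total_mm, 0,
                               background=[bg[c] for c in "ACGT"],
                               template=template)
            assert got == pytest.approx(want, rel=1e-10)

    def test_depends_on_template_composition_under_biased_background(self):
        bg = (0.4, 0.1, 0.1, 0.4)
        p_ht = match_pvalue(0, 0, background=bg, template="TGAAACATGAAACA")
        p_tt = match_pvalue(0, 0, background=bg, template="TGTTTCATGAAACA")
        assert p_ht == pytest.approx(p_tt)  # A<->T symmetric background
        bg2 = (0.5, 0.1, 0.1, 0.3)
        assert match_pvalue(0, 0, background=bg2, template="TGAAACATGAAACA") \
            != match_pvalue(0, 0, background=bg2, template="TGTTTCATGAAACA")

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            match_pvalue(10, 10)
        with pytest.raises(ValueError):
            match_pvalue(0, 0, background=(0.5, 0.5, 0.5, 0.5))


class TestQvaluesAndRanking:
    def test_bh_hand_case(self):
        ms = [_match(p=p) for p in (0.01, 0.02, 0.03, 0.04)]
        qs = [m.q for m in assign_qvalues(ms)]
        assert qs == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_match(self):
        (m,) = assign_qvalues([_match(p=0.005)])
        assert m.q == pytest.approx(0.005)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assign_qvalues([])

    def test_best_match_tie_break_prefers_fewer_mismatches_then_spacing(self):
        ms = assign_qvalues([
            _match(p=0.001, spacing=10, m1=1, m2=1),
            _match(p=0.001, spacing=3, m1=0, m2=0),
            _match(p=0.001, spacing=7, m1=0, m2=0),
        ])
        best = best_match(ms)
        assert (best.total_mm, best.config.spacing) == (0, 3)

    def test_best_match_filters_on_p(self):
        ms = assign_qvalues([_match(p=0.5)])
        assert best_match(ms) is None

    def test_best_never_has_more_mismatches_at_equal_q(self, rng):
        ms = assign_qvalues([
            _match(p=0.001, spacing=int(rng.integers(0, 30)),
                   m1=int(rng.integers(0, 3)), m2=int(rng.integers(0, 3)))
            for _ in range(20)
        ])
        best = best_match(ms)
        same_q = [m for m in ms if m.q == best.q]
        assert all(best.total_mm <= m.total_mm for m in same_q)


def _match(p, spacing=4, m1=0, m2=0, orientation="HT", start=0, strand="+"):
    from dimotif.motif_core import DiMotifMatch

    return DiMotifMatch("r", strand, start, DiMotifConfig(orientation, spacing),
                        m1, m2, p)


class TestCategoriesAndPerfectPre:
    @pytest.mark.parametrize("m1,m2,label", [(0, 0, "0_0"), (1, 2, "1_2"),
                                             (2, 1, "1_2")])
    def test_category_sorted(self, m1, m2, label):
        assert mismatch_category(m1, m2) == label

    def test_perfect_pre_both_strands(self):
        assert find_perfect_pre("TGAAACA") == [(0, "+")]
        assert find_perfect_pre("TGTTTCA") == [(0, "-")]

    def test_perfect_pre_on_dna_model_sequence(self):
        hits = find_perfect_pre(FNAB_60MER)
        assert len(hits) == 3
        assert sum(1 for _, s in hits if s == "+") == 2
        assert sum(1 for _, s in hits if s == "-") == 1


class TestMotifMatrices:
    def test_count_matrix_hand_counts(self):
        counts = build_count_matrix(
            ["TGAAACAAACATGAAACA", "TGACACATACATGAAACC"]
        )
        # position 4 (0-based 3): A in the first sequence, C in the second
        assert counts[3].tolist() == [1, 1, 0, 0]
        assert (counts.sum(axis=1) == 2).all()

    def test_single_input_one_hot(self):
        counts = build_count_matrix(["ACGT"])
        assert (counts == np.eye(4, dtype=int)).all()

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_count_matrix(["ACGT", "ACG"])

    def test_pspm_to_psam_division_by_max(self):
        pspm = PSPM("m", np.array([[0.7, 0.1, 0.1, 0.1]]))
        psam = pspm_to_psam(pspm)
        assert psam.affinities[0].tolist() == pytest.approx([1, 1 / 7, 1 / 7, 1 / 7])

    def test_uniform_column_all_ones(self):
        psam = pspm_to_psam(PSPM("m", np.full((2, 4), 0.25)))
        assert (psam.affinities == 1).all()

    def test_one_hot_column_warns_without_epsilon(self):
        pspm = PSPM("m", np.array([[1.0, 0.0, 0.0, 0.0]]))
        with pytest.warns(UserWarning, match="zero affinities"):
            psam = pspm_to_psam(pspm)
        assert psam.affinities[0].tolist() == [1, 0, 0, 0]
        smoothed = pspm_to_psam(pspm, epsilon=0.01)
        assert (smoothed.affinities > 0).all()

    def test_meme_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        raw = rng.random((8, 4))
        pspm = PSPM("roundtrip", raw / raw.sum(axis=1, keepdims=True))
        path = tmp_path / "motifs.meme"
        write_meme([pspm], path)
        (back,) = read_meme(path)
        assert back.name == "roundtrip"
        assert np.allclose(back.probs, pspm.probs, atol=1e-4)
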