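"""Sliding-window decomposition and the reciprocal-p-value scoring statistics."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vegscreen import (
    BindingScore,
    PValueSet,
    SurrogateProvider,
    binding_score,
    decompose,
    parse_peptide,
    rank_candidates,
    read_pvalue_table,
    score_peptide,
    total_score,
)
from vegscreen.window_scoring import ProviderError, ScoringError

positive_scores = st.floats(min_value=1e-3, max_value=1e6,
                            allow_nan=False, allow_infinity=False)


def pset(seq, *pvalues):
    return PValueSet(parse_peptide(seq), tuple(pvalues))


class TestDecompose:
    def test_template_three_windows(self):
        d = decompose(parse_peptide("QKRKRKKSRYKS"), 10)
        assert d.m == 3
        assert [start for start, _ in d.windows] == [1, 2, 3]
        assert [w.residues for _, w in d.windows] == [
            "QKRKRKKSRY", "KRKRKKSRYK", "RKRKKSRYKS",
        ]

    def test_exact_length_single_window(self):
        pep = parse_peptide("QKRKRKKSRY")
        d = decompose(pep, 10)
        assert d.m == 1 and d.windows[0][1] == pep

    def test_short_core_whole_sequence_window(self, core):
        d = decompose(core, 10)
        assert d.m == 1 and d.windows[0] == (1, core)

    def test_window_cap_enforced(self):
        with pytest.raises(ScoringError, match="limit"):
            decompose(parse_peptide("QKRKRKKSRYKS"), 11)

    @pytest.mark.parametrize("length", range(1, 21))
    def test_count_formula_all_lengths(self, length):
        pep = parse_peptide("A" * length)
        d = decompose(pep, 10)
        assert d.m == max(1, length - 10 + 1)
        covered = set()
        for start, w in d.windows:
            assert pep.residues[start - 1 : start - 1 + len(w)] == w.residues
            covered.update(range(start, start + len(w)))
        assert covered == set(range(1, length + 1))


class TestBindingScore:
    def test_ten_sites_at_point_one(self):
        assert binding_score(pset("RKRKKSR", *([0.1] * 10))).S == pytest.approx(100.0)

    def test_single_half(self):
        assert binding_score(pset("RKRKKSR", 0.5)).S == pytest.approx(2.0)

    def test_worked_example_direct_summation(self):
        ps = [0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.10]
        expected = sum(1.0 / p for p in ps)  # independent direct-arithmetic oracle
        assert expected == pytest.approx(292.8968253968254)
        assert binding_score(pset("RKRKKSR", *ps)).S == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range_pvalues_rejected(self, bad):
        with pytest.raises(ScoringError):
            pset("RKRKKSR", bad)

    def test_empty_rejected(self):
        with pytest.raises(ScoringError):
            PValueSet(parse_peptide("RKRKKSR"), ())

    def test_score_at_least_n(self):
        ps = pset("RKRKKSR", 1.0, 1.0, 0.9)
        assert binding_score(ps).S >= ps.n

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=10),
           st.integers(min_value=0, max_value=9))
    @settings(max_examples=100)
    def test_monotone_in_each_pvalue(self, pvalues, idx):
        idx = idx % len(pvalues)
        base = binding_score(pset("RKRKKSR", *pvalues)).S
        smaller = list(pvalues)
        smaller[idx] = smaller[idx] / 2
        assert binding_score(pset("RKRKKSR", *smaller)).S > base


class TestTotalScore:
    def test_fixed_point_single_window(self):
        ts = total_score([BindingScore(parse_peptide("A"), 10.0)], 10.0)
        assert ts.S_total == pytest.approx(10.0)

    def test_worked_example_two_windows(self):
        scores = [BindingScore(parse_peptide("A"), 10.0),
                  BindingScore(parse_peptide("C"), 20.0)]
        # direct arithmetic: (10*1 + 20*(1+ln 2)) / 2
        expected = (10.0 + 20.0 * (1.0 + math.log(2.0))) / 2.0
        ts = total_score(scores, 10.0)
        assert ts.S_total == pytest.approx(expected)
        assert ts.S_total == pytest.approx(21.93147180559945)

    def test_zero_at_core_over_e(self):
        s = 10.0 / math.e
        ts = total_score([BindingScore(parse_peptide("A"), s)], 10.0)
        assert ts.S_total == pytest.approx(0.0, abs=1e-12)

    def test_log_base_configurable(self):
        scores = [BindingScore(parse_peptide("A"), 100.0)]
        ts10 = total_score(scores, 10.0, log_base=10)
        assert ts10.S_total == pytest.approx(100.0 * (1.0 + 1.0))

    def test_nonpositive_core_rejected(self):
        with pytest.raises(ScoringError):
            total_score([BindingScore(parse_peptide("A"), 1.0)], 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ScoringError):
            total_score([], 1.0)

    @given(st.lists(positive_scores, min_size=1, max_size=8), positive_scores)
    @settings(max_examples=200)
    def test_scale_invariance(self, subs, s_core):
        scores = [BindingScore(parse_peptide("A"), s) for s in subs]
        base = total_score(scores, s_core).S_total
        c = 3.5
        scaled = [BindingScore(parse_peptide("A"), s * c) for s in subs]
        assert total_score(scaled, s_core * c).S_total == pytest.approx(
            c * base, rel=1e-9
        )

    @given(st.lists(positive_scores, min_size=1, max_size=8))
    @settings(max_examples=200)
    def test_fixed_point_property(self, subs):
        s = subs[0]
        scores = [BindingScore(parse_peptide("A"), s) for _ in subs]
        assert total_score(scores, s).S_total == pytest.approx(s, rel=1e-9)


class TestScorePeptide:
    def test_identical_provider_output_hits_fixed_point(self, core):
        provider = lambda w: pset(w.residues, *([0.2] * 10))  # noqa: E731
        ts = score_peptide(parse_peptide("QKRKRKKSRYKS"), provider, core)
        assert ts.S_total == pytest.approx(ts.S_core) == pytest.approx(50.0)

    def test_provider_called_once_per_window_plus_core(self, core):
        calls = []

        def provider(w):
            calls.append(w.residues)
            return pset(w.residues, *([0.5] * 10))

        score_peptide(parse_peptide("QKRKRKKSRYKS"), provider, core, 10)
        assert len(calls) == 3 + 1
        assert calls[-1] == core.residues

    def test_halving_one_window_pvalues_increases_total(self, core):
        tables = {
            "QKRKRKKSRY": [0.2] * 10,
            "KRKRKKSRYK": [0.3] * 10,
            "RKRKKSRYKS": [0.4] * 10,
            "RKRKKSR": [0.25] * 10,
        }
        provider = lambda w: pset(w.residues, *tables[w.residues])  # noqa: E731
        base = score_peptide(parse_peptide("QKRKRKKSRYKS"), provider, core).S_total
        tables["KRKRKKSRYK"] = [p / 2 for p in tables["KRKRKKSRYK"]]
        boosted = score_peptide(parse_peptide("QKRKRKKSRYKS"), provider, core).S_total
        assert boosted > base

    def test_provider_failure_names_window(self, core):
        def provider(w):
            raise RuntimeError("service down")

        with pytest.raises(ProviderError, match="QKRKRKKSRY"):
            score_peptide(parse_peptide("QKRKRKKSRYKS"), provider, core)

    def test_top_n_truncation_keeps_best_sites(self, core):
        provider = lambda w: pset(w.residues, *[0.01 * i for i in range(1, 13)])  # noqa: E731
        ts = score_peptide(core, provider, core, top_n=10)
        expected = sum(1.0 / (0.01 * i) for i in range(1, 11))
        assert ts.S_core == pytest.approx(expected)


class TestRankCandidates:
    def test_table_fixture_order_baseline_last(self, fixtures):
        pairs = [(parse_peptide(s.sequence), s.score) for s in fixtures.table2]
        baseline = fixtures.table2_baseline
        pairs.append((parse_peptide(baseline.sequence), baseline.score))
        ranked = rank_candidates(pairs)
        assert ranked[-1][0].residues == baseline.sequence
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)
        assert scores[0] == 36.8

    def test_ties_lexicographic(self):
        pairs = [(parse_peptide(s), 1.0) for s in ["KKK", "AAA", "CCC"]]
        ranked = rank_candidates(pairs)
        assert [p.residues for p, _ in ranked] == ["AAA", "CCC", "KKK"]

    def test_single_element(self):
        pep = parse_peptide("RKRKKSR")
        assert rank_candidates([(pep, 5.0)]) == [(pep, 5.0)]


class TestProviders:
    def test_surrogate_deterministic_and_valid(self):
        provider = SurrogateProvider(seed=3)
        w = parse_peptide("QKRKRKKSRY")
        a, b = provider(w), provider(w)
        assert a.pvalues == b.pvalues
        assert all(0 < p <= 1 for p in a.pvalues)
        assert a.n == 10

    def test_surrogate_seed_changes_output(self):
        w = parse_peptide("QKRKRKKSRY")
        assert SurrogateProvider(seed=1)(w).pvalues != SurrogateProvider(seed=2)(w).pvalues

    def test_tsv_provider(self, tmp_path):
        path = tmp_path / "pvals.tsv"
        path.write_text(
            "window_sequence\trank\tp_value\n"
            "RKRKKSR\t2\t0.2\n"
            "RKRKKSR\t1\t0.1\n"
        )
        provider = read_pvalue_table(path)
        ps = provider(parse_peptide("RKRKKSR"))
        assert ps.pvalues == (0.1, 0.2)
        with pytest.raises(KeyError):
            provider(parse_peptide("AAAA"))
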