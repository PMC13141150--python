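import itertools
import time

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embalign.align_core import GapPenalties
from embalign.evaluation import (
    AccuracyScores,
    EvaluationError,
    InstrumentationError,
    PhaseProfiler,
    PhaseTimings,
    gap_robustness,
    holm_correct,
    paired_comparison,
    sp_tc,
    summarize_experiment,
    wilcoxon_signed_rank,
)
from embalign.seq_io import MultipleAlignment, SequenceRecord


def _msa(rows):
    return MultipleAlignment(
        rows=[SequenceRecord(i, s, "gapped-protein") for i, s in rows]
    )


REFERENCE = _msa([("a", "MK"), ("b", "MK"), ("c", "MK")])
# test reproducing only reference column 1 (the 'M' column)
PARTIAL = _msa([("a", "MK--"), ("b", "M-K-"), ("c", "M--K")])


class TestSpTc:
    def test_self_identity(self):
        acc = sp_tc(REFERENCE, REFERENCE)
        assert acc.sp == 1.0
        assert acc.tc == 1.0

    def test_hand_enumerated_half(self):
        # 6 reference residue pairs; test recovers the 3 in column 1
        acc = sp_tc(PARTIAL, REFERENCE)
        assert acc.sp == pytest.approx(0.5)
        assert acc.tc == pytest.approx(0.5)

    def test_disjoint_alignment_scores_zero(self):
        ref = _msa([("a", "MK"), ("b", "MK")])
        test = _msa([("a", "MK--"), ("b", "--MK")])
        acc = sp_tc(test, ref)
        assert acc.sp == 0.0
        assert acc.tc == 0.0

    def test_id_mismatch_rejected(self):
        other = _msa([("a", "MK"), ("b", "MK"), ("x", "MK")])
        with pytest.raises(EvaluationError):
            sp_tc(other, REFERENCE)

    def test_sequence_mismatch_rejected(self):
        other = _msa([("a", "MV"), ("b", "MK"), ("c", "MK")])
        with pytest.raises(EvaluationError):
            sp_tc(other, REFERENCE)

    def test_bounds(self, small_family, noisy_provider):
        from embalign.progressive import progressive_align
        from embalign.scoring import CosineBackend

        seqs = small_family.sequences
        embs = [noisy_provider.embed(s) for s in seqs]
        msa = progressive_align(
            seqs, embs, CosineBackend(), GapPenalties(-2.5, -0.7)
        )
        acc = sp_tc(msa, small_family.true_msa)
        assert 0.0 <= acc.sp <= 1.0
        assert 0.0 <= acc.tc <= 1.0

    def test_tc_le_sp_on_fully_populated_reference(self):
        ref = _msa([("a", "MKV"), ("b", "MKV"), ("c", "MKV")])
        test = _msa([("a", "MKV--"), ("b", "MK--V"), ("c", "M--KV")])
        acc = sp_tc(test, ref)
        assert acc.tc <= acc.sp

    def test_invariance_under_disjoint_column_permutation(self):
        # columns 1..3 of PARTIAL have disjoint row support; permuting them
        # preserves within-row residue order and must not change SP/TC
        base = sp_tc(PARTIAL, REFERENCE)
        permuted = _msa([("a", "M-K-"), ("b", "MK--"), ("c", "M--K")])
        acc = sp_tc(permuted, REFERENCE)
        assert acc.sp == base.sp
        assert acc.tc == base.tc

    def test_reference_with_gap_columns_counts_residue_pairs(self):
        ref = _msa([("a", "MK"), ("b", "M-"), ("c", "MK")])
        # reference pairs: col0 -> 3 pairs, col1 -> 1 pair (a,c); total 4
        test = _msa([("a", "MK-"), ("b", "M--"), ("c", "M-K")])
        acc = sp_tc(test, ref)
        assert acc.sp == pytest.approx(3 / 4)
        assert acc.tc == pytest.approx(1 / 2)


def _brute_wilcoxon_p(deltas):
    """Exact two-sided p by enumerating all sign assignments."""
    from scipy.stats import rankdata

    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.array(stats)
    p_le = np.mean(stats <= w_obs + 1e-12)
    p_ge = np.mean(stats >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_five_positive_deltas_exact(self):
        res = wilcoxon_signed_rank([0.1, 0.2, 0.3, 0.4, 0.5])
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.0625)

    def test_negation_symmetry(self, rng):
        d = rng.normal(size=9)
        a = wilcoxon_signed_rank(d)
        b = wilcoxon_signed_rank(-d)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_zeros_dropped(self):
        a = wilcoxon_signed_rank([0.0, 0.1, 0.2, -0.3, 0.0])
        b = wilcoxon_signed_rank([0.1, 0.2, -0.3])
        assert a.pvalue == pytest.approx(b.pvalue)
        assert a.n_used == 3

    def test_all_zero_not_computable(self):
        res = wilcoxon_signed_rank([0.0, 0.0])
        assert not res.computable
        assert res.method == "not-computable"

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        d = np.round(rng.normal(size=n), 2)
        d = d[d != 0]
        if d.size == 0:
            return
        res = wilcoxon_signed_rank(d)
        assert res.pvalue == pytest.approx(_brute_wilcoxon_p(d), abs=1e-12)

    def test_ties_midranked_against_oracle(self):
        d = [0.2, 0.2, -0.2, 0.5, 0.5, 0.7, -0.5]
        res = wilcoxon_signed_rank(d)
        assert res.pvalue == pytest.approx(_brute_wilcoxon_p(d), abs=1e-12)

    def test_large_n_normal_approximation(self, rng):
        d = rng.normal(loc=0.3, size=60)
        res = wilcoxon_signed_rank(d)
        assert res.method == "normal"
        assert 0.0 <= res.pvalue <= 1.0
        from scipy.stats import wilcoxon as scipy_wilcoxon

        ref = scipy_wilcoxon(d, correction=True, method="approx").pvalue
        assert res.pvalue == pytest.approx(ref, rel=1e-6)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_correct([0.03]) == [0.03]

    def test_closed_form_pair(self):
        assert holm_correct([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(EvaluationError):
            holm_correct([0.5, 1.2])

    def _oracle(self, pvalues):
        m = len(pvalues)
        order = sorted(range(m), key=lambda i: pvalues[i])
        adj = [0.0] * m
        running = 0.0
        for k, i in enumerate(order):
            running = max(running, min(1.0, (m - k) * pvalues[i]))
            adj[i] = running
        return adj

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=6))
    def test_matches_definition_oracle(self, ps):
        assert holm_correct(ps) == pytest.approx(self._oracle(ps))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8))
    def test_adjusted_ge_raw_and_monotone(self, ps):
        adj = holm_correct(ps)
        assert all(a >= p - 1e-15 for a, p in zip(adj, ps))
        order = sorted(range(len(ps)), key=lambda i: ps[i])
        sorted_adj = [adj[i] for i in order]
        assert all(x <= y + 1e-15 for x, y in zip(sorted_adj, sorted_adj[1:]))


def _scores(method, values):
    return [
        AccuracyScores(sp=v, tc=v / 2, family_id=f"f{k}", method_id=method)
        for k, v in enumerate(values)
    ]


class TestPairedComparison:
    def test_identical_sets_not_computable(self):
        vals = [0.5, 0.6, 0.7]
        res = _scores("a", vals) + _scores("b", vals)
        comp = paired_comparison(res, "a", "b")
        assert comp.median_delta["sp"] == 0.0
        assert comp.pvalue["sp"] is None

    def test_constant_shift_recovered(self):
        base = [0.5, 0.6, 0.7, 0.4]
        res = _scores("a", [v + 0.1 for v in base]) + _scores("b", base)
        comp = paired_comparison(res, "a", "b")
        assert comp.median_delta["sp"] == pytest.approx(0.1)

    def test_injected_shift_on_20_families(self, rng):
        base = rng.uniform(0.3, 0.7, size=20)
        shift = 0.05
        res = _scores("a", base + shift) + _scores("b", base)
        comp = paired_comparison(res, "a", "b")
        assert comp.median_delta["sp"] == pytest.approx(shift, abs=1e-12)
        assert comp.pvalue["sp"] < 0.01

    def test_missing_family_listed(self):
        res = _scores("a", [0.5, 0.6]) + _scores("b", [0.5])
        with pytest.raises(EvaluationError, match="f1"):
            paired_comparison(res, "a", "b")

    def test_summarize_applies_holm_within_metric(self, rng):
        base = rng.uniform(0.3, 0.7, size=12)
        res = (
            _scores("a", base + 0.1)
            + _scores("b", base)
            + _scores("c", base - 0.05)
        )
        comps = summarize_experiment(res, [("a", "b"), ("a", "c"), ("b", "c")])
        raw = [c.pvalue["sp"] for c in comps]
        adj = [c.holm_pvalue["sp"] for c in comps]
        assert adj == pytest.approx(holm_correct(raw))


class TestGapRobustness:
    BASE = GapPenalties(-2.5, -0.7)

    def _grid_results(self, shifts_by_setting, families=5):
        rng = np.random.default_rng(0)
        base_vals = {f"f{k}": rng.uniform(0.4, 0.8) for k in range(families)}
        results = {}
        for setting, shift in shifts_by_setting.items():
            for fam, v in base_vals.items():
                results[(fam, setting)] = AccuracyScores(
                    sp=v + shift, tc=(v + shift) / 2, family_id=fam, method_id="m"
                )
        return results

    def test_all_settings_equal_baseline(self):
        settings_map = {(-2.5, -0.7): 0.0, (-1.5, -0.3): 0.0}
        summary = gap_robustness(self._grid_results(settings_map), self.BASE)
        for entry in summary.per_setting.values():
            assert entry["median_shift_sp"] == 0.0
            assert entry["median_abs_shift_sp"] == 0.0

    def test_uniform_shift_recovered(self):
        settings_map = {(-2.5, -0.7): 0.0, (-3.5, -1.0): 0.01}
        summary = gap_robustness(self._grid_results(settings_map), self.BASE)
        entry = summary.per_setting[(-3.5, -1.0)]
        assert entry["median_shift_sp"] == pytest.approx(0.01)
        assert entry["median_abs_shift_sp"] == pytest.approx(0.01)
        assert summary.max_median_abs_shift["sp"] == pytest.approx(0.01)

    def test_random_perturbation_matches_direct_recomputation(self, rng):
        families = [f"f{k}" for k in range(7)]
        settings_list = [(-2.5, -0.7), (-1.5, -0.3), (-3.5, -1.0)]
        results = {}
        vals = {}
        for s in settings_list:
            for f in families:
                v = float(rng.uniform(0, 1))
                vals[(f, s)] = v
                results[(f, s)] = AccuracyScores(sp=v, tc=v, family_id=f, method_id="m")
        summary = gap_robustness(results, self.BASE)
        for s in settings_list:
            shifts = [vals[(f, s)] - vals[(f, (-2.5, -0.7))] for f in families]
            assert summary.per_setting[s]["median_shift_sp"] == pytest.approx(
                float(np.median(shifts))
            )
            assert summary.per_setting[s]["median_abs_shift_sp"] == pytest.approx(
                float(np.median(np.abs(shifts)))
            )

    def test_incomplete_grid_names_missing_cells(self):
        results = self._grid_results({(-2.5, -0.7): 0.0, (-1.5, -0.3): 0.0})
        del results[("f0", (-1.5, -0.3))]
        with pytest.raises(EvaluationError, match="f0"):
            gap_robustness(results, self.BASE)

    def test_missing_baseline_rejected(self):
        results = self._grid_results({(-1.5, -0.3): 0.0})
        with pytest.raises(EvaluationError, match="baseline"):
            gap_robustness(results, self.BASE)


class TestProfiler:
    def test_phases_nonnegative_and_bounded_by_total(self):
        with PhaseProfiler() as prof:
            with prof.phase("embedding"):
                time.sleep(0.01)
            with prof.phase("dp"):
                time.sleep(0.01)
        t = prof.timings()
        assert t.embedding >= 0 and t.scoring >= 0 and t.dp >= 0
        assert t.embedding + t.scoring + t.dp <= t.total + 1e-6

    def test_nested_phases_rejected(self):
        with PhaseProfiler() as prof:
            with pytest.raises(InstrumentationError):
                with prof.phase("scoring"):
                    with prof.phase("dp"):
                        pass

    def test_unknown_phase_rejected(self):
        with PhaseProfiler() as prof:
            with pytest.raises(InstrumentationError):
                with prof.phase("misc"):
                    pass

    def test_warm_cache_reduces_embedding_phase(self, clean_provider):
        from embalign.seq_io import SequenceRecord

        rec = SequenceRecord("a", "MKVLIWQERTMKVLIWQERT" * 20, "protein20")
        with PhaseProfiler() as cold:
            with cold.phase("embedding"):
                clean_provider.embed(rec)
        with PhaseProfiler() as warm:
            with warm.phase("embedding"):
                clean_provider.embed(rec)
        # ordering check only: warm (cache hit) never slower than 5x cold
        assert warm.timings().embedding <= max(cold.timings().embedding * 5, 0.05)

    def test_profiling_is_observational(self, small_family, clean_provider):
        from embalign.progressive import progressive_align
        from embalign.scoring import CosineBackend

        seqs = small_family.sequences
        embs = [clean_provider.embed(s) for s in seqs]
        plain = progressive_align(seqs, embs, CosineBackend(), GapPenalties(-2.5, -0.7))
        with PhaseProfiler() as prof:
            profiled = progressive_align(
                seqs, embs, CosineBackend(), GapPenalties(-2.5, -0.7), profiler=prof
            )
        assert [r.residues for r in plain.rows] == [r.residues for r in profiled.rows]

    def test_timings_invariant_enforced(self):
        with pytest.raises(EvaluationError):
            PhaseTimings(embedding=1.0, scoring=1.0, dp=1.0, total=0.5)
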