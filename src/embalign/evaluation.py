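"""Benchmark scoring and paired statistics.

One scoring implementation computes both accuracy metrics against a
reference alignment:

* SP — the fraction of residue pairs co-aligned in reference columns that
  the test alignment also places in a single column (reference pairs in
  the denominator; columns containing gaps still contribute the pairs of
  their residues).
* TC — the fraction of reference columns whose full residue content
  co-occurs in one test column.

Paired contrasts use the two-sided Wilcoxon signed-rank test (zeros
dropped, ties mid-ranked; exact null up to n = 25, normal approximation
with continuity and tie correction above) with Holm step-down correction
across comparisons within each metric.
"""

from __future__ import annotations

import time
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from .align_core import GapPenalties
from .seq_io import GAP, MultipleAlignment

EXACT_WILCOXON_MAX_N = 25


class EvaluationError(ValueError):
    pass


class InstrumentationError(RuntimeError):
    pass


@dataclass(frozen=True)
class AccuracyScores:
    sp: float
    tc: float
    family_id: str = ""
    method_id: str = ""


def _residue_columns(msa: MultipleAlignment) -> dict[str, list[int]]:
    """Per row id: the test/reference column index of each residue ordinal."""
    out = {}
    for row in msa.rows:
        cols = [c for c, sym in enumerate(row.residues) if sym != GAP]
        out[row.id] = cols
    return out


def sp_tc(
    test: MultipleAlignment,
    reference: MultipleAlignment,
    family_id: str = "",
    method_id: str = "",
) -> AccuracyScores:
    """Score a test alignment against a reference with shared sequences."""
    if set(test.ids) != set(reference.ids):
        raise EvaluationError(
            f"id mismatch: test={sorted(test.ids)} reference={sorted(reference.ids)}"
        )
    for rid in reference.ids:
        if test.row(rid).ungapped() != reference.row(rid).ungapped():
            raise EvaluationError(
                f"row {rid!r}: ungapped sequences differ between test and reference"
            )

    test_cols = _residue_columns(test)
    ref_cols = _residue_columns(reference)
    ids = reference.ids

    # residue ordinal per (row, reference column)
    ordinal_at_ref_col: dict[str, dict[int, int]] = {}
    for rid in ids:
        ordinal_at_ref_col[rid] = {c: k for k, c in enumerate(ref_cols[rid])}

    total_pairs = 0
    matched_pairs = 0
    total_columns = reference.column_count
    recovered_columns = 0
    for c in range(reference.column_count):
        members = [rid for rid in ids if c in ordinal_at_ref_col[rid]]
        placements = [
            test_cols[rid][ordinal_at_ref_col[rid][c]] for rid in members
        ]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                total_pairs += 1
                if placements[a] == placements[b]:
                    matched_pairs += 1
        if members and len(set(placements)) == 1:
            recovered_columns += 1
    if total_pairs == 0:
        raise EvaluationError("reference alignment contains no residue pairs")
    return AccuracyScores(
        sp=matched_pairs / total_pairs,
        tc=recovered_columns / total_columns,
        family_id=family_id,
        method_id=method_id,
    )


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ (rank sum of positive deltas)
    pvalue: float | None
    n_used: int
    method: str  # "exact" | "normal" | "not-computable"

    @property
    def computable(self) -> bool:
        return self.pvalue is not None


def wilcoxon_signed_rank(deltas) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences."""
    d = np.asarray(list(deltas), dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=float("nan"), pvalue=None, n_used=0,
                              method="not-computable")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        p = _exact_two_sided_p(ranks, w_plus)
        return WilcoxonResult(statistic=w_plus, pvalue=p, n_used=n, method="exact")
    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts) / 48.0).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(statistic=w_plus, pvalue=None, n_used=n,
                              method="not-computable")
    diff = w_plus - mean
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    z = (diff - cc) / np.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(statistic=w_plus, pvalue=p, n_used=n, method="normal")


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact null of W+ via convolution; mid-ranks handled by doubling."""
    doubled = np.round(ranks * 2).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w_plus * 2))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def holm_correct(pvalues) -> list[float]:
    """Holm step-down adjustment, returned in input order."""
    p = list(pvalues)
    for v in p:
        if not (0.0 <= v <= 1.0):
            raise EvaluationError(f"p-value {v} outside [0, 1]")
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running = max(running, val)
        adjusted[idx] = running
    return adjusted


@dataclass
class PairedComparison:
    method_a: str
    method_b: str
    mean_a: dict[str, float]
    mean_b: dict[str, float]
    median_delta: dict[str, float]
    pvalue: dict[str, float | None]
    holm_pvalue: dict[str, float | None] = field(default_factory=dict)
    n_families: int = 0


def paired_comparison(
    results: list[AccuracyScores], method_a: str, method_b: str
) -> PairedComparison:
    """Family-wise paired contrast of two methods on a shared family set."""
    by_method: dict[str, dict[str, AccuracyScores]] = {}
    for r in results:
        by_method.setdefault(r.method_id, {})[r.family_id] = r
    for m in (method_a, method_b):
        if m not in by_method:
            raise EvaluationError(f"no results for method {m!r}")
    fams_a = set(by_method[method_a])
    fams_b = set(by_method[method_b])
    if fams_a != fams_b:
        missing = sorted(fams_a.symmetric_difference(fams_b))
        raise EvaluationError(f"family sets differ between methods: {missing}")
    families = sorted(fams_a)
    comp = PairedComparison(
        method_a=method_a,
        method_b=method_b,
        mean_a={},
        mean_b={},
        median_delta={},
        pvalue={},
        n_families=len(families),
    )
    for metric in ("sp", "tc"):
        va = np.array([getattr(by_method[method_a][f], metric) for f in families])
        vb = np.array([getattr(by_method[method_b][f], metric) for f in families])
        comp.mean_a[metric] = float(va.mean())
        comp.mean_b[metric] = float(vb.mean())
        deltas = va - vb
        comp.median_delta[metric] = float(np.median(deltas))
        comp.pvalue[metric] = wilcoxon_signed_rank(deltas).pvalue
    return comp


def summarize_experiment(
    results: list[AccuracyScores], method_pairs: list[tuple[str, str]]
) -> list[PairedComparison]:
    """Run all contrasts and apply Holm across comparisons within a metric."""
    comps = [paired_comparison(results, a, b) for a, b in method_pairs]
    for metric in ("sp", "tc"):
        idx = [i for i, c in enumerate(comps) if c.pvalue[metric] is not None]
        adjusted = holm_correct([comps[i].pvalue[metric] for i in idx])
        for i, adj in zip(idx, adjusted):
            comps[i].holm_pvalue[metric] = adj
        for i, c in enumerate(comps):
            if i not in idx:
                c.holm_pvalue[metric] = None
    return comps


@dataclass
class GapRobustnessSummary:
    baseline: tuple[float, float]
    per_setting: dict[tuple[float, float], dict[str, float]]
    max_median_abs_shift: dict[str, float]


def gap_robustness(
    results: dict[tuple[str, tuple[float, float]], AccuracyScores],
    baseline: GapPenalties,
) -> GapRobustnessSummary:
    """Median and median-absolute per-family metric shifts vs the baseline.

    ``results`` is keyed by (family_id, (gap_open, gap_extend)) and must
    cover every family at every setting, including the baseline.
    """
    base_key = (baseline.gap_open, baseline.gap_extend)
    families = sorted({f for f, _ in results})
    settings = sorted({s for _, s in results})
    if base_key not in settings:
        raise EvaluationError(f"baseline setting {base_key} missing from results")
    missing = [
        (f, s) for f in families for s in settings if (f, s) not in results
    ]
    if missing:
        raise EvaluationError(f"incomplete penalty grid; missing cells: {missing}")
    per_setting: dict[tuple[float, float], dict[str, float]] = {}
    max_abs = {"sp": 0.0, "tc": 0.0}
    for s in settings:
        entry: dict[str, float] = {}
        for metric in ("sp", "tc"):
            shifts = np.array(
                [
                    getattr(results[(f, s)], metric) - getattr(results[(f, base_key)], metric)
                    for f in families
                ]
            )
            entry[f"median_shift_{metric}"] = float(np.median(shifts))
            entry[f"median_abs_shift_{metric}"] = float(np.median(np.abs(shifts)))
            if s != base_key:
                max_abs[metric] = max(max_abs[metric], entry[f"median_abs_shift_{metric}"])
        per_setting[s] = entry
    return GapRobustnessSummary(
        baseline=base_key, per_setting=per_setting, max_median_abs_shift=max_abs
    )


@dataclass(frozen=True)
class PhaseTimings:
    embedding: float
    scoring: float
    dp: float
    total: float

    def __post_init__(self) -> None:
        for name in ("embedding", "scoring", "dp", "total"):
            if getattr(self, name) < 0:
                raise EvaluationError(f"negative {name} time")
        if self.embedding + self.scoring + self.dp > self.total + 1e-6:
            raise EvaluationError("phase times exceed total wall-clock time")


class PhaseProfiler:
    """Scoped wall-clock timers for the embedding / scoring / dp phases."""

    PHASES = ("embedding", "scoring", "dp")

    def __init__(self) -> None:
        self.elapsed = {p: 0.0 for p in self.PHASES}
        self._active: str | None = None
        self._t0: float | None = None

    def __enter__(self) -> "PhaseProfiler":
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, *exc) -> None:
        self._total = time.perf_counter() - self._t0

    @contextmanager
    def phase(self, name: str):
        if name not in self.PHASES:
            raise InstrumentationError(f"unknown phase {name!r}")
        if self._active is not None:
            raise InstrumentationError(
                f"phase {name!r} started while {self._active!r} is active"
            )
        self._active = name
        start = time.perf_counter()
        try:
            yield
        finally:
            self.elapsed[name] += time.perf_counter() - start
            self._active = None

    def timings(self) -> PhaseTimings:
        if not hasattr(self, "_total"):
            raise InstrumentationError("profiler was not used as a context manager")
        return PhaseTimings(
            embedding=self.elapsed["embedding"],
            scoring=self.elapsed["scoring"],
            dp=self.elapsed["dp"],
            total=self._total,
        )
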