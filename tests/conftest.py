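import numpy as np
import pytest

from embalign.align_core import GapPenalties
from embalign.embeddings import SyntheticEmbeddingProvider
from embalign.synthetic import FamilyParams, simulate_family

BASELINE = GapPenalties(-2.5, -0.7)


@pytest.fixture
def baseline_penalties():
    return BASELINE


@pytest.fixture
def clean_provider():
    return SyntheticEmbeddingProvider(d=24, noise_sd=0.0, window=1, seed=0)


@pytest.fixture
def noisy_provider():
    return SyntheticEmbeddingProvider(d=24, noise_sd=0.1, window=1, seed=0)


@pytest.fixture
def small_family():
    params = FamilyParams(
        n_taxa=4, ancestor_length=40, substitution_rate=0.05, indel_rate=0.03
    )
    return simulate_family(params, seed=11, family_id="small")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_best_score(S: np.ndarray, penalties: GapPenalties) -> float:
    """Enumerate every global alignment path and score it independently.

    A maximal run of gap moves in one direction is one gap event costing
    gap_open + (L-1) * gap_extend; switching direction opens a new gap.
    """
    n, m = S.shape
    po, pe = penalties.gap_open, penalties.gap_extend
    best = [float("-inf")]

    def rec(i, j, acc, last):
        if i == n and j == m:
            if acc > best[0]:
                best[0] = acc
            return
        if i < n and j < m:
            rec(i + 1, j + 1, acc + S[i, j], "M")
        if i < n:
            rec(i + 1, j, acc + (pe if last == "U" else po), "U")
        if j < m:
            rec(i, j + 1, acc + (pe if last == "L" else po), "L")

    rec(0, 0, 0.0, "S")
    return best[0]
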