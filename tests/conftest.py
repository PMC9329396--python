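import numpy as np
import pytest

from pairpref import CountMatrices, ComparisonRecord, load_fixture_counts
from pairpref.btmodel import fit


@pytest.fixture(scope="session")
def fixture_counts() -> CountMatrices:
    return load_fixture_counts()


@pytest.fixture(scope="session")
def fixture_fit(fixture_counts):
    return fit(fixture_counts, reference="A1")


def expand_to_records(counts: CountMatrices) -> list[ComparisonRecord]:
    """Reconstruct one valid long-format record list from aggregated counts.

    Per unordered pair, presentation orders and winners are listed
    separately and zipped; any such allocation aggregates back to the same
    matrices because wins ignore order.
    """
    items = counts.items.items
    C, W = counts.comparisons, counts.wins
    records, subj = [], 0
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            orders = [(items[i], items[j])] * C[i, j] + [(items[j], items[i])] * C[j, i]
            winners = [items[i]] * W[i, j] + [items[j]] * W[j, i]
            assert len(orders) == len(winners)
            for (first, second), winner in zip(orders, winners):
                subj += 1
                records.append(ComparisonRecord(f"s{subj}", first, second, winner))
    return records


def grid_mle_3item(wins: np.ndarray, lo: float = -5.0, hi: float = 5.0,
                   n_grid: int = 41, n_zoom: int = 8) -> np.ndarray:
    """Independent brute-force MLE for a 3-item win matrix.

    Profile maximization of the Bradley-Terry log-likelihood over
    (beta2, beta3) with beta1 = 0, by iteratively zoomed grid search.
    Deliberately avoids any package code path.
    """
    import math

    def loglik(b2, b3):
        beta = [0.0, b2, b3]
        ll = 0.0
        for i in range(3):
            for j in range(3):
                if i == j or wins[i][j] == 0:
                    continue
                d = beta[i] - beta[j]
                ll += wins[i][j] * -math.log1p(math.exp(-d))
        return ll

    lo2, hi2, lo3, hi3 = lo, hi, lo, hi
    best = (0.0, 0.0)
    for _ in range(n_zoom):
        g2 = np.linspace(lo2, hi2, n_grid)
        g3 = np.linspace(lo3, hi3, n_grid)
        vals = [(loglik(b2, b3), b2, b3) for b2 in g2 for b3 in g3]
        _, b2, b3 = max(vals)
        best = (b2, b3)
        s2, s3 = (hi2 - lo2) / (n_grid - 1), (hi3 - lo3) / (n_grid - 1)
        lo2, hi2 = b2 - 2 * s2, b2 + 2 * s2
        lo3, hi3 = b3 - 2 * s3, b3 + 2 * s3
    return np.array([0.0, *best])
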