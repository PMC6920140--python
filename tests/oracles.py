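"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the isotope oracle
expands the distribution atom by atom with itertools, and the Friedman
oracle enumerates the full permutation product.
"""

import itertools
from typing import Dict, List, Tuple

import numpy as np
from scipy import stats

# element -> [(nucleon offset, mass, abundance)], same physical constants
# as the package but used through an exhaustive expansion, not convolution
ISOTOPES = {
    "H": [(0, 1.00782503207, 0.999885), (1, 2.0141017778, 0.000115)],
    "C": [(0, 12.0, 0.9893), (1, 13.0033548378, 0.0107)],
    "N": [(0, 14.0030740048, 0.99636), (1, 15.0001088982, 0.00364)],
    "O": [
        (0, 15.9949146196, 0.99757),
        (1, 16.9991317, 0.00038),
        (2, 17.9991610, 0.00205),
    ],
    "S": [
        (0, 31.97207100, 0.9499),
        (1, 32.97145876, 0.0075),
        (2, 33.96786690, 0.0425),
        (4, 35.96708076, 0.0001),
    ],
}


def brute_force_isotope_pattern(
    counts: Dict[str, int], n_entries: int = 8
) -> List[Tuple[float, float]]:
    """Exhaustive per-atom expansion of the isotope distribution.

    Feasible only for ~10 atoms.  Returns the first ``n_entries``
    nucleon-binned (centroid mass, abundance) entries, renormalised.
    """
    atoms = []
    for el, n in counts.items():
        atoms.extend([ISOTOPES[el]] * n)
    bins: Dict[int, List[float]] = {}
    for combo in itertools.product(*atoms):
        offset = sum(c[0] for c in combo)
        mass = sum(c[1] for c in combo)
        prob = 1.0
        for c in combo:
            prob *= c[2]
        if offset in bins:
            bins[offset][0] += prob
            bins[offset][1] += prob * mass
        else:
            bins[offset] = [prob, prob * mass]
    entries = [
        (msum / p, p) for _, (p, msum) in sorted(bins.items())
    ][:n_entries]
    total = sum(p for _, p in entries)
    return [(m, p / total) for m, p in entries]


def brute_force_friedman_p(values: np.ndarray) -> Tuple[float, float]:
    """Exact Friedman p by enumerating every within-block permutation."""
    ranks = np.apply_along_axis(stats.rankdata, 1, np.asarray(values, float))
    n, k = ranks.shape

    def statistic(colsums):
        return (
            12.0 / (n * k * (k + 1)) * sum(c**2 for c in colsums)
            - 3.0 * n * (k + 1)
        )

    observed = statistic(ranks.sum(axis=0))
    count = total = 0
    row_perms = [list(itertools.permutations(r)) for r in ranks]
    for combo in itertools.product(*row_perms):
        total += 1
        if statistic(np.sum(combo, axis=0)) >= observed - 1e-9:
            count += 1
    return observed, count / total
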