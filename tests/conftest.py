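import itertools

import numpy as np
import pytest


def brute_force_match(ref, test, half_window):
    """Exhaustive one-to-one assignment oracle for event matching.

    Over all feasible (in-window) one-to-one assignments, maximize the number
    of pairs, then minimize the total |lag|.  Exponential; only for tiny
    instances.  Returns (n_pairs, total_abs_lag).
    """
    ref = list(ref)
    test = list(test)
    best = (0, 0.0)
    n = len(ref)
    for k in range(min(n, len(test)), -1, -1):
        found = False
        for ref_idx in itertools.combinations(range(n), k):
            for perm in itertools.permutations(range(len(test)), k):
                lags = [abs(test[j] - ref[i]) for i, j in zip(ref_idx, perm)]
                if all(l <= half_window for l in lags):
                    total = sum(lags)
                    if not found or total < best[1]:
                        best = (k, total)
                        found = True
        if found:
            return best
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
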