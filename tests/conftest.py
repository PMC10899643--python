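import numpy as np
import pytest

import neutraj as nj


@pytest.fixture(scope="session")
def sim():
    """One reference simulation at the standard study scale."""
    expr, truth = nj.simulate_trajectory_dataset(n_cells=2000, n_genes=300, seed=11)
    return expr, truth


@pytest.fixture(scope="session")
def pipeline(sim):
    """Normalized data, pseudotime, binned trajectory and association test
    computed once from the reference simulation."""
    expr, truth = sim
    filtered = nj.filter_features(expr)
    norm = nj.normalize_expression(filtered)
    pt = nj.infer_pseudotime(norm, "lyz_like", "mmp9_like")
    binned = nj.bin_trajectory(norm, pt)
    assoc = nj.association_test(norm, pt, raw_counts=filtered)
    return {"expr": expr, "truth": truth, "norm": norm, "pt": pt,
            "binned": binned, "assoc": assoc}


def brute_force_dtw(a, b):
    """Independent DTW oracle: explicit enumeration of every monotone warping
    path; diagonal steps pay the local cost twice, others once."""
    a = list(a)
    b = list(b)
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, acc):
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc + 2 * abs(a[i + 1] - b[j + 1]))
        if i + 1 < n:
            walk(i + 1, j, acc + abs(a[i + 1] - b[j]))
        if j + 1 < m:
            walk(i, j + 1, acc + abs(a[i] - b[j + 1]))

    walk(0, 0, abs(a[0] - b[0]))
    return best[0]


def brute_force_ccf(ref, query, max_lag):
    """Independent cross-correlation oracle: full-series moments, explicit
    python loop over every shift."""
    ref = np.asarray(ref, float)
    query = np.asarray(query, float)
    n = len(ref)
    xc = (query - query.mean()) / query.std()
    yc = (ref - ref.mean()) / ref.std()
    out = {}
    for k in range(-max_lag, max_lag + 1):
        s = 0.0
        for t in range(n):
            if 0 <= t + k < n:
                s += xc[t + k] * yc[t]
        out[k] = s / n
    return out
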