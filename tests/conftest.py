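import numpy as np
import pytest
from hypothesis import settings

import tailmorph as tm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_specs():
    return tm.default_study_specs()


@pytest.fixture(scope="session")
def study_frame(default_specs):
    """One synthetic study at the default design, fixed seed."""
    return tm.generate_study(default_specs, seed=11)


@pytest.fixture(scope="session")
def zero_variance_frame():
    """Study drawn with all SDs at zero: group means are exact."""
    specs = [
        tm.GroupSpec(name=n, ok_mean=om, ok_sd=0.0, thick_mean=tmn, thick_sd=0.0)
        for n, om, _, tmn, _ in tm.DEFAULT_GROUP_PARAMS
    ]
    return tm.generate_study(specs, seed=3)


def brute_force_longest_run(flags):
    """O(n^2) oracle: scan every contiguous interval."""
    flags = list(flags)
    best = 0
    for i in range(len(flags)):
        for j in range(i, len(flags)):
            if all(flags[i: j + 1]):
                best = max(best, j - i + 1)
    return best


def kruskal_h_oracle(groups):
    """Naive textbook Kruskal-Wallis H on midranks with tie correction."""
    pooled = [float(v) for g in groups for v in g]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        midrank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    n = len(pooled)
    h = 0.0
    pos = 0
    for g in groups:
        r = sum(ranks[pos: pos + len(g)])
        h += r * r / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    return h / (1 - tie / (n**3 - n))


@pytest.fixture(scope="session")
def oracles():
    return {"longest_run": brute_force_longest_run, "kw_h": kruskal_h_oracle}
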