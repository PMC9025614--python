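"""Nonparametric group comparisons: Kruskal-Wallis and pairwise matrices.

The omnibus test is the tie-corrected Kruskal-Wallis H on midranks, with
a chi-square (k - 1 df) p-value by default and an exact-permutation
p-value for small samples.  Pairwise comparisons run the two-sample
special case of the test (equivalent to a tie-corrected two-sided
rank-sum test) for every unordered group pair, on the chosen unit of
analysis — per-animal means by default, so the exchangeable unit is the
animal (n = 6 per group under the study design) rather than the scale.

For two groups the exact permutation null enumerates all C(N, n1)
assignments of the pooled midranks; p is the fraction of assignments
with H at least the observed value (the observed assignment is included,
so p is in (0, 1]).  No multiple-testing correction is applied by
default; Holm and Benjamini-Hochberg adjustments are opt-in.
"""

from __future__ import annotations

import warnings
from functools import lru_cache
from itertools import combinations
from math import comb
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .synthetic import thickness_columns
from .types import PairwiseMatrix, ValidationError

#: Largest number of enumerated assignments before the exact two-group
#: permutation test falls back to Monte-Carlo resampling.
MAX_EXACT = 200_000


class KruskalResult(NamedTuple):
    statistic: float
    pvalue: float
    method: str


def _check_groups(samples: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(samples) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    for i, a in enumerate(arrays):
        if a.size == 0:
            raise ValidationError(f"group {i} is empty")
    return arrays


def _h_from_rank_sums(rank_sums: np.ndarray, sizes: np.ndarray, n: int, tie_term: float) -> np.ndarray:
    """Tie-corrected H from per-group rank sums (vectorized over axis 0)."""
    h = 12.0 / (n * (n + 1)) * (rank_sums**2 / sizes).sum(axis=-1) - 3.0 * (n + 1)
    return h / (1.0 - tie_term)


def _rank_setup(arrays: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, int, float]:
    pooled = np.concatenate(arrays)
    ranks = scipy.stats.rankdata(pooled)
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / (n**3 - n)
    sizes = np.array([a.size for a in arrays])
    return ranks, sizes, n, tie_term


@lru_cache(maxsize=32)
def _combination_indices(n: int, k: int) -> np.ndarray:
    return np.array(list(combinations(range(n), k)), dtype=np.intp)


def _exact_two_group_p(ranks: np.ndarray, n1: int, tie_term: float, h_obs: float) -> float:
    n = ranks.size
    idx = _combination_indices(n, n1)
    r1 = ranks[idx].sum(axis=1)
    r2 = ranks.sum() - r1
    sums = np.stack([r1, r2], axis=1)
    h_all = _h_from_rank_sums(sums, np.array([n1, n - n1]), n, tie_term)
    return float(np.mean(h_all >= h_obs - 1e-9))


def _montecarlo_p(
    ranks: np.ndarray, sizes: np.ndarray, tie_term: float, h_obs: float,
    n_resamples: int, rng: np.random.Generator,
) -> float:
    n = ranks.size
    perm = rng.permuted(np.tile(ranks, (n_resamples, 1)), axis=1)
    edges = np.concatenate(([0], np.cumsum(sizes)))
    sums = np.stack(
        [perm[:, edges[i]: edges[i + 1]].sum(axis=1) for i in range(sizes.size)], axis=1
    )
    h_all = _h_from_rank_sums(sums, sizes, n, tie_term)
    return float((1 + np.sum(h_all >= h_obs - 1e-9)) / (n_resamples + 1))


def kruskal_wallis(
    samples: Sequence[Sequence[float]],
    method: str = "chi2",
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> KruskalResult:
    """Kruskal-Wallis H test across two or more groups.

    ``method='chi2'`` uses the chi-square approximation with k - 1
    degrees of freedom; ``'permutation'`` computes an exact p by full
    enumeration for two groups (up to ``MAX_EXACT`` assignments) and a
    Monte-Carlo p otherwise.  Degenerate all-identical input returns
    H = 0, p = 1 with a warning rather than an exception.
    """
    arrays = _check_groups(samples)
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size < 2:
        warnings.warn("all values identical; degenerate Kruskal-Wallis (H=0, p=1)")
        return KruskalResult(0.0, 1.0, "degenerate")

    h_obs, p_chi2 = scipy.stats.kruskal(*arrays)
    if method == "chi2":
        return KruskalResult(float(h_obs), float(p_chi2), "chi2")
    if method != "permutation":
        raise ValidationError(f"unknown method {method!r}")

    ranks, sizes, n, tie_term = _rank_setup(arrays)
    if len(arrays) == 2 and comb(n, int(sizes[0])) <= MAX_EXACT:
        p = _exact_two_group_p(ranks, int(sizes[0]), tie_term, float(h_obs))
        return KruskalResult(float(h_obs), p, "permutation-exact")
    rng = np.random.default_rng(seed)
    p = _montecarlo_p(ranks, sizes, tie_term, float(h_obs), n_resamples, rng)
    return KruskalResult(float(h_obs), p, "permutation-montecarlo")


# ---------------------------------------------------------------------------
# endpoint aggregation and the pairwise matrix

def aggregate_endpoint(frame: pd.DataFrame, endpoint: str, unit: str) -> pd.DataFrame:
    """Reduce a measurement table to (group, value) rows at the chosen unit.

    ``endpoint`` is ``'orthokeratosis'`` (per-scale degree; the reading
    unit coincides with the scale unit) or ``'thickness'`` (individual
    readings, per-scale means, or per-animal means).
    """
    if unit not in ("animal", "scale", "reading"):
        raise ValidationError(f"unknown unit {unit!r}")
    tcols = thickness_columns(frame)
    work = frame.copy()
    if endpoint == "orthokeratosis":
        work["value"] = (100.0 * work["A_um"] / work["B_um"]).clip(upper=100.0)
        if unit == "animal":
            agg = work.groupby(["group", "animal"], sort=False)["value"].mean().reset_index()
        else:  # scale and reading coincide: the degree is a per-scale quantity
            agg = work[["group", "animal", "value"]]
    elif endpoint == "thickness":
        if not tcols:
            raise ValidationError("measurement table has no thickness columns")
        if unit == "reading":
            agg = work.melt(id_vars=["group", "animal"], value_vars=tcols, value_name="value")
            agg = agg.dropna(subset=["value"])[["group", "animal", "value"]]
        else:
            work["value"] = work[tcols].mean(axis=1)
            if unit == "animal":
                agg = work.groupby(["group", "animal"], sort=False)["value"].mean().reset_index()
            else:
                agg = work[["group", "animal", "value"]]
    else:
        raise ValidationError(f"unknown endpoint {endpoint!r}")
    return agg[["group", "value"]].reset_index(drop=True)


def pairwise_comparisons(
    frame: pd.DataFrame,
    endpoint: str = "orthokeratosis",
    unit: str = "animal",
    alpha: float = 0.05,
    adjust: str | None = None,
    exact: bool = True,
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> PairwiseMatrix:
    """Two-sample Kruskal-Wallis test for every unordered group pair.

    Aggregates the endpoint to the chosen unit of analysis, then tests
    each pair (exact permutation p by default) and assembles the
    symmetric p-value matrix with S/N flags at ``alpha``.  ``adjust``
    may be ``'holm'`` or ``'bh'``; adjusted p-values then populate the
    matrix (documented in the output).
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if adjust not in (None, "holm", "bh"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    agg = aggregate_endpoint(frame, endpoint, unit)
    labels = list(dict.fromkeys(agg["group"]))
    if len(labels) < 2:
        raise ValidationError("need at least two groups")
    values = {g: agg.loc[agg["group"] == g, "value"].to_numpy() for g in labels}
    for g, v in values.items():
        if v.size < 2:
            raise ValidationError(
                f"group {g!r} has {v.size} observation(s) at unit={unit!r}; need >=2"
            )

    k = len(labels)
    p = np.full((k, k), np.nan)
    method = "permutation" if exact else "chi2"
    raw = []
    pairs = list(combinations(range(k), 2))
    for i, j in pairs:
        res = kruskal_wallis(
            [values[labels[i]], values[labels[j]]],
            method=method, n_resamples=n_resamples, seed=seed,
        )
        raw.append(res.pvalue)
    if adjust is not None:
        from statsmodels.stats.multitest import multipletests

        raw = list(
            multipletests(raw, method={"holm": "holm", "bh": "fdr_bh"}[adjust])[1]
        )
    for (i, j), pv in zip(pairs, raw):
        p[i, j] = p[j, i] = pv

    flags = np.full((k, k), "", dtype=object)
    for i, j in pairs:
        flags[i, j] = flags[j, i] = "S" if p[i, j] <= alpha else "N"
    return PairwiseMatrix(labels=labels, p=p, flags=flags, alpha=alpha,
                          endpoint=endpoint, unit=unit)
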