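"""Superfamily benchmark statistics.

Given a distance matrix over proteins with family and superfamily labels
(SCOP-style: families group close homologues, superfamilies group remote
homologues sharing ancestry), the central question is whether a distance
measure separates within-family from between-family pairs inside each
superfamily.

* ``sfsd`` — the standard deviation of between-family distances within a
  superfamily (heterogeneity of the remote relationships).
* ``RR`` (recognition rate) — the fraction of superfamilies whose
  within-family and between-family distance samples differ significantly
  under a two-sided Mann-Whitney U test at ``alpha`` (default 0.001).
* ``RD`` (relative distance) — over recognized superfamilies, the mean of
  ``(d_diff - d_same) / d_diff`` where ``d_same``/``d_diff`` are the mean
  within-/between-family distances.

TM-score utilities: the length-weighted combination of the two
chain-normalized TM-scores of a pair, and the ``D0`` scale factor that
makes the TM-score length-independent.  TM-scores enter as data (no
structure superposition is performed here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .records import ConsistencyError, DistanceMatrix, PadistError


@dataclass
class SuperfamilyBench:
    """Distance matrix plus family/superfamily labels (+ optional TM-scores).

    ``tm_scores`` maps unordered id pairs (any order accepted) to a
    combined TM-score in [0, 1].
    """

    dm: DistanceMatrix
    family_of: dict[str, str]
    superfamily_of: dict[str, str]
    tm_scores: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        missing = [
            i
            for i in self.dm.ids
            if i not in self.family_of or i not in self.superfamily_of
        ]
        if missing:
            raise ConsistencyError(
                f"ids without family/superfamily labels: {missing[:5]}..."
                if len(missing) > 5
                else f"ids without family/superfamily labels: {missing}"
            )

    def tm(self, a: str, b: str) -> float | None:
        if self.tm_scores is None:
            return None
        return self.tm_scores.get((a, b), self.tm_scores.get((b, a)))

    def superfamilies(self) -> list[str]:
        return sorted({self.superfamily_of[i] for i in self.dm.ids})

    def pair_samples(self, sf: str) -> tuple[np.ndarray, np.ndarray]:
        """(within-family, between-family) distance samples of superfamily sf."""
        ids = [i for i in self.dm.ids if self.superfamily_of[i] == sf]
        within, between = [], []
        for a, b in combinations(ids, 2):
            dist = self.dm.get(a, b)
            if self.family_of[a] == self.family_of[b]:
                within.append(dist)
            else:
                between.append(dist)
        return np.asarray(within), np.asarray(between)


@dataclass
class RRRDReport:
    """Per-superfamily test results plus the aggregate RR and RD."""

    per_superfamily: pd.DataFrame = field(repr=False)
    rr: float
    rd: float
    n_evaluable: int
    excluded: list[str]


def mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact null enumeration when both samples have <= 8 observations and no
    ties are present; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and tie_free) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def sfsd(bench: SuperfamilyBench, sf: str) -> float:
    """Population standard deviation of between-family distances in sf.

    NaN (reported as missing) when the superfamily has no between-family
    pair.
    """
    _, between = bench.pair_samples(sf)
    if between.size == 0:
        return float("nan")
    return float(np.std(between, ddof=0))


def rr_rd(bench: SuperfamilyBench, alpha: float = 0.001) -> RRRDReport:
    """Recognition rate and relative distance over a benchmark.

    Superfamilies lacking either a within-family or a between-family pair
    are excluded (listed in the report).  RD averages
    ``(d_diff - d_same)/d_diff`` over recognized superfamilies only;
    recognized superfamilies with ``d_diff == 0`` are dropped from the RD
    mean with a warning.
    """
    rows = []
    excluded: list[str] = []
    for sf in bench.superfamilies():
        within, between = bench.pair_samples(sf)
        if within.size == 0 or between.size == 0:
            excluded.append(sf)
            continue
        p = mann_whitney_p(within, between)
        rows.append(
            {
                "superfamily": sf,
                "p_value": p,
                "sfsd": sfsd(bench, sf),
                "d_same_mean": float(within.mean()),
                "d_diff_mean": float(between.mean()),
                "n_within": within.size,
                "n_between": between.size,
                "in_Q": bool(p < alpha),
            }
        )
    if not rows:
        raise PadistError("no evaluable superfamily (need within and between pairs)")
    table = pd.DataFrame(rows).set_index("superfamily")
    rr = float(table["in_Q"].mean())
    q = table[table["in_Q"]]
    terms = []
    for sf, row in q.iterrows():
        if row["d_diff_mean"] == 0:
            warnings.warn(
                f"{sf}: zero mean between-family distance, excluded from RD",
                stacklevel=2,
            )
            continue
        terms.append(
            (row["d_diff_mean"] - row["d_same_mean"]) / row["d_diff_mean"]
        )
    rd = float(np.mean(terms)) if terms else float("nan")
    return RRRDReport(
        per_superfamily=table,
        rr=rr,
        rd=rd,
        n_evaluable=len(table),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# TM-score utilities


def combine_tm(tm_i: float, tm_j: float, n_i: int, n_j: int) -> float:
    """Length-weighted combination of two chain-normalized TM-scores.

    ``(n_i*tm_i + n_j*tm_j) / (n_i + n_j)`` — symmetric in the chain used
    for normalization.
    """
    if not (0 <= tm_i <= 1 and 0 <= tm_j <= 1):
        raise PadistError("TM-scores must lie in [0, 1]")
    if n_i <= 0 or n_j <= 0:
        raise PadistError("chain lengths must be positive")
    return (n_i * tm_i + n_j * tm_j) / (n_i + n_j)


def tm_d0(n: int) -> float:
    """TM-score distance scale factor, ``1.24*(n-15)^(1/3) - 1.8``.

    Clamped below at 0.5 (the raw formula goes negative for short chains).
    """
    if n < 1:
        raise PadistError("chain length must be >= 1")
    raw = 1.24 * np.cbrt(n - 15.0) - 1.8
    return float(max(raw, 0.5))


# ---------------------------------------------------------------------------
# Structure correlation and nearest-homologue ranking


def correlate_with_structure(
    bench: SuperfamilyBench, n_bins: int = 10
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of pair distances with TM-scores, plus TM bins.

    Pools every pair that has a TM-score; bins are equal-width on [0, 1]
    with per-bin mean and (population) standard deviation of the distance.
    Empty bins carry NaN.  The correlation is NaN (missing) when either
    variable is constant.
    """
    if bench.tm_scores is None:
        raise PadistError("benchmark has no TM-scores")
    dists, tms = [], []
    for a, b in combinations(bench.dm.ids, 2):
        t = bench.tm(a, b)
        if t is None:
            continue
        dists.append(bench.dm.get(a, b))
        tms.append(t)
    if len(dists) < 2:
        raise PadistError("need at least 2 pairs with TM-scores")
    dists, tms = np.asarray(dists), np.asarray(tms)
    if np.std(dists) == 0 or np.std(tms) == 0:
        warnings.warn("constant input; correlation undefined", stacklevel=2)
        r = float("nan")
    else:
        r = float(stats.pearsonr(dists, tms).statistic)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(tms, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for k in range(n_bins):
        sel = dists[idx == k]
        rows.append(
            {
                "tm_lo": edges[k],
                "tm_hi": edges[k + 1],
                "n_pairs": sel.size,
                "mean_distance": float(sel.mean()) if sel.size else float("nan"),
                "sd_distance": float(np.std(sel, ddof=0)) if sel.size else float("nan"),
            }
        )
    return r, pd.DataFrame(rows)


def top1_homolog(query_id: str, dm: DistanceMatrix) -> str:
    """Closest non-self id to the query; lexicographic tie-break."""
    if len(dm) < 2:
        raise PadistError("need at least 2 taxa")
    qi = dm.index(query_id)
    best_id, best_d = None, None
    for j, other in enumerate(sorted(dm.ids)):
        if other == query_id:
            continue
        dist = dm.values[qi, dm.index(other)]
        if best_d is None or dist < best_d:
            best_id, best_d = other, dist
    return best_id
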