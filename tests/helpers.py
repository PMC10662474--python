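"""Shared test utilities: record builders and the alignment enumeration oracle."""

from __future__ import annotations

import warnings

import numpy as np

from padist.records import AA_ORDER, ProteinRecord


def onehot_record(rng: np.random.Generator, L: int, name: str = "r") -> ProteinRecord:
    """Record whose probability rows are one-hot on a random sequence."""
    idx = rng.integers(0, 20, L)
    return make_record(
        name,
        idx,
        np.eye(20)[idx],
        "".join("HEC"[i] for i in rng.integers(0, 3, L)),
        "".join("BE"[i] for i in rng.integers(0, 2, L)),
    )


def random_record(rng: np.random.Generator, L: int, name: str = "r") -> ProteinRecord:
    """Record with random (Dirichlet-ish) probability rows."""
    idx = rng.integers(0, 20, L)
    probs = rng.random((L, 20))
    probs /= probs.sum(axis=1, keepdims=True)
    return make_record(
        name,
        idx,
        probs,
        "".join("HEC"[i] for i in rng.integers(0, 3, L)),
        "".join("BE"[i] for i in rng.integers(0, 2, L)),
    )


def make_record(name, idx, probs, ss, acc) -> ProteinRecord:
    seq = "".join(AA_ORDER[i] for i in idx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short test sequences
        return ProteinRecord(name, seq, probs, ss, acc)


def gap_cost(k: int, d: float, e: float) -> float:
    return 0.0 if k == 0 else d + (k - 1) * e


def enumerate_matchings(n: int, m: int):
    """All monotone matchings between site sets of sizes n and m."""

    def rec(a0, b0):
        yield []
        for a in range(a0, n):
            for b in range(b0, m):
                for rest in rec(a + 1, b + 1):
                    yield [(a, b)] + rest

    return rec(0, 0)


def matching_score(pairs, n, m, S, d, e) -> float:
    """Score of one monotone matching under per-run affine gap costs."""
    s = sum(S[a, b] for a, b in pairs)
    pa = pb = -1
    for a, b in pairs:
        s += gap_cost(a - pa - 1, d, e) + gap_cost(b - pb - 1, d, e)
        pa, pb = a, b
    s += gap_cost(n - 1 - pa, d, e) + gap_cost(m - 1 - pb, d, e)
    return s


def oracle_align_score(S: np.ndarray, d: float, e: float) -> float:
    """Brute-force optimum over every global alignment (small inputs only)."""
    n, m = S.shape
    return max(
        matching_score(p, n, m, S, d, e) for p in enumerate_matchings(n, m)
    )
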