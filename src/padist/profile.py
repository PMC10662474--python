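"""Site-correlated feature profiles.

Each sequence site is expanded into a 640-dimensional vector that encodes
the correlation between a site and its right-hand neighbour:

* a 400-component block, the flattened outer product of the amino-acid
  probability vectors at sites ``i`` and ``i+1`` — the joint occurrence
  probability of every ordered residue pair at adjacent sites;
* a 240-component block crossing the joint accessibility state of the
  adjacent pair (BB, BE, EB, EE), the secondary-structure state of site
  ``i`` (H, E, C) and the amino-acid probabilities of site ``i`` —
  4 x 3 x 20 indicator-weighted probabilities.

Both blocks are probability distributions (each sums to 1), so every full
vector sums to 2.  The terminal site pairs with itself, keeping the profile
the same length as the sequence so alignment coordinates map one-to-one to
residues.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .records import (
    AA_INDEX,
    ACC_INDEX,
    SS_INDEX,
    ConsistencyError,
    PadistError,
    ProteinRecord,
)

PAIR_BLOCK = 400
STRUCT_BLOCK = 240
PROFILE_DIM = PAIR_BLOCK + STRUCT_BLOCK

_NORM_TOL = 1e-4


@dataclass
class FeatureProfile:
    """Per-site 640-dimensional feature vectors for one protein."""

    id: str
    vectors: np.ndarray = field(repr=False)
    ss: str
    acc: str
    ss_codes: np.ndarray = field(init=False, repr=False)
    acc_codes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[1] != PROFILE_DIM:
            raise ConsistencyError(
                f"{self.id}: profile vectors must be (L, {PROFILE_DIM}), "
                f"got {v.shape}"
            )
        L = v.shape[0]
        if len(self.ss) != L or len(self.acc) != L:
            raise ConsistencyError(f"{self.id}: ss/acc length != {L}")
        self.vectors = v
        self.ss_codes = np.array([SS_INDEX[s] for s in self.ss])
        self.acc_codes = np.array([ACC_INDEX[a] for a in self.acc])

    def __len__(self) -> int:
        return self.vectors.shape[0]


def _check_prob(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (20,):
        raise ConsistencyError(f"{name} must have 20 components")
    if np.any(p < 0) or abs(p.sum() - 1.0) > _NORM_TOL:
        raise ConsistencyError(f"{name} is not a probability vector")
    return p


def build_pair_block(p_i: np.ndarray, p_next: np.ndarray) -> np.ndarray:
    """Flattened 20x20 outer product of two per-site probability vectors.

    Entry ``(a, b)`` (row-major, ``a`` at site i, ``b`` at site i+1) is
    ``p_i[a] * p_next[b]``; the 400-vector sums to 1.
    """
    p_i = _check_prob(p_i, "p_i")
    p_next = _check_prob(p_next, "p_next")
    return np.outer(p_i, p_next).ravel()


def build_structure_block(
    acc_i: str, acc_next: str, ss_i: str, p_i: np.ndarray
) -> np.ndarray:
    """Indicator(acc pair) x indicator(ss) x p_i, flattened to 240.

    Exactly one 20-long slice — at (acc_i acc_next, ss_i) — is nonzero and
    equals ``p_i``, so the block sums to 1.
    """
    if acc_i not in ACC_INDEX or acc_next not in ACC_INDEX:
        raise ConsistencyError(f"invalid accessibility label {acc_i}{acc_next!r}")
    if ss_i not in SS_INDEX:
        raise ConsistencyError(f"invalid SS label {ss_i!r}")
    p_i = _check_prob(p_i, "p_i")
    block = np.zeros(STRUCT_BLOCK)
    pair = 2 * ACC_INDEX[acc_i] + ACC_INDEX[acc_next]  # BB, BE, EB, EE
    off = pair * 60 + SS_INDEX[ss_i] * 20
    block[off : off + 20] = p_i
    return block


def build_profile(rec: ProteinRecord) -> FeatureProfile:
    """Build the length-L feature profile of a record (requires L >= 2)."""
    L = len(rec)
    if L < 2:
        raise PadistError(
            f"{rec.id}: cannot build a profile for length {L} (< 2): "
            "no adjacent site pair exists"
        )
    P = rec.aa_probs
    nxt = np.arange(1, L + 1)
    nxt[-1] = L - 1  # terminal site pairs with itself
    Pn = P[nxt]
    pair = np.einsum("ia,ib->iab", P, Pn).reshape(L, PAIR_BLOCK)

    acc_i = np.array([ACC_INDEX[a] for a in rec.acc])
    acc_next = acc_i[nxt]
    ss_i = np.array([SS_INDEX[s] for s in rec.ss])
    struct = np.zeros((L, STRUCT_BLOCK))
    offsets = (2 * acc_i + acc_next) * 60 + ss_i * 20
    cols = offsets[:, None] + np.arange(20)[None, :]
    np.put_along_axis(struct, cols, P, axis=1)

    return FeatureProfile(rec.id, np.hstack([pair, struct]), rec.ss, rec.acc)


def dump_profile(profile: FeatureProfile, path: str | os.PathLike) -> None:
    """Plain-text debug dump: one site per line, 640 floats."""
    with open(path, "w") as fh:
        fh.write(f"# {profile.id} L={len(profile)} ss={profile.ss} "
                 f"acc={profile.acc}\n")
        for row in profile.vectors:
            fh.write(" ".join(f"{x:.8g}" for x in row) + "\n")


def save_profile(profile: FeatureProfile, path: str | os.PathLike) -> None:
    """Cache a profile as an .npz archive keyed by record id."""
    np.savez_compressed(
        path, id=profile.id, vectors=profile.vectors,
        ss=profile.ss, acc=profile.acc,
    )


def load_profile(path: str | os.PathLike) -> FeatureProfile:
    with np.load(path, allow_pickle=False) as z:
        return FeatureProfile(
            str(z["id"]), z["vectors"], str(z["ss"]), str(z["acc"])
        )
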