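"""Core record types shared across the package.

A :class:`ProteinRecord` bundles a protein sequence with its per-site raw
features: 20 amino-acid occurrence probabilities (PSSM-derived), a
three-state secondary-structure label (H/E/C) and a two-state solvent
accessibility label (B = buried, rASA < 20%; E = exposed).  That is 23 raw
feature dimensions per site (20 + 1 + 2), the input layer of the
feature-profile construction.

A :class:`DistanceMatrix` is a labelled symmetric matrix of pairwise
evolutionary distances with a zero diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: PSI-BLAST PSSM column order for the 20 standard amino acids.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: Secondary-structure states: alpha-helix, beta-strand, coil.
SS_ORDER = "HEC"
SS_INDEX = {s: i for i, s in enumerate(SS_ORDER)}

#: Solvent accessibility states: buried (rASA < 0.20) and exposed.
ACC_ORDER = "BE"
ACC_INDEX = {a: i for i, a in enumerate(ACC_ORDER)}

#: Strict rASA threshold below which a residue is labelled buried.
RASA_BURIED_THRESHOLD = 0.20

#: Working sequence-length range; records outside it are accepted with a warning.
LENGTH_RANGE = (50, 500)


class PadistError(Exception):
    """Base class for padist errors."""


class ParseError(PadistError):
    """A file could not be parsed (malformed line, unknown symbol...)."""


class ConsistencyError(PadistError):
    """Inputs disagree with each other (lengths, residue letters, ids...)."""


@dataclass
class ProteinRecord:
    """A protein sequence plus its per-site raw features.

    Parameters
    ----------
    id : str
        Unique identifier.
    sequence : str
        Amino-acid sequence over the 20-letter alphabet, length ``L``.
    aa_probs : (L, 20) ndarray
        Per-site amino-acid occurrence probabilities in :data:`AA_ORDER`
        column order.  Rows are renormalized to sum to 1 on construction.
    ss : str
        Length-``L`` secondary-structure string over ``{H, E, C}``.
    acc : str
        Length-``L`` accessibility string over ``{B, E}``.
    """

    id: str
    sequence: str
    aa_probs: np.ndarray
    ss: str
    acc: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(AA_ORDER)
        if bad:
            raise ConsistencyError(
                f"{self.id}: non-standard residue letters {sorted(bad)}"
            )
        L = len(self.sequence)
        probs = np.asarray(self.aa_probs, dtype=float)
        if probs.shape != (L, 20):
            raise ConsistencyError(
                f"{self.id}: aa_probs shape {probs.shape} != ({L}, 20)"
            )
        if np.any(probs < 0):
            raise ConsistencyError(f"{self.id}: negative aa_probs entries")
        sums = probs.sum(axis=1)
        if np.any(sums <= 0):
            raise ConsistencyError(f"{self.id}: aa_probs row with zero mass")
        self.aa_probs = probs / sums[:, None]
        if len(self.ss) != L or len(self.acc) != L:
            raise ConsistencyError(
                f"{self.id}: ss/acc length ({len(self.ss)}/{len(self.acc)}) != {L}"
            )
        if set(self.ss) - set(SS_ORDER):
            raise ConsistencyError(f"{self.id}: invalid SS symbols")
        if set(self.acc) - set(ACC_ORDER):
            raise ConsistencyError(f"{self.id}: invalid accessibility symbols")
        lo, hi = LENGTH_RANGE
        if not lo <= L <= hi:
            warnings.warn(
                f"{self.id}: length {L} outside the typical working range "
                f"[{lo}, {hi}]", stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def raw_features(self) -> np.ndarray:
        """Per-site raw feature matrix of shape (L, 23).

        Columns: 20 amino-acid probabilities, 1 secondary-structure state
        code (H=0, E=1, C=2), 2 accessibility indicator columns (B, E).
        """
        L = len(self)
        ss_code = np.array([SS_INDEX[s] for s in self.ss], dtype=float)
        acc_onehot = np.zeros((L, 2))
        acc_onehot[np.arange(L), [ACC_INDEX[a] for a in self.acc]] = 1.0
        return np.hstack([self.aa_probs, ss_code[:, None], acc_onehot])


@dataclass
class DistanceMatrix:
    """Symmetric labelled matrix of pairwise distances, zero diagonal."""

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        if len(set(self.ids)) != len(self.ids):
            raise ConsistencyError("duplicate ids in distance matrix")
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ConsistencyError(f"matrix shape {v.shape} != ({n}, {n})")
        if np.max(np.abs(v - v.T), initial=0.0) > 1e-6:
            raise ConsistencyError("matrix asymmetric beyond 1e-6")
        if np.max(np.abs(np.diag(v)), initial=0.0) > 1e-6:
            raise ConsistencyError("nonzero diagonal beyond 1e-6")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v
        self._index = {name: k for k, name in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, id_: str) -> int:
        return self._index[id_]

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        """Restrict / reorder to the given ids."""
        idx = [self.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)
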