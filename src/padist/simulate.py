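"""Synthetic fixtures: superfamily benchmarks and additive matrices.

The generator emulates the inputs of the distance pipeline without any
external tool: per superfamily an ancestor sequence is drawn uniformly,
family founders are derived by point substitutions at the between-family
rate, and family members from their founder at the (lower) within-family
rate; substitutions are i.i.d. per site with the target uniform over the
other 19 residues.  Pseudo-PSSM rows mix a one-hot on the observed residue
with the uniform background (weight ``c/(c+1)`` for concentration ``c``).

Local-structure labels are drawn for the ancestor — secondary structure as
geometric-length runs over {H, E, C}, rASA uniformly on [0, 1] (threshold
0.20 into buried/exposed) — and inherited along the same genealogy as the
sequence, with per-site redraws at the between-/within-family rates.  The
labels carry no dependence on residue identities, but they are conserved
within a family the way predicted structure is for near-identical
sequences.  All of this is bit-reproducible given the seed.

``make_additive_matrix`` produces a random binary tree with branch lengths
uniform on [0.1, 1] together with its exact leaf-to-leaf path-length
matrix — the consistency oracle for distance-based tree building.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from . import io as pio
from .records import AA_ORDER, DistanceMatrix, PadistError, ProteinRecord
from .tree import tree_distance_matrix

_SS_MEAN_RUN = 5.0  # mean secondary-structure run length (residues)


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic superfamily benchmark.

    Defaults: 10 superfamilies of 3 families x 4 proteins, lengths 60-120,
    substitution rates 0.05 per site within families versus 0.5 between
    (the separation the RR/RD statistics assume), pseudo-PSSM
    concentration 4 (rows are 80% one-hot, 20% uniform).
    """

    seed: int = 0
    n_superfamilies: int = 10
    families_per_sf: int = 3
    proteins_per_family: int = 4
    length_range: tuple[int, int] = (60, 120)
    within_family_subs: float = 0.05
    between_family_subs: float = 0.5
    pssm_concentration: float = 4.0

    def __post_init__(self) -> None:
        if min(self.n_superfamilies, self.families_per_sf,
               self.proteins_per_family) < 1:
            raise PadistError("all counts must be >= 1")
        lo, hi = self.length_range
        if not (10 <= lo <= hi <= 1000):
            raise PadistError("length range must lie within [10, 1000]")
        if not self.between_family_subs > self.within_family_subs:
            raise PadistError(
                "between_family_subs must exceed within_family_subs"
            )
        if not 0 <= self.within_family_subs <= 1:
            raise PadistError("substitution rates are per-site probabilities")
        if self.pssm_concentration < 0:
            raise PadistError("pssm_concentration must be >= 0")


@dataclass
class SyntheticBenchmark:
    """Generated records, labels, per-record rASA and generating trees."""

    records: list[ProteinRecord]
    family_of: dict[str, str]
    superfamily_of: dict[str, str]
    rasa: dict[str, np.ndarray] = field(repr=False)
    truth_trees: dict[str, dendropy.Tree] = field(repr=False)


def _mutate(idx: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. per-site substitution, target uniform over the other 19."""
    mask = rng.random(idx.size) < rate
    shift = 1 + rng.integers(0, 19, size=idx.size)
    return np.where(mask, (idx + shift) % 20, idx)


def _draw_ss(L: int, rng: np.random.Generator) -> str:
    out: list[str] = []
    while len(out) < L:
        state = "HEC"[rng.integers(3)]
        run = int(rng.geometric(1.0 / _SS_MEAN_RUN))
        out.extend(state * min(run, L - len(out)))
    return "".join(out)


def _flip_ss(ss: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site redraw of SS state codes (uniform over the other 2 states)."""
    mask = rng.random(ss.size) < rate
    shift = 1 + rng.integers(0, 2, size=ss.size)
    return np.where(mask, (ss + shift) % 3, ss)


def _flip_rasa(rasa: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site redraw of rASA values, uniform on [0, 1]."""
    mask = rng.random(rasa.size) < rate
    return np.where(mask, rng.random(rasa.size), rasa)


def _pseudo_pssm(idx: np.ndarray, concentration: float) -> np.ndarray:
    w = concentration / (concentration + 1.0) if np.isfinite(concentration) else 1.0
    probs = np.full((idx.size, 20), (1.0 - w) / 20.0)
    probs[np.arange(idx.size), idx] += w
    return probs


def make_superfamily(cfg: SyntheticConfig) -> SyntheticBenchmark:
    """Generate the full benchmark described by *cfg* (deterministic)."""
    rng = np.random.default_rng(cfg.seed)
    records: list[ProteinRecord] = []
    family_of: dict[str, str] = {}
    superfamily_of: dict[str, str] = {}
    rasa_of: dict[str, np.ndarray] = {}
    truth: dict[str, dendropy.Tree] = {}
    lo, hi = cfg.length_range
    for s in range(cfg.n_superfamilies):
        sf = f"sf{s:03d}"
        L = int(rng.integers(lo, hi + 1))
        ancestor = rng.integers(0, 20, size=L)
        anc_ss = np.array(["HEC".index(c) for c in _draw_ss(L, rng)])
        anc_rasa = rng.random(L)
        fam_clades = []
        for f in range(cfg.families_per_sf):
            fam = f"{sf}_f{f}"
            founder = _mutate(ancestor, cfg.between_family_subs, rng)
            founder_ss = _flip_ss(anc_ss, cfg.between_family_subs, rng)
            founder_rasa = _flip_rasa(anc_rasa, cfg.between_family_subs, rng)
            members = []
            for p in range(cfg.proteins_per_family):
                name = f"{fam}_p{p}"
                idx = _mutate(founder, cfg.within_family_subs, rng)
                seq = "".join(AA_ORDER[i] for i in idx)
                probs = _pseudo_pssm(idx, cfg.pssm_concentration)
                ss_codes = _flip_ss(founder_ss, cfg.within_family_subs, rng)
                ss = "".join("HEC"[i] for i in ss_codes)
                rasa = _flip_rasa(founder_rasa, cfg.within_family_subs, rng)
                acc = "".join("B" if x < 0.20 else "E" for x in rasa)
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")  # lengths < 50 allowed here
                    rec = ProteinRecord(name, seq, probs, ss, acc)
                records.append(rec)
                family_of[name] = fam
                superfamily_of[name] = sf
                rasa_of[name] = rasa
                members.append(f"{name}:{cfg.within_family_subs:g}")
            fam_clades.append(
                f"({','.join(members)}):{cfg.between_family_subs:g}"
            )
        nwk = f"({','.join(fam_clades)});"
        t = dendropy.Tree.get(data=nwk, schema="newick",
                              preserve_underscores=True)
        t.is_rooted = False
        truth[sf] = t
    return SyntheticBenchmark(records, family_of, superfamily_of,
                              rasa_of, truth)


def make_additive_matrix(
    n_leaves: int, seed: int
) -> tuple[dendropy.Tree, DistanceMatrix]:
    """Random binary tree + its exact path-length distance matrix."""
    if n_leaves < 3:
        raise PadistError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    leaves = [f"t{i:03d}" for i in range(n_leaves)]

    def grow(names: list[str]) -> str:
        if len(names) == 1:
            return names[0]
        k = int(rng.integers(1, len(names)))
        perm = rng.permutation(len(names))
        left = [names[i] for i in perm[:k]]
        right = [names[i] for i in perm[k:]]
        bl, br = rng.uniform(0.1, 1.0, size=2)
        return f"({grow(left)}:{bl:.12g},{grow(right)}:{br:.12g})"

    tree = dendropy.Tree.get(
        data=grow(leaves) + ";", schema="newick", preserve_underscores=True
    )
    tree.is_rooted = False
    return tree, tree_distance_matrix(tree)


def write_fixture_dir(
    bench: SyntheticBenchmark, outdir: str | os.PathLike,
    cfg: SyntheticConfig | None = None,
) -> None:
    """Write FASTA, pseudo-PSSMs, SS/rASA tables, labels and truth trees.

    Lays the files out exactly as the command-line pipeline expects:
    ``sequences.fasta``, ``pssm/<id>.pssm``, ``struct/<id>.ss.tsv``,
    ``labels.tsv`` and ``truth/<superfamily>.nwk``.
    """
    outdir = Path(outdir)
    (outdir / "pssm").mkdir(parents=True, exist_ok=True)
    (outdir / "struct").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    pio.write_fasta(
        {r.id: r.sequence for r in bench.records}, outdir / "sequences.fasta"
    )
    for rec in bench.records:
        pio.write_pssm(outdir / "pssm" / f"{rec.id}.pssm", rec.sequence,
                       rec.aa_probs)
        pio.write_local_structure(
            outdir / "struct" / f"{rec.id}.ss.tsv", rec.sequence, rec.ss,
            bench.rasa[rec.id],
        )
    with open(outdir / "labels.tsv", "w") as fh:
        fh.write("id\tfamily\tsuperfamily\n")
        for rec in bench.records:
            fh.write(
                f"{rec.id}\t{bench.family_of[rec.id]}\t"
                f"{bench.superfamily_of[rec.id]}\n"
            )
    from .tree import write_newick

    for sf, t in bench.truth_trees.items():
        write_newick(t, outdir / "truth" / f"{sf}.nwk")
    if cfg is not None:
        import dataclasses
        import json

        with open(outdir / "config.json", "w") as fh:
            json.dump(dataclasses.asdict(cfg), fh, indent=2)
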