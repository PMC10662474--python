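"""Readers and writers for the formats around the distance pipeline.

Supported formats:

* FASTA sequences (via Biopython).
* PSI-BLAST ASCII PSSM (the ``-out_ascii_pssm`` dialect): per-residue rows
  carrying 20 log-odds integers followed by 20 weighted observed
  percentages.  The percentages, divided by 100 and renormalized, are the
  per-site amino-acid occurrence probabilities used downstream.
* Per-residue local-structure tables (SPIDER2-style layout, or any
  whitespace table whose first four columns are position, residue, SS label
  and rASA).  rASA may be a fraction or a percentage; percentages are
  auto-detected (any value > 1.5) and divided by 100.
* Square PHYLIP distance matrices, relaxed dialect: whitespace-delimited
  names up to 50 characters, so SCOP-style identifiers survive.

Internally everything is 0-based; the 1-based conventions of the file
formats are translated at the boundary.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .records import (
    AA_INDEX,
    AA_ORDER,
    RASA_BURIED_THRESHOLD,
    SS_ORDER,
    ConsistencyError,
    DistanceMatrix,
    ParseError,
    ProteinRecord,
)

MAX_PHYLIP_NAME = 50


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ConsistencyError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ParseError(f"no sequences found in {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def read_pssm(path: str | os.PathLike, sequence: str) -> np.ndarray:
    """Parse a PSI-BLAST ASCII PSSM into per-site probability rows.

    Returns an (L, 20) array in :data:`~padist.records.AA_ORDER` column
    order.  The 20 weighted-observed-percentage columns are divided by 100
    and renormalized row-wise; rows whose percentages are all zero fall back
    to a one-hot vector on the observed residue.
    """
    sequence = sequence.upper()
    rows: list[np.ndarray] = []
    residues: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if len(tok) < 3 or not tok[0].isdigit():
                continue  # header, footer statistics, blank lines
            if len(tok) not in (42, 44):
                raise ParseError(
                    f"{path}:{lineno}: expected 42 or 44 columns, got {len(tok)}"
                )
            pos = int(tok[0])
            if pos != len(rows) + 1:
                raise ParseError(
                    f"{path}:{lineno}: position {pos} out of order "
                    f"(expected {len(rows) + 1})"
                )
            aa = tok[1].upper()
            try:
                pct = np.array([float(x) for x in tok[22:42]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})")
            if np.any(pct < 0):
                raise ParseError(f"{path}:{lineno}: negative percentage")
            residues.append(aa)
            rows.append(pct)
    L = len(sequence)
    if len(rows) != L:
        raise ConsistencyError(
            f"{path}: {len(rows)} PSSM rows for a length-{L} sequence"
        )
    mismatches = [i for i, (a, b) in enumerate(zip(residues, sequence)) if a != b]
    if mismatches:
        i = mismatches[0]
        raise ConsistencyError(
            f"{path}: residue mismatch at position {i + 1}: "
            f"PSSM {residues[i]!r} vs sequence {sequence[i]!r}"
        )
    probs = np.array(rows) / 100.0
    for i in range(L):
        s = probs[i].sum()
        if s <= 0:
            probs[i] = 0.0
            probs[i, AA_INDEX[sequence[i]]] = 1.0
        else:
            probs[i] /= s
    return probs


def write_pssm(
    path: str | os.PathLike, sequence: str, probs: np.ndarray
) -> None:
    """Write probability rows in the PSI-BLAST ASCII PSSM dialect.

    Percentages are rounded to integers (as PSI-BLAST prints them); the
    log-odds columns are filled with a rounded log-ratio against the uniform
    background so the file looks like the real thing to any parser.
    """
    probs = np.asarray(probs, dtype=float)
    L = len(sequence)
    if probs.shape != (L, 20):
        raise ConsistencyError(f"probs shape {probs.shape} != ({L}, 20)")
    hdr = " ".join(AA_ORDER)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        fh.write("           " + hdr + "  " + hdr + "\n")
        for i, aa in enumerate(sequence):
            p = probs[i]
            with np.errstate(divide="ignore"):
                lo = np.rint(2.0 * np.log2(np.where(p > 0, p, 1e-9) / 0.05))
            lo = np.clip(lo, -9, 11).astype(int)
            pct = np.rint(p * 100).astype(int)
            cells = "".join(f"{v:4d}" for v in lo) + "".join(
                f"{v:4d}" for v in pct
            )
            fh.write(f"{i + 1:5d} {aa} {cells}  0.50 1.00\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# Local structure (SS + rASA) tables


def read_local_structure(
    path: str | os.PathLike, sequence: str
) -> tuple[str, str]:
    """Read a per-residue SS/rASA table; return (ss, acc) strings.

    Accepts SPIDER2-style tables or the minimal TSV dialect
    ``pos  aa  ss  rasa``; only the first four columns are used.  rASA
    values are auto-detected as percentages when any exceeds 1.5.  A residue
    is buried (``B``) when rASA < 0.20, exposed (``E``) otherwise — the
    threshold is strict, so exactly 0.20 is exposed.
    """
    sequence = sequence.upper()
    ss_labels: list[str] = []
    residues: list[str] = []
    rasa: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if not tok[0].lstrip("-").isdigit():
                continue  # column-header line
            if len(tok) < 4:
                raise ParseError(
                    f"{path}:{lineno}: expected >=4 columns, got {len(tok)}"
                )
            aa, ss = tok[1].upper(), tok[2].upper()
            if ss not in SS_ORDER:
                raise ParseError(
                    f"{path}:{lineno}: unknown SS symbol {tok[2]!r}"
                )
            try:
                r = float(tok[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad rASA value {tok[3]!r}")
            residues.append(aa)
            ss_labels.append(ss)
            rasa.append(r)
    L = len(sequence)
    if len(residues) != L:
        raise ConsistencyError(
            f"{path}: {len(residues)} rows for a length-{L} sequence"
        )
    mismatches = [i for i, (a, b) in enumerate(zip(residues, sequence)) if a != b]
    if mismatches:
        i = mismatches[0]
        raise ConsistencyError(
            f"{path}: residue mismatch at position {i + 1}: "
            f"{residues[i]!r} vs {sequence[i]!r}"
        )
    r = np.array(rasa)
    if np.any(r > 1.5):  # values given as percentages
        r = r / 100.0
    acc = "".join("B" if x < RASA_BURIED_THRESHOLD else "E" for x in r)
    return "".join(ss_labels), acc


def write_local_structure(
    path: str | os.PathLike, sequence: str, ss: str, rasa: np.ndarray
) -> None:
    """Write the minimal TSV local-structure dialect (pos, aa, ss, rasa)."""
    with open(path, "w") as fh:
        fh.write("# pos\taa\tss\trasa\n")
        for i, (aa, s, r) in enumerate(zip(sequence, ss, rasa)):
            fh.write(f"{i + 1}\t{aa}\t{s}\t{r:.4f}\n")


# ---------------------------------------------------------------------------
# Record assembly


def load_records(
    fasta_path: str | os.PathLike,
    pssm_dir: str | os.PathLike,
    struct_dir: str | os.PathLike,
    pssm_suffix: str = ".pssm",
    struct_suffix: str = ".ss.tsv",
) -> list[ProteinRecord]:
    """Assemble ProteinRecords from a FASTA file plus per-id feature files.

    Per-id files are discovered by naming convention: ``<id><pssm_suffix>``
    in *pssm_dir* and ``<id><struct_suffix>`` in *struct_dir*.
    """
    seqs = read_fasta(fasta_path)
    pssm_dir, struct_dir = Path(pssm_dir), Path(struct_dir)
    missing = [
        name
        for name in seqs
        if not (pssm_dir / f"{name}{pssm_suffix}").exists()
        or not (struct_dir / f"{name}{struct_suffix}").exists()
    ]
    if missing:
        raise ConsistencyError(
            f"missing PSSM or structure files for ids: {', '.join(missing)}"
        )
    records = []
    for name, seq in seqs.items():
        probs = read_pssm(pssm_dir / f"{name}{pssm_suffix}", seq)
        ss, acc = read_local_structure(struct_dir / f"{name}{struct_suffix}", seq)
        records.append(ProteinRecord(name, seq, probs, ss, acc))
    return records


# ---------------------------------------------------------------------------
# PHYLIP square distance matrices


def write_phylip(dm: DistanceMatrix, path: str | os.PathLike) -> None:
    """Write a square PHYLIP distance matrix (relaxed names, <=50 chars)."""
    too_long = [i for i in dm.ids if len(i) > MAX_PHYLIP_NAME]
    if too_long:
        raise ConsistencyError(f"ids longer than {MAX_PHYLIP_NAME}: {too_long}")
    if any(any(c.isspace() for c in i) for i in dm.ids):
        raise ConsistencyError("whitespace in taxon ids")
    width = max(10, max(len(i) for i in dm.ids)) + 2
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for name, row in zip(dm.ids, dm.values):
            cells = " ".join(f"{x:.10f}" for x in row)
            fh.write(f"{name:<{width}}{cells}\n")


def read_phylip(path: str | os.PathLike) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix (relaxed dialect)."""
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(tokens[0])
    except ValueError:
        raise ParseError(f"{path}: first token {tokens[0]!r} is not a count")
    expected = 1 + n * (n + 1)
    if len(tokens) != expected:
        raise ParseError(
            f"{path}: expected {expected} tokens for a square {n}-taxon "
            f"matrix, got {len(tokens)}"
        )
    ids, rows = [], []
    k = 1
    for _ in range(n):
        ids.append(tokens[k])
        try:
            rows.append([float(x) for x in tokens[k + 1 : k + 1 + n]])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric distance ({exc})")
        k += 1 + n
    return DistanceMatrix(ids, np.array(rows))
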