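"""Readers and writers for the formats the tool touches.

Supported formats:

* multi-record FASTA (sequences);
* per-residue disorder labels in a simple three-line dialect
  (``>id`` / sequence line / label line of ``0``/``1`` characters);
* PSI-BLAST ASCII PSSM files (the ``-out_ascii_pssm`` dialect) — only the
  first 20 log-odds columns are retained, in the canonical residue order;
* per-residue prediction TSV (id, 1-based position, residue, probability,
  call).

Residue indexing is 1-based in every file this module writes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import AMINO_ACIDS, NONSTANDARD, is_standard
from .errors import DataError

__all__ = [
    "ProteinRecord",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "read_labeled_fasta",
    "read_pssm",
    "write_pssm",
    "write_predictions",
    "read_predictions",
]


@dataclass
class ProteinRecord:
    """A protein sequence with optional per-residue disorder labels.

    ``labels[i] == 1`` marks residue ``i`` (0-based internally) as
    disordered.  Nonstandard residues (B, J, O, U, X, Z) are accepted and
    flagged; downstream feature modules each document how they treat them.
    """

    id: str
    sequence: str
    labels: np.ndarray | None = None
    nonstandard_positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if len(self.labels) != len(self.sequence):
                raise DataError(
                    f"record {self.id!r}: {len(self.labels)} labels for "
                    f"{len(self.sequence)} residues"
                )
        bad = [c for c in set(self.sequence) if not is_standard(c)]
        unknown = [c for c in bad if c not in NONSTANDARD]
        if unknown:
            raise DataError(f"record {self.id!r}: unknown residue symbols {unknown}")
        self.nonstandard_positions = tuple(
            i for i, c in enumerate(self.sequence) if not is_standard(c)
        )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_nonstandard(self) -> bool:
        return bool(self.nonstandard_positions)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file, preserving file order.

    Sequences are uppercased.  An empty file yields an empty list with a
    warning; a non-empty file from which no record can be parsed is an
    error.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
        return []
    if not text.lstrip().startswith(">"):
        first_bad = next(
            i + 1 for i, line in enumerate(text.splitlines()) if line.strip()
        )
        raise DataError(f"{path}: malformed FASTA header at line {first_bad}")
    records = [
        ProteinRecord(id=r.id, sequence=str(r.seq))
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise DataError(f"{path}: no FASTA records could be parsed")
    return records


def write_fasta(path: str | Path, records: Iterable[ProteinRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_labels(path: str | Path) -> dict[str, np.ndarray]:
    """Read per-residue disorder labels in the three-line dialect.

    Each entry is ``>id``, a sequence line, and a label line of '0'/'1' of
    equal length (1 = disordered).  Returns a map id -> int8 vector.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) % 3 != 0:
        raise DataError(f"{path}: expected groups of 3 lines, got {len(lines)} lines")
    out: dict[str, np.ndarray] = {}
    for i in range(0, len(lines), 3):
        header, seq, lab = lines[i : i + 3]
        if not header.startswith(">"):
            raise DataError(f"{path}: expected '>' header at line group {i // 3 + 1}")
        pid = header[1:].split()[0]
        if len(seq) != len(lab):
            raise DataError(
                f"{path}: record {pid!r}: label line length {len(lab)} != "
                f"sequence length {len(seq)}"
            )
        if set(lab) - {"0", "1"}:
            raise DataError(f"{path}: record {pid!r}: labels must be 0/1")
        out[pid] = np.frombuffer(lab.encode(), dtype=np.uint8).astype(np.int8) - ord("0")
    return out


def write_labels(path: str | Path, records: Iterable[ProteinRecord]) -> None:
    """Write labelled records in the three-line dialect read by read_labels."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.labels is None:
                raise DataError(f"record {rec.id!r} has no labels")
            fh.write(f">{rec.id}\n{rec.sequence}\n")
            fh.write("".join(str(int(v)) for v in rec.labels) + "\n")


def read_labeled_fasta(fasta_path: str | Path, label_path: str | Path) -> list[ProteinRecord]:
    """Read sequences plus a label file and attach labels by id.

    This is the loader interface for deposited disorder corpora laid out as
    a FASTA plus an aligned label file.
    """
    records = read_fasta(fasta_path)
    labels = read_labels(label_path)
    out = []
    for rec in records:
        if rec.id not in labels:
            raise DataError(f"no labels for record {rec.id!r}")
        out.append(ProteinRecord(rec.id, rec.sequence, labels[rec.id]))
    return out


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def read_pssm(path: str | Path, record: ProteinRecord | None = None) -> np.ndarray:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into an L x 20 float matrix.

    Rows follow the residue order of the query sequence; only the first 20
    numeric columns (the log-odds scores) are retained, in the canonical
    A..V column order used throughout the package.  When ``record`` is
    given, the row count is checked against the sequence length.
    """
    path = Path(path)
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        parts = line.split()
        # Data rows start with a residue index followed by the residue letter.
        if len(parts) >= 22 and parts[0].isdigit() and len(parts[1]) == 1 and parts[1].isalpha():
            try:
                scores = [float(v) for v in parts[2:22]]
            except ValueError as exc:
                raise DataError(f"{path}: unparseable PSSM row at line {lineno}") from exc
            rows.append(scores)
    if not rows:
        raise DataError(f"{path}: no PSSM data rows found")
    values = np.array(rows, dtype=np.float64)
    if record is not None and values.shape[0] != len(record):
        raise DataError(
            f"{path}: {values.shape[0]} PSSM rows but record {record.id!r} "
            f"has {len(record)} residues"
        )
    return values


def write_pssm(path: str | Path, record: ProteinRecord, values: np.ndarray) -> None:
    """Write an L x 20 score matrix in the PSI-BLAST ASCII dialect.

    Emits the two header lines, the double column header, one row per
    residue (index, residue, 20 integer-formatted log-odds, then 20 dummy
    percentage columns and two trailing floats, as real PSI-BLAST output
    carries), and a blank footer.  Round-trips through :func:`read_pssm`.
    """
    values = np.asarray(values)
    if values.shape != (len(record), 20):
        raise DataError(
            f"PSSM shape {values.shape} does not match record length {len(record)}"
        )
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed, weighted "
                 "observed percentages rounded down, information per position, "
                 "and relative weight of gapless real matches to pseudocounts\n")
        fh.write(" " * 11 + "  ".join(AMINO_ACIDS) + "   " + "  ".join(AMINO_ACIDS) + "\n")
        for i, (aa, row) in enumerate(zip(record.sequence, values), start=1):
            scores = " ".join(f"{v:3.0f}" for v in row)
            percents = " ".join("  0" for _ in range(20))
            fh.write(f"{i:5d} {aa} {scores} {percents}  0.00 0.00\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

_PRED_HEADER = "protein_id\tposition\tresidue\tprobability\tcall"


def write_predictions(
    path: str | Path,
    records: Sequence[ProteinRecord],
    probabilities: Sequence[np.ndarray],
    calls: Sequence[np.ndarray],
) -> None:
    """Write per-residue predictions as TSV (positions are 1-based)."""
    if not (len(records) == len(probabilities) == len(calls)):
        raise DataError("records, probabilities and calls must align")
    with open(path, "w") as fh:
        fh.write(_PRED_HEADER + "\n")
        for rec, probs, cs in zip(records, probabilities, calls):
            probs = np.asarray(probs, dtype=float)
            cs = np.asarray(cs, dtype=int)
            if not (len(rec) == len(probs) == len(cs)):
                raise DataError(f"record {rec.id!r}: prediction length mismatch")
            for j, (aa, p, c) in enumerate(zip(rec.sequence, probs, cs), start=1):
                fh.write(f"{rec.id}\t{j}\t{aa}\t{p:.6f}\t{c}\n")


def read_predictions(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Parse a prediction TSV back into id -> (probabilities, calls)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("position")
        out[pid] = (grp["probability"].to_numpy(), grp["call"].to_numpy(dtype=int))
    return out
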