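"""Corpus k-mer probability tracks (PCAA2 / PCAA3).

A dipeptide (k=2) or tripeptide (k=3) table is built over a training corpus
by sliding a k-window one residue at a time across every sequence and
counting occurrences of each of the 400 / 8000 possible k-mers.  Counts are
converted to probabilities and min-max scaled to [0, 1].  A protein's
per-residue track H2 / H3 then averages the scaled values of the 1..k
k-mers that cover each position:

    H2(1) = N2(I2(1)),  H2(j) = (N2(I2(j-1)) + N2(I2(j)))/2 for 1 < j < L,
    H2(L) = N2(I2(L-1)),

and analogously for k=3 with up to three covering tripeptides.  K-mers
containing nonstandard residues are skipped in counting and contribute 0 to
the positional averages.

The lookup table does not require the query protein to belong to the
corpus: test proteins are scored with the training-corpus table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AMINO_ACIDS, is_standard
from .errors import DataError, NumericalError
from .seq_io import ProteinRecord

__all__ = [
    "KmerTable",
    "kmer_index",
    "count_kmers",
    "finalize_table",
    "build_kmer_table",
    "pcaa_track",
    "write_kmer_table",
    "read_kmer_table",
]


@dataclass
class KmerTable:
    """Counts, probabilities and min-max scaled values over the k-mer alphabet."""

    k: int
    counts: np.ndarray
    probs: np.ndarray | None = None
    scaled: np.ndarray | None = None
    corpus_id: str = ""

    def __post_init__(self) -> None:
        if self.k not in (2, 3):
            raise DataError("k must be 2 or 3")
        expected = 20 ** self.k
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (expected,):
            raise DataError(f"counts must have length {expected}")

    @property
    def size(self) -> int:
        return 20 ** self.k


def kmer_index(kmer: str) -> int | None:
    """1-based index of a k-mer in mixed-radix canonical-alphabet order.

    "AA" -> 1, "VV" -> 400, "AAA" -> 1, "VVV" -> 8000.  Returns None for
    k-mers containing a nonstandard residue.
    """
    k = len(kmer)
    if k not in (2, 3):
        raise DataError("k-mer length must be 2 or 3")
    idx = 0
    for c in kmer:
        if not is_standard(c):
            return None
        idx = idx * 20 + (AA_INDEX[c] - 1)
    return idx + 1


def _sequence_indices(sequence: str, k: int) -> np.ndarray:
    """0-based k-mer indices along a sequence; -1 where nonstandard."""
    codes = np.array([AA_INDEX.get(c, 0) - 1 for c in sequence], dtype=np.int64)
    L = len(sequence)
    if L < k:
        return np.empty(0, dtype=np.int64)
    idx = np.zeros(L - k + 1, dtype=np.int64)
    valid = np.ones(L - k + 1, dtype=bool)
    for t in range(k):
        part = codes[t : L - k + 1 + t]
        idx = idx * 20 + part
        valid &= part >= 0
    idx[~valid] = -1
    return idx


def count_kmers(corpus: Sequence[ProteinRecord], k: int, corpus_id: str = "") -> KmerTable:
    """Count k-mer occurrences across a corpus (sliding by one residue).

    K-mers containing nonstandard residues are skipped, so for a fully
    standard corpus the counts sum to ``sum_p (L_p - k + 1)``.
    """
    if not corpus:
        raise DataError("corpus is empty")
    counts = np.zeros(20 ** k, dtype=np.int64)
    any_kmer = False
    for rec in corpus:
        idx = _sequence_indices(rec.sequence, k)
        idx = idx[idx >= 0]
        if idx.size:
            any_kmer = True
            np.add.at(counts, idx, 1)
    if not any_kmer:
        warnings.warn(f"no countable length-{k} k-mers in corpus", stacklevel=2)
    return KmerTable(k=k, counts=counts, corpus_id=corpus_id)


def finalize_table(table: KmerTable) -> KmerTable:
    """Fill probabilities (counts / total) and min-max scaled values.

    Scaling maps the probability range onto [0, 1]; in the degenerate case
    where every k-mer is equally probable (range 0) all scaled values are 1.
    """
    total = int(table.counts.sum())
    if total == 0:
        raise NumericalError("empty corpus statistics: no k-mers were counted")
    probs = table.counts / total
    delta = float(probs.max() - probs.min())
    if delta == 0.0:
        scaled = np.ones_like(probs)
    else:
        scaled = (probs - probs.min()) / delta
    table.probs = probs
    table.scaled = scaled
    return table


def build_kmer_table(corpus: Sequence[ProteinRecord], k: int, corpus_id: str = "") -> KmerTable:
    """Convenience: count then finalize."""
    return finalize_table(count_kmers(corpus, k, corpus_id=corpus_id))


def pcaa_track(record: ProteinRecord, table: KmerTable) -> np.ndarray:
    """Per-residue track of averaged scaled k-mer probabilities, in [0, 1].

    Position j averages the scaled values of the k-mers covering it (one at
    the termini, up to k in the interior, with the fixed 1/2 and 1/3 weights
    of the covering count).  Nonstandard-containing k-mers contribute 0.
    """
    if table.scaled is None:
        raise DataError("k-mer table is not finalized")
    k = table.k
    L = len(record)
    if L < k:
        raise DataError(f"sequence shorter than k={k}")
    idx = _sequence_indices(record.sequence, k)  # length L-k+1, 0-based, -1 invalid
    vals = np.where(idx >= 0, table.scaled[np.clip(idx, 0, None)], 0.0)

    out = np.empty(L, dtype=np.float64)
    if k == 2:
        out[0] = vals[0]
        out[-1] = vals[-1]
        if L > 2:
            out[1:-1] = 0.5 * (vals[:-1] + vals[1:])
    else:
        out[0] = vals[0]
        out[-1] = vals[-1]
        if L > 2:
            out[1] = 0.5 * (vals[0] + vals[1]) if L >= 4 else vals[0]
        if L >= 4:
            out[-2] = 0.5 * (vals[-2] + vals[-1])
        if L >= 5:
            out[2:-2] = (vals[:-2] + vals[1:-1] + vals[2:]) / 3.0
    return out


# ---------------------------------------------------------------------------
# TSV serialization
# ---------------------------------------------------------------------------

def _kmer_string(index0: int, k: int) -> str:
    chars = []
    for _ in range(k):
        chars.append(AMINO_ACIDS[index0 % 20])
        index0 //= 20
    return "".join(reversed(chars))


def write_kmer_table(path: str | Path, table: KmerTable) -> None:
    """Serialize a finalized table as TSV (index, kmer, count, probability, scaled)."""
    if table.probs is None or table.scaled is None:
        raise DataError("finalize the table before writing")
    df = pd.DataFrame(
        {
            "index": np.arange(1, table.size + 1),
            "kmer": [_kmer_string(i, table.k) for i in range(table.size)],
            "count": table.counts,
            "probability": table.probs,
            "scaled": table.scaled,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# k={table.k} corpus={table.corpus_id}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_kmer_table(path: str | Path) -> KmerTable:
    """Load a table written by :func:`write_kmer_table`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise DataError(f"{path}: missing k-mer table header line")
        meta = dict(tok.split("=", 1) for tok in header[1:].split() if "=" in tok)
        df = pd.read_csv(fh, sep="\t")
    k = int(meta.get("k", 0))
    table = KmerTable(
        k=k,
        counts=df["count"].to_numpy(np.int64),
        corpus_id=meta.get("corpus", ""),
    )
    table.probs = df["probability"].to_numpy(np.float64)
    table.scaled = df["scaled"].to_numpy(np.float64)
    return table
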