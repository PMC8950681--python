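"""Assembly of the 35-row per-residue feature matrix.

Row semantics (1-based):

* rows 1-20: PSSM log-odds channels, window-averaged with zero padding;
* rows 21-27: the seven physicochemical scales, window-averaged likewise;
* rows 28-30: the three disorder propensities, window-averaged likewise;
* row 31: Shannon entropy of the residue window (terminal-residue padding);
* row 32: topological (subword-complexity) entropy of the window;
* row 33: persistent entropy of the window point cloud;
* rows 34-35: the PCAA2 / PCAA3 k-mer probability tracks (values in [0,1]).

The two padding conventions are deliberate: the thirty scalar channels are
averaged over windows padded with zeros, while the three entropy rows use
windows padded with copies of the terminal residues.
"""

from __future__ import annotations

import math
from collections import Counter
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import AA_INDEX
from .errors import DataError
from .kmers import KmerTable, pcaa_track
from .scales import ScaleTable, default_scales
from .seq_io import ProteinRecord
from .tda import persistent_entropy_track

__all__ = [
    "FEATURE_ROW_NAMES",
    "windowed_average_track",
    "shannon_entropy_track",
    "topological_entropy_track",
    "assemble_feature_matrix",
    "pseudo_pssm",
    "write_feature_tsv",
    "read_feature_tsv",
]

FEATURE_ROW_NAMES: tuple[str, ...] = (
    tuple(f"pssm_{aa}" for aa in "ARNDCQEGHILKMFPSTWYV")
    + (
        "steric_parameter",
        "polarizability",
        "volume",
        "hydrophobicity",
        "isoelectric_point",
        "helix_probability",
        "sheet_probability",
        "remark465_propensity",
        "deleage_roux_propensity",
        "bfactor_2std_propensity",
        "shannon_entropy",
        "topological_entropy",
        "persistent_entropy",
        "pcaa2",
        "pcaa3",
    )
)


def _check_window(n: int, L: int) -> None:
    if n % 2 == 0:
        raise DataError("window size must be odd")
    if n >= L:
        raise DataError(f"window size {n} must be smaller than sequence length {L}")


def windowed_average_track(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with zero padding at both ends.

    Output j is the mean of the ``window`` padded values centred at j, so
    terminal positions are pulled toward zero.
    """
    values = np.asarray(values, dtype=np.float64)
    _check_window(window, len(values))
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="same")


def _padded_windows(sequence: str, window: int):
    half = (window - 1) // 2
    padded = sequence[0] * half + sequence + sequence[-1] * half
    for j in range(len(sequence)):
        yield padded[j : j + window]


def shannon_entropy_track(record: ProteinRecord, window: int) -> np.ndarray:
    """Shannon entropy (base 2) of residue frequencies per window.

    Windows are padded with terminal-residue copies, matching the other
    entropy features.  Values lie in [0, log2 20].
    """
    _check_window(window, len(record))
    out = np.empty(len(record), dtype=np.float64)
    for j, win in enumerate(_padded_windows(record.sequence, window)):
        counts = np.array(list(Counter(win).values()), dtype=np.float64)
        p = counts / window
        out[j] = float(-(p * np.log2(p)).sum())
    return out


def _topo_word_length(window: int) -> int:
    """Largest n with 20**n + n - 1 <= window."""
    n = 0
    while 20 ** (n + 1) + n <= window:
        n += 1
    return n


def topological_entropy_track(record: ProteinRecord, window: int) -> np.ndarray:
    """Subword-complexity (topological) entropy per window, in [0, 1].

    For word length n — the largest with ``20**n + n - 1 <= window`` — the
    value is ``log20(#distinct n-subwords of the first 20**n + n - 1 window
    characters) / n``.  Windows below 20 residues cannot calibrate even
    n = 1 and are an error.
    """
    _check_window(window, len(record))
    n = _topo_word_length(window)
    if n == 0:
        raise DataError(
            f"window {window} too small for topological entropy (need >= 20)"
        )
    prefix = 20 ** n + n - 1
    out = np.empty(len(record), dtype=np.float64)
    for j, win in enumerate(_padded_windows(record.sequence, window)):
        head = win[:prefix]
        distinct = len({head[i : i + n] for i in range(prefix - n + 1)})
        out[j] = math.log(distinct, 20) / n
    return out


def pseudo_pssm(record: ProteinRecord) -> np.ndarray:
    """BLOSUM62-row pseudo-profile for PSSM-free operation.

    Each residue's 20 scores are its BLOSUM62 substitution row — a crude
    stand-in for an alignment-derived profile, available without any
    database search.  Nonstandard residues get an all-zero row.
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    out = np.zeros((len(record), 20), dtype=np.float64)
    for i, aa in enumerate(record.sequence):
        if aa in AA_INDEX and aa in blosum.alphabet:
            for j, bb in enumerate("ARNDCQEGHILKMFPSTWYV"):
                out[i, j] = blosum[aa][bb]
    return out


def assemble_feature_matrix(
    record: ProteinRecord,
    pssm: np.ndarray | None,
    table2: KmerTable,
    table3: KmerTable,
    window: int = 33,
    scales: Sequence[ScaleTable] | None = None,
    tda_max_dim: int = 1,
    tda_cap: float | str = "auto",
    pssm_fallback: bool = False,
) -> np.ndarray:
    """Build the 35 x L feature matrix for one protein.

    ``pssm`` is the L x 20 log-odds profile; when None and
    ``pssm_fallback`` is set, a BLOSUM62 pseudo-profile is used instead
    (otherwise an error).  The topological-entropy row uses a window of at
    least 21 residues (the smallest that calibrates a word length), even
    when the sweep window is smaller.
    """
    L = len(record)
    _check_window(window, L)
    if scales is None:
        scales = default_scales()
    if len(scales) != 10:
        raise DataError(f"expected 10 scale tables, got {len(scales)}")
    if pssm is None:
        if not pssm_fallback:
            raise DataError(
                f"record {record.id!r}: no PSSM given and fallback disabled"
            )
        pssm = pseudo_pssm(record)
    pssm = np.asarray(pssm, dtype=np.float64)
    if pssm.shape != (L, 20):
        raise DataError(
            f"record {record.id!r}: PSSM shape {pssm.shape}, expected ({L}, 20)"
        )

    F = np.empty((35, L), dtype=np.float64)
    for c in range(20):
        F[c] = windowed_average_track(pssm[:, c], window)
    for s, scale in enumerate(scales):
        lookup = {aa: v for aa, v in zip("ARNDCQEGHILKMFPSTWYV", scale.vector())}
        raw = np.array([lookup.get(aa, 0.0) for aa in record.sequence])
        F[20 + s] = windowed_average_track(raw, window)
    F[30] = shannon_entropy_track(record, window)
    F[31] = topological_entropy_track(record, max(window, 21))
    F[32] = persistent_entropy_track(record, window, max_dim=tda_max_dim, cap=tda_cap)
    F[33] = pcaa_track(record, table2)
    F[34] = pcaa_track(record, table3)
    if not np.isfinite(F).all():
        raise DataError(f"record {record.id!r}: non-finite feature values")
    return F


def write_feature_tsv(path: str | Path, record: ProteinRecord, F: np.ndarray) -> None:
    """Export a feature matrix as TSV: one named row per feature, one column per residue."""
    if F.shape[0] != 35:
        raise DataError("feature matrix must have 35 rows")
    with open(path, "w") as fh:
        cols = "\t".join(f"{record.sequence[j]}{j + 1}" for j in range(F.shape[1]))
        fh.write(f"feature\t{cols}\n")
        for name, row in zip(FEATURE_ROW_NAMES, F):
            fh.write(name + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_feature_tsv(path: str | Path) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=np.float64)
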