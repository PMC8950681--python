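"""Synthetic corpora with planted order/disorder structure.

Generated proteins alternate ordered and disordered blocks.  Disordered
blocks draw residues from a composition biased toward disorder-promoting
residues (P, E, S, Q, K, G up-weighted); ordered blocks are biased toward
order-promoting ones (W, C, F, I, Y, V, L).  Block lengths are geometric;
the ordered-block mean is scaled so the expected disordered-residue
fraction matches ``disorder_fraction`` (default 0.2, the rough disorder
rate of curated disorder corpora).

Each protein also gets a fabricated PSSM: per residue, the rounded
log-odds of its generating state's composition against a uniform
background, plus seeded integer-rounded Gaussian noise — mimicking the
integer log-odds columns of PSI-BLAST ASCII output.  Corpora are exactly
reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import AMINO_ACIDS
from .errors import DataError
from .seq_io import ProteinRecord, write_fasta, write_labels, write_pssm

__all__ = ["SynthConfig", "default_planted_config", "generate_corpus", "write_corpus"]

_DISORDER_UP = "PESQKG"
_ORDER_UP = "WCFIYVL"
_BIAS = 3.0  # up-weight factor applied to the favoured residue set


def _biased_composition(up: str, factor: float = _BIAS) -> np.ndarray:
    w = np.ones(20)
    for aa in up:
        w[AMINO_ACIDS.index(aa)] *= factor
    return w / w.sum()


@dataclass
class SynthConfig:
    n_proteins: int = 60
    length_range: tuple[int, int] = (120, 200)
    disorder_fraction: float = 0.2
    mean_block_length: float = 30.0
    disorder_composition: np.ndarray = field(
        default_factory=lambda: _biased_composition(_DISORDER_UP)
    )
    order_composition: np.ndarray = field(
        default_factory=lambda: _biased_composition(_ORDER_UP)
    )
    pssm_noise: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise DataError("n_proteins must be >= 1")
        if not 0.0 < self.disorder_fraction < 1.0:
            raise DataError("disorder_fraction must lie strictly in (0, 1)")
        if self.length_range[0] < 2 or self.length_range[0] > self.length_range[1]:
            raise DataError("invalid length range")
        for name, comp in (
            ("disorder_composition", self.disorder_composition),
            ("order_composition", self.order_composition),
        ):
            comp = np.asarray(comp, dtype=float)
            if comp.shape != (20,) or not np.isclose(comp.sum(), 1.0):
                raise DataError(f"{name} must be a 20-simplex distribution")
        if self.pssm_noise < 0:
            raise DataError("pssm_noise must be >= 0")


def default_planted_config(scale: str = "small", seed: int = 0) -> SynthConfig:
    """The documented planted-signal configurations.

    ``small``: 60 proteins of length 120-200; ``standard``: 400 proteins
    of length 100-600.  Both use disorder fraction 0.2 and mean disordered
    block length 30.
    """
    if scale == "small":
        return SynthConfig(n_proteins=60, length_range=(120, 200), seed=seed)
    if scale == "standard":
        return SynthConfig(n_proteins=400, length_range=(100, 600), seed=seed)
    raise DataError(f"unknown scale {scale!r} (expected 'small' or 'standard')")


def _geometric_length(rng: np.random.Generator, mean: float) -> int:
    # support {1, 2, ...} with the requested mean
    return int(rng.geometric(1.0 / max(mean, 1.0)))


def generate_corpus(
    config: SynthConfig,
) -> tuple[list[ProteinRecord], dict[str, np.ndarray]]:
    """Generate labelled proteins and fabricated PSSMs.

    Returns (records, pssms-by-id).  Blocks alternate between ordered and
    disordered states; the first block is disordered with probability
    ``disorder_fraction``.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    f = config.disorder_fraction
    mean_dis = config.mean_block_length
    mean_ord = mean_dis * (1.0 - f) / f
    comps = {0: np.asarray(config.order_composition), 1: np.asarray(config.disorder_composition)}
    background = 0.05
    aa_arr = np.array(list(AMINO_ACIDS))

    records: list[ProteinRecord] = []
    pssms: dict[str, np.ndarray] = {}
    for p in range(config.n_proteins):
        L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        state = int(rng.random() < f)
        seq_parts: list[str] = []
        labels = np.empty(L, dtype=np.int8)
        pos = 0
        while pos < L:
            mean = mean_dis if state == 1 else mean_ord
            blen = min(_geometric_length(rng, mean), L - pos)
            draws = rng.choice(20, size=blen, p=comps[state])
            seq_parts.append("".join(aa_arr[draws]))
            labels[pos : pos + blen] = state
            pos += blen
            state = 1 - state
        sequence = "".join(seq_parts)
        rec = ProteinRecord(f"synth{p:04d}", sequence, labels)
        logodds = {
            s: 2.0 * np.log2(comps[s] / background) for s in (0, 1)
        }
        rows = np.stack([logodds[int(lab)] for lab in labels])
        rows = rows + rng.normal(0.0, config.pssm_noise, size=rows.shape)
        pssms[rec.id] = np.clip(np.round(rows), -12, 12)
        records.append(rec)
    return records, pssms


def write_corpus(
    out_dir: str | Path, records: list[ProteinRecord], pssms: dict[str, np.ndarray]
) -> None:
    """Write FASTA + label file + one ASCII PSSM per protein.

    Exercises the same writers/parsers used for real data, so synthetic
    runs cover the full I/O path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(out_dir / "sequences.fasta", records)
    write_labels(out_dir / "labels.txt", records)
    pssm_dir = out_dir / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    for rec in records:
        write_pssm(pssm_dir / f"{rec.id}.pssm", rec, pssms[rec.id])
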