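"""Per-residue scale tables: physicochemical descriptors and disorder propensities.

Seven physicochemical descriptors (steric parameter, polarizability, volume,
hydrophobicity, isoelectric point, helix probability, sheet probability) are
the reduced amino-acid parameter representation of Meiler et al. (2001),
transcribed here.

The three disorder-propensity channels are named after the GlobPlot
propensity variants (Remark465, Deleage/Roux, Bfactor(2STD)) but ship with
synthetic stand-in values: documented, deterministic tables that reproduce
the qualitative disorder-promoting vs. order-promoting residue split
(P, E, S, Q, K, G high; W, C, F, I, Y, V low) without claiming to be the
published numbers.  All tables are replaceable from a JSON config so users
can substitute their preferred scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .alphabet import AMINO_ACIDS
from .errors import DataError

__all__ = [
    "ScaleTable",
    "default_scales",
    "load_scales_json",
    "save_scales_json",
    "MEILER_PARAMETERS",
]


@dataclass(frozen=True)
class ScaleTable:
    """A named map from the 20 standard residues to real values."""

    name: str
    values: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        extra = set(self.values) - set(AMINO_ACIDS)
        if missing or extra:
            raise DataError(
                f"scale {self.name!r}: missing {sorted(missing)}, extra {sorted(extra)}"
            )

    def vector(self) -> list[float]:
        """Values in canonical A..V order."""
        return [self.values[aa] for aa in AMINO_ACIDS]


# Meiler, Mueller, Zeidler & Schmaeschke (2001), J Mol Model 7:360-369:
# steric parameter, polarizability, volume, hydrophobicity, isoelectric
# point, helix probability, sheet probability.
MEILER_PARAMETERS: dict[str, tuple[float, ...]] = {
    "A": (1.28, 0.05, 1.00, 0.31, 6.11, 0.42, 0.23),
    "R": (2.34, 0.29, 6.13, -1.01, 10.74, 0.36, 0.25),
    "N": (1.60, 0.13, 2.95, -0.60, 6.52, 0.21, 0.22),
    "D": (1.60, 0.11, 2.78, -0.77, 2.95, 0.25, 0.20),
    "C": (1.77, 0.13, 2.43, 1.54, 6.35, 0.17, 0.41),
    "Q": (1.56, 0.18, 3.95, -0.22, 5.65, 0.36, 0.25),
    "E": (1.56, 0.15, 3.78, -0.64, 3.09, 0.42, 0.21),
    "G": (0.00, 0.00, 0.00, 0.00, 6.07, 0.13, 0.15),
    "H": (2.99, 0.23, 4.66, 0.13, 7.69, 0.27, 0.30),
    "I": (4.19, 0.19, 4.00, 1.80, 6.04, 0.30, 0.45),
    "L": (2.59, 0.19, 4.00, 1.70, 6.04, 0.39, 0.31),
    "K": (1.89, 0.22, 4.77, -0.99, 9.99, 0.32, 0.27),
    "M": (2.35, 0.22, 4.43, 1.23, 5.71, 0.38, 0.32),
    "F": (2.94, 0.29, 5.89, 1.79, 5.67, 0.30, 0.38),
    "P": (2.67, 0.00, 2.72, 0.72, 6.80, 0.13, 0.34),
    "S": (1.31, 0.06, 1.60, -0.04, 5.70, 0.20, 0.28),
    "T": (3.03, 0.11, 2.60, 0.26, 5.60, 0.21, 0.36),
    "W": (3.21, 0.41, 8.08, 2.25, 5.94, 0.32, 0.42),
    "Y": (2.94, 0.30, 6.47, 0.96, 5.66, 0.25, 0.41),
    "V": (3.67, 0.14, 3.00, 1.22, 6.02, 0.27, 0.49),
}

_MEILER_NAMES = (
    "steric_parameter",
    "polarizability",
    "volume",
    "hydrophobicity",
    "isoelectric_point",
    "helix_probability",
    "sheet_probability",
)

# Synthetic stand-in disorder propensity (higher = more disorder-prone),
# calibrated to the canonical disorder-promoting residue ranking.
_DISORDER_PROPENSITY: dict[str, float] = {
    "P": 0.99, "E": 0.74, "K": 0.59, "S": 0.34, "Q": 0.32, "H": 0.30,
    "D": 0.19, "R": 0.18, "G": 0.17, "A": 0.06, "T": 0.06, "N": 0.01,
    "C": -0.02, "V": -0.12, "L": -0.33, "M": -0.40, "I": -0.49,
    "Y": -0.51, "F": -0.70, "W": -0.88,
}


def _propensity_variant(offset: float, gain: float, tweak: dict[str, float]) -> dict[str, float]:
    values = {aa: offset + gain * v for aa, v in _DISORDER_PROPENSITY.items()}
    for aa, dv in tweak.items():
        values[aa] += dv
    return values


def default_scales() -> list[ScaleTable]:
    """The ten packaged scale tables, in feature-matrix row order (rows 21-30)."""
    scales = [
        ScaleTable(name, {aa: vals[i] for aa, vals in MEILER_PARAMETERS.items()},
                   provenance="Meiler et al. 2001, J Mol Model 7:360-369")
        for i, name in enumerate(_MEILER_NAMES)
    ]
    prop_provenance = (
        "synthetic stand-in disorder propensity (not the published GlobPlot table)"
    )
    scales.append(ScaleTable(
        "remark465_propensity",
        _propensity_variant(0.0, 1.0, {"G": 0.15, "D": 0.10}),
        provenance=prop_provenance,
    ))
    scales.append(ScaleTable(
        "deleage_roux_propensity",
        _propensity_variant(1.0, 0.4, {"N": 0.12, "G": 0.20, "P": -0.10}),
        provenance=prop_provenance,
    ))
    scales.append(ScaleTable(
        "bfactor_2std_propensity",
        _propensity_variant(0.5, 0.6, {"K": 0.10, "E": 0.08, "T": 0.05}),
        provenance=prop_provenance,
    ))
    return scales


def save_scales_json(path: str | Path, scales: list[ScaleTable]) -> None:
    payload = [
        {"name": s.name, "provenance": s.provenance, "values": s.values}
        for s in scales
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_scales_json(path: str | Path) -> list[ScaleTable]:
    payload = json.loads(Path(path).read_text())
    return [
        ScaleTable(entry["name"], dict(entry["values"]), entry.get("provenance", ""))
        for entry in payload
    ]
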