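"""The 20-letter amino-acid alphabet and its canonical ordering.

Every indexed structure in the package (point-cloud embedding angles, k-mer
tables, PSSM columns, scale tables) uses this single ordering:
A, R, N, D, C, Q, E, G, H, I, L, K, M, F, P, S, T, W, Y, V.
"""

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

# 1-based index of each standard residue in the canonical order.
AA_INDEX = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}

# Ambiguity / nonstandard codes seen in real annotation databases.
NONSTANDARD = frozenset("BJOUXZ*")


def is_standard(residue: str) -> bool:
    return residue in AA_INDEX


def aa_index(residue: str) -> int:
    """1-based canonical index of a standard residue (KeyError otherwise)."""
    return AA_INDEX[residue]
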