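"""Per-residue feature tables and windowed residue-pair vectors.

Each residue gets F = 32 features: 20 PSSM log-odds, the two trailing PSSM
columns (information per position, relative weight), a 3-state secondary
structure one-hot, binary solvent accessibility, the five Atchley factors
and the relative sequence position p/L.  A residue-pair instance concatenates
two 9-residue windows (one per residue), zero-padded at the termini, giving
a fixed 2 * 9 * 32 = 576-dimensional vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ProteinRecord
from .io_formats import AA_ORDER, PSSMProfile

__all__ = [
    "ATCHLEY_FACTORS",
    "atchley_factors",
    "relative_position",
    "build_feature_table",
    "build_pair_vector",
    "ResidueFeatureTable",
    "PairFeatureVector",
    "N_FEATURES",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 9

# Five-factor solution scores per amino acid (factor I..V): bipolar/polarity,
# secondary-structure propensity, volume, codon diversity, electrostatic charge.
ATCHLEY_FACTORS: dict[str, tuple[float, float, float, float, float]] = {
    "A": (-0.591, -1.302, -0.733,  1.570, -0.146),
    "C": (-1.343,  0.465, -0.862, -1.020, -0.255),
    "D": ( 1.050,  0.302, -3.656, -0.259, -3.242),
    "E": ( 1.357, -1.453,  1.477,  0.113, -0.837),
    "F": (-1.006, -0.590,  1.891, -0.397,  0.412),
    "G": (-0.384,  1.652,  1.330,  1.045,  2.064),
    "H": ( 0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547,  2.131,  0.393,  0.816),
    "K": ( 1.831, -0.561,  0.533, -0.277,  1.648),
    "L": (-1.019, -0.987, -1.505,  1.266, -0.912),
    "M": (-0.663, -1.524,  2.219, -1.005,  1.212),
    "N": ( 0.945,  0.828,  1.299, -0.169,  0.933),
    "P": ( 0.189,  2.081, -1.628,  0.421, -1.392),
    "Q": ( 0.931, -0.179, -3.005, -0.503, -1.853),
    "R": ( 1.538, -0.055,  1.502,  0.440,  2.897),
    "S": (-0.228,  1.399, -4.760,  0.670, -2.647),
    "T": (-0.032,  0.326,  2.213,  0.908,  1.313),
    "V": (-1.337, -0.279, -0.544,  1.242, -1.262),
    "W": (-0.595,  0.009,  0.672, -2.128, -0.184),
    "Y": ( 0.260,  0.830,  3.097, -0.838,  1.512),
}

SS_ALPHABET = "HEC"

FEATURE_COLUMNS: list[str] = (
    [f"pssm_{a}" for a in AA_ORDER]
    + ["pssm_info", "pssm_relwt"]
    + [f"ss_{s}" for s in SS_ALPHABET]
    + ["sa_exposed"]
    + [f"atchley_{k}" for k in range(1, 6)]
    + ["rel_position"]
)

N_FEATURES = len(FEATURE_COLUMNS)  # 32


def atchley_factors(aa: str) -> np.ndarray:
    """Five-factor vector for a 1-letter amino-acid code.

    Lowercase is normalized; letters outside the standard 20 (X, B, Z, ...)
    map to the zero vector.  Non-alphabetic input raises.
    """
    if not isinstance(aa, str) or len(aa) != 1 or not aa.isalpha():
        raise ValueError(f"expected a single amino-acid letter, got {aa!r}")
    return np.array(ATCHLEY_FACTORS.get(aa.upper(), (0.0,) * 5))


def relative_position(p: int, L: int) -> float:
    """Relative sequence position p/L for a 1-based index p."""
    if not 1 <= p <= L:
        raise ValueError(f"position {p} outside [1, {L}]")
    return p / L


@dataclass
class ResidueFeatureTable:
    """L x F matrix of per-residue features with fixed column order."""

    matrix: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.columns):
            raise ValueError("feature matrix / column-name mismatch")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PairFeatureVector:
    """Concatenated windowed feature vector for one residue pair (i < j)."""

    vector: np.ndarray
    pair: tuple[int, int]


def build_feature_table(record: ProteinRecord, pssm: PSSMProfile,
                        ss_string: str, sa_string: str) -> ResidueFeatureTable:
    """Assemble the L x 32 residue feature table in documented column order."""
    L = record.length
    for name, n in (("pssm", pssm.length), ("ss", len(ss_string)), ("sa", len(sa_string))):
        if n != L:
            raise ValueError(
                f"{record.id}: {name} input length {n} does not match sequence length {L}"
            )
    m = np.zeros((L, N_FEATURES))
    m[:, 0:20] = pssm.scores
    m[:, 20] = pssm.info_per_pos
    m[:, 21] = pssm.rel_weight
    for p, s in enumerate(ss_string):
        try:
            m[p, 22 + SS_ALPHABET.index(s)] = 1.0
        except ValueError:
            raise ValueError(f"{record.id}: invalid SS symbol {s!r} at position {p + 1}") from None
    for p, s in enumerate(sa_string):
        if s not in "be":
            raise ValueError(f"{record.id}: invalid SA symbol {s!r} at position {p + 1}")
        m[p, 25] = 1.0 if s == "e" else 0.0
    for p, aa in enumerate(record.sequence):
        m[p, 26:31] = atchley_factors(aa) if aa.isalpha() else 0.0
        m[p, 31] = relative_position(p + 1, L)
    return ResidueFeatureTable(matrix=m, columns=list(FEATURE_COLUMNS))


def build_pair_vector(table: ResidueFeatureTable, i: int, j: int,
                      window: int = DEFAULT_WINDOW) -> PairFeatureVector:
    """Windowed pair vector: window rows centred at i, then at j, flattened.

    1-based i < j.  Window positions outside [1, L] contribute zero rows so
    the vector length is always 2 * window * F.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if not (1 <= i < j <= table.length):
        raise ValueError(f"need 1 <= i < j <= {table.length}, got ({i}, {j})")
    half = window // 2
    F = table.n_features
    out = np.zeros((2, window, F))
    for slot, centre in enumerate((i, j)):
        for w in range(-half, half + 1):
            p = centre + w
            if 1 <= p <= table.length:
                out[slot, w + half] = table.matrix[p - 1]
    return PairFeatureVector(vector=out.reshape(-1), pair=(i, j))


def pair_vector_length(window: int = DEFAULT_WINDOW, n_features: int = N_FEATURES) -> int:
    return 2 * window * n_features
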