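"""Readers and writers for the stage-1 input files and RR prediction lists.

Formats handled:

* PSI-BLAST ASCII PSSM profiles (the ``-Q`` layout: header, one row per
  residue with 20 log-odds integers, 20 percentage integers and two trailing
  floats — information per position and relative weight of gapless matches).
* Correlated-mutations score matrices in three dialects: whitespace triplets
  ``i j score``, full LxL matrices, and CASP RR lines ``i j d1 d2 prob``.
* CASP-RR-style prediction lists ``i j 0 8 score``.
* Per-residue one-line strings for predicted secondary structure (H/E/C)
  and binary solvent accessibility (b/e).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import RangeClass

__all__ = [
    "PSSMProfile",
    "CMScoreMatrix",
    "PredictionList",
    "read_pssm",
    "write_pssm",
    "read_cm_scores",
    "normalize_cm",
    "read_rr",
    "write_rr",
    "read_ss",
    "read_sa",
]

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


class ParseError(ValueError):
    """Raised when an input file does not match its declared layout."""


@dataclass
class PSSMProfile:
    """Parsed PSSM: LX20 log-odds plus the two trailing per-position columns."""

    scores: np.ndarray          # (L, 20) log-odds, PSI-BLAST column order
    info_per_pos: np.ndarray    # (L,) information per position
    rel_weight: np.ndarray      # (L,) relative weight of gapless real matches
    sequence: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.info_per_pos = np.asarray(self.info_per_pos, dtype=float)
        self.rel_weight = np.asarray(self.rel_weight, dtype=float)
        L = self.scores.shape[0]
        if self.scores.shape != (L, 20):
            raise ValueError(f"PSSM scores must be Lx20, got {self.scores.shape}")
        if self.info_per_pos.shape != (L,) or self.rel_weight.shape != (L,):
            raise ValueError("trailing PSSM columns must have one entry per residue")
        if not (np.isfinite(self.info_per_pos).all() and np.isfinite(self.rel_weight).all()):
            raise ValueError("trailing PSSM columns must be finite")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class CMScoreMatrix:
    """Symmetric LxL correlated-mutations score matrix."""

    scores: np.ndarray
    method_tag: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        L = self.scores.shape[0]
        if self.scores.shape != (L, L):
            raise ValueError(f"CM scores must be square, got {self.scores.shape}")
        if not np.allclose(self.scores, self.scores.T, equal_nan=True):
            raise ValueError("CM score matrix must be symmetric")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class PredictionList:
    """Ranked residue-pair predictions for one target.

    Records are (i, j, score) with 1-based i < j, sorted by descending score
    with (i, j) lexicographic order among ties.  Scores must be finite and,
    for RR serialization, inside [0, 1].
    """

    target_id: str
    records: list[tuple[int, int, float]] = field(default_factory=list)
    range_class: RangeClass | None = None

    def __post_init__(self) -> None:
        seen = set()
        for i, j, s in self.records:
            if i >= j:
                raise ValueError(f"prediction pair ({i}, {j}) must have i < j")
            if (i, j) in seen:
                raise ValueError(f"duplicate prediction pair ({i}, {j})")
            if not np.isfinite(s):
                raise ValueError(f"non-finite score for pair ({i}, {j})")
            seen.add((i, j))
        self.records = sorted(self.records, key=lambda r: (-r[2], r[0], r[1]))

    def __len__(self) -> int:
        return len(self.records)

    def top(self, k: int) -> list[tuple[int, int, float]]:
        return self.records[:k]


def read_pssm(path) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM file.

    Data rows carry: index, residue letter, 20 log-odds integers, 20
    percentage integers, then two floats (information per position, relative
    weight).  Header and footer lines are skipped by shape.
    """
    rows, info, relw, seq = [], [], [], []
    n_data = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 2 or not parts[0].isdigit():
                continue  # header / footer / blank
            if len(parts) != 44:
                raise ParseError(
                    f"{path}:{lineno}: expected 44 columns "
                    f"(idx, aa, 20+20 ints, 2 floats), got {len(parts)}"
                )
            n_data += 1
            try:
                rows.append([int(x) for x in parts[2:22]])
                info.append(float(parts[42]))
                relw.append(float(parts[43]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            seq.append(parts[1])
    if n_data == 0:
        raise ParseError(f"{path}: no PSSM data rows found")
    return PSSMProfile(
        scores=np.array(rows, dtype=float),
        info_per_pos=np.array(info),
        rel_weight=np.array(relw),
        sequence="".join(seq),
    )


def write_pssm(profile: PSSMProfile, path) -> None:
    """Write a profile back in the PSI-BLAST ASCII layout read_pssm expects.

    The 20 percentage columns, which the reader ignores, are written as zeros.
    """
    seq = profile.sequence or "X" * profile.length
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write(" " * 9 + "  ".join(AA_ORDER) + "   " + "  ".join(AA_ORDER) + "\n")
        for p in range(profile.length):
            cells = [f"{int(round(v)):3d}" for v in profile.scores[p]]
            pct = ["  0"] * 20
            fh.write(
                f"{p + 1:5d} {seq[p]} "
                + " ".join(cells)
                + "  "
                + " ".join(pct)
                + f"  {profile.info_per_pos[p]:6.2f} {profile.rel_weight[p]:6.2f}\n"
            )
        fh.write("\n")


def normalize_cm(matrix: np.ndarray) -> np.ndarray:
    """Min-max normalize a score matrix to [0, 1] over its off-diagonal entries.

    A constant matrix maps to all 0.5 (no order information either way).
    """
    m = np.asarray(matrix, dtype=float).copy()
    L = m.shape[0]
    off = ~np.eye(L, dtype=bool)
    vals = m[off]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return np.full_like(m, 0.5)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        out = np.full_like(m, 0.5)
    else:
        out = (m - lo) / (hi - lo)
    np.fill_diagonal(out, 0.0)
    return np.clip(out, 0.0, 1.0)


def read_cm_scores(path, dialect: str, L: int, method_tag: str = "",
                   normalize: bool = True) -> CMScoreMatrix:
    """Read a correlated-mutations score matrix.

    dialect: ``triplet`` (lines "i j score", 1-based), ``matrix`` (L rows of
    L floats) or ``rr`` (CASP RR lines "i j d1 d2 prob").  Unlisted pairs
    default to 0; self-pairs are ignored.  Duplicate pairs with conflicting
    scores raise; asymmetric full matrices are symmetrized by averaging with
    a warning.  By default the result is min-max normalized to [0, 1].
    """
    if dialect not in ("triplet", "matrix", "rr"):
        raise ValueError(f"unknown CM dialect {dialect!r}")
    m = np.zeros((L, L))
    if dialect == "matrix":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                try:
                    rows.append([float(x) for x in parts])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        arr = np.array(rows)
        if arr.shape != (L, L):
            raise ParseError(f"{path}: matrix shape {arr.shape} conflicts with L={L}")
        if not np.allclose(arr, arr.T):
            warnings.warn(f"{path}: asymmetric matrix symmetrized by averaging")
            arr = (arr + arr.T) / 2.0
        m = arr
    else:
        score_col = 2 if dialect == "triplet" else 4
        seen: dict[tuple[int, int], float] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts or not parts[0].lstrip("-").isdigit():
                    continue  # RR headers (PFRMAT/TARGET/MODEL/END) and blanks
                if len(parts) <= score_col:
                    raise ParseError(f"{path}:{lineno}: too few columns")
                try:
                    i, j = int(parts[0]), int(parts[1])
                    s = float(parts[score_col])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
                if not (1 <= i <= L and 1 <= j <= L):
                    raise ParseError(
                        f"{path}:{lineno}: index ({i}, {j}) outside [1, {L}]"
                    )
                if i == j:
                    continue
                key = (min(i, j), max(i, j))
                if key in seen and seen[key] != s:
                    raise ParseError(
                        f"{path}:{lineno}: conflicting duplicate for pair {key}"
                    )
                seen[key] = s
        for (i, j), s in seen.items():
            m[i - 1, j - 1] = m[j - 1, i - 1] = s
    np.fill_diagonal(m, 0.0)
    if normalize:
        m = normalize_cm(m)
    return CMScoreMatrix(scores=m, method_tag=method_tag)


_RR_HEADER = "PFRMAT RR"


def write_rr(predictions: PredictionList, path) -> None:
    """Write a prediction list as CASP RR lines ``i j 0 8 score``.

    Scores must already be in [0, 1]; out-of-range scores raise rather than
    being clipped silently.
    """
    for i, j, s in predictions.records:
        if not (0.0 <= s <= 1.0):
            raise ValueError(
                f"score {s} for pair ({i}, {j}) outside [0, 1]; "
                "rescale before writing RR"
            )
    with open(path, "w") as fh:
        fh.write(f"{_RR_HEADER}\n")
        fh.write(f"TARGET {predictions.target_id}\n")
        fh.write("MODEL 1\n")
        for i, j, s in predictions.records:
            fh.write(f"{i} {j} 0 8 {s:.6f}\n")
        fh.write("END\n")


def read_rr(path) -> PredictionList:
    """Read a CASP RR prediction file written by :func:`write_rr`."""
    target_id = ""
    records: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "TARGET" and len(parts) > 1:
                target_id = parts[1]
                continue
            if not parts[0].lstrip("-").isdigit():
                continue
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: RR line needs 5 fields")
            records.append((int(parts[0]), int(parts[1]), float(parts[4])))
    return PredictionList(target_id=target_id, records=records)


def read_ss(path, L: int | None = None) -> str:
    """Read a one-line 3-state secondary-structure string over {H, E, C}."""
    s = _read_string(path)
    bad = set(s) - set("HEC")
    if bad:
        raise ParseError(f"{path}: invalid secondary-structure symbols {sorted(bad)}")
    if L is not None and len(s) != L:
        raise ParseError(f"{path}: length {len(s)} conflicts with declared L={L}")
    return s


def read_sa(path, L: int | None = None) -> str:
    """Read a one-line solvent-accessibility string over {b, e}."""
    s = _read_string(path)
    bad = set(s) - set("be")
    if bad:
        raise ParseError(f"{path}: invalid solvent-accessibility symbols {sorted(bad)}")
    if L is not None and len(s) != L:
        raise ParseError(f"{path}: length {len(s)} conflicts with declared L={L}")
    return s


def _read_string(path) -> str:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith(">")]
    if not lines:
        raise ParseError(f"{path}: empty file")
    return "".join(lines)
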