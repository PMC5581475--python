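"""Contact-map geometry: residue coordinates, contact labels, range classes.

Contacts follow the CASP convention: two residues are in contact when the
Euclidean distance between their Cbeta atoms (Calpha for glycine) is strictly
less than 8 Angstrom.  Pairs are stratified by sequence separation |i - j|
into short (6-11), medium (12-23) and long (>= 24) range classes; pairs
closer than 6 along the chain are excluded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProteinRecord",
    "ContactMap",
    "RangeClass",
    "contact_map",
    "classify_separation",
    "enumerate_pairs",
    "read_pdb",
    "CONTACT_THRESHOLD",
    "MIN_SEPARATION",
    "LONG_MIN_SEPARATION",
    "MEDIUM_MIN_SEPARATION",
]

#: default contact distance threshold in Angstrom (strict less-than)
CONTACT_THRESHOLD = 8.0
#: smallest sequence separation considered at all
MIN_SEPARATION = 6
#: smallest separation of the medium-range class
MEDIUM_MIN_SEPARATION = 12
#: smallest separation of the long-range class
LONG_MIN_SEPARATION = 24


class RangeClass(enum.Enum):
    """Sequence-separation stratum of a residue pair."""

    SHORT = "short"
    MEDIUM = "medium"
    LONG = "long"
    EXCLUDED = "excluded"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_string(cls, s: str) -> "RangeClass":
        try:
            return cls(s.lower())
        except ValueError:
            raise ValueError(f"unknown range class {s!r}") from None


#: the three assessable classes, in canonical order
ASSESSED_RANGES = (RangeClass.SHORT, RangeClass.MEDIUM, RangeClass.LONG)


@dataclass
class ProteinRecord:
    """A protein chain: id, one-letter sequence and one coordinate per residue.

    ``coords`` has shape (L, 3); rows of NaN mark residues without a usable
    coordinate (missing density, missing Cbeta).
    """

    id: str
    sequence: str
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sequence), 3):
            raise ValueError(
                f"{self.id}: coords shape {self.coords.shape} does not match "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_coords(self) -> np.ndarray:
        """Boolean mask of residues with a defined coordinate."""
        return np.isfinite(self.coords).all(axis=1)


@dataclass
class ContactMap:
    """Symmetric distance matrix plus thresholded boolean contact matrix.

    Entries of ``distances`` are NaN where either residue lacks coordinates;
    the matching ``defined`` mask is False there and such pairs never count
    as contacts nor as evaluable non-contacts.
    """

    distances: np.ndarray
    contacts: np.ndarray
    threshold: float

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.distances)

    @property
    def length(self) -> int:
        return self.distances.shape[0]

    def density(self, range_class: RangeClass | None = None) -> float:
        """Fraction of defined considered pairs (sep >= 6) that are contacts."""
        L = self.length
        idx = np.triu_indices(L, k=1)
        sep = idx[1] - idx[0]
        mask = sep >= MIN_SEPARATION
        if range_class is not None:
            lo, hi = _SEP_BOUNDS[range_class]
            mask = (sep >= lo) & (sep <= hi)
        mask &= self.defined[idx]
        n = int(mask.sum())
        if n == 0:
            return float("nan")
        return float(self.contacts[idx][mask].sum()) / n


_SEP_BOUNDS = {
    RangeClass.SHORT: (MIN_SEPARATION, MEDIUM_MIN_SEPARATION - 1),
    RangeClass.MEDIUM: (MEDIUM_MIN_SEPARATION, LONG_MIN_SEPARATION - 1),
    RangeClass.LONG: (LONG_MIN_SEPARATION, np.inf),
    RangeClass.EXCLUDED: (1, MIN_SEPARATION - 1),
}


def contact_map(record: ProteinRecord, threshold: float = CONTACT_THRESHOLD) -> ContactMap:
    """Compute the symmetric contact map of a record.

    A pair is a contact iff its distance is strictly below ``threshold``.
    Pairs involving a residue without coordinates get NaN distance and are
    never contacts.  Raises if the record has no coordinates at all.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    mask = record.has_coords
    if not mask.any():
        raise ValueError(f"record {record.id!r} has no residue coordinates")
    diff = record.coords[:, None, :] - record.coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    undefined = ~(mask[:, None] & mask[None, :])
    dist[undefined] = np.nan
    contacts = dist < threshold  # NaN compares False
    np.fill_diagonal(contacts, False)
    return ContactMap(distances=dist, contacts=contacts, threshold=threshold)


def classify_separation(i: int, j: int) -> RangeClass:
    """Range class of the 1-based residue pair (i, j) from |i - j| alone."""
    if i == j:
        raise ValueError(f"residue pair ({i}, {j}) has zero separation")
    sep = abs(i - j)
    if sep < MIN_SEPARATION:
        return RangeClass.EXCLUDED
    if sep < MEDIUM_MIN_SEPARATION:
        return RangeClass.SHORT
    if sep < LONG_MIN_SEPARATION:
        return RangeClass.MEDIUM
    return RangeClass.LONG


def enumerate_pairs(L: int, range_class: RangeClass) -> list[tuple[int, int]]:
    """All 1-based pairs (i, j), i < j, whose separation is in ``range_class``.

    Deterministic row-major order: sorted by i, then j.
    """
    if L < 2:
        raise ValueError(f"need L >= 2, got {L}")
    lo, hi = _SEP_BOUNDS[range_class]
    out = []
    for i in range(1, L + 1):
        j_lo = i + int(lo)
        j_hi = i + int(min(hi, L))
        for j in range(j_lo, min(j_hi, L) + 1):
            out.append((i, j))
    return out


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def read_pdb(path, chain: str | None = None, record_id: str | None = None) -> ProteinRecord:
    """Minimal PDB ATOM-record reader producing one coordinate per residue.

    Uses the CB atom where present, falling back to CA for glycine.  Altlocs
    other than blank or 'A' are ignored.  ``chain`` selects a chain id; by
    default the first chain encountered is used.  Residues with neither a
    usable CB nor (for GLY) CA keep NaN coordinates.
    """
    residues: dict[tuple[str, int, str], dict] = {}
    order: list[tuple[str, int, str]] = []
    picked_chain = chain
    with open(path) as fh:
        for line in fh:
            if not line.startswith(("ATOM  ", "ATOM\t")):
                continue
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            ch = line[21]
            if picked_chain is None:
                picked_chain = ch
            if ch != picked_chain:
                continue
            resname = line[17:20].strip()
            resseq = int(line[22:26])
            icode = line[26]
            atom = line[12:16].strip()
            key = (ch, resseq, icode)
            if key not in residues:
                residues[key] = {"name": resname, "atoms": {}}
                order.append(key)
            xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            residues[key]["atoms"].setdefault(atom, xyz)
    if not order:
        raise ValueError(f"no ATOM records found in {path}")
    seq = []
    coords = np.full((len(order), 3), np.nan)
    for k, key in enumerate(order):
        res = residues[key]
        seq.append(_THREE_TO_ONE.get(res["name"], "X"))
        atoms = res["atoms"]
        if "CB" in atoms:
            coords[k] = atoms["CB"]
        elif res["name"] == "GLY" and "CA" in atoms:
            coords[k] = atoms["CA"]
    rid = record_id or str(path)
    return ProteinRecord(id=rid, sequence="".join(seq), coords=coords)
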