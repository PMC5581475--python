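"""Synthetic fixtures: toy folded structures, score matrices and feature files.

The generator emulates the statistical shape of real inputs without any
external data: a confined self-avoiding walk produces compact coordinate
sets whose contact density among considered pairs (separation >= 6) sits in
the sparse 1-5% band typical of native structures; correlated-mutations
matrices mix the true contact indicator with uniform noise at a tunable
signal level rho; and PSSM/SS/SA files carry a tunable amount of
contact-informative signal so the feature-based stage has something to learn.

Everything is deterministic under (parameters, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (
    CONTACT_THRESHOLD,
    ContactMap,
    ProteinRecord,
    RangeClass,
    contact_map,
)
from .io_formats import AA_ORDER, CMScoreMatrix, PSSMProfile, normalize_cm, write_pssm

__all__ = [
    "SyntheticTarget",
    "generate_structure",
    "generate_cm_scores",
    "generate_feature_files",
    "make_target",
    "write_target_files",
    "DENSITY_BAND",
]

#: acceptable contact density among considered pairs (fraction)
DENSITY_BAND = (0.01, 0.05)

STEP_LENGTH = 3.8       # Angstrom between consecutive residues
EXCLUSION = 4.0         # minimum distance between non-adjacent residues
RADIUS_COEFF = 4.1      # confinement radius = compactness * RADIUS_COEFF * L^(1/3)


@dataclass
class SyntheticTarget:
    """One generated target: structure, truth, score matrices, feature files."""

    record: ProteinRecord
    cmap: ContactMap
    cm_scores: dict[str, CMScoreMatrix]
    pssm: PSSMProfile
    ss_string: str
    sa_string: str
    params: dict = field(default_factory=dict)


def _attempt_walk(L: int, rng: np.random.Generator, radius: float,
                  max_restarts: int = 60) -> np.ndarray | None:
    """One confined self-avoiding walk try; None when it dead-ends."""
    coords = np.zeros((L, 3))
    # start off-centre so early residues are not privileged
    coords[0] = rng.normal(size=3) * radius / 4.0
    k = 1
    stuck = 0
    while k < L:
        placed = False
        for _ in range(40):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            cand = coords[k - 1] + STEP_LENGTH * d
            if np.linalg.norm(cand) > radius:
                continue
            if k >= 2:
                dists = np.linalg.norm(coords[: k - 1] - cand, axis=1)
                if dists.min() < EXCLUSION:
                    continue
            coords[k] = cand
            k += 1
            placed = True
            break
        if not placed:
            # back up a few residues and retry
            k = max(1, k - 3)
            stuck += 1
            if stuck > max_restarts:
                return None
    return coords


def generate_structure(L: int, seed: int, compactness: float = 1.0,
                       density_band: tuple[float, float] = DENSITY_BAND,
                       max_attempts: int = 50,
                       threshold: float = CONTACT_THRESHOLD,
                       ) -> tuple[ProteinRecord, ContactMap]:
    """Compact self-avoiding walk with contact density inside ``density_band``.

    Consecutive residues sit 3.8 A apart, non-adjacent residues at least
    4.0 A apart, all inside a sphere of radius compactness * 3.4 * L^(1/3)
    — roughly the packing of a globular domain.  Attempts are repeated with
    seed offsets until the density of considered pairs (sep >= 6) lands in
    the band; failure after ``max_attempts`` raises with advice.
    """
    if L < 10:
        raise ValueError(f"need L >= 10, got {L}")
    radius = compactness * RADIUS_COEFF * L ** (1.0 / 3.0)
    for attempt in range(max_attempts):
        rng = np.random.default_rng((seed, attempt))
        coords = _attempt_walk(L, rng, radius)
        if coords is None:
            continue
        seq = "".join(rng.choice(list(AA_ORDER), size=L))
        record = ProteinRecord(id=f"SYN{L}_{seed}", sequence=seq, coords=coords)
        cmap = contact_map(record, threshold=threshold)
        density = cmap.density()
        if density_band[0] <= density <= density_band[1]:
            return record, cmap
    raise RuntimeError(
        f"no structure with contact density in {density_band} after "
        f"{max_attempts} attempts (L={L}, seed={seed}); adjust compactness "
        "or widen the density band"
    )


def generate_cm_scores(cmap: ContactMap, rho: float, seed: int,
                       method_tag: str = "synthetic",
                       signal_range: RangeClass | None = None) -> CMScoreMatrix:
    """Score matrix = rho * contact indicator + (1 - rho) * uniform noise.

    Symmetrized and min-max normalized; rho=1 is a perfect oracle, rho=0
    pure noise.  With ``signal_range`` set, only pairs of that range class
    receive the contact signal (other pairs get noise only), emulating
    methods whose strength is range-specific.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    rng = np.random.default_rng(seed)
    L = cmap.length
    noise = rng.uniform(size=(L, L))
    noise = (noise + noise.T) / 2.0
    signal = cmap.contacts.astype(float)
    if signal_range is not None:
        i, j = np.indices((L, L))
        sep = np.abs(i - j)
        from .geometry import _SEP_BOUNDS  # stratum bounds shared with geometry

        lo, hi = _SEP_BOUNDS[signal_range]
        signal = signal * ((sep >= lo) & (sep <= hi))
    m = rho * signal + (1.0 - rho) * noise
    np.fill_diagonal(m, 0.0)
    return CMScoreMatrix(scores=normalize_cm(m), method_tag=method_tag)


# crude per-letter background log-odds centre so rows look residue-conditioned
_AA_BIAS = {a: k % 5 - 2 for k, a in enumerate(AA_ORDER)}


def generate_feature_files(record: ProteinRecord, cmap: ContactMap,
                           informativeness: float, seed: int,
                           ) -> tuple[PSSMProfile, str, str]:
    """Synthetic PSSM profile plus SS and SA strings for one target.

    The contact-informative signal is planted by marking, in residue i's 20
    PSSM columns, which of 20 equal sequence segments hold a contact partner
    of i.  A pair (i, j) is then decodable from its two windows: column
    segment(j) of i's profile row, cross-referenced against j's relative
    position.  At informativeness 1 the marks dominate the profile noise; at
    0 the profile is pure noise (note the mandatory relative-position
    feature still carries the generic positional contact prior of compact
    structures, so a learner never falls all the way to chance).  SS strings
    come from a seeded Markov process; the SA state is weakly tied to burial
    depth so it stays structure-flavoured.
    """
    if not 0.0 <= informativeness <= 1.0:
        raise ValueError(f"informativeness must be in [0, 1], got {informativeness}")
    rng = np.random.default_rng(seed)
    L = record.length
    scores = rng.integers(-4, 5, size=(L, 20)).astype(float)
    for p, aa in enumerate(record.sequence):
        scores[p] += _AA_BIAS.get(aa, 0)
    partner_mark = np.zeros((L, 20))
    for i in range(L):
        for j in np.flatnonzero(cmap.contacts[i]):
            partner_mark[i, int(j * 20 / L)] = 1.0
    scores = scores * (1.0 - informativeness) + 8.0 * informativeness * partner_mark
    coords = np.where(np.isfinite(record.coords), record.coords, 0.0)
    info = np.round(rng.uniform(0.0, 2.0, size=L), 2)
    relw = np.round(rng.uniform(0.0, 1.0, size=L), 2)
    pssm = PSSMProfile(scores=np.round(scores), info_per_pos=info,
                       rel_weight=relw, sequence=record.sequence)

    ss = _markov_string(rng, L, "HEC", stay=0.85)
    depth = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
    buried = depth < np.median(depth)
    flip = rng.uniform(size=L) < 0.25
    sa = "".join("b" if (b ^ f) else "e" for b, f in zip(buried, flip))
    return pssm, ss, sa


def _markov_string(rng: np.random.Generator, L: int, alphabet: str,
                   stay: float) -> str:
    state = int(rng.integers(len(alphabet)))
    out = []
    for _ in range(L):
        out.append(alphabet[state])
        if rng.uniform() >= stay:
            state = int(rng.integers(len(alphabet)))
    return "".join(out)


def make_target(L: int, seed: int, rhos: dict[str, float] | None = None,
                informativeness: float = 0.5, compactness: float = 1.0,
                signal_ranges: dict[str, RangeClass | None] | None = None,
                ) -> SyntheticTarget:
    """Generate one complete synthetic target (structure + all inputs)."""
    if rhos is None:
        rhos = {"cm_a": 0.6, "cm_b": 0.5, "cm_c": 0.4}
    signal_ranges = signal_ranges or {}
    record, cmap = generate_structure(L, seed, compactness=compactness)
    cm_scores = {
        tag: generate_cm_scores(
            cmap, rho,
            seed=(seed * 1_000_003 + zlib.crc32(tag.encode())) % (2**32),
            method_tag=tag, signal_range=signal_ranges.get(tag),
        )
        for tag, rho in rhos.items()
    }
    pssm, ss, sa = generate_feature_files(record, cmap, informativeness, seed)
    return SyntheticTarget(
        record=record, cmap=cmap, cm_scores=cm_scores,
        pssm=pssm, ss_string=ss, sa_string=sa,
        params={
            "L": L, "seed": seed, "rhos": dict(rhos),
            "informativeness": informativeness, "compactness": compactness,
        },
    )


def write_target_files(target: SyntheticTarget, outdir) -> dict[str, Path]:
    """Write one target's fixture files (PDB-style coords, PSSM, SS, SA, CMs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tid = target.record.id
    paths: dict[str, Path] = {}

    pdb_path = outdir / f"{tid}.pdb"
    _write_pdb(target.record, pdb_path)
    paths["pdb"] = pdb_path

    pssm_path = outdir / f"{tid}.pssm"
    write_pssm(target.pssm, pssm_path)
    paths["pssm"] = pssm_path

    for key, text in (("ss", target.ss_string), ("sa", target.sa_string)):
        p = outdir / f"{tid}.{key}"
        p.write_text(text + "\n")
        paths[key] = p

    for tag, cm in target.cm_scores.items():
        p = outdir / f"{tid}.{tag}.cm"
        with open(p, "w") as fh:
            L = cm.length
            for i in range(L):
                for j in range(i + 1, L):
                    if cm.scores[i, j] != 0.0:
                        fh.write(f"{i + 1} {j + 1} {cm.scores[i, j]:.6f}\n")
        paths[f"cm:{tag}"] = p
    return paths


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _write_pdb(record: ProteinRecord, path) -> None:
    """PDB ATOM records carrying the one representative coordinate per residue.

    Glycines get a CA atom, everything else a CB, matching what read_pdb
    expects to pick up.
    """
    with open(path, "w") as fh:
        serial = 1
        for p, aa in enumerate(record.sequence):
            x, y, z = record.coords[p]
            if not np.isfinite([x, y, z]).all():
                continue
            atom = "CA" if aa == "G" else "CB"
            res3 = _ONE_TO_THREE.get(aa, "UNK")
            fh.write(
                f"ATOM  {serial:5d}  {atom:<3s} {res3:<3s} A{p + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
            )
            serial += 1
        fh.write("END\n")
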