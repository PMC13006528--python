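"""Secondary-structure and solvent-accessibility feature tracks.

Residues inside defined secondary-structure elements (helices G/H/I, strands
E, polyproline P) score 0 — insertions there are expected to be disruptive —
while coil scores 1. Relative solvent accessibility is each residue's
accessible area divided by its residue-type maximum, clamped to [0, 1].
A built-in Shrake–Rupley surface-area calculation serves as a fallback when
no precomputed secondary-structure/accessibility file is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import DsspRecord, StructureModel
from .scoring import FeatureTrack

log = logging.getLogger(__name__)

# Theoretical maximum accessible surface areas (A^2) from the Tien et al.
# Gly-X-Gly tripeptide scale; the normalisation denominator for RSA.
MAX_ASA_THEORETICAL = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Empirical maxima from the same study (observed in folded structures).
MAX_ASA_EMPIRICAL = {
    "A": 121.0, "R": 265.0, "N": 187.0, "D": 187.0, "C": 148.0,
    "E": 214.0, "Q": 214.0, "G": 97.0, "H": 216.0, "I": 195.0,
    "L": 191.0, "K": 230.0, "M": 203.0, "F": 228.0, "P": 154.0,
    "S": 143.0, "T": 163.0, "W": 264.0, "Y": 255.0, "V": 165.0,
}

MAX_ASA_TABLES = {
    "theoretical": MAX_ASA_THEORETICAL,
    "empirical": MAX_ASA_EMPIRICAL,
}


@dataclass
class StructureFeatureConfig:
    """How secondary-structure codes map to scores and how RSA is normalised.

    The codes not fixed by the scoring scheme (B isolated bridge, T turn,
    S bend) default to: T, S -> 1 (flexible, loop-like) and B -> 0 (a paired
    strand residue); both sets are configurable.
    """

    zero_codes: frozenset[str] = frozenset("GHIEPB")
    one_codes: frozenset[str] = frozenset("CTS")
    max_asa_source: str = "theoretical"
    missing_residue_policy: str = "score_zero"  # or "error"

    def __post_init__(self) -> None:
        if set(self.zero_codes) & set(self.one_codes):
            raise ValueError("zero_codes and one_codes overlap")
        if self.max_asa_source not in MAX_ASA_TABLES:
            raise ValueError(f"unknown max_asa_source {self.max_asa_source!r}")
        if self.missing_residue_policy not in ("score_zero", "error"):
            raise ValueError(
                f"unknown missing_residue_policy {self.missing_residue_policy!r}"
            )

    @property
    def max_asa(self) -> dict[str, float]:
        return MAX_ASA_TABLES[self.max_asa_source]


def ss_feature(ss_code: str, config: Optional[StructureFeatureConfig] = None) -> int:
    """Score one normalised secondary-structure code as 0 or 1."""
    config = config or StructureFeatureConfig()
    if ss_code in config.zero_codes:
        return 0
    if ss_code in config.one_codes:
        return 1
    raise ValueError(f"unknown secondary-structure code {ss_code!r}")


def rsa_feature(acc: float, aa: str, table: Optional[dict[str, float]] = None) -> float:
    """Relative solvent accessibility: acc / max ASA, clamped to [0, 1]."""
    table = table if table is not None else MAX_ASA_THEORETICAL
    if acc < 0:
        raise ValueError(f"negative accessible area {acc}")
    if aa not in table:
        raise ValueError(f"no maximum ASA tabulated for residue {aa!r}")
    return min(acc / table[aa], 1.0)


def structure_feature_tracks(
    dssp: Sequence[DsspRecord],
    query_length: int,
    config: Optional[StructureFeatureConfig] = None,
) -> tuple[FeatureTrack, FeatureTrack]:
    """Build the secondary-structure and RSA tracks from per-residue records.

    Records must already be re-indexed to query positions. Positions absent
    from the records are handled per ``missing_residue_policy``: scored 0 on
    both tracks with a warning (conservative — never recommends an
    unobserved position), or a hard error.
    """
    config = config or StructureFeatureConfig()
    ss = np.zeros(query_length)
    rsa = np.zeros(query_length)
    seen: set[int] = set()
    for rec in dssp:
        if rec.seq_index in seen:
            raise ValueError(f"duplicate residue index {rec.seq_index}")
        if not 1 <= rec.seq_index <= query_length:
            raise ValueError(
                f"residue index {rec.seq_index} outside 1..{query_length}"
            )
        seen.add(rec.seq_index)
        ss[rec.seq_index - 1] = ss_feature(rec.ss_code, config)
        if rec.aa in config.max_asa:
            rsa[rec.seq_index - 1] = rsa_feature(rec.acc, rec.aa, config.max_asa)
        else:
            log.warning("position %d: non-standard residue %r, RSA set to 0",
                        rec.seq_index, rec.aa)
    missing = sorted(set(range(1, query_length + 1)) - seen)
    if missing:
        if config.missing_residue_policy == "error":
            raise ValueError(f"residues missing from structure annotation: "
                             f"{missing}")
        log.warning("%d residues missing from structure annotation scored 0: "
                    "%s", len(missing), missing[:10])
    return (FeatureTrack("secondary_structure", ss), FeatureTrack("rsa", rsa))


# ---------------------------------------------------------------------------
# Built-in solvent accessible surface area (Shrake-Rupley via biotite)


def sasa_shrake_rupley(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-residue solvent accessible surface area (A^2) of an all-atom model.

    Thin wrapper over biotite's Shrake-Rupley implementation with
    single-atom van der Waals radii; deterministic for fixed ``n_points``.
    Used when no precomputed accessibility file is supplied.
    """
    import biotite.structure as bst

    if len(structure) == 0:
        raise ValueError("empty structure")
    atom_names = [a[0] for res in structure.residues for a in res.atoms]
    if set(atom_names) <= {"CA"}:
        raise ValueError("all-atom model required (got CA-only coordinates)")
    n_atoms = len(atom_names)
    arr = bst.AtomArray(n_atoms)
    coords = np.empty((n_atoms, 3))
    i = 0
    for res in structure.residues:
        for name, element, x, y, z in res.atoms:
            coords[i] = (x, y, z)
            arr.atom_name[i] = name
            arr.element[i] = element
            arr.res_id[i] = res.seq_index
            arr.res_name[i] = "UNK"
            arr.chain_id[i] = structure.chain_id or "A"
            arr.hetero[i] = False
            i += 1
    arr.coord = coords
    atom_sasa = bst.sasa(arr, probe_radius=probe_radius, point_number=n_points,
                         vdw_radii="Single")
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)
    per_res = np.zeros(len(structure))
    for j, res in enumerate(structure.residues):
        mask = arr.res_id == res.seq_index
        per_res[j] = atom_sasa[mask].sum()
    return per_res


def rsa_from_structure(
    structure: StructureModel,
    config: Optional[StructureFeatureConfig] = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> FeatureTrack:
    """RSA track computed from coordinates alone (fallback path)."""
    config = config or StructureFeatureConfig()
    sasa = sasa_shrake_rupley(structure, probe_radius, n_points)
    values = np.zeros(len(structure))
    for i, res in enumerate(structure.residues):
        if res.aa in config.max_asa:
            values[i] = rsa_feature(sasa[i], res.aa, config.max_asa)
    return FeatureTrack("rsa", values)
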