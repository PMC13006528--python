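"""Self-contained synthetic test inputs with engineered feature structure.

Generates, from a small declarative spec, a mutually consistent bundle of
input files — query FASTA, per-species homolog FASTA, pre-aligned FASTA, a
toy all-atom PDB, a classic-format secondary-structure/accessibility file,
an ANCHOR-style disorder file and a BLAST tabular file — in the exact
dialects the parsers expect. Regions of the protein are assigned regimes:

* ``taggable``   — diversified homolog columns, coil, exposed, no binding
* ``structured`` — helix (secondary structure vetoes the site)
* ``conserved``  — invariant columns (entropy vetoes)
* ``binding``    — high binding propensity (the disorder feature vetoes)

so that an end-to-end run must recover the engineered taggable region.
Everything is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .conservation import DEFAULT_SPECIES_PANEL
from .io import STANDARD_AA, SequenceRecord, write_fasta
from .structure import MAX_ASA_THEORETICAL

_REGIMES = ("taggable", "structured", "conserved", "binding")

_AA_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class FixtureSpec:
    length: int = 100
    #: (start, end, regime), 1-based inclusive, non-overlapping.
    regions: Sequence[tuple[int, int, str]] = ((40, 50, "taggable"),)
    seed: int = 0
    background: str = "structured"

    def __post_init__(self) -> None:
        occupied: set[int] = set()
        for start, end, regime in self.regions:
            if regime not in _REGIMES:
                raise ValueError(f"unknown regime {regime!r}")
            if not (1 <= start <= end <= self.length):
                raise ValueError(f"region {start}-{end} outside 1..{self.length}")
            span = set(range(start, end + 1))
            if span & occupied:
                raise ValueError(f"region {start}-{end} overlaps another region")
            occupied |= span
        if self.background not in _REGIMES:
            raise ValueError(f"unknown background regime {self.background!r}")

    def regime_at(self, pos: int) -> str:
        for start, end, regime in self.regions:
            if start <= pos <= end:
                return regime
        return self.background


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    directory: Path
    query_fasta: Path
    homologs_fasta: Path
    aligned_fasta: Path
    pdb: Path
    dssp: Path
    anchor2: Path
    blast_tab: Path
    query: SequenceRecord = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Toy structure builder (internal-coordinate chain construction)

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_BOND_CA_CB = 1.521
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.5
_ANGLE_C_CA_CB = 110.4

#: (phi, psi) in degrees for the named backbone conformations.
CONFORMATIONS = {"extended": (-140.0, 135.0), "helix": (-57.0, -47.0)}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position atom d given three predecessors and internal coordinates."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain_coords(
    sequence: str, conformation: str = "extended"
) -> list[dict[str, np.ndarray]]:
    """Backbone + CB coordinates for the sequence at ideal geometry."""
    if not sequence:
        raise ValueError("at least one residue required")
    phi, psi = CONFORMATIONS[conformation]
    residues: list[dict[str, np.ndarray]] = []
    for i, aa in enumerate(sequence):
        atoms: dict[str, np.ndarray] = {}
        if i == 0:
            atoms["N"] = np.zeros(3)
            atoms["CA"] = np.array([_BOND_N_CA, 0.0, 0.0])
            ang = math.radians(_ANGLE_N_CA_C)
            atoms["C"] = atoms["CA"] + np.array(
                [-_BOND_CA_C * math.cos(ang), _BOND_CA_C * math.sin(ang), 0.0]
            )
        else:
            prev = residues[-1]
            atoms["N"] = _place_atom(prev["N"], prev["CA"], prev["C"],
                                     _BOND_C_N, _ANGLE_CA_C_N, psi)
            atoms["CA"] = _place_atom(prev["CA"], prev["C"], atoms["N"],
                                      _BOND_N_CA, _ANGLE_C_N_CA, 180.0)
            atoms["C"] = _place_atom(prev["C"], atoms["N"], atoms["CA"],
                                     _BOND_CA_C, _ANGLE_N_CA_C, phi)
        atoms["O"] = _place_atom(atoms["N"], atoms["CA"], atoms["C"],
                                 _BOND_C_O, _ANGLE_CA_C_O, psi + 180.0)
        if aa != "G":
            atoms["CB"] = _place_atom(atoms["C"], atoms["N"], atoms["CA"],
                                      _BOND_CA_CB, _ANGLE_C_CA_CB, 122.68)
        residues.append(atoms)
    return residues


def make_toy_pdb(
    sequence: str,
    conformation: str = "extended",
    chain_id: str = "A",
    bfactor: float = 90.0,
    coords: Optional[list[dict[str, np.ndarray]]] = None,
) -> str:
    """Render a toy all-atom chain as PDB text parseable by the readers."""
    if not sequence:
        raise ValueError("at least one residue required")
    coords = coords if coords is not None else build_chain_coords(sequence, conformation)
    lines = []
    serial = 1
    for i, aa in enumerate(sequence):
        res3 = _AA_ONE_TO_THREE[aa]
        for name in ("N", "CA", "C", "O", "CB"):
            if name not in coords[i]:
                continue
            x, y, z = coords[i][name]
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise ValueError(f"non-finite coordinate at residue {i + 1}")
            element = name[0]
            name_field = f" {name:<3s}"  # element right-justified in cols 13-14
            lines.append(
                f"ATOM  {serial:5d} {name_field} {res3} {chain_id}{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{bfactor:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Per-regime file content


def _regime_profile(regime: str, rng: np.random.Generator) -> dict:
    """File-level settings for one position under the given regime."""
    if regime == "taggable":
        return {"diversify": True, "ss": " ", "acc_frac": rng.uniform(0.80, 0.95),
                "br": rng.uniform(0.02, 0.08)}
    if regime == "structured":
        return {"diversify": False, "ss": "H", "acc_frac": rng.uniform(0.05, 0.15),
                "br": rng.uniform(0.35, 0.55)}
    if regime == "conserved":
        return {"diversify": False, "ss": " ", "acc_frac": rng.uniform(0.80, 0.95),
                "br": rng.uniform(0.02, 0.08)}
    if regime == "binding":
        return {"diversify": True, "ss": " ", "acc_frac": rng.uniform(0.80, 0.95),
                "br": rng.uniform(0.85, 0.95)}
    raise ValueError(regime)


def _write_dssp_classic(path: Path, sequence: str, ss_codes: Sequence[str],
                        accs: Sequence[int]) -> None:
    header = [
        "==== Secondary Structure Definition, synthetic fixture ====",
        "REFERENCE   synthetic",
        f"  {len(sequence):3d}  1  0  0  0   TOTAL NUMBER OF RESIDUES",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N"
        "    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    rows = []
    for i, (aa, ss, acc) in enumerate(zip(sequence, ss_codes, accs), start=1):
        row = f"{i:5d}{i:5d} A {aa}  {ss}"
        row = row.ljust(34) + f"{acc:4d}"
        rows.append(row)
    path.write_text("\n".join(header + rows) + "\n")


def _write_anchor_long(path: Path, sequence: str, brs: Sequence[float]) -> None:
    lines = [
        "# Synthetic disordered-binding propensity file (IUPred2A long dialect)",
        "# POS\tRES\tIUPRED2\tANCHOR2",
    ]
    for i, (aa, br) in enumerate(zip(sequence, brs), start=1):
        iupred = min(max(br + 0.05, 0.0), 1.0)
        lines.append(f"{i}\t{aa}\t{iupred:.4f}\t{br:.4f}")
    path.write_text("\n".join(lines) + "\n")


def _write_blast_tab(path: Path, query_id: str, subject_ids: Sequence[str],
                     length: int) -> None:
    rows = []
    for i, sid in enumerate(subject_ids):
        evalue = f"1e-{120 - 2 * i}"
        bitscore = f"{900 - 5 * i:.1f}"
        rows.append("\t".join([
            query_id, sid, "85.0", str(length), "10", "0", "1", str(length),
            "1", str(length), evalue, bitscore,
        ]))
        # decoy: a worse hit for the same species that must never be selected
        rows.append("\t".join([
            query_id, sid.replace("hom", "decoy"), "55.0", str(length), "40",
            "2", "1", str(length), "1", str(length), f"1e-{30 - i}",
            f"{200 - 5 * i:.1f}",
        ]))
    path.write_text("\n".join(rows) + "\n")


def make_fixture_protein(spec: FixtureSpec, out_dir: str | Path) -> FixtureBundle:
    """Write the full mutually consistent input bundle for one toy protein."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    aa_pool = np.array(list(STANDARD_AA))

    query_seq = "".join(rng.choice(aa_pool, size=spec.length))
    profiles = [_regime_profile(spec.regime_at(p), rng)
                for p in range(1, spec.length + 1)]

    species = list(DEFAULT_SPECIES_PANEL)
    subject_ids = [f"hom{i}__{sp.replace(' ', '_')}"
                   for i, sp in enumerate(species)]
    homolog_seqs = []
    for _ in species:
        chars = []
        for p in range(spec.length):
            if profiles[p]["diversify"]:
                chars.append(str(rng.choice(aa_pool)))
            else:
                chars.append(query_seq[p])
        homolog_seqs.append("".join(chars))

    query_id = "QUERY"
    query_rec = SequenceRecord(id=query_id, sequence=query_seq)
    homolog_recs = [SequenceRecord(id=sid, sequence=s)
                    for sid, s in zip(subject_ids, homolog_seqs)]

    paths = {
        "query_fasta": out_dir / "query.fasta",
        "homologs_fasta": out_dir / "homologs.fasta",
        "aligned_fasta": out_dir / "aligned.fasta",
        "pdb": out_dir / "model.pdb",
        "dssp": out_dir / "model.dssp",
        "anchor2": out_dir / "anchor2.txt",
        "blast_tab": out_dir / "hits.tsv",
    }
    write_fasta([query_rec], paths["query_fasta"])
    write_fasta(homolog_recs, paths["homologs_fasta"])
    # all sequences are equal-length by construction, so the identity
    # alignment (no gaps) is already a valid MSA
    write_fasta([query_rec, *homolog_recs], paths["aligned_fasta"])
    paths["pdb"].write_text(make_toy_pdb(query_seq))
    accs = [int(round(profiles[p]["acc_frac"] * MAX_ASA_THEORETICAL[query_seq[p]]))
            for p in range(spec.length)]
    _write_dssp_classic(paths["dssp"], query_seq,
                        [profiles[p]["ss"] for p in range(spec.length)], accs)
    _write_anchor_long(paths["anchor2"], query_seq,
                       [profiles[p]["br"] for p in range(spec.length)])
    _write_blast_tab(paths["blast_tab"], query_id, subject_ids, spec.length)
    return FixtureBundle(spec=spec, directory=out_dir, query=query_rec, **paths)
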