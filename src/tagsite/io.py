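"""Readers and writers for the external file formats the pipeline consumes.

Every parser returns plain dataclasses indexed the way the files index them;
re-indexing onto the query sequence happens in :mod:`tagsite.pipeline` so that
parsing stays a faithful record of what the file said.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
from Bio import SeqIO

log = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Codes accepted in sequences but flagged as non-standard (ambiguity codes,
#: selenocysteine, stop, gap).
EXTENDED_AA = set("XBZU*-")

#: DSSP secondary-structure alphabet after normalisation (blank -> C).
DSSP_CODES = set("GHIEBTSPC")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


@dataclass
class SequenceRecord:
    """One FASTA record: an accession/label and an uppercase AA sequence."""

    id: str
    sequence: str
    nonstandard_positions: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        flagged = []
        for i, ch in enumerate(self.sequence, start=1):
            if ch in STANDARD_AA:
                continue
            if ch in EXTENDED_AA:
                flagged.append(i)
            else:
                raise FormatError(
                    f"record {self.id!r}: invalid sequence character {ch!r} "
                    f"at position {i}"
                )
        if flagged and not self.nonstandard_positions:
            self.nonstandard_positions = tuple(flagged)


@dataclass
class ResidueAtoms:
    """One residue of a structure model."""

    seq_index: int  # 1-based, strictly increasing within a chain
    aa: str  # one-letter code; 'X' for non-standard amino acids
    atoms: list[tuple[str, str, float, float, float]]  # (name, element, x, y, z)
    confidence: Optional[float] = None  # pLDDT when the model is AlphaFold-like


@dataclass
class StructureModel:
    """A single protein chain with per-residue atoms and optional confidence."""

    chain_id: str
    residues: list[ResidueAtoms]
    is_alphafold: bool = False

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class DsspRecord:
    """One residue row of a DSSP run: structure code and accessible area."""

    seq_index: int
    aa: str
    ss_code: str  # normalised: blank mapped to 'C'
    acc: float  # solvent accessible surface area, A^2

    def __post_init__(self) -> None:
        if self.acc < 0:
            raise FormatError(f"residue {self.seq_index}: negative ACC {self.acc}")
        if self.ss_code not in DSSP_CODES:
            raise FormatError(
                f"residue {self.seq_index}: unknown SS code {self.ss_code!r}"
            )


@dataclass
class DisorderRecord:
    """Per-residue disordered-binding propensity (ANCHOR2 score, in [0, 1])."""

    seq_index: int
    br: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.br <= 1.0:
            raise FormatError(
                f"residue {self.seq_index}: binding propensity {self.br} "
                f"outside [0, 1]"
            )


@dataclass
class BlastHit:
    query_id: str
    subject_id: str
    subject_species: Optional[str]
    evalue: float
    bitscore: float
    subject_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"hit {self.subject_id}: negative E-value")


@dataclass
class QueryProtein:
    """The protein being scored: sequence plus (optionally) its structure."""

    record: SequenceRecord
    structure: Optional[StructureModel] = None
    accession: Optional[str] = None

    @property
    def sequence(self) -> str:
        return self.record.sequence


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and whitespace-stripped; record order is
    preserved. Raises :class:`FormatError` for empty files, records without
    sequence, or content that is not FASTA.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FormatError(f"{path}: line {lineno}: expected FASTA header")
        break
    else:
        raise FormatError(f"{path}: empty file")
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = "".join(str(rec.seq).split()).upper()
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} has no sequence")
            records.append(SequenceRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Structures (PDB / mmCIF)


def read_structure(
    path: str | Path,
    chain: Optional[str] = None,
    is_alphafold: bool = False,
) -> StructureModel:
    """Read a PDB or mmCIF file into a single-chain :class:`StructureModel`.

    The requested chain (default: first chain containing protein residues) is
    returned with residues re-indexed 1..N in order of appearance. HETATM
    groups and waters are excluded; alternate locations are resolved by
    highest occupancy; residues with insertion codes are rejected. The
    B-factor of the first atom of each residue is exposed as ``confidence``
    (the pLDDT convention for AlphaFold models).
    """
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse structure: {exc}") from exc
    structure.setup_entities()
    if len(structure) == 0:
        raise FormatError(f"{path}: no models in structure")
    model = structure[0]

    chosen = None
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        residues = _protein_residues(ch, path)
        if residues:
            chosen = StructureModel(chain_id=ch.name, residues=residues,
                                    is_alphafold=is_alphafold)
            break
    if chosen is None:
        if chain is not None:
            raise FormatError(f"{path}: chain {chain!r} not found or has "
                              f"zero protein residues")
        raise FormatError(f"{path}: zero protein residues")
    return chosen


def _protein_residues(ch: "gemmi.Chain", path: Path) -> list[ResidueAtoms]:
    residues: list[ResidueAtoms] = []
    for res in ch:
        info = gemmi.find_tabulated_residue(res.name)
        is_aa = (info is not None and info.is_amino_acid()) or res.name in _THREE_TO_ONE
        if not is_aa:
            continue
        if res.het_flag == "H" and res.name not in _THREE_TO_ONE:
            continue  # modified/het groups outside the standard 20
        if res.seqid.icode not in (" ", "\0", ""):
            raise FormatError(
                f"{path}: residue {res.name} {res.seqid.num} has insertion "
                f"code {res.seqid.icode!r}; renumber the model first"
            )
        atoms: dict[str, tuple[float, "gemmi.Atom"]] = {}
        for atom in res:
            prev = atoms.get(atom.name)
            if prev is None or atom.occ > prev[0]:
                atoms[atom.name] = (atom.occ, atom)
        if not atoms:
            continue
        first = next(iter(atoms.values()))[1]
        residues.append(
            ResidueAtoms(
                seq_index=len(residues) + 1,
                aa=_THREE_TO_ONE.get(res.name, "X"),
                atoms=[
                    (a.name, a.element.name, a.pos.x, a.pos.y, a.pos.z)
                    for _, a in atoms.values()
                ],
                confidence=first.b_iso,
            )
        )
    return residues


# ---------------------------------------------------------------------------
# DSSP output (classic fixed-column and mmCIF dialects)

# Classic format column offsets (0-based): AA at 13, SS at 16, ACC at 34:38.
_CLASSIC_AA_COL = 13
_CLASSIC_SS_COL = 16
_CLASSIC_ACC_SLICE = slice(34, 38)


def parse_dssp(path: str | Path) -> list[DsspRecord]:
    """Parse DSSP output (classic or mmCIF dialect, auto-detected).

    Blank secondary-structure fields are normalised to ``C``; chain-break
    rows (``!``) are skipped. One record is returned per residue row.
    """
    path = Path(path)
    text = path.read_text()
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if first.startswith("data_"):
        return _parse_dssp_cif(path)
    return _parse_dssp_classic(path, text)


def _parse_dssp_classic(path: Path, text: str) -> list[DsspRecord]:
    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#") and "RESIDUE" in line and "AA" in line:
            start = i + 1
            break
    if start is None:
        raise FormatError(f"{path}: no '#  RESIDUE AA' header line; "
                          f"not classic DSSP output")
    records: list[DsspRecord] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        if len(line) <= _CLASSIC_SS_COL:
            raise FormatError(f"{path}: line {lineno}: truncated residue row")
        aa = line[_CLASSIC_AA_COL]
        if aa == "!":  # chain break marker
            continue
        ss = line[_CLASSIC_SS_COL]
        ss = "C" if ss == " " else ss
        try:
            seq_index = int(line[0:5])
            acc = int(line[_CLASSIC_ACC_SLICE])
        except ValueError as exc:
            raise FormatError(
                f"{path}: line {lineno}: malformed column layout: {exc}"
            ) from exc
        try:
            records.append(DsspRecord(seq_index=seq_index, aa=aa,
                                      ss_code=ss, acc=float(acc)))
        except FormatError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return records


def _parse_dssp_cif(path: Path) -> list[DsspRecord]:
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    table = block.find(
        "_dssp_struct_summary.",
        ["label_seq_id", "label_comp_id", "secondary_structure", "accessibility"],
    )
    if len(table) == 0:
        raise FormatError(f"{path}: no _dssp_struct_summary loop in mmCIF DSSP file")
    records: list[DsspRecord] = []
    for row in table:
        ss = row[2].strip()
        ss = "C" if ss in (".", "?", "", "~") else ss
        acc_str = row[3].strip()
        acc = 0.0 if acc_str in (".", "?") else float(acc_str)
        records.append(
            DsspRecord(
                seq_index=int(row[0]),
                aa=_THREE_TO_ONE.get(row[1].upper(), "X"),
                ss_code=ss,
                acc=acc,
            )
        )
    return records


# ---------------------------------------------------------------------------
# IUPred2A / ANCHOR2 output


def parse_anchor2(path: str | Path) -> list[DisorderRecord]:
    """Parse per-residue disordered-binding propensities.

    Accepts IUPred2A long-format output (position, residue, IUPred score,
    ANCHOR score) or a minimal two-column position/score file. Comment lines
    starting with ``#`` are ignored.
    """
    path = Path(path)
    records: list[DisorderRecord] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        try:
            pos = int(fields[0])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: bad position field") from exc
        if len(fields) >= 4:
            score_field = fields[3]  # ANCHOR column of the long format
        elif len(fields) == 2:
            score_field = fields[1]
        else:
            raise FormatError(
                f"{path}: line {lineno}: expected 2 or >=4 columns, "
                f"got {len(fields)} (missing ANCHOR column?)"
            )
        try:
            br = float(score_field)
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: bad ANCHOR score") from exc
        try:
            records.append(DisorderRecord(seq_index=pos, br=br))
        except FormatError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    if not records:
        warnings.warn(f"{path}: no residue rows found (comments only?)")
    return records


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

_OUTFMT6_MIN_COLS = 12
_EVALUE_COL = 10
_BITSCORE_COL = 11


def parse_blast_tabular(
    path: str | Path,
    species_col: Optional[int] = None,
    species_sep: str = "__",
) -> list[BlastHit]:
    """Parse BLAST tabular (outfmt-6-style) hits; no filtering at this layer.

    Species labels are taken from column index ``species_col`` when given,
    from the 13th column when present (``sscinames`` convention), or parsed
    from the subject id after ``species_sep``. Hits whose species cannot be
    determined carry ``subject_species=None``.
    """
    path = Path(path)
    hits: list[BlastHit] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < _OUTFMT6_MIN_COLS:
            raise FormatError(
                f"{path}: line {lineno}: expected >= {_OUTFMT6_MIN_COLS} "
                f"tab-separated columns, got {len(fields)}"
            )
        try:
            evalue = float(fields[_EVALUE_COL])
            bitscore = float(fields[_BITSCORE_COL])
        except ValueError as exc:
            raise FormatError(
                f"{path}: line {lineno}: non-numeric E-value/bitscore"
            ) from exc
        subject_id = fields[1]
        if species_col is not None:
            species = fields[species_col] if species_col < len(fields) else None
        elif len(fields) > _OUTFMT6_MIN_COLS:
            species = fields[_OUTFMT6_MIN_COLS]
        elif species_sep in subject_id:
            species = subject_id.rsplit(species_sep, 1)[1].replace("_", " ")
        else:
            species = None
        hits.append(
            BlastHit(
                query_id=fields[0],
                subject_id=subject_id,
                subject_species=species,
                evalue=evalue,
                bitscore=bitscore,
            )
        )
    return hits
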