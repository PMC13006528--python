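"""Homolog selection, alignment handling, and the conservation feature.

Sequence conservation is measured as column-wise Shannon entropy of a
multiple sequence alignment of the query with one ortholog per species,
normalised by the maximum entropy over 20 amino acids. High entropy
(low conservation) marks positions more tolerant of an inserted tag.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence

import numpy as np

from .io import STANDARD_AA, BlastHit, SequenceRecord, read_fasta, write_fasta
from .scoring import FeatureTrack

log = logging.getLogger(__name__)

#: Species panel over which orthologs are collected by default: a diverse
#: set of vertebrates spanning mammals, bird, amphibian and teleost fish.
DEFAULT_SPECIES_PANEL = (
    "Bos taurus",
    "Canis lupus",
    "Gallus gallus",
    "Homo sapiens",
    "Mus musculus",
    "Takifugu rubripes",
    "Xenopus tropicalis",
)

#: Printed-precision entropy normalisation constant, log2(20) rounded to
#: two decimals. Kept at 2 dp so reported scores round-trip with published
#: per-residue tables; pass ``full_precision_norm=True`` for exact log2(20).
ENTROPY_NORM = 4.32


@dataclass
class HomologSet:
    """At most one homolog per species, chosen by best (lowest) E-value."""

    query: SequenceRecord
    homologs: dict[str, SequenceRecord]
    evalues: dict[str, float]
    missing_species: tuple[str, ...] = ()

    def all_records(self) -> list[SequenceRecord]:
        return [self.query, *self.homologs.values()]


@dataclass
class Alignment:
    """A multiple sequence alignment with an identified query row."""

    rows: list[tuple[str, str]]  # (id, aligned sequence with '-' gaps)
    query_row_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        width = len(self.rows[0][1])
        for rid, seq in self.rows:
            if len(seq) != width:
                raise ValueError(
                    f"alignment row {rid!r} has length {len(seq)}, "
                    f"expected {width}"
                )
        if self.query_row_id not in {rid for rid, _ in self.rows}:
            raise ValueError(f"query row {self.query_row_id!r} not in alignment")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def query_row(self) -> str:
        for rid, seq in self.rows:
            if rid == self.query_row_id:
                return seq
        raise AssertionError("unreachable")

    def column(self, c: int) -> list[str]:
        return [seq[c] for _, seq in self.rows]


@dataclass
class ColumnMap:
    """1-based query position -> 0-based alignment column, for non-gap sites."""

    query_pos_to_column: dict[int, int]

    def __post_init__(self) -> None:
        cols = [self.query_pos_to_column[p]
                for p in sorted(self.query_pos_to_column)]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("column map is not strictly increasing")


# ---------------------------------------------------------------------------
# Homolog selection


def select_best_hits(
    hits: Sequence["BlastHit"],
    query: SequenceRecord,
    species_list: Sequence[str] = DEFAULT_SPECIES_PANEL,
    sequence_lookup: Optional[dict[str, SequenceRecord]] = None,
) -> HomologSet:
    """Keep, for each species, the hit with the lowest E-value.

    Ties are broken by highest bitscore, then by file order. Species without
    any hit are recorded in ``missing_species`` (and logged) rather than
    treated as fatal. Homolog sequences are taken from the hit itself when
    present, otherwise resolved through ``sequence_lookup`` (subject id ->
    record).
    """
    if not hits:
        raise ValueError("empty hit list")
    best: dict[str, tuple[float, float, int, "BlastHit"]] = {}
    for order, hit in enumerate(hits):
        sp = hit.subject_species
        if sp is None or sp not in species_list:
            continue
        key = (hit.evalue, -hit.bitscore, order)
        if sp not in best or key < (best[sp][0], best[sp][1], best[sp][2]):
            best[sp] = (hit.evalue, -hit.bitscore, order, hit)
    homologs: dict[str, SequenceRecord] = {}
    evalues: dict[str, float] = {}
    for sp, (_, _, _, hit) in best.items():
        if hit.subject_sequence is not None:
            rec = SequenceRecord(id=hit.subject_id, sequence=hit.subject_sequence)
        elif sequence_lookup and hit.subject_id in sequence_lookup:
            rec = sequence_lookup[hit.subject_id]
        else:
            raise ValueError(
                f"no sequence available for subject {hit.subject_id!r} "
                f"({sp}); provide sequence_lookup"
            )
        homologs[sp] = rec
        evalues[sp] = hit.evalue
    missing = tuple(sp for sp in species_list if sp not in homologs)
    for sp in missing:
        log.warning("no homolog found for species %s", sp)
    return HomologSet(query=query, homologs=homologs, evalues=evalues,
                      missing_species=missing)


# ---------------------------------------------------------------------------
# Alignment construction


class AlignerAdapter(Protocol):
    """Adapter contract: align a set of sequences, return aligned records."""

    def align(self, records: Sequence[SequenceRecord]) -> list[SequenceRecord]: ...


class PreAlignedAdapter:
    """Satisfies the aligner contract by loading an existing aligned FASTA."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def align(self, records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
        aligned = read_fasta(self.path)
        ids_in = {r.id for r in records}
        ids_aligned = {r.id for r in aligned}
        if not ids_in <= ids_aligned:
            raise ValueError(
                f"pre-aligned file {self.path} is missing sequences: "
                f"{sorted(ids_in - ids_aligned)}"
            )
        return [r for r in aligned if r.id in ids_in]


class ExternalAlignerAdapter:
    """Runs an external aligner binary (mafft or muscle style CLI)."""

    def __init__(self, executable: str = "mafft"):
        self.executable = executable

    def align(self, records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
        exe = shutil.which(self.executable)
        if exe is None:
            raise RuntimeError(
                f"aligner {self.executable!r} not found on PATH; either "
                f"install it or supply a pre-aligned FASTA"
            )
        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "unaligned.fasta"
            write_fasta(records, inp)
            if Path(exe).name.startswith("mafft"):
                cmd = [exe, "--auto", "--quiet", str(inp)]
            else:  # muscle-style
                cmd = [exe, "-align", str(inp), "-output", "-"]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise RuntimeError(
                    f"aligner failed (exit {proc.returncode}): {proc.stderr[-500:]}"
                )
            out = Path(tmp) / "aligned.fasta"
            out.write_text(proc.stdout)
            return read_fasta(out)


def build_msa(
    sequences: Sequence[SequenceRecord],
    aligner: AlignerAdapter,
    query_row_id: Optional[str] = None,
) -> Alignment:
    """Align sequences (query first) through the given adapter."""
    if len(sequences) < 2:
        raise ValueError(">=2 sequences required to build an alignment")
    query_row_id = query_row_id or sequences[0].id
    aligned = aligner.align(sequences)
    return Alignment(
        rows=[(r.id, r.sequence) for r in aligned],
        query_row_id=query_row_id,
    )


def map_columns_to_query(alignment: Alignment) -> ColumnMap:
    """Map each non-gap query position to its alignment column."""
    qrow = alignment.query_row
    mapping: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(qrow):
        if ch != "-":
            pos += 1
            mapping[pos] = col
    if not mapping:
        raise ValueError("query row is all gaps")
    return ColumnMap(query_pos_to_column=mapping)


# ---------------------------------------------------------------------------
# Shannon entropy


def shannon_entropy(column: Iterable[str]) -> float:
    """Shannon entropy (bits) of one alignment column.

    H = -sum_a p(x_a) log2 p(x_a) over the 20 standard amino acids. Gaps and
    non-standard codes are excluded before computing frequencies (treated as
    missing data, not a 21st symbol). Columns with fewer than two counted
    residues return 0.
    """
    counts = Counter(ch.upper() for ch in column if ch.upper() in STANDARD_AA)
    total = sum(counts.values())
    if total < 2:
        return 0.0
    # "+ 0.0" normalises the -0.0 a fully conserved column would produce
    return -sum((n / total) * math.log2(n / total) for n in counts.values()) + 0.0


def entropy_feature(
    alignment: Alignment,
    full_precision_norm: bool = False,
) -> FeatureTrack:
    """Per-query-position normalised entropy track in [0, 1].

    Entropy at each query position is divided by 4.32 (printed-precision
    log2(20); or the full-precision constant when requested) and clipped to
    [0, 1]. Higher values mean less conserved, hence more taggable.
    """
    norm = math.log2(20.0) if full_precision_norm else ENTROPY_NORM
    cmap = map_columns_to_query(alignment)
    length = len(cmap.query_pos_to_column)
    values = np.zeros(length)
    degenerate = 0
    for pos, col in cmap.query_pos_to_column.items():
        h = shannon_entropy(alignment.column(col))
        if h == 0.0 and sum(
            1 for ch in alignment.column(col) if ch.upper() in STANDARD_AA
        ) < 2:
            degenerate += 1
        values[pos - 1] = min(h / norm, 1.0)
    if degenerate:
        log.warning("%d columns had <2 counted residues; entropy set to 0",
                    degenerate)
    return FeatureTrack(name="entropy", values=values)
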