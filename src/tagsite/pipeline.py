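"""End-to-end workflow: files in, ranked tag-insertion sites out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import conservation, disorder, structure
from .conservation import (
    DEFAULT_SPECIES_PANEL,
    Alignment,
    ExternalAlignerAdapter,
    entropy_feature,
    select_best_hits,
)
from .io import (
    DsspRecord,
    QueryProtein,
    SequenceRecord,
    parse_anchor2,
    parse_blast_tabular,
    parse_dssp,
    read_fasta,
    read_structure,
)
from .scoring import (
    FEATURE_ORDER,
    ScoringConfig,
    TagSiteReport,
    assemble_features,
    rank_sites,
    score_residues,
)
from .structure import StructureFeatureConfig, rsa_from_structure

log = logging.getLogger(__name__)

TSV_COLUMNS = ("position", "aa", "entropy", "ss", "rsa", "dbr",
               "e_min", "s_weighted", "e_windowed")


@dataclass
class RunConfig:
    sequence_path: Optional[Path] = None
    structure_path: Optional[Path] = None
    alignment_path: Optional[Path] = None
    dssp_path: Optional[Path] = None
    anchor2_path: Optional[Path] = None
    blast_tab_path: Optional[Path] = None
    homologs_path: Optional[Path] = None
    accession: Optional[str] = None
    species_panel: Sequence[str] = DEFAULT_SPECIES_PANEL
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    structure_config: StructureFeatureConfig = field(
        default_factory=StructureFeatureConfig)
    out_dir: Path = Path("tagsite_out")
    offline: bool = True
    make_plot: bool = False
    aligner: str = "mafft"
    cache_dir: Path = Path("~/.cache/tagsite")

    def __post_init__(self) -> None:
        for name in ("sequence_path", "structure_path", "alignment_path",
                     "dssp_path", "anchor2_path", "blast_tab_path",
                     "homologs_path", "out_dir", "cache_dir"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        if self.offline and self.accession and self.sequence_path is None:
            raise ValueError(
                "offline mode requires an explicit sequence file; an "
                "accession alone implies a network fetch"
            )
        if self.sequence_path is None and self.accession is None:
            raise ValueError("either a sequence file or an accession is required")


def _load_query(config: RunConfig) -> QueryProtein:
    if config.sequence_path is not None:
        record = read_fasta(config.sequence_path)[0]
        model = None
        if config.structure_path is not None:
            model = read_structure(config.structure_path)
        return QueryProtein(record=record, structure=model,
                            accession=config.accession)
    from .fetch import fetch_query

    return fetch_query(config.accession, cache_dir=config.cache_dir)


def _load_alignment(config: RunConfig, query: QueryProtein) -> Alignment:
    qseq = query.sequence
    if config.alignment_path is not None:
        rows = [(r.id, r.sequence) for r in read_fasta(config.alignment_path)]
        query_row_id = None
        for rid, seq in rows:
            if rid == query.record.id or seq.replace("-", "") == qseq:
                query_row_id = rid
                break
        if query_row_id is None:
            raise ValueError(
                f"alignment {config.alignment_path} has no row matching the "
                f"query id or sequence"
            )
        aln = Alignment(rows=rows, query_row_id=query_row_id)
    elif config.blast_tab_path is not None and config.homologs_path is not None:
        hits = parse_blast_tabular(config.blast_tab_path)
        lookup = {r.id: r for r in read_fasta(config.homologs_path)}
        homolog_set = select_best_hits(hits, query.record,
                                       species_list=config.species_panel,
                                       sequence_lookup=lookup)
        adapter = ExternalAlignerAdapter(config.aligner)
        aln = conservation.build_msa(homolog_set.all_records(), adapter,
                                     query_row_id=query.record.id)
    else:
        raise ValueError(
            "conservation input missing: supply a pre-computed alignment, or "
            "a BLAST tabular file plus a homolog FASTA"
        )
    ungapped = aln.query_row.replace("-", "")
    if ungapped != qseq:
        diffs = [i + 1 for i, (a, b) in enumerate(zip(ungapped, qseq)) if a != b]
        raise ValueError(
            f"aligned query row disagrees with the query sequence "
            f"(length {len(ungapped)} vs {len(qseq)}; first differing "
            f"positions {diffs[:10]})"
        )
    return aln


def reindex_dssp_to_query(records: Sequence[DsspRecord], query_seq: str
                          ) -> list[DsspRecord]:
    """Re-index structure annotations onto the query sequence (1..L).

    Author numbering from the structure is discarded; records are matched to
    the query by order of appearance after checking the annotated sequence
    equals the query sequence (lowercase codes, the disulfide convention,
    count as cysteine).
    """
    if len(records) != len(query_seq):
        raise ValueError(
            f"structure annotation covers {len(records)} residues but the "
            f"query has {len(query_seq)}"
        )
    mismatches = []
    out = []
    for i, rec in enumerate(records):
        aa = "C" if rec.aa.islower() else rec.aa
        if aa not in ("X", query_seq[i]):
            mismatches.append(i + 1)
        out.append(DsspRecord(seq_index=i + 1, aa=query_seq[i],
                              ss_code=rec.ss_code, acc=rec.acc))
    if mismatches:
        raise ValueError(
            f"structure annotation sequence differs from the query at "
            f"positions {mismatches[:10]}"
        )
    return out


def run_pipeline(config: RunConfig) -> TagSiteReport:
    """Run the full scoring workflow and write the report artifacts.

    Writes a per-residue TSV (full precision), a ranked-candidate JSON and,
    optionally, a two-panel plot into ``config.out_dir``. Partial outputs
    are removed if any stage fails.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        query = _load_query(config)
        L = len(query.sequence)

        aln = _load_alignment(config, query)
        entropy = entropy_feature(aln)

        if config.dssp_path is not None:
            records = reindex_dssp_to_query(parse_dssp(config.dssp_path),
                                            query.sequence)
            ss, rsa = structure.structure_feature_tracks(
                records, L, config.structure_config)
        elif query.structure is not None:
            log.warning(
                "no secondary-structure annotation supplied; RSA computed "
                "from coordinates, secondary structure assumed coil everywhere"
            )
            if query.structure.sequence != query.sequence:
                raise ValueError("structure sequence does not match the query")
            rsa = rsa_from_structure(query.structure, config.structure_config)
            import numpy as np

            ss = structure.FeatureTrack("secondary_structure", np.ones(L))
        else:
            raise ValueError(
                "structure input missing: supply a DSSP-style annotation "
                "file or an all-atom structure"
            )

        if config.anchor2_path is None:
            raise ValueError("disordered-binding input missing "
                             "(ANCHOR-style file required)")
        dbr = disorder.dbr_feature(parse_anchor2(config.anchor2_path), L)

        matrix = assemble_features(entropy, ss, rsa, dbr)
        scores = score_residues(matrix, query.sequence, config.scoring)
        report = rank_sites(scores, config=config.scoring,
                            query_id=query.record.id)

        tsv_path = out_dir / "residue_scores.tsv"
        _write_tsv(report, tsv_path)
        written.append(tsv_path)
        json_path = out_dir / "tag_sites.json"
        json_path.write_text(report.to_json() + "\n")
        written.append(json_path)
        if config.make_plot:
            from .plotting import plot_tracks

            plot_path = out_dir / "tracks.png"
            plot_tracks(report, plot_path)
            written.append(plot_path)
        return report
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _write_tsv(report: TagSiteReport, path: Path) -> None:
    rows = [
        {
            "position": r.position,
            "aa": r.aa,
            "entropy": r.features["entropy"],
            "ss": r.features["secondary_structure"],
            "rsa": r.features["rsa"],
            "dbr": r.features["dbr"],
            "e_min": r.e_min,
            "s_weighted": r.s_weighted,
            "e_windowed": r.e_windowed,
        }
        for r in report.residues
    ]
    frame = pd.DataFrame(rows, columns=list(TSV_COLUMNS))
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
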