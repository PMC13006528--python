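"""Optional network fetchers for query sequence and predicted structure.

Everything else in the package works offline from files; these helpers only
pre-populate a local cache from the UniProt REST sequence endpoint and the
public repository of predicted structure models for an accession. Every test
in the repository passes with this module unused.
"""

from __future__ import annotations

import logging
import re
import urllib.request
from pathlib import Path
from typing import Optional

from .io import FormatError, QueryProtein, read_fasta, read_structure

log = logging.getLogger(__name__)

UNIPROT_FASTA_URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"
ALPHAFOLD_PDB_URL = "https://alphafold.ebi.ac.uk/files/AF-{acc}-F1-model_v4.pdb"

# UniProt accession grammar (6- and 10-character forms).
_ACCESSION_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)


def validate_accession(accession: str) -> str:
    accession = accession.strip().upper()
    if not _ACCESSION_RE.match(accession):
        raise ValueError(f"malformed UniProt accession {accession!r}")
    return accession


def _cached_download(url: str, dest: Path, timeout: float = 30.0) -> Path:
    if dest.exists():
        return dest
    dest.parent.mkdir(parents=True, exist_ok=True)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except Exception as exc:  # URLError, HTTPError, timeout
        raise RuntimeError(f"failed to fetch {url}: {exc}") from exc
    tmp = dest.with_suffix(dest.suffix + ".part")
    tmp.write_bytes(data)
    tmp.rename(dest)
    return dest


def fetch_query(
    accession: str,
    cache_dir: str | Path = "~/.cache/tagsite",
    with_structure: bool = True,
) -> QueryProtein:
    """Fetch sequence (and predicted structure) for a UniProt accession.

    Results are cached on disk under ``cache_dir``; repeat calls are served
    from the cache without touching the network.
    """
    accession = validate_accession(accession)
    cache = Path(cache_dir).expanduser() / accession
    fasta = _cached_download(UNIPROT_FASTA_URL.format(acc=accession),
                             cache / f"{accession}.fasta")
    records = read_fasta(fasta)
    record = records[0]
    structure = None
    if with_structure:
        pdb = _cached_download(ALPHAFOLD_PDB_URL.format(acc=accession),
                               cache / f"{accession}.pdb")
        structure = read_structure(pdb, is_alphafold=True)
        if structure.sequence != record.sequence:
            raise FormatError(
                f"{accession}: structure sequence length "
                f"{len(structure.sequence)} does not match UniProt sequence "
                f"length {len(record.sequence)}"
            )
    return QueryProtein(record=record, structure=structure, accession=accession)
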