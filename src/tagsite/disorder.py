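"""Disordered-binding-region feature track.

The upstream predictor reports, per residue, the probability BR that a
disordered segment participates in a binding interaction. To avoid placing a
tag inside a predicted interaction region the score used downstream is the
complement 1 - BR: high values mean the position is unlikely to mediate
binding and is therefore suitable for tagging. No smoothing is applied here;
windowing happens only at the combined-score stage.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .io import DisorderRecord
from .scoring import FeatureTrack


def dbr_feature(records: Sequence[DisorderRecord], query_length: int) -> FeatureTrack:
    """Complement track 1 - BR over positions 1..query_length.

    Records must cover every query position exactly once; gaps or duplicates
    raise with the offending positions listed (truncation would silently
    misalign all downstream scores).
    """
    values = np.full(query_length, np.nan)
    duplicates = []
    for rec in records:
        if not 1 <= rec.seq_index <= query_length:
            raise ValueError(
                f"disorder record at position {rec.seq_index} outside "
                f"1..{query_length}"
            )
        if not np.isnan(values[rec.seq_index - 1]):
            duplicates.append(rec.seq_index)
        values[rec.seq_index - 1] = 1.0 - rec.br
    missing = [i + 1 for i in range(query_length) if np.isnan(values[i])]
    if duplicates or missing:
        raise ValueError(
            f"disorder records must cover each position once; "
            f"duplicates={duplicates[:10]}, missing={missing[:10]}"
        )
    return FeatureTrack("dbr", values)
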