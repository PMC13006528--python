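"""Two-panel report figure: the four feature tracks and the windowed score."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .scoring import FEATURE_ORDER, TagSiteReport  # noqa: E402

_LABELS = {
    "entropy": "Shannon entropy",
    "secondary_structure": "secondary structure",
    "rsa": "RSA",
    "dbr": "DBR (1 - binding propensity)",
}


def plot_tracks(report: TagSiteReport, path: str | Path) -> Path:
    """Render feature tracks and windowed minimum score with top sites marked."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    positions = [r.position for r in report.residues]
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    for name in FEATURE_ORDER:
        ax1.plot(positions, [r.features[name] for r in report.residues],
                 label=_LABELS[name], linewidth=1)
    ax1.set_ylabel("feature score")
    ax1.set_ylim(-0.05, 1.05)
    ax1.legend(fontsize=8, ncol=2)
    ax2.plot(positions, [r.e_windowed for r in report.residues],
             color="black", linewidth=1.2, label="windowed min score")
    for pos, _, _ in report.candidates:
        ax2.axvline(pos, color="red", linewidth=0.8, alpha=0.7)
    ax2.set_xlabel("residue position")
    ax2.set_ylabel("windowed $E_i$")
    ax2.legend(fontsize=8)
    fig.suptitle(f"{report.query_id}: candidate tag insertion sites")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
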