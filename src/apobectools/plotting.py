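"""96-channel mutational profile plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .channels import CHANNEL_LABELS, SUBSTITUTIONS
from .signatures import Catalog96

_CLASS_COLORS = ["#03BCEE", "#010101", "#E32926", "#CAC9C9", "#A1CE63", "#EBC6C4"]


def plot_catalog96(catalog: Catalog96, path, title: str | None = None) -> None:
    """Bar plot of mutation counts over the 96 trinucleotide channels,
    grouped into the six substitution classes."""
    counts = np.asarray(catalog.counts, dtype=float)
    fig, ax = plt.subplots(figsize=(14, 3.2))
    colors = [_CLASS_COLORS[i // 16] for i in range(96)]
    ax.bar(range(96), counts, color=colors, width=0.75)
    ax.set_xticks(range(96))
    ax.set_xticklabels(
        [lab[0] + lab[2] + lab[6] for lab in CHANNEL_LABELS],
        rotation=90, fontsize=4.5, family="monospace",
    )
    top = counts.max() if counts.max() > 0 else 1.0
    for j, (ref, alt) in enumerate(SUBSTITUTIONS):
        ax.text(16 * j + 7.5, top * 1.08, f"{ref}>{alt}", ha="center", fontsize=9)
        if j:
            ax.axvline(16 * j - 0.5, color="0.8", lw=0.6)
    ax.set_ylim(0, top * 1.2)
    ax.set_ylabel("mutations")
    ax.set_title(title or catalog.sample_id, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
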