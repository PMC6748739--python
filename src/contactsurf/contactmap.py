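"""Heat-map rendering of contact matrices.

Reads a matrix in this package's TSV dialect (read-only) and renders it
with rows and columns in file order and cell color monotone in contact
area, blue (low) to red (high).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .structure_io import read_matrix_tsv  # noqa: E402


@dataclass
class MapStyle:
    """Appearance of a rendered contact map."""

    colormap: str = "coolwarm"  # blue (0 / low) -> red (high)
    max_labels: int = 40        # decimate axis tick labels beyond this
    dpi: int = 150


def render_contact_map(tsv_path: str | Path, out_path: str | Path,
                       style: MapStyle | None = None) -> Path:
    """Render a contact-matrix TSV to a PNG or SVG image (by extension)."""
    style = style or MapStyle()
    matrix = read_matrix_tsv(tsv_path)
    out_path = Path(out_path)
    nrow, ncol = matrix.values.shape
    fig, ax = plt.subplots(
        figsize=(max(3.0, min(12.0, 0.25 * ncol + 2)),
                 max(2.5, min(12.0, 0.25 * nrow + 1.5))))
    vmax = matrix.values.max()
    im = ax.imshow(matrix.values, cmap=style.colormap, vmin=0.0,
                   vmax=vmax if vmax > 0 else 1.0, aspect="auto",
                   interpolation="nearest")
    ax.set_xticks(*_ticks(matrix.col_labels, style.max_labels))
    ax.set_yticks(*_ticks(matrix.row_labels, style.max_labels))
    ax.tick_params(axis="x", labelrotation=90, labelsize=7)
    ax.tick_params(axis="y", labelsize=7)
    fig.colorbar(im, ax=ax, label="contact surface area (Å²)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=style.dpi)
    plt.close(fig)
    return out_path


def _ticks(labels: list[str], max_labels: int) -> tuple[list[int], list[str]]:
    step = max(1, -(-len(labels) // max_labels))
    idx = list(range(0, len(labels), step))
    return idx, [labels[i] for i in idx]
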