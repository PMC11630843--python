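"""Vector-graphic rendering of the three analysis outputs.

* **GRM diagram** — stem plot of repeat-period frequency (the
  monomeric analogue of a Southern-blot band pattern);
* **MD diagram** — scatter of monomer ordinal vs next-similar
  distance, which localises HOR regions along the array;
* **aligned scheme** — one coloured box per monomer, same type = same
  colour and column, each row one repeat unit.

Rendering is display-only: ``RenderConfig`` never influences any
computed quantity, and the period cut-off (default 60) truncates the
plot but never the exported spectrum.  SVG output is byte-stable for
identical inputs (fixed hash salt, no timestamp metadata); PostScript
output suppresses its creation-date comment.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib import rc_context
from matplotlib.patches import Rectangle

from .grm_core import AlignedScheme, NextSimilarVector, PeriodSpectrum, TypeAssignment
from .monomer_model import MonomerArray

_HATCHES = [None, "//", "..", "xx", "\\\\", "++"]


@dataclass(frozen=True)
class RenderConfig:
    """Display parameters; none of them affects computation."""

    max_displayed_period: int = 60
    start_monomer: int = 0
    show_genomic_positions: bool = False
    output_format: str = "svg"

    def __post_init__(self) -> None:
        if self.max_displayed_period < 2:
            raise ValueError("max_displayed_period must be >= 2")
        if self.start_monomer < 0:
            raise ValueError("start_monomer must be >= 0")
        if self.output_format not in ("svg", "ps"):
            raise ValueError("output_format must be 'svg' or 'ps'")


DEFAULT_RENDER = RenderConfig()


def _save(fig, path: Path, cfg: RenderConfig) -> Path:
    with rc_context({"svg.hashsalt": "grmhor"}):
        if cfg.output_format == "svg":
            fig.savefig(path, format="svg", metadata={"Date": None})
        else:
            # a file object suppresses the filename Title comment; a pinned
            # SOURCE_DATE_EPOCH suppresses the wall-clock CreationDate
            had = os.environ.get("SOURCE_DATE_EPOCH")
            os.environ["SOURCE_DATE_EPOCH"] = "0"
            try:
                with open(path, "wb") as fh:
                    fig.savefig(fh, format="ps")
            finally:
                if had is None:
                    os.environ.pop("SOURCE_DATE_EPOCH", None)
                else:
                    os.environ["SOURCE_DATE_EPOCH"] = had
    plt.close(fig)
    return path


def render_grm_diagram(
    spectrum: PeriodSpectrum, cfg: RenderConfig, path: Union[str, Path]
) -> Path:
    """Stem plot of frequency vs period, truncated for display at
    ``cfg.max_displayed_period`` (the spectrum itself is never cut)."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(8, 3.2))
    shown = {
        j: f for j, f in spectrum.bins.items() if j <= cfg.max_displayed_period
    }
    if shown:
        periods = sorted(shown)
        ax.stem([j for j in periods], [shown[j] for j in periods], basefmt=" ")
    ax.set_xlim(0, cfg.max_displayed_period + 1)
    ax.set_xlabel("period (monomer units)")
    ax.set_ylabel("frequency")
    ax.set_title("GRM diagram")
    fig.tight_layout()
    return _save(fig, path, cfg)


def render_md_diagram(
    v: NextSimilarVector, cfg: RenderConfig, path: Union[str, Path]
) -> Path:
    """Scatter of monomer ordinal vs next-similar distance; entries
    with no downstream similar monomer sit at y = 0."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(8, 3.2))
    xs = [m1 + cfg.start_monomer for m1, _ in v.entries]
    shown = [
        (x, m2)
        for x, (_, m2) in zip(xs, v.entries)
        if m2 <= cfg.max_displayed_period
    ]
    if shown:
        ax.scatter([x for x, _ in shown], [y for _, y in shown], s=6)
    ax.set_ylim(bottom=-1)
    ax.set_xlabel("monomer index")
    ax.set_ylabel("period (monomer units)")
    ax.set_title("MD diagram")
    fig.tight_layout()
    return _save(fig, path, cfg)


def _type_colors(labels):
    cmap = plt.get_cmap("tab20")
    colors = {}
    for i, lab in enumerate(labels):
        colors[lab] = (cmap(i % 20), _HATCHES[(i // 20) % len(_HATCHES)])
    return colors


def render_aligned_scheme(
    scheme: AlignedScheme,
    types: TypeAssignment,
    cfg: RenderConfig,
    path: Union[str, Path],
    array: Optional[MonomerArray] = None,
) -> Path:
    """One coloured box per monomer at (column, row); same type means
    same colour and column.  When more types than distinguishable
    colours exist, the palette cycles with a hatch-pattern fallback.
    With ``cfg.show_genomic_positions`` and loci available, each row is
    annotated with the genomic start of its first monomer."""
    path = Path(path)
    n_rows = scheme.n_rows
    n_cols = scheme.n_columns
    order = sorted(scheme.column_of_type, key=scheme.column_of_type.get)
    colors = _type_colors(order)
    if len(order) > 20:
        import warnings

        warnings.warn(
            f"{len(order)} monomer types exceed the 20-colour palette; "
            "cycling colours with hatch patterns"
        )
    fig_h = max(2.0, 0.18 * n_rows + 1.0)
    fig_w = max(3.0, 0.3 * n_cols + 1.2)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    row_first_monomer = {}
    for idx, (row, col) in enumerate(scheme.placements, start=1):
        lab = types.label_of(idx)
        color, hatch = colors[lab]
        ax.add_patch(
            Rectangle(
                (col - 0.45, -row - 0.45),
                0.9,
                0.9,
                facecolor=color,
                hatch=hatch,
                edgecolor="black",
                linewidth=0.3,
            )
        )
        row_first_monomer.setdefault(row, idx)
    if cfg.show_genomic_positions and array is not None:
        for row, idx in row_first_monomer.items():
            locus = array.record(idx).locus
            if locus is not None:
                ax.text(
                    0.35,
                    -row,
                    f"{locus.contig}:{locus.start}",
                    ha="right",
                    va="center",
                    fontsize=6,
                )
    ax.set_xlim(-2 if cfg.show_genomic_positions else 0, n_cols + 1)
    ax.set_ylim(-n_rows - 1, 0)
    ax.set_xticks(range(1, n_cols + 1))
    ax.set_xticklabels(order, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_title("aligned HOR scheme")
    fig.tight_layout()
    return _save(fig, path, cfg)
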