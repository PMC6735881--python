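"""Static heatmap rendering of a variant-effect map.

The map is drawn as 21 substitution rows (20 amino acids in a fixed
physicochemically grouped order, stop last) by L position columns. The
color scale is anchored at 0 (null-like, dark) and 1 (wild-type-like,
white) and monotone in score; imputed cells carry a dot overlay and
undefined cells are grey. Rendering is deterministic: the same map and
spec produce a byte-identical SVG.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap, Normalize
from matplotlib.patches import Circle, Rectangle

from .aminoacids import AA_ALPHABET, STOP
from .refine import VEMap

#: Row order: hydrophobic, special, polar, charged, then stop.
ROW_ORDER = "AVLIMFWYGPCSTNQHKRDE" + STOP

LAYERS = ("refined", "measured", "predictors")


@dataclasses.dataclass
class MapFigureSpec:
    """Appearance and layer selection for :func:`render_map`."""

    layer: str = "refined"
    color_null: str = "#08306b"
    color_wt: str = "#ffffff"
    na_color: str = "#d4d4d4"
    dot_color: str = "#e34a33"
    vmin: float = 0.0
    vmax: float = 1.0
    predictor_column: str = "polyphen2"
    cell_size: float = 0.18

    def colormap(self) -> LinearSegmentedColormap:
        return LinearSegmentedColormap.from_list(
            "function_score", [self.color_null, self.color_wt]
        )


def _cell_visible(provenance: str, layer: str) -> bool:
    if layer == "measured":
        # only cells backed by an actual measurement
        return provenance in ("measured", "refined")
    return provenance != "undefined"


def render_map(
    vemap: VEMap,
    path,
    spec: Optional[MapFigureSpec] = None,
    predictors: Optional[pd.DataFrame] = None,
) -> str:
    """Render ``vemap`` to an SVG (or PNG, by file extension) heatmap.

    Every map cell becomes one rectangle element tagged with
    ``id="cell-<position>-<alt>"``; imputed cells additionally carry a
    dot overlay. ``layer='measured'`` blanks imputed cells;
    ``layer='predictors'`` colors missense cells by an external
    predictor column (min-max scaled) instead of the map scores.
    """
    spec = spec or MapFigureSpec()
    if spec.layer not in LAYERS:
        raise ValueError(f"layer must be one of {LAYERS}, got {spec.layer!r}")
    frame = vemap.to_frame()
    if frame.empty:
        raise ValueError("cannot render an empty map")
    L = vemap.length

    cmap = spec.colormap()
    norm = Normalize(vmin=spec.vmin, vmax=spec.vmax, clip=True)

    pred_values: dict[str, float] = {}
    if spec.layer == "predictors":
        if predictors is None or spec.predictor_column not in predictors.columns:
            raise ValueError(
                f"layer='predictors' needs a predictor table with a "
                f"{spec.predictor_column!r} column"
            )
        vals = predictors[spec.predictor_column].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            raise ValueError(f"no finite {spec.predictor_column!r} values to render")
        lo, hi = float(finite.min()), float(finite.max())
        span = (hi - lo) or 1.0
        pred_values = {
            v: (x - lo) / span
            for v, x in zip(predictors["variant"], vals)
            if np.isfinite(x)
        }

    s = spec.cell_size
    fig_w = max(3.0, s * L + 1.6)
    fig_h = s * 21 + 1.4
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))

    row_index = {alt: i for i, alt in enumerate(ROW_ORDER)}
    for row in frame.itertuples():
        # synonymous cells live on the wild-type residue's row
        row_alt = row.wt if row.alt == "=" else row.alt
        y = 20 - row_index[row_alt]
        x = row.position - 1
        if spec.layer == "predictors":
            tok = f"{row.wt}{row.position}{row.alt}"
            val = pred_values.get(tok)
            color = cmap(norm(1.0 - val)) if val is not None else spec.na_color
        elif _cell_visible(row.provenance, spec.layer) and np.isfinite(row.score):
            color = cmap(norm(row.score))
        else:
            color = spec.na_color
        rect = Rectangle((x, y), 1, 1, facecolor=color, edgecolor="#ffffff",
                         linewidth=0.3)
        rect.set_gid(f"cell-{row.position}-{row.alt}")
        ax.add_patch(rect)
        if spec.layer == "refined" and row.provenance == "imputed":
            dot = Circle((x + 0.5, y + 0.5), 0.12, facecolor=spec.dot_color,
                         edgecolor="none")
            dot.set_gid(f"dot-{row.position}-{row.alt}")
            ax.add_patch(dot)

    ax.set_xlim(0, L)
    ax.set_ylim(0, 21)
    ax.set_yticks([20 - row_index[a] + 0.5 for a in ROW_ORDER])
    ax.set_yticklabels(list(ROW_ORDER), fontsize=6, family="monospace")
    step = max(1, L // 20)
    ax.set_xticks([p - 0.5 for p in range(1, L + 1, step)])
    ax.set_xticklabels([str(p) for p in range(1, L + 1, step)], fontsize=6)
    ax.set_xlabel("position")
    ax.set_ylabel("substitution")
    ax.set_title(f"variant-effect map ({spec.layer} layer)", fontsize=9)

    sm = plt.cm.ScalarMappable(cmap=cmap, norm=norm)
    cbar = fig.colorbar(sm, ax=ax, fraction=0.025, pad=0.02, ticks=[0.0, 1.0])
    cbar.ax.set_yticklabels(["0 (null-like)", "1 (wild-type-like)"], fontsize=6)

    with matplotlib.rc_context({"svg.hashsalt": "maveimpute"}):
        fig.savefig(str(path), metadata={"Date": None} if str(path).endswith(".svg") else None,
                    bbox_inches="tight")
    plt.close(fig)
    return str(path)
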