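"""Squarified treemap layout of a scaffold's children.

One rendered frame shows the children of a single scaffold as a rectangle
tiling: cell area encodes frequency in the background library (or in the
user dataset), cell color encodes frequency in the user dataset, in the
background, or the dataset/background enrichment ratio.  The squarified
layout greedily builds rows so that cells stay as close to squares as the
weights allow.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

from matplotlib import colors as mcolors
from matplotlib import colormaps

from .chem_io import ScaffoldKey
from .hierarchy import Hierarchy, ScaffoldNode

log = logging.getLogger(__name__)

SizeMode = Literal["background", "dataset"]
ColorMode = Literal["dataset", "background", "relative"]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, origin top-left, y growing downwards."""

    x: float
    y: float
    w: float
    h: float

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def aspect(self) -> float:
        return max(self.w / self.h, self.h / self.w)


@dataclass
class TreemapLayout:
    parent: Rect
    cells: list[tuple[ScaffoldKey, Rect, float, float]]  # key, rect, size, color


# ---------------------------------------------------------------------------
# layout algorithms
# ---------------------------------------------------------------------------


def _row_worst(row: Sequence[float], side: float) -> float:
    """Worst aspect ratio if ``row`` areas are laid along a side of length
    ``side`` (the row then has thickness sum(row)/side)."""
    s = sum(row)
    mx, mn = max(row), min(row)
    return max(side * side * mx / (s * s), s * s / (side * side * mn))


def _layout_row(row: Sequence[float], free: Rect) -> tuple[list[Rect], Rect]:
    """Place a finalized row along the shorter side of the free rectangle;
    returns the cell rects (in row order) and the remaining free space."""
    s = sum(row)
    rects = []
    if free.w >= free.h:  # row is a vertical strip on the left
        thickness = s / free.h
        y = free.y
        for a in row:
            cell_h = a / thickness
            rects.append(Rect(free.x, y, thickness, cell_h))
            y += cell_h
        remaining = Rect(free.x + thickness, free.y, free.w - thickness, free.h)
    else:  # horizontal strip on top
        thickness = s / free.w
        x = free.x
        for a in row:
            cell_w = a / thickness
            rects.append(Rect(x, free.y, cell_w, thickness))
            x += cell_w
        remaining = Rect(free.x, free.y + thickness, free.w, free.h - thickness)
    return rects, remaining


def squarify(weights: Sequence[float], parent: Rect) -> list[Rect]:
    """Squarified treemap layout.

    Weights are scaled so cell areas are exactly proportional and tile the
    parent rectangle.  Internally the weights are processed in
    non-increasing order (the greedy row construction requires it); the
    returned rectangles are in the order of the *input* weights.  Rows are
    laid along the shorter side of the remaining free rectangle, and a
    weight is added to the current row only while it does not worsen the
    row's worst aspect ratio.
    """
    if any(w <= 0 for w in weights):
        raise ValueError("squarify requires strictly positive weights")
    n = len(weights)
    if n == 0:
        return []
    scale = parent.area / sum(weights)
    order = sorted(range(n), key=lambda i: -weights[i])
    areas = [weights[i] * scale for i in order]

    out: list[Rect | None] = [None] * n
    free = parent
    row: list[float] = []
    row_idx: list[int] = []
    pos = 0
    while pos < len(areas):
        a = areas[pos]
        side = min(free.w, free.h)
        # a weight joins the current row only if it strictly improves the
        # row's worst aspect ratio; on a tie the row is finalized
        if not row or _row_worst(row + [a], side) < _row_worst(row, side):
            row.append(a)
            row_idx.append(order[pos])
            pos += 1
        else:
            rects, free = _layout_row(row, free)
            for i, r in zip(row_idx, rects):
                out[i] = r
            row, row_idx = [], []
    if row:
        rects, _ = _layout_row(row, free)
        for i, r in zip(row_idx, rects):
            out[i] = r
    return out  # type: ignore[return-value]


def slice_and_dice(weights: Sequence[float], parent: Rect) -> list[Rect]:
    """Single-direction layout (all cells in one strip along the longer
    side); the quality baseline the squarified layout is measured against."""
    if any(w <= 0 for w in weights):
        raise ValueError("positive weights required")
    total = sum(weights)
    rects = []
    offset = 0.0
    for w in weights:
        frac = w / total
        if parent.w >= parent.h:
            rects.append(Rect(parent.x + offset * parent.w, parent.y,
                              frac * parent.w, parent.h))
        else:
            rects.append(Rect(parent.x, parent.y + offset * parent.h,
                              parent.w, frac * parent.h))
        offset += frac
    return rects


def worst_aspect(rects: Sequence[Rect]) -> float:
    return max(r.aspect for r in rects) if rects else 1.0


# ---------------------------------------------------------------------------
# size and color encodings
# ---------------------------------------------------------------------------


def compute_sizes(children: Sequence[ScaffoldNode], mode: SizeMode = "background",
                  log_scale: bool = False) -> list[float]:
    """Cell weights for a set of sibling scaffolds.

    Weight is the node frequency in the selected source, optionally
    log-damped as ``log(1 + f)`` so a single dominant scaffold does not
    crush the rest of the frame.  Zero-frequency children get weight 0 and
    receive no cell.
    """
    freqs = [c.background_freq if mode == "background" else c.dataset_freq
             for c in children]
    if all(f == 0 for f in freqs) and children:
        log.warning("all %s frequencies are zero; layout will be empty", mode)
    return [math.log1p(f) if log_scale else float(f) for f in freqs]


def compute_colors(children: Sequence[ScaffoldNode],
                   mode: ColorMode = "dataset",
                   total_dataset: int | None = None,
                   total_background: int | None = None,
                   log_scale: bool = False) -> list[float]:
    """Color values in [0, 1], min-max normalized across the siblings.

    Modes: ``dataset`` / ``background`` use the raw frequencies;
    ``relative`` uses the enrichment ratio
    ``(dataset_freq/total_dataset) / (background_freq/total_background)``.
    A scaffold present in the dataset but absent from the background is
    maximally enriched and maps to the top of the gradient.  When all
    values coincide the midpoint is returned for every child.
    """
    values: list[float] = []
    for c in children:
        if mode == "dataset":
            v = float(c.dataset_freq)
        elif mode == "background":
            v = float(c.background_freq)
        else:
            td = total_dataset or sum(x.dataset_freq for x in children) or 1
            tb = total_background or sum(x.background_freq for x in children) or 1
            if c.background_freq == 0:
                v = math.inf if c.dataset_freq > 0 else 0.0
            else:
                v = (c.dataset_freq / td) / (c.background_freq / tb)
        values.append(v)
    if log_scale:
        values = [math.log1p(v) if math.isfinite(v) else v for v in values]
    finite = [v for v in values if math.isfinite(v)]
    if not finite:
        return [1.0 for _ in values]
    lo, hi = min(finite), max(finite)
    if hi == lo:
        return [0.5 if math.isfinite(v) else 1.0 for v in values]
    return [(min(v, hi) - lo) / (hi - lo) if math.isfinite(v) else 1.0
            for v in values]


_WHITE_RED = mcolors.LinearSegmentedColormap.from_list(
    "white_red", ["#ffffff", "#d62728"])


def get_gradient(name: str = "white_red"):
    """Color gradient by name: the default white-to-red map or any
    matplotlib colormap."""
    if name == "white_red":
        return _WHITE_RED
    return colormaps[name]


# ---------------------------------------------------------------------------
# layout assembly and export
# ---------------------------------------------------------------------------


def layout_children(h: Hierarchy, key: ScaffoldKey, parent: Rect,
                    size_mode: SizeMode = "background",
                    color_mode: ColorMode = "dataset",
                    log_size: bool = False, log_color: bool = False
                    ) -> TreemapLayout:
    """Treemap layout for the children of one hierarchy node."""
    children = h.children(key)
    sizes = compute_sizes(children, size_mode, log_size)
    colors = compute_colors(children, color_mode,
                            total_dataset=h.dataset_count or None,
                            total_background=h.molecule_count or None,
                            log_scale=log_color)
    visible = [(c, s, col) for c, s, col in zip(children, sizes, colors)
               if s > 0]
    rects = squarify([s for _, s, _ in visible], parent)
    cells = [(c.key, r, s, col)
             for (c, s, col), r in zip(visible, rects)]
    return TreemapLayout(parent=parent, cells=cells)


def export_json(layout: TreemapLayout) -> str:
    """Serialize a layout (keys, rects, size and color values) to JSON so
    any front end can redraw or zoom it."""
    doc = {
        "parent": vars(layout.parent),
        "cells": [{"level": k.level, "key": k.key, "rect": vars(r),
                   "size": s, "color": c}
                  for k, r, s, c in layout.cells],
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def layout_from_json(text: str) -> TreemapLayout:
    doc = json.loads(text)
    return TreemapLayout(
        parent=Rect(**doc["parent"]),
        cells=[(ScaffoldKey(c["level"], c["key"]), Rect(**c["rect"]),
                c["size"], c["color"]) for c in doc["cells"]],
    )


def _depiction_svg(key: ScaffoldKey, rect: Rect) -> str:
    """Inline 2D depiction of a scaffold inside its cell (chemical levels
    only); falls back to a text label for abstract or unrenderable keys."""
    label = key.key if len(key.key) <= 20 else key.key[:17] + "..."
    text = (f'<text x="{rect.x + rect.w / 2:.3f}" y="{rect.y + rect.h / 2:.3f}" '
            f'text-anchor="middle" dominant-baseline="middle" '
            f'font-size="{max(min(rect.h * 0.25, rect.w / max(len(label), 1) * 1.6), 1.0):.2f}">'
            f'{_xml_escape(label)}</text>')
    return text


def _xml_escape(s: str) -> str:
    return (s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
            .replace('"', "&quot;"))


def render_svg(h: Hierarchy, key: ScaffoldKey, *, width: float = 1000,
               height: float = 600, depth: int = 1,
               size_mode: SizeMode = "background",
               color_mode: ColorMode = "dataset",
               log_size: bool = False, log_color: bool = False,
               gradient: str = "white_red") -> str:
    """Static SVG of the treemap rooted at ``key``.

    ``depth`` > 1 nests each cell's own children inside it, emulating the
    zoomable-map frames of an interactive client in one static picture.
    Output is deterministic for fixed input.
    """
    cmap = get_gradient(gradient)
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" '
             f'width="{width}" height="{height}" '
             f'viewBox="0 0 {width} {height}">']

    def emit(node_key: ScaffoldKey, rect: Rect, level_depth: int) -> None:
        layout = layout_children(h, node_key, rect, size_mode, color_mode,
                                 log_size, log_color)
        for ckey, r, _s, col in layout.cells:
            fill = mcolors.to_hex(cmap(col))
            parts.append(
                f'<rect x="{r.x:.3f}" y="{r.y:.3f}" width="{r.w:.3f}" '
                f'height="{r.h:.3f}" fill="{fill}" stroke="#333" '
                f'stroke-width="{0.5 * level_depth:.2f}">'
                f'<title>{_xml_escape(f"L{ckey.level} {ckey.key}")}</title></rect>')
            if level_depth > 1 and h.nodes[ckey].children:
                pad = min(r.w, r.h) * 0.06
                inner = Rect(r.x + pad, r.y + pad, r.w - 2 * pad, r.h - 2 * pad)
                if inner.w > 0 and inner.h > 0:
                    emit(ckey, inner, level_depth - 1)
            else:
                parts.append(_depiction_svg(ckey, r))

    emit(key, Rect(0, 0, width, height), depth)
    parts.append("</svg>")
    return "\n".join(parts)
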