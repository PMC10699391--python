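"""Deterministic SVG and plain-text rendering of a map layout.

SVG output is produced by direct string templating of a handful of element
types (lines, text, ellipses) with fixed-precision coordinates, so identical
layouts always render to identical bytes — the property the snapshot tests
rely on.  Labels are anchor-positioned, never measured, so no font metrics
enter the output.  The plain-text renderer draws the same map on a
monospaced grid, one row per 0.25-logit band, for terminals and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import GimLayout, GimError, Side, SubjectFlag

__all__ = ["StyleConfig", "render_svg", "render_text"]


@dataclass
class StyleConfig:
    """Canvas geometry, colours and axis range for SVG rendering."""

    width: float = 900.0
    height: float = 700.0
    margin: float = 50.0
    y_min: float = -4.0
    y_max: float = 4.0
    strength_color: str = "green"
    weakness_color: str = "red"
    font_family: str = "monospace"
    font_size: float = 11.0
    nudge: float = 0.1  # logits applied to overlapping labels, document order

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise GimError("canvas dimensions must be positive")


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _expand_range(style: StyleConfig, layout: GimLayout) -> tuple[float, float]:
    ys = [p.y for p in layout.placed] + [layout.ability_line]
    if layout.pass_line is not None:
        ys.append(layout.pass_line)
    lo = min(style.y_min, min(ys) - 0.25)
    hi = max(style.y_max, max(ys) + 0.25)
    return lo, hi


def render_svg(layout: GimLayout, style: Optional[StyleConfig] = None) -> str:
    """Render a layout to an SVG 1.1 document string.

    Central vertical latent-scale axis; one cluster column per configured
    cluster on each side (left = correct, right = incorrect); group labels
    carry parenthesised counts; a horizontal line marks the candidate's
    ability and, when present, a dashed line the pass standard.  Flagged
    clusters are outlined with an ellipse (green strength, red weakness)
    around their groups on the relevant side.  Byte-identical for identical
    inputs.
    """
    style = style or StyleConfig()
    layout.validate()
    if not layout.placed:
        raise GimError("cannot render an empty layout")
    y_lo, y_hi = _expand_range(style, layout)
    W, H, M = style.width, style.height, style.margin
    cx = W / 2.0

    def ypix(y: float) -> float:
        # affine logits -> pixels, higher logit = higher on the canvas
        return M + (y_hi - y) / (y_hi - y_lo) * (H - 2 * M)

    columns = layout.columns
    ncol = max(len(columns), 1)
    half = (W / 2.0 - M - 20.0) / ncol

    def xcol(cluster: str, side: Side) -> float:
        try:
            k = columns.index(cluster)
        except ValueError:
            k = ncol - 1
        if side is Side.LEFT_CORRECT:
            return cx - 20.0 - (k + 0.5) * half
        return cx + 20.0 + (k + 0.5) * half

    parts: list[str] = []
    parts.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(W)}" height="{_fmt(H)}" '
        f'font-family="{style.font_family}" font-size="{_fmt(style.font_size)}">'
    )
    parts.append(f'<title>GIM {layout.candidate_id}</title>')
    # central latent-scale axis with logit ticks
    parts.append(
        f'<line class="axis" x1="{_fmt(cx)}" y1="{_fmt(M)}" '
        f'x2="{_fmt(cx)}" y2="{_fmt(H - M)}" stroke="black" stroke-width="1.5"/>'
    )
    for t in np.arange(np.ceil(y_lo), np.floor(y_hi) + 0.5, 1.0):
        yp = ypix(float(t))
        parts.append(
            f'<line class="tick" x1="{_fmt(cx - 4)}" y1="{_fmt(yp)}" '
            f'x2="{_fmt(cx + 4)}" y2="{_fmt(yp)}" stroke="black" stroke-width="1"/>'
        )
        parts.append(
            f'<text class="ticklabel" x="{_fmt(cx + 8)}" y="{_fmt(yp + 3)}" '
            f'fill="black">{t:+.0f}</text>'
        )
    # column headers
    for side in (Side.LEFT_CORRECT, Side.RIGHT_INCORRECT):
        for c in columns:
            xp = xcol(c, side)
            parts.append(
                f'<text class="header" x="{_fmt(xp)}" y="{_fmt(M - 10)}" '
                f'text-anchor="middle" fill="black">{c}</text>'
            )
    parts.append(
        f'<text class="sidelabel" x="{_fmt(M)}" y="{_fmt(M - 28)}" fill="black">'
        f'CORRECT</text>'
    )
    parts.append(
        f'<text class="sidelabel" x="{_fmt(W - M - 70)}" y="{_fmt(M - 28)}" '
        f'fill="black">INCORRECT</text>'
    )
    # ability line (solid) and pass line (dashed)
    ya = ypix(layout.ability_line)
    parts.append(
        f'<line class="ability" x1="{_fmt(M)}" y1="{_fmt(ya)}" '
        f'x2="{_fmt(W - M)}" y2="{_fmt(ya)}" stroke="blue" stroke-width="1"/>'
    )
    parts.append(
        f'<text class="abilitylabel" x="{_fmt(M)}" y="{_fmt(ya - 4)}" fill="blue">'
        f'ability {layout.ability_line:+.2f}</text>'
    )
    if layout.pass_line is not None:
        yp = ypix(layout.pass_line)
        parts.append(
            f'<line class="pass" x1="{_fmt(M)}" y1="{_fmt(yp)}" '
            f'x2="{_fmt(W - M)}" y2="{_fmt(yp)}" stroke="black" '
            f'stroke-width="1" stroke-dasharray="6,3"/>'
        )
        parts.append(
            f'<text class="passlabel" x="{_fmt(W - M - 90)}" y="{_fmt(yp - 4)}" '
            f'fill="black">pass {layout.pass_line:+.2f}</text>'
        )
    # groups: anti-overlap nudge applied in document order per column
    last_y: dict[tuple[str, str], float] = {}
    min_gap = style.nudge
    group_pix: dict[int, tuple[float, float]] = {}
    for gi, g in enumerate(layout.groups):
        key = (g.subject_cluster, g.side.value)
        y = g.y
        if key in last_y and abs(y - last_y[key]) < min_gap:
            y = last_y[key] + min_gap
        last_y[key] = y
        xp = xcol(g.subject_cluster, g.side)
        yp = ypix(y)
        group_pix[gi] = (xp, yp)
        parts.append(
            f'<text class="group" x="{_fmt(xp)}" y="{_fmt(yp)}" '
            f'text-anchor="middle" data-count="{g.count}" '
            f'data-y="{g.y:.6f}" fill="black">{g.label}</text>'
        )
    # ellipses around flagged clusters (drawn over the relevant side)
    for cluster in columns:
        flag = layout.flags.get(cluster, SubjectFlag.NONE)
        if flag is SubjectFlag.NONE:
            continue
        side = Side.RIGHT_INCORRECT if flag is SubjectFlag.WEAKNESS else Side.LEFT_CORRECT
        pts = [group_pix[gi] for gi, g in enumerate(layout.groups)
               if g.subject_cluster == cluster and g.side is side]
        if not pts:  # strength cluster may have all items on the left only
            pts = [group_pix[gi] for gi, g in enumerate(layout.groups)
                   if g.subject_cluster == cluster]
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        cx_e, cy_e = (min(xs) + max(xs)) / 2.0, (min(ys) + max(ys)) / 2.0
        rx = (max(xs) - min(xs)) / 2.0 + half * 0.45
        ry = (max(ys) - min(ys)) / 2.0 + 14.0
        color = style.weakness_color if flag is SubjectFlag.WEAKNESS else style.strength_color
        parts.append(
            f'<ellipse class="flag-{flag.value}" cx="{_fmt(cx_e)}" cy="{_fmt(cy_e)}" '
            f'rx="{_fmt(rx)}" ry="{_fmt(ry)}" fill="none" '
            f'stroke="{color}" stroke-width="1.5"/>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render_text(layout: GimLayout, width: int = 100) -> str:
    """Render a layout as a monospaced text map.

    One row per 0.25-logit band, highest band first; group labels sit left
    or right of a central ``|`` axis column; the row containing the
    candidate's ability is marked with ``=`` fill and the pass line, when
    present, with ``-``.
    """
    if width < 40:
        raise GimError("text rendering needs width >= 40")
    layout.validate()
    band = 0.25
    ys = [g.y for g in layout.groups] + [layout.ability_line]
    if layout.pass_line is not None:
        ys.append(layout.pass_line)
    lo = np.floor(min(ys) / band) * band
    hi = np.ceil(max(ys) / band) * band
    n_rows = int(round((hi - lo) / band)) + 1
    axis_col = width // 2
    lines = []
    header = "CORRECT".ljust(axis_col - 1) + "|" + " INCORRECT"
    lines.append(header[:width])

    def row_of(y: float) -> int:
        # highest band first; band k covers [k*band, (k+1)*band)
        return int(round((hi - (np.floor(y / band) * band)) / band)) + 1

    rows_left: dict[int, list[str]] = {}
    rows_right: dict[int, list[str]] = {}
    for g in layout.groups:
        r = row_of(g.y)
        target = rows_left if g.side is Side.LEFT_CORRECT else rows_right
        target.setdefault(r, []).append(g.label)
    ability_row = row_of(layout.ability_line)
    pass_row = None if layout.pass_line is None else row_of(layout.pass_line)

    for r in range(1, n_rows + 1):
        y_band = hi - (r - 1) * band
        left = " ".join(sorted(rows_left.get(r, [])))
        right = " ".join(sorted(rows_right.get(r, [])))
        fill = " "
        tag = f"{y_band:+.2f} "
        if r == ability_row:
            fill = "="
        elif pass_row is not None and r == pass_row:
            fill = "-"
        lhs = (tag + left).ljust(axis_col - 1, fill)[: axis_col - 1]
        rhs = (" " + right).ljust(width - axis_col - 1, fill)
        lines.append(lhs + "|" + rhs[: width - axis_col - 1])
    flagged = [f"{c}:{f.value}" for c, f in sorted(layout.flags.items())
               if f is not SubjectFlag.NONE]
    lines.append(f"candidate {layout.candidate_id}  ability {layout.ability_line:+.2f}"
                 + (f"  pass {layout.pass_line:+.2f}" if layout.pass_line is not None else "")
                 + ("  flags: " + ", ".join(flagged) if flagged else ""))
    return "\n".join(lines) + "\n"
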