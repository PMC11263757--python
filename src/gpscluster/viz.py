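"""Static HTML map export of an analysis result.

Renders a self-contained HTML file with an inline SVG: cluster polygons
colored by their field ``State`` (New = red, Grown = orange, Done = green)
or filled by ``Event`` (palette auto-assigned, stable by sorted event
name), optional fix points whose radius grows with recency, optional
per-animal track polylines, cluster-ID labels, and a distinct marker on
each animal's last position.  The renderer only reads the analysis output;
it never mutates it.  Elements carry ``class`` and ``data-*`` attributes so
the file is both styleable and machine-checkable.
"""

from __future__ import annotations

import html
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .errors import ConfigError
from .model import Cluster, GpsFix

__all__ = ["STATE_PALETTE", "event_palette", "render_map"]

STATE_PALETTE = {"New": "#d62728", "Grown": "#ff7f0e", "Done": "#2ca02c"}

_EVENT_CYCLE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
]

_TRACK_CYCLE = ["#1f77b4", "#9467bd", "#8c564b", "#e377c2", "#17becf", "#bcbd22"]

_VIEW_W, _VIEW_H, _PAD = 1000.0, 800.0, 40.0


def event_palette(clusters: Sequence[Cluster]) -> Dict[str, str]:
    """Stable event -> color mapping: colors assigned by sorted event name."""
    events = sorted({c.event for c in clusters if c.event})
    return {e: _EVENT_CYCLE[i % len(_EVENT_CYCLE)] for i, e in enumerate(events)}


class _Projector:
    """Affine map from study coordinates (meters) to SVG viewport pixels."""

    def __init__(self, xs: List[float], ys: List[float]):
        if not xs:
            xs, ys = [0.0, 1.0], [0.0, 1.0]
        x0, x1 = min(xs), max(xs)
        y0, y1 = min(ys), max(ys)
        spanx = max(x1 - x0, 1.0)
        spany = max(y1 - y0, 1.0)
        self.scale = min((_VIEW_W - 2 * _PAD) / spanx, (_VIEW_H - 2 * _PAD) / spany)
        self.x0, self.y1 = x0, y1

    def __call__(self, x: float, y: float):
        # northing grows upward; SVG y grows downward
        return (
            _PAD + (x - self.x0) * self.scale,
            _PAD + (self.y1 - y) * self.scale,
        )


def _polygon_paths(polygon) -> str:
    polys = polygon.geoms if polygon.geom_type == "MultiPolygon" else [polygon]
    return polys


def render_map(
    clusters: Sequence[Cluster],
    fixes: Optional[Sequence[GpsFix]],
    path,
    show_fixes: bool = True,
    show_tracks: bool = False,
    show_labels: bool = False,
    color_by: str = "state",
) -> Path:
    """Write the map HTML; returns the written path.

    ``fixes`` may be None only when neither fixes nor tracks are requested.
    ``color_by`` is ``"state"`` or ``"event"``.
    """
    if color_by not in ("state", "event"):
        raise ConfigError(f"color_by must be 'state' or 'event', got {color_by!r}")
    if fixes is None and (show_fixes or show_tracks):
        raise ConfigError("fix table required to draw fixes or tracks")

    xs: List[float] = []
    ys: List[float] = []
    for c in clusters:
        bx = c.polygon.bounds
        xs.extend([bx[0], bx[2]])
        ys.extend([bx[1], bx[3]])
    for f in fixes or []:
        xs.append(f.x)
        ys.append(f.y)
    proj = _Projector(xs, ys)
    ev_palette = event_palette(clusters)

    parts: List[str] = []
    parts.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 {_VIEW_W:g} {_VIEW_H:g}" '
        f'width="{_VIEW_W:g}" height="{_VIEW_H:g}" style="background:#f4f2ec">'
    )

    per_animal: Dict[str, List[GpsFix]] = {}
    for f in fixes or []:
        per_animal.setdefault(f.animal_id, []).append(f)
    for track in per_animal.values():
        track.sort(key=lambda f: f.timestamp)

    if show_tracks:
        for i, (animal, track) in enumerate(sorted(per_animal.items())):
            pts = " ".join("%.2f,%.2f" % proj(f.x, f.y) for f in track)
            color = _TRACK_CYCLE[i % len(_TRACK_CYCLE)]
            parts.append(
                f'<polyline class="track" data-animal="{html.escape(animal)}" '
                f'points="{pts}" fill="none" stroke="{color}" stroke-width="1"/>'
            )

    for c in clusters:
        if color_by == "event":
            fill = ev_palette.get(c.event, "#bbbbbb")
        else:
            fill = STATE_PALETTE.get(c.state, "#bbbbbb")
        d_parts = []
        for poly in _polygon_paths(c.polygon):
            coords = " L ".join("%.2f %.2f" % proj(x, y) for x, y in poly.exterior.coords)
            d_parts.append(f"M {coords} Z")
        parts.append(
            f'<path class="cluster-polygon" data-cluster-id="{html.escape(c.cluster_id)}" '
            f'data-state="{html.escape(c.state)}" data-event="{html.escape(c.event)}" '
            f'd="{" ".join(d_parts)}" fill="{fill}" fill-opacity="0.55" '
            f'stroke="{fill}" stroke-width="1.5"/>'
        )
        if show_labels:
            lx, ly = proj(c.mean_x, c.mean_y)
            parts.append(
                f'<text class="cluster-label" x="{lx:.2f}" y="{ly - 8:.2f}" '
                f'font-size="11" text-anchor="middle">{html.escape(c.cluster_id)}</text>'
            )

    if show_fixes:
        for i, (animal, track) in enumerate(sorted(per_animal.items())):
            color = _TRACK_CYCLE[i % len(_TRACK_CYCLE)]
            n = len(track)
            for rank, f in enumerate(track):
                # radius strictly increasing with recency within each animal
                r = 1.2 + 2.8 * (rank / (n - 1) if n > 1 else 1.0)
                fx, fy = proj(f.x, f.y)
                parts.append(
                    f'<circle class="fix" data-animal="{html.escape(animal)}" '
                    f'cx="{fx:.2f}" cy="{fy:.2f}" r="{r:.3f}" fill="{color}" '
                    f'fill-opacity="0.8"/>'
                )

    for animal, track in sorted(per_animal.items()):
        last = track[-1]
        lx, ly = proj(last.x, last.y)
        parts.append(
            f'<g class="last-position" data-animal="{html.escape(animal)}">'
            f'<circle cx="{lx:.2f}" cy="{ly:.2f}" r="6" fill="#1f4fd6" stroke="white" '
            f'stroke-width="1.5"/>'
            f'<text x="{lx:.2f}" y="{ly - 10:.2f}" font-size="10" text-anchor="middle" '
            f'fill="#1f4fd6">{html.escape(animal)}</text></g>'
        )

    parts.append("</svg>")
    svg = "\n".join(parts)
    legend = "".join(
        f'<span style="color:{col}">&#9632; {name}</span>&nbsp; '
        for name, col in (
            ev_palette.items() if color_by == "event" else STATE_PALETTE.items()
        )
    )
    doc = (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>GPS cluster map</title></head>\n"
        f"<body><h3>GPS activity clusters</h3><p>{legend}</p>\n{svg}\n</body></html>\n"
    )
    path = Path(path)
    path.write_text(doc)
    return path
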