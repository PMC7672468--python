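"""Additive rasterization of very large low-alpha scatter plots.

Plotting 10⁸–10⁹ embedded events through a general plotting library is
hopeless; instead each point deposits an alpha-scaled, premultiplied color
into its pixel bin and the canvas is tone-mapped once at the end. Because
the accumulation is a plain sum, partial canvases rasterized on different
workers merge exactly: merge(raster(A), raster(B)) == raster(A ∪ B),
bit for bit. To make that equality exact regardless of summation order,
contributions are accumulated as integers (values scaled by 2²⁰ and
rounded once per point).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["RasterCanvas", "rasterize", "merge", "develop", "marker_mix_colors"]

#: fixed-point scale for the integer accumulation buffer
_SCALE = 1 << 20

Bounds = tuple[float, float, float, float]  # xmin, xmax, ymin, ymax


@dataclass
class RasterCanvas:
    """Accumulation buffer: width × height × 4 premultiplied RGBA sums.

    ``accum_int`` holds exact integer sums (value × 2²⁰); ``accum`` exposes
    them in real units. ``n_clipped`` counts points outside the bounds.
    """

    width: int
    height: int
    bounds: Bounds
    accum_int: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_clipped: int = 0

    def __post_init__(self) -> None:
        xmin, xmax, ymin, ymax = self.bounds
        if self.width < 1 or self.height < 1:
            raise ValueError("canvas must be at least 1×1 pixels")
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"zero-area bounds {self.bounds}")
        if self.accum_int is None:
            self.accum_int = np.zeros((self.width, self.height, 4), dtype=np.int64)

    @property
    def accum(self) -> np.ndarray:
        return self.accum_int / _SCALE

    def compatible(self, other: "RasterCanvas") -> bool:
        return (self.width, self.height, self.bounds) == (
            other.width, other.height, other.bounds)


def rasterize(points: np.ndarray, colors: np.ndarray | Sequence[float],
              alpha: float, width: int, height: int, bounds: Bounds,
              ) -> RasterCanvas:
    """Deposit n points into pixel bins additively.

    Binning is half-open per pixel; points exactly on the xmax/ymax edge are
    clipped out (and counted) rather than clamped in. ``colors`` is either a
    single RGB triple or an n × 3 array in [0, 1].
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    canvas = RasterCanvas(width=width, height=height, bounds=bounds)
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.shape[0] == 0:
        return canvas
    col = np.asarray(colors, dtype=np.float64)
    if col.ndim == 1:
        col = np.broadcast_to(col, (pts.shape[0], 3))
    if col.shape != (pts.shape[0], 3):
        raise ValueError("colors must be RGB, one triple or one per point")

    xmin, xmax, ymin, ymax = bounds
    inb = ((pts[:, 0] >= xmin) & (pts[:, 0] < xmax)
           & (pts[:, 1] >= ymin) & (pts[:, 1] < ymax))
    canvas.n_clipped = int((~inb).sum())
    pts = pts[inb]
    col = col[inb]
    if pts.shape[0] == 0:
        return canvas

    ix = np.floor((pts[:, 0] - xmin) / (xmax - xmin) * width).astype(np.int64)
    iy = np.floor((pts[:, 1] - ymin) / (ymax - ymin) * height).astype(np.int64)
    np.clip(ix, 0, width - 1, out=ix)   # guards float-edge rounding only
    np.clip(iy, 0, height - 1, out=iy)

    flat = ix * height + iy
    # one rounding per point, then exact integer sums
    contrib = np.empty((pts.shape[0], 4), dtype=np.int64)
    contrib[:, :3] = np.rint(alpha * col * _SCALE).astype(np.int64)
    contrib[:, 3] = int(round(alpha * _SCALE))
    acc = canvas.accum_int.reshape(-1, 4)
    for ch in range(4):
        acc[:, ch] += np.bincount(flat, weights=contrib[:, ch].astype(np.float64),
                                  minlength=width * height).astype(np.int64)
    return canvas


def merge(canvases: Sequence[RasterCanvas]) -> RasterCanvas:
    """Elementwise sum of compatible canvases (exact, associative)."""
    if not canvases:
        raise ValueError("cannot merge zero canvases")
    first = canvases[0]
    out = RasterCanvas(width=first.width, height=first.height, bounds=first.bounds)
    for c in canvases:
        if not first.compatible(c):
            raise ValueError("canvases differ in dimensions or bounds")
        out.accum_int = out.accum_int + c.accum_int
        out.n_clipped += c.n_clipped
    return out


def develop(canvas: RasterCanvas, path: str | Path | None = None,
            gamma: float = 1.0) -> np.ndarray:
    """Tone-map the accumulation buffer to an 8-bit RGBA image.

    Coverage is scaled linearly by the maximum accumulated coverage (then
    optionally gamma-adjusted), and colors are un-premultiplied. The map is
    monotone: more coverage never yields lower alpha. A fully empty canvas
    develops to a transparent image. Row 0 of the returned array is the top
    of the image (ymax edge). Pure function of the canvas.
    """
    acc = canvas.accum  # width × height × 4
    cov = acc[..., 3]
    peak = cov.max()
    a = np.zeros_like(cov) if peak == 0 else np.clip(cov / peak, 0.0, 1.0)
    if gamma != 1.0:
        a = a ** (1.0 / gamma)
    rgb = np.zeros_like(acc[..., :3])
    nz = cov > 0
    rgb[nz] = np.clip(acc[..., :3][nz] / cov[nz, None], 0.0, 1.0)
    img = np.concatenate([rgb, a[..., None]], axis=-1)
    # (x, y) accumulation → image rows top-down
    img8 = np.rint(img.transpose(1, 0, 2)[::-1] * 255).astype(np.uint8)
    if path is not None:
        from PIL import Image

        Image.fromarray(img8, mode="RGBA").save(Path(path), format="PNG")
    return img8


def marker_mix_colors(expressions: np.ndarray, p_low: float = 1.0,
                      p_high: float = 99.0) -> np.ndarray:
    """Mix up to 3 marker channels into per-event RGB colors.

    Each channel is robustly rescaled to [0, 1] by percentile clipping
    (default 1st–99th) and assigned to red, green and blue in order — e.g.
    a CD8/CD4/CD161 panel view with CD8 in red, CD4 in green, CD161 in
    blue. Fewer than 3 channels leave the remaining colors at 0.
    """
    expr = np.atleast_2d(np.asarray(expressions, dtype=np.float64))
    if expr.ndim != 2 or not (1 <= expr.shape[1] <= 3):
        raise ValueError("expressions must be n × (1..3) channels")
    out = np.zeros((expr.shape[0], 3))
    for ch in range(expr.shape[1]):
        lo, hi = np.percentile(expr[:, ch], [p_low, p_high])
        if hi > lo:
            out[:, ch] = np.clip((expr[:, ch] - lo) / (hi - lo), 0.0, 1.0)
        # constant channel → constant 0 intensity
    return out
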