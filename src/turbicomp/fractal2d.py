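"""Box-counting complexity (fractal dimension) of binary slice images.

The 2D complexity of a turbinal cross-section is the box-counting
dimension Db of its outline: cover the foreground with grids of shrinking
box size s and regress log(count) on log(1/s); the slope is Db.  A smooth
curve scores ~1, a space-filling region ~2, a scrolled turbinal outline in
between.

The full slice protocol is :func:`slice_complexity`: record the foreground
area of the raw slice (a size proxy carried alongside Db), skeletonise the
shape to a single-pixel-wide contour, scale and centre it onto a square
black frame (300 px by default), then box-count.  The counting and fitting
primitive :func:`fractal_dimension` is also exposed directly, without
skeletonisation, so calibration shapes (lines, filled regions, classical
fractals) are measured as supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from skimage.morphology import skeletonize as _skel
from skimage.transform import resize as _resize

__all__ = [
    "BoxCountResult",
    "DEFAULT_SIZES",
    "ensure_binary",
    "load_binary_image",
    "load_stack",
    "skeletonize",
    "normalize_to_frame",
    "box_count",
    "fractal_dimension",
    "slice_complexity",
    "middle_slice",
]

#: Dyadic box-size series used by default (pixels, large to small fit order).
DEFAULT_SIZES: tuple[int, ...] = (2, 4, 8, 16, 32, 64, 128)


@dataclass
class BoxCountResult:
    """Box-counting outcome for one binary image."""

    box_sizes: np.ndarray  # px, one per counted size
    counts: np.ndarray  # occupied boxes per size (min over grid offsets)
    db: float  # fitted complexity value (slope in log-log space)
    fit_r2: float
    slice_area: float  # foreground pixel count of the *input* image (size proxy)


def ensure_binary(img: np.ndarray) -> np.ndarray:
    """Coerce to a boolean grid; values other than {0, 1} are rejected."""
    a = np.asarray(img)
    if a.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {a.shape}")
    if a.dtype == bool:
        return a
    u = np.unique(a)
    if not np.isin(u, (0, 1)).all():
        raise ValueError(f"image is not binary; pixel values {u[:10]}")
    return a.astype(bool)


def load_binary_image(path: str | Path, threshold: float = 0.5) -> np.ndarray:
    """Read a PNG/TIFF image and binarise at `threshold` of its max value."""
    a = iio.imread(str(path))
    if a.ndim == 3:  # RGB(A) -> luminance
        a = a[..., :3].mean(axis=-1)
    mx = a.max()
    return (a > threshold * mx) if mx > 0 else np.zeros(a.shape, bool)


def load_stack(path: str | Path) -> list[np.ndarray]:
    """Read an ordered slice stack: a multipage TIFF or a directory of images."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        return [load_binary_image(p) for p in files]
    a = iio.imread(str(path))
    if a.ndim == 2:
        return [ensure_binary((a > 0.5 * a.max()) if a.max() > 0 else a.astype(bool))]
    return [ensure_binary(s > 0.5 * s.max()) if s.max() > 0 else np.zeros(s.shape, bool)
            for s in a]


def skeletonize(img: np.ndarray) -> np.ndarray:
    """Thin the foreground to a single-pixel-wide, topology-preserving contour.

    Zhang–Suen iterative thinning; idempotent, and an empty image passes
    through unchanged.
    """
    b = ensure_binary(img)
    if not b.any():
        return b.copy()
    return _skel(b)


def normalize_to_frame(img: np.ndarray, frame: int = 300, margin: int = 5) -> np.ndarray:
    """Scale and centre the foreground onto a frame x frame black square.

    The foreground bounding box is resized (aspect preserved,
    nearest-neighbour so the image stays strictly binary) to fit inside the
    frame minus `margin` pixels on each side, then centred.
    """
    b = ensure_binary(img)
    ys, xs = np.nonzero(b)
    if ys.size == 0:
        raise ValueError("cannot normalise an image with empty foreground")
    crop = b[ys.min(): ys.max() + 1, xs.min(): xs.max() + 1]
    avail = frame - 2 * margin
    if avail <= 0:
        raise ValueError("frame too small for the requested margin")
    scale = min(avail / crop.shape[0], avail / crop.shape[1])
    h = max(1, int(round(crop.shape[0] * scale)))
    w = max(1, int(round(crop.shape[1] * scale)))
    resized = _resize(crop.astype(float), (h, w), order=0, anti_aliasing=False) > 0.5
    out = np.zeros((frame, frame), bool)
    y0 = (frame - h) // 2
    x0 = (frame - w) // 2
    out[y0: y0 + h, x0: x0 + w] = resized
    return out


def _offsets_for(size: int, n_offsets: int) -> list[tuple[int, int]]:
    # Origin plus evenly shifted grid placements; 4 gives the origin and
    # half-box shifts along x, y and the diagonal.
    base = [(0, 0), (size // 2, 0), (0, size // 2), (size // 2, size // 2)]
    if n_offsets <= 4:
        return base[:n_offsets]
    out = list(base)
    k = 1
    while len(out) < n_offsets:
        d = (k * size) // (n_offsets)
        if (d, d) not in out:
            out.append((d, d))
        k += 1
    return out[:n_offsets]


def box_count(
    img: np.ndarray,
    sizes: Sequence[int],
    offsets: int | Sequence[tuple[int, int]] = 1,
) -> np.ndarray:
    """Occupied-box counts per box size, minimised over grid offsets.

    For each size the image plane is tiled with size x size boxes anchored
    at each offset; the count is the number of boxes containing at least
    one foreground pixel, and the minimum over offsets is reported (the
    tightest cover among the tried placements).
    """
    b = ensure_binary(img)
    h, w = b.shape
    ys, xs = np.nonzero(b)
    if ys.size == 0:
        raise ValueError("box_count needs at least one foreground pixel")
    counts = []
    for s in sizes:
        s = int(s)
        if s < 1 or s > max(h, w):
            raise ValueError(f"box size {s} outside [1, {max(h, w)}]")
        offs = _offsets_for(s, offsets) if isinstance(offsets, int) else list(offsets)
        best = None
        for oy, ox in offs:
            keys = ((ys + oy) // s).astype(np.int64) * ((w + s) // s + 2) + (xs + ox) // s
            c = np.unique(keys).size
            best = c if best is None else min(best, c)
        counts.append(best)
    return np.asarray(counts, dtype=np.int64)


def fractal_dimension(
    img: np.ndarray,
    sizes: Sequence[int] = DEFAULT_SIZES,
    offsets: int | Sequence[tuple[int, int]] = 4,
) -> BoxCountResult:
    """Box-counting dimension of the image as supplied (no preprocessing).

    Db is the least-squares slope of log(count) against log(1/size); at
    least four sizes are required for a meaningful fit.
    """
    sizes = np.asarray(sorted(set(int(s) for s in sizes)), dtype=int)
    if sizes.size < 4:
        raise ValueError("need at least 4 box sizes to fit a dimension")
    b = ensure_binary(img)
    counts = box_count(b, sizes, offsets)
    x = np.log(1.0 / sizes)
    y = np.log(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return BoxCountResult(
        box_sizes=sizes[::-1].copy(),
        counts=counts[::-1].copy(),
        db=float(slope),
        fit_r2=r2,
        slice_area=float(b.sum()),
    )


def slice_complexity(
    img: np.ndarray,
    frame: int = 300,
    sizes: Sequence[int] = DEFAULT_SIZES,
    offsets: int = 4,
) -> BoxCountResult:
    """Full slice protocol: area proxy, skeletonise, normalise, box-count.

    ``slice_area`` is the foreground pixel count of the raw slice, before
    skeletonisation, and is reported alongside Db as a size proxy (for use
    as a covariate downstream, never divided into Db).
    """
    b = ensure_binary(img)
    area = float(b.sum())
    sk = skeletonize(b)
    framed = normalize_to_frame(sk, frame=frame)
    res = fractal_dimension(framed, sizes=sizes, offsets=offsets)
    res.slice_area = area
    return res


def middle_slice(stack: Sequence[np.ndarray]) -> np.ndarray:
    """The slice at index floor(n/2) of an ordered stack (0-based)."""
    if len(stack) == 0:
        raise ValueError("empty slice stack")
    return stack[len(stack) // 2]
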