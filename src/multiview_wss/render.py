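"""Geometry → multi-view image domain transformation.

A field-colored (or shaded) surface is rendered from a ring of camera
angles around one axis into fixed-size rasters with exact foreground masks.
Scalar fields travel through images via an invertible colormap codec, so
stress values can be recovered from predicted pixels.

Rendering is a small orthographic z-buffer rasterizer with barycentric
interpolation: deterministic, dependency-free, and exact about which pixels
belong to the geometry (the mask comes from triangle coverage, not from
white-pixel detection).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .mesh import TriMesh

__all__ = [
    "ColorMapCodec",
    "ViewImage",
    "encode_field",
    "decode_image",
    "render_views",
    "downsample",
    "augment_axes",
    "random_zoom",
    "rotation_matrix",
]

BACKGROUND = np.array([1.0, 1.0, 1.0])
#: Maximum pixel intensity of rendered images (images live in [0, 1]).
MAX_INTENSITY = 1.0
NO_VALUE = np.nan  # sentinel for decoded background pixels


@dataclass(frozen=True)
class ColorMapCodec:
    """Invertible scalar ↔ color mapping over an explicit value range.

    ``encode`` maps a scalar linearly onto the L-entry lookup table;
    ``decode`` recovers the scalar of the nearest LUT color, so the round
    trip is exact up to half a quantization step of span/L. The background
    color (white) is reserved and never emitted for in-range values.
    """

    name: str
    lut: np.ndarray
    range: tuple[float, float]
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())

    def __post_init__(self) -> None:
        lut = np.asarray(self.lut, dtype=float)
        if lut.ndim != 2 or lut.shape[1] != 3 or lut.shape[0] < 2:
            raise ValueError("lut must be (L, 3) with L >= 2")
        if not self.range[0] < self.range[1]:
            raise ValueError("codec range must be non-degenerate")
        if np.any(np.all(np.abs(lut - np.asarray(self.background)) < 1e-9, axis=1)):
            raise ValueError("lut contains the reserved background color")
        object.__setattr__(self, "lut", lut)

    @classmethod
    def rainbow(cls, levels: int = 256,
                value_range: tuple[float, float] = (0.0, 1.0)) -> "ColorMapCodec":
        """Rainbow LUT (blue → red hue sweep at full saturation).

        A pure hue sweep moves through RGB space at constant speed, so every
        LUT entry is well separated from its neighbors and nearest-color
        decoding is exact — unlike e.g. ``jet``, whose saturated ends contain
        nearly duplicate colors that break invertibility.
        """
        from matplotlib.colors import hsv_to_rgb

        hue = np.linspace(2.0 / 3.0, 0.0, levels)  # blue (low) → red (high)
        hsv = np.stack([hue, np.ones_like(hue), np.full_like(hue, 0.95)], axis=1)
        lut = hsv_to_rgb(hsv)
        return cls(f"rainbow{levels}", lut,
                   (float(value_range[0]), float(value_range[1])))

    @classmethod
    def from_matplotlib(cls, cmap_name: str, levels: int = 256,
                        value_range: tuple[float, float] = (0.0, 1.0)) -> "ColorMapCodec":
        """Build from a named matplotlib colormap (invertibility not checked)."""
        import matplotlib

        cmap = matplotlib.colormaps[cmap_name]
        lut = np.asarray(cmap(np.linspace(0, 1, levels)))[:, :3]
        return cls(cmap_name, lut, (float(value_range[0]), float(value_range[1])))

    def with_range(self, value_range: tuple[float, float]) -> "ColorMapCodec":
        return ColorMapCodec(self.name, self.lut, (float(value_range[0]), float(value_range[1])),
                             self.background)

    @property
    def levels(self) -> int:
        return len(self.lut)

    @property
    def quantization_step(self) -> float:
        return (self.range[1] - self.range[0]) / self.levels

    def encode(self, values: np.ndarray) -> np.ndarray:
        """Scalars → LUT colors; out-of-range values clip to the endpoints."""
        values = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("cannot encode non-finite scalars")
        lo, hi = self.range
        x = (values - lo) / (hi - lo)
        idx = np.clip(np.round(x * (self.levels - 1)), 0, self.levels - 1).astype(int)
        return self.lut[idx]

    def decode(self, colors: np.ndarray, return_distance: bool = False):
        """Colors → scalars of the nearest LUT entry (nearest in RGB)."""
        colors = np.asarray(colors, dtype=float)
        flat = colors.reshape(-1, 3)
        d2 = ((flat[:, None, :] - self.lut[None, :, :]) ** 2).sum(axis=2)
        idx = d2.argmin(axis=1)
        lo, hi = self.range
        vals = lo + idx / (self.levels - 1) * (hi - lo)
        vals = vals.reshape(colors.shape[:-1])
        if return_distance:
            return vals, np.sqrt(d2[np.arange(len(idx)), idx]).reshape(colors.shape[:-1])
        return vals


def encode_field(values: np.ndarray, codec: ColorMapCodec) -> np.ndarray:
    """Per-vertex scalars → per-vertex RGB colors through the codec."""
    return codec.encode(values)


@dataclass
class ViewImage:
    """One rendered snapshot: color raster, exact foreground mask, metadata."""

    pixels: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.mask.shape != self.pixels.shape[:2]:
            raise ValueError("mask shape must match pixels")
        n_fg = int(self.mask.sum())
        if n_fg == 0 or n_fg == self.mask.size:
            raise ValueError("mask must contain both geometry and background")

    @property
    def resolution(self) -> int:
        return self.pixels.shape[0]

    def copy(self) -> "ViewImage":
        return ViewImage(self.pixels.copy(), self.mask.copy(), dict(self.meta))

    def save(self, path: str | Path) -> None:
        """PNG raster + 1-bit mask PNG + JSON metadata sidecar."""
        from PIL import Image

        path = Path(path)
        Image.fromarray((np.clip(self.pixels, 0, 1) * 255).round().astype(np.uint8)).save(path)
        Image.fromarray(self.mask).save(path.with_suffix(".mask.png"))
        meta = {k: v for k, v in self.meta.items()}
        path.with_suffix(".json").write_text(json.dumps(meta, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "ViewImage":
        from PIL import Image

        path = Path(path)
        pixels = np.asarray(Image.open(path), dtype=float)[..., :3] / 255.0
        mask = np.asarray(Image.open(path.with_suffix(".mask.png")), dtype=bool)
        meta = json.loads(path.with_suffix(".json").read_text())
        img = cls(pixels, mask, meta)
        img.pixels[~mask] = BACKGROUND
        return img


def decode_image(image: ViewImage, codec: ColorMapCodec) -> np.ndarray:
    """Masked pixels → scalar values (field renders only); background → NaN."""
    if image.meta.get("render_mode", "field") != "field":
        raise ValueError("decode_image requires a field-mode render")
    out = np.full(image.mask.shape, NO_VALUE)
    out[image.mask] = codec.decode(image.pixels[image.mask])
    return out


# ---------------------------------------------------------------------------
# Rasterizer
# ---------------------------------------------------------------------------

def rotation_matrix(axis: str, degrees: float) -> np.ndarray:
    """Counterclockwise rotation about a world axis, viewed from +axis."""
    a = np.deg2rad(degrees)
    c, s = np.cos(a), np.sin(a)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    raise ValueError(f"axis must be x, y or z, got {axis!r}")


# projection plane per rotation axis: camera direction is perpendicular to
# the axis so every rotation step changes the silhouette
_PROJECTIONS = {
    "z": (0, 2, 1),   # u=x, v=z, depth=y  (camera looks along +y)
    "x": (0, 2, 1),
    "y": (1, 2, 0),   # u=y, v=z, depth=x  (camera looks along +x)
}


def _rasterize(vertices: np.ndarray, faces: np.ndarray, vertex_colors: np.ndarray,
               axis: str, center: np.ndarray, half_extent: float,
               resolution: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthographic z-buffer rasterization with barycentric color interpolation."""
    iu, iv, idepth = _PROJECTIONS[axis]
    rel = vertices - center
    u = rel[:, iu]
    v = rel[:, iv]
    depth = rel[:, idepth]

    H = W = resolution
    # pixel center grid over [-half_extent, half_extent]; v points up
    scale = resolution / (2.0 * half_extent)
    px = (u + half_extent) * scale - 0.5
    py = (half_extent - v) * scale - 0.5

    zbuf = np.full((H, W), np.inf)
    color = np.tile(BACKGROUND, (H, W, 1))
    covered = np.zeros((H, W), dtype=bool)

    tx = px[faces]  # (F, 3)
    ty = py[faces]
    tz = depth[faces]
    tc = vertex_colors[faces]  # (F, 3, 3)

    xmin = np.maximum(np.floor(tx.min(axis=1)).astype(int), 0)
    xmax = np.minimum(np.ceil(tx.max(axis=1)).astype(int), W - 1)
    ymin = np.maximum(np.floor(ty.min(axis=1)).astype(int), 0)
    ymax = np.minimum(np.ceil(ty.max(axis=1)).astype(int), H - 1)

    for f in range(len(faces)):
        if xmax[f] < xmin[f] or ymax[f] < ymin[f]:
            continue
        x0, y0 = tx[f], ty[f]
        # signed area (in pixel coords, y down): degenerate → skip
        area = ((x0[1] - x0[0]) * (y0[2] - y0[0])
                - (x0[2] - x0[0]) * (y0[1] - y0[0]))
        if abs(area) < 1e-12:
            continue
        gx = np.arange(xmin[f], xmax[f] + 1)
        gy = np.arange(ymin[f], ymax[f] + 1)
        GX, GY = np.meshgrid(gx, gy)
        w0 = ((x0[1] - GX) * (y0[2] - GY) - (x0[2] - GX) * (y0[1] - GY)) / area
        w1 = ((x0[2] - GX) * (y0[0] - GY) - (x0[0] - GX) * (y0[2] - GY)) / area
        w2 = 1.0 - w0 - w1
        inside = (w0 >= -1e-9) & (w1 >= -1e-9) & (w2 >= -1e-9)
        if not inside.any():
            continue
        z = w0 * tz[f, 0] + w1 * tz[f, 1] + w2 * tz[f, 2]
        sub = zbuf[ymin[f]:ymax[f] + 1, xmin[f]:xmax[f] + 1]
        upd = inside & (z < sub)
        if not upd.any():
            continue
        sub[upd] = z[upd]
        col = (w0[..., None] * tc[f, 0] + w1[..., None] * tc[f, 1]
               + w2[..., None] * tc[f, 2])
        color[ymin[f]:ymax[f] + 1, xmin[f]:xmax[f] + 1][upd] = col[upd]
        covered[ymin[f]:ymax[f] + 1, xmin[f]:xmax[f] + 1] |= upd

    color[~covered] = BACKGROUND
    return np.clip(color, 0.0, 1.0), covered


def _shaded_colors(mesh: TriMesh, axis: str, metallic: float = 0.5,
                   roughness: float = 0.5) -> np.ndarray:
    """Per-vertex grayscale shading: headlight diffuse + PBR-style specular.

    A single light at the camera; diffuse weight (1 - metallic), specular
    lobe sharpness from roughness (Blinn exponent 2/roughness²). Gives
    curvature-revealing shading comparable to a PBR preview render.
    """
    normals = mesh.vertex_normals()
    idepth = _PROJECTIONS[axis][2]
    light = np.zeros(3)
    light[idepth] = -1.0  # toward the camera
    ndl = np.abs(normals @ light)
    exponent = 2.0 / max(roughness, 1e-3) ** 2
    spec = ndl ** exponent
    base = 0.72
    intensity = 0.12 + base * (1.0 - 0.5 * metallic) * ndl + 0.45 * metallic * spec
    intensity = np.clip(intensity, 0.0, 0.97)  # keep off the reserved white
    return np.repeat(intensity[:, None], 3, axis=1)


def render_views(
    mesh: TriMesh,
    mode: str = "field",
    codec: ColorMapCodec | None = None,
    field_name: str = "tawss",
    axis: str = "z",
    step_degrees: float = 30.0,
    resolution: int = 256,
    margin: float = 0.05,
) -> list[ViewImage]:
    """Render ``360/step_degrees`` views by rotating the mesh about ``axis``.

    Each step rotates the geometry ``step_degrees`` counterclockwise (viewed
    from +axis) and takes an orthographic snapshot. Framing is locked per
    geometry: the window is the bounding sphere about the bounding-box
    centroid plus a fixed margin, so the apparent size is identical at every
    angle, and rendering a pre-rotated mesh reproduces the next view of the
    original up to the sub-pixel shift of its re-estimated frame center.
    """
    if 360.0 % step_degrees != 0:
        raise ValueError("step_degrees must divide 360")
    if resolution < 64:
        raise ValueError("resolution must be >= 64")
    if mode not in ("field", "shaded"):
        raise ValueError(f"mode must be 'field' or 'shaded', got {mode!r}")

    bbox_min = mesh.vertices.min(axis=0)
    bbox_max = mesh.vertices.max(axis=0)
    if np.all(bbox_max - bbox_min < 1e-12):
        raise ValueError("degenerate mesh: zero spatial extent")
    center = 0.5 * (bbox_min + bbox_max)
    radius = np.linalg.norm(mesh.vertices - center, axis=1).max()
    half_extent = radius * (1.0 + margin)

    if mode == "field":
        if codec is None:
            fld = mesh.fields[field_name]
            codec = ColorMapCodec.rainbow(value_range=fld.range)
        vertex_colors = codec.encode(mesh.fields[field_name].values)
        frange = mesh.fields[field_name].range
    else:
        vertex_colors = None
        frange = None

    n_views = int(round(360.0 / step_degrees))
    views = []
    for k in range(n_views):
        R = rotation_matrix(axis, k * step_degrees)
        verts = (mesh.vertices - center) @ R.T + center
        if mode == "shaded":
            rmesh = TriMesh(verts, mesh.faces)
            colors = _shaded_colors(rmesh, axis)
        else:
            colors = vertex_colors
        pixels, mask = _rasterize(verts, mesh.faces, colors, axis, center,
                                  half_extent, resolution)
        meta = {
            "geometry_id": mesh.metadata.get("id"),
            "axis": axis,
            "step_index": k,
            "step_degrees": step_degrees,
            "render_mode": mode,
            "field_name": field_name if mode == "field" else None,
            "field_range": tuple(frange) if frange is not None else None,
            "codec": codec.name if codec is not None else None,
            "augmentation": axis != "z",
        }
        views.append(ViewImage(pixels, mask, meta))
    return views


def downsample(image: ViewImage, target: int) -> ViewImage:
    """Area-averaged downsampling; mask by majority vote; background restored.

    When the target divides the source the block mean is exact; otherwise a
    smoothed resize is used.
    """
    src = image.resolution
    if target > src:
        raise ValueError("target must not exceed source resolution")
    if target == src:
        return image.copy()
    if src % target == 0:
        k = src // target
        pix = image.pixels.reshape(target, k, target, k, 3).mean(axis=(1, 3))
        frac = image.mask.reshape(target, k, target, k).mean(axis=(1, 3))
    else:
        from skimage.transform import resize

        pix = resize(image.pixels, (target, target, 3), anti_aliasing=True)
        frac = resize(image.mask.astype(float), (target, target), anti_aliasing=True)
    mask = frac >= 0.5
    pix = np.clip(pix, 0, 1)
    pix[~mask] = BACKGROUND
    meta = dict(image.meta)
    meta["downsampled_from"] = src
    return ViewImage(pix, mask, meta)


def augment_axes(
    mesh: TriMesh,
    mode: str = "field",
    codec: ColorMapCodec | None = None,
    field_name: str = "tawss",
    step_degrees: float = 30.0,
    resolution: int = 256,
) -> list[ViewImage]:
    """x- and y-axis view rings, flagged as training-only augmentation."""
    out = []
    for axis in ("x", "y"):
        views = render_views(mesh, mode, codec, field_name, axis,
                             step_degrees, resolution)
        for vw in views:
            vw.meta["augmentation"] = True
        out.extend(views)
    return out


def random_zoom(
    images: ViewImage | list[ViewImage],
    zoom_range: tuple[float, float],
    rng: np.random.Generator | int,
    max_retries: int = 10,
) -> ViewImage | list[ViewImage]:
    """Zoom about the image center by one shared seeded factor.

    Pass the (input, target) images of one training pair together so both
    receive the same factor and their masks stay identical. Factors < 1
    shrink (background fills in); factors > 1 crop the edges. If a factor
    crops away the whole geometry, a fresh factor is drawn (bounded retries).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    lo, hi = zoom_range
    if not 0 < lo <= hi:
        raise ValueError("need 0 < low <= high")
    single = isinstance(images, ViewImage)
    batch = [images] if single else list(images)
    for _ in range(max_retries):
        factor = float(rng.uniform(lo, hi))
        out = [_apply_zoom(img, factor) for img in batch]
        if all(o is not None for o in out):
            return out[0] if single else out
    raise ValueError(f"zoom range {zoom_range} crops away the entire geometry")


def _apply_zoom(image: ViewImage, factor: float) -> ViewImage | None:
    if factor == 1.0:
        out = image.copy()
        out.meta["zoom"] = 1.0
        return out
    H, W = image.mask.shape
    c = (np.array([H, W]) - 1) / 2.0
    matrix = np.diag([1.0 / factor, 1.0 / factor])
    offset = c - c / factor
    pix = np.stack([
        ndimage.affine_transform(image.pixels[..., ch], matrix, offset=offset,
                                 order=1, mode="constant", cval=1.0)
        for ch in range(3)
    ], axis=-1)
    mask = ndimage.affine_transform(image.mask.astype(float), matrix, offset=offset,
                                    order=0, mode="constant", cval=0.0) >= 0.5
    if not mask.any() or mask.all():
        return None
    pix = np.clip(pix, 0, 1)
    pix[~mask] = BACKGROUND
    meta = dict(image.meta)
    meta["zoom"] = factor
    return ViewImage(pix, mask, meta)
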