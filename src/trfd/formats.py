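"""On-disk artifacts and their containers.

Three containers cover everything the tool reads or writes:

* :class:`FrameStack` -- the raw measurement: an ordered stack of 8-bit
  single-channel (red) camera frames with frame rate and pixel pitch.
* :class:`SpotList` -- a pencil-beam-scanning delivery plan: ordered
  (x, y, MU) triples, one spot per line of a plain-text file.  The line
  order is the delivery order.
* :class:`ScalarMap` -- any 2D quantity on a regular grid (dose, delta-t,
  dose rate) with geometry and a per-pixel validity mask.

Coordinate convention: x right / y up, in mm, isocenter at the map center.
Pixel centers sit at ``origin + (index + 0.5) * pitch``; ``values[i, j]``
maps to ``y = origin_y + (i + 0.5) * pitch`` and
``x = origin_x + (j + 0.5) * pitch``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "FrameStack",
    "SpotList",
    "ScalarMap",
    "read_frame_stack",
    "write_frame_stack",
    "parse_spot_list",
    "format_spot_list",
    "read_spot_list",
    "write_spot_list",
    "read_scalar_map",
    "write_scalar_map",
]


def _centered_origin(shape: tuple[int, int], pitch: float) -> tuple[float, float]:
    return (-shape[1] * pitch / 2.0, -shape[0] * pitch / 2.0)


@dataclass
class FrameStack:
    """Ordered 8-bit single-channel frames plus acquisition metadata.

    frames
        ``(T, H, W)`` uint8 array of pixel values (PV).
    fps
        Frame rate in frames per second.
    pixel_pitch_mm
        Physical size of one camera pixel on the film, mm.
    beam_start_index
        Frame index at which beam delivery starts (optional).
    """

    frames: np.ndarray
    fps: float
    pixel_pitch_mm: float
    beam_start_index: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.frames.dtype != np.uint8:
            if np.issubdtype(self.frames.dtype, np.integer) and (
                self.frames.min() >= 0 and self.frames.max() <= 255
            ):
                self.frames = self.frames.astype(np.uint8)
            else:
                raise ValueError("frames must be 8-bit (uint8) pixel values")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel_pitch_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def origin_mm(self) -> tuple[float, float]:
        """Grid corner (x, y) of the centered camera area, mm."""
        return _centered_origin(self.shape, self.pixel_pitch_mm)

    def times(self) -> np.ndarray:
        """Frame sample times in seconds, t = index / fps."""
        return np.arange(self.n_frames) / self.fps


@dataclass
class SpotList:
    """Ordered PBS spots: positions in mm and monitor units per spot."""

    x_mm: np.ndarray
    y_mm: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.x_mm = np.atleast_1d(np.asarray(self.x_mm, dtype=float))
        self.y_mm = np.atleast_1d(np.asarray(self.y_mm, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        if not (self.x_mm.shape == self.y_mm.shape == self.mu.shape):
            raise ValueError("x_mm, y_mm, mu must have equal length")
        if self.mu.size and not np.all(self.mu > 0):
            raise ValueError("every spot must have mu > 0")

    def __len__(self) -> int:
        return self.mu.size

    def __iter__(self):
        return iter(zip(self.x_mm, self.y_mm, self.mu))

    @property
    def total_mu(self) -> float:
        return float(self.mu.sum())


@dataclass
class ScalarMap:
    """2D scalar field on a regular grid with validity mask."""

    values: np.ndarray
    pixel_pitch_mm: float
    origin_mm: tuple[float, float] | None = None
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if self.origin_mm is None:
            self.origin_mm = _centered_origin(self.values.shape, self.pixel_pitch_mm)
        self.origin_mm = (float(self.origin_mm[0]), float(self.origin_mm[1]))
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values")
        if self.mask.any() and not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("values must be finite on masked-in pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def x_centers(self) -> np.ndarray:
        return self.origin_mm[0] + (np.arange(self.shape[1]) + 0.5) * self.pixel_pitch_mm

    def y_centers(self) -> np.ndarray:
        return self.origin_mm[1] + (np.arange(self.shape[0]) + 0.5) * self.pixel_pitch_mm


# ---------------------------------------------------------------------------
# Frame stacks
# ---------------------------------------------------------------------------

_FRAME_PATTERN = "frame_{:06d}.png"
_META_NAME = "meta.json"


def write_frame_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a frame stack.

    ``path`` ending in ``.tif``/``.tiff`` writes a multi-page 8-bit TIFF with
    the metadata in the TIFF description; otherwise ``path`` is a directory of
    zero-padded ``frame_%06d.png`` files plus a ``meta.json`` sidecar.
    """
    path = Path(path)
    meta = {
        "fps": stack.fps,
        "pixel_pitch_mm": stack.pixel_pitch_mm,
        "beam_start_index": stack.beam_start_index,
    }
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, stack.frames, description=json.dumps(meta))
        return path
    path.mkdir(parents=True, exist_ok=True)
    (path / _META_NAME).write_text(json.dumps(meta, indent=1))
    for i, frame in enumerate(stack.frames):
        iio.imwrite(path / _FRAME_PATTERN.format(i), frame)
    return path


def read_frame_stack(path: str | Path) -> FrameStack:
    """Read a frame stack written by :func:`write_frame_stack`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            desc = tf.pages[0].description
        meta = json.loads(desc)
        if frames.ndim == 2:
            frames = frames[None]
    else:
        meta_path = path / _META_NAME
        if not meta_path.exists():
            raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
        meta = json.loads(meta_path.read_text())
        frame_files = sorted(path.glob("frame_*.png"))
        if not frame_files:
            raise FileNotFoundError(f"no frame_*.png files in {path}")
        imgs = [iio.imread(f) for f in frame_files]
        shapes = {im.shape for im in imgs}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
        for im in imgs:
            if im.dtype != np.uint8:
                raise ValueError("frames must be 8-bit grayscale images")
            if im.ndim != 2:
                raise ValueError("frames must be single-channel images")
        frames = np.stack(imgs)
    if frames.dtype != np.uint8:
        raise ValueError("frame stack is not 8-bit")
    return FrameStack(
        frames=frames,
        fps=float(meta["fps"]),
        pixel_pitch_mm=float(meta["pixel_pitch_mm"]),
        beam_start_index=meta.get("beam_start_index"),
    )


# ---------------------------------------------------------------------------
# Spot lists
# ---------------------------------------------------------------------------


def parse_spot_list(text: str) -> SpotList:
    """Parse a plain-text spot list: one ``x_mm y_mm mu`` triple per line.

    Blank lines and lines starting with ``#`` are ignored.  Order is the
    delivery order.
    """
    xs: list[float] = []
    ys: list[float] = []
    mus: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 3 fields, got {len(parts)}")
        try:
            x, y, mu = (float(p) for p in parts)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric field in {line!r}") from exc
        if not mu > 0:
            raise ValueError(f"line {lineno}: non-positive MU ({mu})")
        xs.append(x)
        ys.append(y)
        mus.append(mu)
    if not xs:
        raise ValueError("empty spot list")
    return SpotList(np.array(xs), np.array(ys), np.array(mus))


def format_spot_list(spots: SpotList, header: str | None = None) -> str:
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    lines.extend(f"{x:.6g} {y:.6g} {mu:.10g}" for x, y, mu in spots)
    return "\n".join(lines) + "\n"


def read_spot_list(path: str | Path) -> SpotList:
    return parse_spot_list(Path(path).read_text())


def write_spot_list(spots: SpotList, path: str | Path, header: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(format_spot_list(spots, header))
    return path


# ---------------------------------------------------------------------------
# Scalar maps
# ---------------------------------------------------------------------------


def write_scalar_map(smap: ScalarMap, path: str | Path) -> Path:
    """Write a scalar map.

    ``.csv`` writes a plain-text matrix plus a ``<stem>.json`` geometry
    sidecar (and ``<stem>.mask.csv`` when the mask is non-trivial);
    ``.tif``/``.tiff`` writes a two-page float32 TIFF (values, mask) with the
    geometry in the description.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"pixel_pitch_mm": smap.pixel_pitch_mm, "origin_mm": list(smap.origin_mm)}
    if path.suffix.lower() in (".tif", ".tiff"):
        pages = np.stack(
            [smap.values.astype(np.float32), smap.mask.astype(np.float32)]
        )
        tifffile.imwrite(path, pages, description=json.dumps(meta))
        return path
    if path.suffix.lower() != ".csv":
        raise ValueError("scalar maps are written as .csv or .tif")
    # NaN on masked-out pixels is legal in CSV; keep full float precision
    np.savetxt(path, smap.values, delimiter=",", fmt="%.17g")
    if not smap.mask.all():
        mask_path = path.with_suffix(".mask.csv")
        np.savetxt(mask_path, smap.mask.astype(int), delimiter=",", fmt="%d")
        meta["mask_file"] = mask_path.name
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_scalar_map(path: str | Path) -> ScalarMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            pages = tf.asarray()
            meta = json.loads(tf.pages[0].description)
        values = pages[0].astype(float)
        mask = pages[1].astype(bool) if pages.shape[0] > 1 else None
    else:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing geometry sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        values = np.atleast_2d(np.loadtxt(path, delimiter=","))
        mask = None
        if "mask_file" in meta:
            mask = np.atleast_2d(
                np.loadtxt(path.parent / meta["mask_file"], delimiter=",")
            ).astype(bool)
    return ScalarMap(
        values=values,
        pixel_pitch_mm=float(meta["pixel_pitch_mm"]),
        origin_mm=tuple(meta["origin_mm"]),
        mask=mask,
    )
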