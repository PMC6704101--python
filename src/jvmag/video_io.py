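"""Frame-sequence I/O and color transforms.

The pipeline operates on a :class:`FrameSequence` — a ``T x H x W x 3`` float
array of channel values in ``[0, 1]`` plus a frame rate.  Sequences are read
from and written to lossless paths: directories of numbered PNG/TIFF images,
or a single multi-page TIFF stack.  The frame rate travels in a JSON sidecar
(``<stem>.fps.json`` next to the stack, or ``fps.json`` inside a directory)
unless supplied explicitly.

The magnification stage works on a luma/chroma decomposition; the YIQ
transform (luma weights 0.299/0.587/0.114, an invertible 3x3 linear map) is
used, delegated to :mod:`skimage.color`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import color as _skcolor

__all__ = [
    "FrameSequence",
    "read_frames",
    "write_frames",
    "to_luma_chroma",
    "from_luma_chroma",
]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass
class FrameSequence:
    """An ordered stack of frames with its sampling rate.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W, 3)`` with finite values in ``[0, 1]``
        (RGB) or the luma/chroma range after :func:`to_luma_chroma`.
    fps
        Frames per second, ``> 0``.
    colorspace
        ``"RGB"`` or ``"luma-chroma"``.
    source_bit_depth
        Bit depth of the material the frames came from (metadata only).
    """

    frames: np.ndarray
    fps: float
    colorspace: str = "RGB"
    source_bit_depth: int = 8

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(
                f"frames must be (T, H, W, 3), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("sequence must contain at least one frame")
        if not np.isfinite(self.frames).all():
            raise ValueError("frames contain non-finite values")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.colorspace not in ("RGB", "luma-chroma"):
            raise ValueError(f"unknown colorspace {self.colorspace!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps


def _load_fps(path: Path, fps_override: float | None) -> float:
    if fps_override is not None:
        if not fps_override > 0:
            raise ValueError(f"fps_override must be positive, got {fps_override}")
        return float(fps_override)
    sidecars = []
    if path.is_dir():
        sidecars.append(path / "fps.json")
    else:
        sidecars.append(path.with_suffix(path.suffix + ".fps.json"))
        sidecars.append(path.with_suffix(".fps.json"))
    for sc in sidecars:
        if sc.is_file():
            fps = float(json.loads(sc.read_text())["fps"])
            if not fps > 0:
                raise ValueError(f"sidecar {sc} declares non-positive fps {fps}")
            return fps
    raise ValueError(
        f"no frame rate available for {path}: pass fps_override or provide a "
        "JSON sidecar with an 'fps' key"
    )


def _to_unit(img: np.ndarray) -> tuple[np.ndarray, int]:
    """Scale an integer or float image into [0, 1]; return (array, bit depth)."""
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0, 8
    if img.dtype == np.uint16:
        return img.astype(np.float64) / 65535.0, 16
    img = img.astype(np.float64)
    return img, 0  # float source; bit depth unknown


def read_frames(path: str | Path, fps_override: float | None = None) -> FrameSequence:
    """Read a frame sequence from an image directory or a TIFF stack.

    Directories are scanned for PNG/TIFF files and sorted lexicographically,
    so frame indices should be zero-padded.  All frames must share one shape.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    fps = _load_fps(path, fps_override)

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise ValueError(f"no PNG/TIFF frames found in directory {path}")
        imgs = [iio.imread(f) for f in files]
        shapes = {im.shape for im in imgs}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
        stack = np.stack(imgs)
    elif path.suffix.lower() in (".tif", ".tiff"):
        stack = np.asarray(iio.imread(path))
        if stack.ndim == 3:  # single frame H x W x 3
            stack = stack[None]
    else:
        raise ValueError(
            f"unsupported input {path}: use an image directory or a TIFF stack"
        )

    frames, depth = _to_unit(stack)
    if frames.ndim == 3:  # grayscale stack -> replicate channels
        frames = np.repeat(frames[..., None], 3, axis=-1)
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError(f"frames in {path} are not RGB (shape {frames.shape})")
    return FrameSequence(
        frames=np.clip(frames, 0.0, 1.0),
        fps=fps,
        colorspace="RGB",
        source_bit_depth=depth or 8,
    )


def write_frames(seq: FrameSequence, path: str | Path, bit_depth: int = 16) -> None:
    """Write a sequence losslessly.

    A directory path receives zero-padded image frames plus an ``fps.json``
    sidecar; a ``.tif``/``.tiff`` path receives a multi-page stack plus a
    ``.fps.json`` sidecar.  16-bit quantization (default) keeps the
    round-trip error below 1/65535 per channel; directory frames are PNG at
    8 bits and TIFF at 16 (RGB PNG is 8-bit only).
    """
    if seq.colorspace != "RGB":
        raise ValueError("write_frames expects an RGB sequence")
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    path = Path(path)
    scale = 255 if bit_depth == 8 else 65535
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    quant = np.clip(np.rint(seq.frames * scale), 0, scale).astype(dtype)

    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        iio.imwrite(path, quant)
        sidecar = path.with_suffix(path.suffix + ".fps.json")
        sidecar.write_text(json.dumps({"fps": seq.fps}))
    else:
        path.mkdir(parents=True, exist_ok=True)
        width = max(6, len(str(seq.n_frames - 1)))
        suffix = ".png" if bit_depth == 8 else ".tif"
        for t in range(seq.n_frames):
            iio.imwrite(path / f"frame_{t:0{width}d}{suffix}", quant[t])
        (path / "fps.json").write_text(json.dumps({"fps": seq.fps}))


# YIQ: luma = 0.299 R + 0.587 G + 0.114 B (weights sum to 1); I/Q chroma.
def to_luma_chroma(seq: FrameSequence) -> FrameSequence:
    """Convert an RGB sequence to luma/chroma (YIQ)."""
    if seq.colorspace != "RGB":
        raise ValueError("sequence is not in RGB")
    yiq = _skcolor.rgb2yiq(seq.frames)
    return replace(seq, frames=yiq, colorspace="luma-chroma")


def from_luma_chroma(seq: FrameSequence) -> FrameSequence:
    """Convert a luma/chroma (YIQ) sequence back to RGB."""
    if seq.colorspace != "luma-chroma":
        raise ValueError("sequence is not in luma-chroma")
    rgb = _skcolor.yiq2rgb(seq.frames)
    return replace(seq, frames=rgb, colorspace="RGB")
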