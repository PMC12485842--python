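"""Reading and writing mask streams, keypoint tables, annotations and config.

Mask streams live in HDF5 (dataset ``masks``, uint8, shape ``(T, H, W)``,
stream metadata as attributes) or as a directory of 8-bit single-channel PNGs
with a ``stream.json`` metadata sidecar.  Keypoint tracks are CSV with columns
``frame, track, keypoint, x, y``.  ZOD annotations are a JSON array; run
configuration is YAML.  Frame indexing is 0-based and all intervals half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .zod import ZOD

__all__ = [
    "MaskStream",
    "KeypointSet",
    "RunConfig",
    "FormatError",
    "read_mask_stream",
    "write_mask_stream",
    "read_keypoints",
    "write_keypoints",
    "read_zod_annotations",
    "write_zod_annotations",
    "downsample_mask",
]

DIRECTIONS = ("forward", "reverse")


class FormatError(ValueError):
    """A file or in-memory container violates the expected mask/keypoint format."""


@dataclass
class MaskStream:
    """Time-ordered label images from one inference direction.

    ``frames`` is a ``(T, H, W)`` integer array with 0 = background and
    ``1..n_animals`` = animals.  ``frame_offset`` places the first frame in
    global video time; ``scale`` is the integer downsampling factor relative
    to acquisition resolution (4 for the standard fourfold-downsampled masks).
    Reverse-direction streams are always held in forward temporal order.
    """

    frames: np.ndarray
    n_animals: int
    direction: str = "forward"
    frame_offset: int = 0
    scale: int = 1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or len(self.frames) < 1:
            raise FormatError(
                f"frames must be a nonempty (T, H, W) volume, got shape {self.frames.shape}"
            )
        if not np.issubdtype(self.frames.dtype, np.integer):
            raise FormatError(f"labels must be integers, got {self.frames.dtype}")
        if self.n_animals < 1:
            raise FormatError("n_animals must be positive")
        if self.direction not in DIRECTIONS:
            raise FormatError(f"direction must be one of {DIRECTIONS}")
        if self.frame_offset < 0:
            raise FormatError("frame_offset must be nonnegative")
        if self.scale < 1:
            raise FormatError("scale must be a positive integer")
        mx = int(self.frames.max())
        mn = int(self.frames.min())
        if mn < 0 or mx > self.n_animals:
            bad = int(np.argmax((self.frames < 0) | (self.frames > self.n_animals)
                                ).item() // (self.frames.shape[1] * self.frames.shape[2]))
            raise FormatError(
                f"frame {bad}: label outside 0..{self.n_animals} "
                f"(range seen: {mn}..{mx})"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __eq__(self, other) -> bool:
        if not isinstance(other, MaskStream):
            return NotImplemented
        return (
            self.n_animals == other.n_animals
            and self.direction == other.direction
            and self.frame_offset == other.frame_offset
            and self.scale == other.scale
            and self.frames.shape == other.frames.shape
            and bool(np.array_equal(self.frames, other.frames))
        )

    def copy(self) -> "MaskStream":
        return MaskStream(
            self.frames.copy(), self.n_animals, self.direction,
            self.frame_offset, self.scale,
        )


@dataclass
class KeypointSet:
    """Per-frame, per-track 2D keypoints with validity flags.

    ``records`` has columns ``frame, track, keypoint, x, y, valid``.  A record
    is valid iff both coordinates are non-NaN and non-negative; invalid rows
    are retained so missingness stays visible to displacement and alignment.
    Coordinates are pixels at downsampling factor ``scale`` (1 = acquisition
    resolution).  Tracks are ``1..n_tracks``, keypoints ``1..n_keypoints``.
    """

    records: pd.DataFrame
    n_tracks: int
    n_keypoints: int
    scale: int = 1

    def __post_init__(self) -> None:
        needed = {"frame", "track", "keypoint", "x", "y"}
        missing = needed - set(self.records.columns)
        if missing:
            raise FormatError(f"keypoint table missing columns: {sorted(missing)}")
        if "valid" not in self.records.columns:
            self.records = self.records.assign(
                valid=_valid_mask(self.records["x"], self.records["y"])
            )

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, KeypointSet):
            return NotImplemented
        if (self.n_tracks, self.n_keypoints, self.scale) != (
            other.n_tracks, other.n_keypoints, other.scale,
        ):
            return False
        a = self.records.reset_index(drop=True)
        b = other.records.reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True

    def copy(self) -> "KeypointSet":
        return KeypointSet(self.records.copy(), self.n_tracks,
                           self.n_keypoints, self.scale)


def _valid_mask(x: pd.Series, y: pd.Series) -> pd.Series:
    return (~x.isna()) & (~y.isna()) & (x >= 0) & (y >= 0)


@dataclass
class RunConfig:
    """Pipeline parameters with the defaults used throughout the package.

    ``zod_radius`` is the phase-1 window radius in frames, ``dominant_iou_threshold``
    the phase-2 review threshold tau (raise it as n_animals grows),
    ``quality_threshold`` the two-animal review criterion on minimum quality
    score, ``dilation_radius`` the binary-dilation radius in mask-scale pixels
    for keypoint alignment, and ``keypoint_subset`` the 1-based keypoint
    indices used for displacement and alignment (None = all; the standard
    skeleton drops the two unreliable tail points).
    """

    n_animals: int = 2
    zod_radius: int = 25
    dominant_iou_threshold: float = 0.5
    quality_threshold: float = 0.5
    dilation_radius: int = 5
    default_direction: str = "forward"
    random_seed: int = 0
    keypoint_subset: list[int] | None = None

    def __post_init__(self) -> None:
        if self.zod_radius < 0:
            raise FormatError("zod_radius must be nonnegative")
        if not 0.0 < self.dominant_iou_threshold < 1.0:
            raise FormatError("dominant_iou_threshold must lie in (0, 1)")
        if self.dilation_radius < 0:
            raise FormatError("dilation_radius must be nonnegative")
        if self.default_direction not in DIRECTIONS:
            raise FormatError(f"default_direction must be one of {DIRECTIONS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# mask streams


def read_mask_stream(
    path: str | Path,
    direction: str | None = None,
    n_animals: int | None = None,
) -> MaskStream:
    """Read a mask stream from an HDF5 file or a PNG directory.

    ``direction`` overrides the stored direction; ``n_animals`` overrides the
    stored (or inferred) animal count and is validated against the data.
    Streams stored in reverse temporal order (attribute ``stored_order =
    'reverse'``) are flipped so that returned frames always run forward.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return _read_png_dir(path, direction, n_animals)
    return _read_h5(path, direction, n_animals)


def _finalize(frames, meta, direction, n_animals) -> MaskStream:
    if meta.pop("stored_order", "forward") == "reverse":
        frames = frames[::-1].copy()
    if direction is not None:
        meta["direction"] = direction
    if n_animals is not None:
        meta["n_animals"] = n_animals
    if "n_animals" not in meta:
        meta["n_animals"] = int(frames.max()) if frames.max() > 0 else 1
    return MaskStream(frames, **meta)


def _read_h5(path, direction, n_animals) -> MaskStream:
    with h5py.File(path, "r") as fh:
        if "masks" not in fh:
            raise FormatError(f"{path}: no 'masks' dataset")
        ds = fh["masks"]
        if ds.ndim != 3 or not np.issubdtype(ds.dtype, np.integer):
            raise FormatError(
                f"{path}: 'masks' must be a 3-D integer volume, "
                f"got {ds.ndim}-D {ds.dtype}"
            )
        frames = ds[...]
        meta = {
            k: (v.decode() if isinstance(v, bytes) else
                v.item() if hasattr(v, "item") else v)
            for k, v in ds.attrs.items()
            if k in {"n_animals", "direction", "frame_offset", "scale", "stored_order"}
        }
    return _finalize(frames, meta, direction, n_animals)


def _read_png_dir(path, direction, n_animals) -> MaskStream:
    pngs = sorted(path.glob("*.png"))
    if not pngs:
        raise FormatError(f"{path}: no PNG frames found")
    frames = []
    shape = None
    for p in pngs:
        img = iio.imread(p)
        if img.ndim != 2:
            raise FormatError(f"{p.name}: expected single-channel image")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise FormatError(
                f"{p.name}: frame shape {img.shape} differs from {shape}"
            )
        frames.append(img)
    meta = {}
    sidecar = path / "stream.json"
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = {
                k: v for k, v in json.load(fh).items()
                if k in {"n_animals", "direction", "frame_offset", "scale",
                         "stored_order"}
            }
    return _finalize(np.stack(frames), meta, direction, n_animals)


def write_mask_stream(stream: MaskStream, path: str | Path) -> None:
    """Write a stream as HDF5 (``.h5``/``.hdf5`` suffix) or a PNG directory.

    Round-trips pixel-for-pixel and metadata-for-metadata through
    :func:`read_mask_stream`.
    """
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset(
                "masks", data=stream.frames.astype(np.uint8),
                compression="gzip", compression_opts=4,
                track_times=False,  # byte-identical files for identical inputs
            )
            ds.attrs["n_animals"] = stream.n_animals
            ds.attrs["direction"] = stream.direction
            ds.attrs["frame_offset"] = stream.frame_offset
            ds.attrs["scale"] = stream.scale
        return
    path.mkdir(parents=True, exist_ok=True)
    width = max(6, len(str(len(stream) - 1)))
    for t, frame in enumerate(stream.frames):
        iio.imwrite(path / f"frame_{t:0{width}d}.png", frame.astype(np.uint8))
    with open(path / "stream.json", "w") as fh:
        json.dump(
            {
                "n_animals": stream.n_animals,
                "direction": stream.direction,
                "frame_offset": stream.frame_offset,
                "scale": stream.scale,
            },
            fh,
            indent=2,
        )


# ---------------------------------------------------------------------------
# keypoints


def read_keypoints(path: str | Path, scale: int = 1) -> KeypointSet:
    """Read a keypoint table (CSV: ``frame, track, keypoint, x, y``).

    Rows with NaN or negative coordinates are kept but flagged invalid, per
    the validity rule (non-NaN and non-negative).
    """
    df = pd.read_csv(path)
    needed = {"frame", "track", "keypoint", "x", "y"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("x", "y"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"{path}: column {col!r} is not numeric")
    for col in ("frame", "track", "keypoint"):
        if not np.issubdtype(df[col].dtype, np.integer):
            raise FormatError(f"{path}: column {col!r} must be integer")
    return KeypointSet(
        records=df,
        n_tracks=int(df["track"].max()) if len(df) else 0,
        n_keypoints=int(df["keypoint"].max()) if len(df) else 0,
        scale=scale,
    )


def write_keypoints(kps: KeypointSet, path: str | Path) -> None:
    kps.records[["frame", "track", "keypoint", "x", "y"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ZOD annotations


def read_zod_annotations(path: str | Path) -> list[ZOD]:
    """Read a JSON array of annotated ZODs."""
    with open(path) as fh:
        data = json.load(fh)
    return [ZOD.from_dict(d) for d in data]


def write_zod_annotations(zods: Sequence[ZOD], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([z.to_dict() for z in zods], fh, indent=2)


# ---------------------------------------------------------------------------
# downsampling


def downsample_mask(frame: np.ndarray, factor: int) -> np.ndarray:
    """Downsample a label image by block top-left subsampling.

    Each output pixel takes the label of the top-left pixel of its
    ``factor x factor`` block; trailing rows/columns that do not fill a block
    are dropped.  Stride sampling never interpolates, so the output label
    alphabet is a subset of the input's.  The standard pipeline factor is 4
    (1536 x 2048 acquisition frames become 384 x 512).
    """
    if factor < 1:
        raise ValueError("downsampling factor must be >= 1")
    h, w = frame.shape
    return frame[: (h // factor) * factor : factor, : (w // factor) * factor : factor]
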