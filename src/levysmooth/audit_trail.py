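"""Storage, rendering and replay of the progressive smoothing evolution.

Every smoothing run is written as one TIFF per frame plus a montage and a
JSON manifest.  The manifest carries the input digest, every processing
parameter, and per-frame digests of the quantized pixels, so a run can be
replayed later and verified byte-exactly — the stored evolution is the audit
trail that makes the enhancement examinable.

Digests are SHA-256 over the quantized pixel buffer prefixed by the image
dimensions.  All floating-point differences are absorbed by quantization
before digesting, so replay on a compliant platform reproduces every digest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .levy_diffusion import DiffusionParams, SmoothingSuite, diffuse_suite
from .raster_io import EmbedRecord, embed_center, crop_center, invert, quantize, write_gray_tiff

__all__ = [
    "AuditManifest",
    "AuditMismatchError",
    "image_digest",
    "save_suite",
    "render_montage",
    "select_frame",
    "replay_manifest",
    "load_manifest",
    "smooth_workflow",
]

MANIFEST_VERSION = 1
DIGEST_ALGORITHM = "sha256"


class AuditMismatchError(RuntimeError):
    """A replayed frame or input did not reproduce its recorded digest."""


def image_digest(image: np.ndarray) -> str:
    """SHA-256 of the quantized pixel buffer plus dimensions."""
    q = quantize(image)
    hasher = hashlib.sha256()
    hasher.update(f"{q.shape[0]}x{q.shape[1]}:".encode())
    hasher.update(q.tobytes())
    return hasher.hexdigest()


@dataclass
class AuditManifest:
    """Machine-readable provenance record making a smoothing run replayable."""

    input_digest: str
    p: float
    t_max: float
    n_frames: int
    frame_times: list[float]
    frame_digests: list[str]
    input_path: str | None = None
    enhancement: dict | None = None
    embed: dict | None = None
    selected_frame: int | None = None
    seed: int | None = None
    tool_version: str = ""
    manifest_version: int = MANIFEST_VERSION
    digest_algorithm: str = DIGEST_ALGORITHM
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "manifest_version": self.manifest_version,
            "tool_version": self.tool_version,
            "digest_algorithm": self.digest_algorithm,
            "input_path": self.input_path,
            "input_digest": self.input_digest,
            "enhancement": self.enhancement,
            "embed": self.embed,
            "p": self.p,
            "t_max": self.t_max,
            "n_frames": self.n_frames,
            "frame_times": self.frame_times,
            "frame_digests": self.frame_digests,
            "selected_frame": self.selected_frame,
            "seed": self.seed,
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AuditManifest":
        return cls(
            input_digest=d["input_digest"],
            p=float(d["p"]),
            t_max=float(d["t_max"]),
            n_frames=int(d["n_frames"]),
            frame_times=[float(t) for t in d["frame_times"]],
            frame_digests=list(d["frame_digests"]),
            input_path=d.get("input_path"),
            enhancement=d.get("enhancement"),
            embed=d.get("embed"),
            selected_frame=d.get("selected_frame"),
            seed=d.get("seed"),
            tool_version=d.get("tool_version", ""),
            manifest_version=int(d.get("manifest_version", MANIFEST_VERSION)),
            digest_algorithm=d.get("digest_algorithm", DIGEST_ALGORITHM),
            notes=d.get("notes", {}),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def load_manifest(path) -> AuditManifest:
    return AuditManifest.from_dict(json.loads(Path(path).read_text()))


def _frame_filename(index: int, t: float) -> str:
    return f"frame_{index:02d}_t{t:.6f}.tiff"


def smooth_workflow(
    image: np.ndarray,
    params: DiffusionParams,
    pad_to: int | None = None,
) -> SmoothingSuite:
    """Embed an image in an even square of zeros and run the smoothing suite.

    ``pad_to`` is the outer square side; ``None`` chooses the smallest even
    integer >= the larger image dimension.  The returned suite carries the
    embed record (for cropping selected frames back) and the digest of the
    pre-embed input.
    """
    arr = np.asarray(image, dtype=float)
    if pad_to is None:
        pad_to = max(arr.shape)
        if pad_to % 2 != 0:
            pad_to += 1
    digest = image_digest(arr)
    padded, record = embed_center(arr, int(pad_to))
    return diffuse_suite(padded, params, source_digest=digest, embed=record)


def render_montage(
    suite: SmoothingSuite, thumb_side: int = 600, columns: int = 3
) -> np.ndarray:
    """Row-major contact sheet of the suite, intensity-reversed for display.

    Each frame is nearest-neighbor downsampled to thumb_side x thumb_side.
    The montage is (ceil(n/columns) * thumb_side) rows by
    (columns * thumb_side) columns; the default six-frame suite gives the
    familiar 1200 x 1800 layout.
    """
    if len(suite.frames) == 0:
        raise ValueError("cannot render an empty suite")
    n = len(suite.frames)
    columns = min(int(columns), n)
    rows = -(-n // columns)
    montage = np.zeros((rows * thumb_side, columns * thumb_side), dtype=float)
    for idx, (_, frame) in enumerate(suite.frames):
        h, w = frame.shape
        ri = (np.arange(thumb_side) * h) // thumb_side
        ci = (np.arange(thumb_side) * w) // thumb_side
        thumb = invert(np.clip(frame, 0, 255))[np.ix_(ri, ci)]
        r0 = (idx // columns) * thumb_side
        c0 = (idx % columns) * thumb_side
        montage[r0 : r0 + thumb_side, c0 : c0 + thumb_side] = thumb
    return montage


def select_frame(suite: SmoothingSuite, index: int) -> np.ndarray:
    """Return the 1-based frame ``index``, cropped to the pre-embed geometry.

    Index 1 is the unsmoothed input; the last index is the frame at t_max.
    """
    if not (1 <= index <= len(suite.frames)):
        raise IndexError(
            f"frame index {index} out of range 1..{len(suite.frames)}"
        )
    frame = suite.frames[index - 1][1]
    if suite.embed is not None:
        return crop_center(frame, suite.embed)
    return frame.copy()


def save_suite(
    suite: SmoothingSuite,
    directory,
    input_path: str | None = None,
    enhancement: dict | None = None,
    selected_frame: int | None = None,
    seed: int | None = None,
) -> AuditManifest:
    """Write frame TIFFs, a montage TIFF and the JSON manifest.

    Frames are named ``frame_<index>_t<time>.tiff``; the montage is
    ``montage.tiff`` and the manifest ``manifest.json``.  Re-running on the
    same suite produces byte-identical files.  Returns the manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    digests = []
    for idx, (t, frame) in enumerate(suite.frames, start=1):
        write_gray_tiff(frame, directory / _frame_filename(idx, t))
        digests.append(image_digest(frame))
    write_gray_tiff(render_montage(suite), directory / "montage.tiff")

    from . import __version__

    manifest = AuditManifest(
        input_digest=suite.source_digest or "",
        p=suite.params.p,
        t_max=suite.params.t_max,
        n_frames=suite.params.n_frames,
        frame_times=[t for t, _ in suite.frames],
        frame_digests=digests,
        input_path=str(input_path) if input_path else None,
        enhancement=enhancement,
        embed=suite.embed.to_dict() if suite.embed is not None else None,
        selected_frame=selected_frame,
        seed=seed,
        tool_version=__version__,
    )
    manifest.save(directory / "manifest.json")
    return manifest


def replay_manifest(manifest: AuditManifest, input_image: np.ndarray) -> SmoothingSuite:
    """Re-run a manifest on its input and verify every frame digest.

    Raises :class:`AuditMismatchError` naming the first mismatching frame, or
    the input itself if its digest differs from the recorded one.
    """
    digest = image_digest(input_image)
    if manifest.input_digest and digest != manifest.input_digest:
        raise AuditMismatchError(
            f"input digest mismatch: manifest records {manifest.input_digest}, "
            f"supplied image has {digest}"
        )
    params = DiffusionParams(
        p=manifest.p, t_max=manifest.t_max, n_frames=manifest.n_frames
    )
    if manifest.embed is not None:
        record = EmbedRecord.from_dict(manifest.embed)
        suite = smooth_workflow(input_image, params, pad_to=record.outer_side)
    else:
        suite = diffuse_suite(
            np.asarray(input_image, dtype=float), params, source_digest=digest
        )
    for idx, (t, frame) in enumerate(suite.frames, start=1):
        actual = image_digest(frame)
        if actual != manifest.frame_digests[idx - 1]:
            raise AuditMismatchError(
                f"frame {idx} (t={t:g}) digest mismatch: manifest records "
                f"{manifest.frame_digests[idx - 1]}, replay produced {actual}"
            )
    return suite
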