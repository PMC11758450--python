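"""Bar-aperture stimulus generation for pRF mapping.

The stimulus is a binary bar aperture sweeping through a circular visual
field, the standard traveling-bar retinotopy design: a bar of fixed width
translates across the field in equal steps, once per sweep direction
(default eight directions in 45 deg increments).  Coordinates are
visual-field degrees with x rightward, y upward and the origin at fixation;
pixel (0, 0) sits at the lower-left of the grid and masks are sampled at
pixel centers.  A pixel is "on" when its center lies inside both the bar
strip and the stimulated disc.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["StimulusSequence", "make_bar_apertures", "save_stimulus", "load_stimulus"]


@dataclass(frozen=True)
class StimulusSequence:
    """A binary aperture movie over a circular visual field.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, height, width), values in {0, 1}
    extent_deg : float
        Radius of the stimulated field, deg.
    deg_per_pixel : float
    tr_s : float
        Frame duration (repetition time), seconds.
    """

    frames: np.ndarray
    extent_deg: float
    deg_per_pixel: float
    tr_s: float

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError("frames must be a (time, height, width) array")
        if not np.isin(f, (0, 1)).all():
            raise ValueError("frames must be binary")
        object.__setattr__(self, "frames", f.astype(np.int8))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def resolution_px(self) -> int:
        return self.frames.shape[1]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinate grids (X, Y) in degrees, y increasing upward."""
        r, h = self.extent_deg, self.deg_per_pixel
        n = self.resolution_px
        coords = -r + h * (np.arange(n) + 0.5)
        X, Y = np.meshgrid(coords, coords, indexing="xy")
        return X, Y

    def fingerprint(self) -> tuple:
        """Cheap content key used to cache per-stimulus fitting precomputations."""
        import hashlib

        return (self.frames.shape, self.extent_deg, self.deg_per_pixel, self.tr_s,
                hashlib.sha1(self.frames.tobytes()).hexdigest())


def make_bar_apertures(
    radius_deg: float = 7.8,
    bar_width_deg: float = 1.95,
    n_directions: int = 8,
    frames_per_sweep: int = 16,
    resolution_px: int = 101,
    tr_s: float = 1.883,
    n_blank_frames: int = 0,
) -> StimulusSequence:
    """Generate a multi-direction traveling-bar aperture sequence.

    For each sweep direction (equally spaced over 360 deg starting at 0) the
    bar translates across the field in ``frames_per_sweep`` equal steps; bar
    positions are symmetric about fixation so reversing a direction yields
    the time-reversed frames of the opposite sweep.  ``n_blank_frames``
    all-zero frames are appended after the sweeps (e.g. to pad a run to the
    acquired number of volumes).
    """
    if radius_deg <= 0 or bar_width_deg <= 0:
        raise ValueError("radius_deg and bar_width_deg must be positive")
    if bar_width_deg > 2 * radius_deg:
        raise ValueError("bar is wider than the stimulated field diameter")
    if n_directions < 1:
        raise ValueError("need at least one sweep direction")
    if resolution_px < 16:
        raise ValueError("resolution_px must be at least 16")
    for name, v in (("n_directions", n_directions),
                    ("frames_per_sweep", frames_per_sweep),
                    ("n_blank_frames", n_blank_frames)):
        if int(v) != v:
            raise ValueError(f"{name} must be an integer, got {v!r}")

    n_px = int(resolution_px)
    h = 2 * radius_deg / n_px
    coords = -radius_deg + h * (np.arange(n_px) + 0.5)
    X, Y = np.meshgrid(coords, coords, indexing="xy")
    in_disc = X**2 + Y**2 <= radius_deg**2

    step = 2 * radius_deg / frames_per_sweep
    offsets = -radius_deg + step * (np.arange(frames_per_sweep) + 0.5)

    frames = np.zeros(
        (n_directions * frames_per_sweep + n_blank_frames, n_px, n_px), dtype=np.int8
    )
    t = 0
    for k in range(n_directions):
        theta = np.deg2rad(k * 360.0 / n_directions)
        u = X * np.cos(theta) + Y * np.sin(theta)  # signed distance along motion
        for c in offsets:
            frames[t] = (np.abs(u - c) <= bar_width_deg / 2) & in_disc
            t += 1
    return StimulusSequence(frames=frames, extent_deg=radius_deg,
                            deg_per_pixel=h, tr_s=tr_s)


def save_stimulus(stim: StimulusSequence, nifti_path, sidecar_path=None) -> None:
    """Write the aperture movie as NIfTI (x, y, 1, time; int8) plus a JSON sidecar."""
    nifti_path = Path(nifti_path)
    data = np.transpose(stim.frames, (2, 1, 0))[:, :, np.newaxis, :].astype(np.int8)
    affine = np.diag([stim.deg_per_pixel, stim.deg_per_pixel, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(nifti_path))
    if sidecar_path is None:
        sidecar_path = nifti_path.with_suffix("").with_suffix(".json")
    meta = {"radius_deg": stim.extent_deg, "deg_per_pixel": stim.deg_per_pixel,
            "tr_s": stim.tr_s}
    Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def load_stimulus(nifti_path, sidecar_path=None) -> StimulusSequence:
    """Read an aperture movie written by :func:`save_stimulus`."""
    nifti_path = Path(nifti_path)
    if sidecar_path is None:
        sidecar_path = nifti_path.with_suffix("").with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    data = np.asanyarray(nib.load(str(nifti_path)).dataobj)
    frames = np.transpose(data[:, :, 0, :], (2, 1, 0))
    return StimulusSequence(frames=frames, extent_deg=meta["radius_deg"],
                            deg_per_pixel=meta["deg_per_pixel"], tr_s=meta["tr_s"])
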