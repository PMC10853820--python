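"""Pericentrosomal quantification: disk-ROI enrichment and signed line profiles.

Two measurements per centrosome:

* **Disk enrichment** — the total intensity inside a circular ROI (default
  radius 2 µm) about the centrosome, minus a matched in-cell background
  total taken as the median of identically sized disks placed at seeded
  random positions inside the cell that exclude all centrosomes.
* **Line-profile peak position** — intensities sampled along the signed
  spindle→astral axis through the marker peak, ±1 µm by default; the peak
  position of each channel is the signed µm coordinate of its maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class LineProfile:
    """Channel intensities along the signed spindle→astral axis.

    ``positions`` is a uniform grid symmetric about 0 (negative = spindle
    side); ``values`` maps channel name → sampled intensities.
    """

    positions: np.ndarray
    values: dict[str, np.ndarray]

    def __post_init__(self):
        for name, v in self.values.items():
            if len(v) != len(self.positions):
                raise ValueError(f"channel {name}: value/position length mismatch")


@dataclass
class QuantRecord:
    """Per-centrosome quantification result."""

    cell_id: int
    centrosome_id: int
    disk_total: dict[str, float] = field(default_factory=dict)
    background_total: dict[str, float] = field(default_factory=dict)
    enrichment: dict[str, float] = field(default_factory=dict)
    peak_position: dict[str, float] = field(default_factory=dict)
    timepoint: float | None = None
    stage_label: str = "metaphase"
    flagged: bool = False


def disk_pixel_indices(shape: tuple[int, int], center: np.ndarray,
                       radius: float, pixel_size: float
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Indices of pixels whose centres lie within ``radius`` µm of ``center``.

    Membership is pixel-centre-in-circle, no partial-pixel weighting.
    """
    cy, cx = np.asarray(center, dtype=float) / pixel_size
    r_px = radius / pixel_size
    y0, y1 = max(0, int(np.floor(cy - r_px))), min(shape[0], int(np.ceil(cy + r_px)) + 1)
    x0, x1 = max(0, int(np.floor(cx - r_px))), min(shape[1], int(np.ceil(cx + r_px)) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    return yy[inside], xx[inside]


def disk_sum(image: np.ndarray, center: np.ndarray, radius: float,
             pixel_size: float) -> float:
    yy, xx = disk_pixel_indices(image.shape, center, radius, pixel_size)
    return float(image[yy, xx].sum())


def disk_enrichment(image: np.ndarray, center: np.ndarray, radius: float,
                    pixel_size: float, cell_mask: np.ndarray,
                    exclusion_centers: list[np.ndarray], seed: int,
                    n_background: int = 10, max_tries: int = 1000
                    ) -> tuple[float, float, float]:
    """Background-subtracted total intensity in a disk about the centrosome.

    ``disk_total`` sums pixels whose centres lie within ``radius`` of
    ``center``; ``background_total`` is the median of the same-radius disk
    sum over ``n_background`` seeded random placements whose centres lie
    inside ``cell_mask``, at least ``2 * radius`` from every exclusion
    centre, with the whole disk inside the image.  Background centres are
    drawn on the integer-pixel lattice shifted by the fractional pixel
    offset of the measurement centre, so every background disk covers
    exactly as many pixels as the measurement disk (a uniform image
    therefore has enrichment exactly 0).

    Returns (disk_total, background_total, enrichment); enrichment may be
    negative.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    center = np.asarray(center, dtype=float)
    cy_px, cx_px = center / pixel_size
    if not (0 <= cy_px <= image.shape[0] - 1 and 0 <= cx_px <= image.shape[1] - 1):
        raise ValueError("center lies outside the image")

    yy, xx = disk_pixel_indices(image.shape, center, radius, pixel_size)
    total = float(image[yy, xx].sum())

    # One integer offset stencil, anchored at floor(center), reused for
    # every background disk: each placement covers exactly the same pixel
    # pattern as the measurement disk, just translated.
    iy0, ix0 = int(np.floor(cy_px)), int(np.floor(cx_px))
    dy, dx = yy - iy0, xx - ix0
    frac = np.array([cy_px - iy0, cx_px - ix0])
    excl = [np.asarray(e, dtype=float) for e in exclusion_centers]

    rng = np.random.default_rng(int(seed))
    bg_sums: list[float] = []
    tries = 0
    while len(bg_sums) < n_background:
        if tries >= max_tries:
            raise RuntimeError(
                "cell too small for background ROI: no valid placement "
                f"after {max_tries} tries"
            )
        tries += 1
        iy = int(rng.integers(0, image.shape[0]))
        ix = int(rng.integers(0, image.shape[1]))
        if not cell_mask[iy, ix]:
            continue
        if (iy + dy.min() < 0 or iy + dy.max() >= image.shape[0] or
                ix + dx.min() < 0 or ix + dx.max() >= image.shape[1]):
            continue
        c_um = (np.array([iy, ix], dtype=float) + frac) * pixel_size
        if any(np.linalg.norm(c_um - e) < 2.0 * radius for e in excl):
            continue
        bg_sums.append(float(image[iy + dy, ix + dx].sum()))

    background = float(np.median(bg_sums))
    return total, background, total - background


def _sample_bilinear(image: np.ndarray, points_px: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at (y, x) pixel coordinates."""
    return ndimage.map_coordinates(image.astype(float), points_px.T, order=1,
                                   mode="constant", cval=np.nan)


def line_profile(channels: dict[str, np.ndarray], frame, pixel_size: float,
                 half_length: float = 1.0, step: float = 0.05,
                 marker_channel: str = "marker", width: float = 0.5,
                 refine_range: float = 0.5) -> LineProfile:
    """Sample all channels along the signed spindle→astral axis.

    The profile is centred on the marker-channel peak, re-refined along the
    axis within ``refine_range`` µm of the nominal centre (argmax of the
    width-averaged marker profile), then every channel is sampled by
    bilinear interpolation at positions ``t * axis + center`` for t from
    −half_length to +half_length in steps of ``step``.  Intensities are
    averaged across ``width`` µm perpendicular to the line (a wide line
    ROI); negative positions are the spindle side.
    """
    if half_length <= 0 or step <= 0:
        raise ValueError("half_length and step must be > 0")
    shape = next(iter(channels.values())).shape
    axis = np.asarray(frame.axis, dtype=float)
    perp = np.array([axis[1], -axis[0]])
    n_perp = max(1, int(round(width / step)) // 2 * 2 + 1)
    offsets = (np.arange(n_perp) - n_perp // 2) * step

    def sample(channel: np.ndarray, center: np.ndarray,
               ts: np.ndarray) -> np.ndarray:
        pts = (center[None, None, :]
               + ts[:, None, None] * axis[None, None, :]
               + offsets[None, :, None] * perp[None, None, :])
        vals = _sample_bilinear(channel, pts.reshape(-1, 2) / pixel_size)
        return vals.reshape(len(ts), n_perp).mean(axis=1)

    n_half = int(round(half_length / step))
    ts = np.arange(-n_half, n_half + 1) * step

    # Re-centre on the marker peak along the axis.
    n_ref = int(round(refine_range / step))
    ts_ref = np.arange(-n_ref, n_ref + 1) * step
    center = np.asarray(frame.center, dtype=float)
    marker_vals = sample(channels[marker_channel], center, ts_ref)
    if np.all(np.isnan(marker_vals)):
        raise ValueError(
            f"centrosome {getattr(frame, 'centrosome_id', '?')}: marker "
            "profile leaves the image"
        )
    center = center + ts_ref[int(np.nanargmax(marker_vals))] * axis

    # Bounds check: the full profile (with width) must stay inside the image.
    extreme = np.array([center + s * half_length * axis + o * perp
                        for s in (-1, 1) for o in (offsets[0], offsets[-1])])
    lim = (np.array(shape) - 1) * pixel_size
    if np.any(extreme < 0) or np.any(extreme > lim[None, :]):
        raise ValueError(
            f"centrosome {getattr(frame, 'centrosome_id', '?')} (cell "
            f"{getattr(frame, 'cell_id', '?')}): line profile leaves the image"
        )

    values = {name: sample(img, center, ts) for name, img in channels.items()}
    return LineProfile(positions=ts, values=values)


def peak_position(profile: LineProfile, channel: str) -> float:
    """Signed µm position of the channel's maximum along the profile.

    Ties are broken by smallest |position|, then by the spindle (negative)
    side.  Equivalent to a brute-force argmax over the grid.
    """
    v = np.asarray(profile.values[channel], dtype=float)
    if np.all(np.isnan(v)):
        raise ValueError(f"channel {channel}: all-NaN profile")
    vmax = np.nanmax(v)
    candidates = profile.positions[v == vmax]
    # smallest |p| first; among equal |p|, negative (spindle) side first
    key = np.lexsort((candidates > 0, np.abs(candidates)))
    return float(candidates[key[0]])


def quantify_centrosome(channels: dict[str, np.ndarray], frame,
                        pixel_size: float, cell_mask: np.ndarray,
                        exclusion_centers: list[np.ndarray], seed: int,
                        radius: float = 2.0, half_length: float = 1.0,
                        step: float = 0.05, width: float = 0.5,
                        timepoint: float | None = None,
                        stage_label: str = "metaphase") -> QuantRecord:
    """Disk enrichment and line-profile peaks for one centrosome frame."""
    rec = QuantRecord(cell_id=frame.cell_id, centrosome_id=frame.centrosome_id,
                      timepoint=timepoint, stage_label=stage_label,
                      flagged=getattr(frame, "flagged", False))
    for name, img in channels.items():
        d, b, e = disk_enrichment(img, frame.center, radius, pixel_size,
                                  cell_mask, exclusion_centers, seed)
        rec.disk_total[name] = d
        rec.background_total[name] = b
        rec.enrichment[name] = e
    profile = line_profile(channels, frame, pixel_size,
                           half_length=half_length, step=step, width=width)
    for name in channels:
        rec.peak_position[name] = peak_position(profile, name)
    return rec
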