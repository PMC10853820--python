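"""Centrosome and smFISH spot detection, and the signed spindle→astral frame.

Coordinates: (y, x) order, 0-based pixel indices, physical position in µm
equal to index × pixel_size at pixel centres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max


@dataclass
class Spot:
    """A detected diffraction-limited spot."""

    position: np.ndarray   # (y, x) in µm, subpixel
    intensity: float       # background-subtracted peak photons
    score: float           # detection-filter (LoG) response


@dataclass
class CentrosomeFrame:
    """A centrosome centre with its signed spindle→astral unit axis.

    The axis points from the partner centrosome through this one, i.e. away
    from the metaphase plate; signed coordinates along it are negative on the
    spindle side and positive on the astral side.
    """

    center: np.ndarray          # (y, x) µm
    partner_center: np.ndarray  # (y, x) µm
    axis: np.ndarray            # unit vector, positive sense = astral
    cell_id: int = 0
    centrosome_id: int = 0
    flagged: bool = False


def _subpixel_centroid(image: np.ndarray, peak: np.ndarray) -> np.ndarray:
    """Intensity-weighted centroid in a 3x3 window about an integer peak."""
    y, x = int(peak[0]), int(peak[1])
    y0, y1 = max(0, y - 1), min(image.shape[0], y + 2)
    x0, x1 = max(0, x - 1), min(image.shape[1], x + 2)
    win = image[y0:y1, x0:x1]
    win = win - win.min()
    total = win.sum()
    if total <= 0:
        return np.array([float(y), float(x)])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return np.array([(win * yy).sum() / total, (win * xx).sum() / total])


def _robust_threshold(response: np.ndarray, k: float) -> float:
    """median + k * 1.4826 * MAD of the response image (robust k-sigma)."""
    med = float(np.median(response))
    mad = float(np.median(np.abs(response - med)))
    return med + k * 1.4826 * mad


def detect_centrosomes(marker_channel: np.ndarray, pixel_size: float,
                       expected_n: int = 2, min_separation: float = 2.0,
                       smooth_sigma: float = 0.2,
                       k: float = 5.0) -> list[np.ndarray]:
    """Locate up to ``expected_n`` centrosome centres in the marker channel.

    Local maxima of the Gaussian-smoothed marker image above a robust
    median + k·MAD threshold, mutually separated by at least
    ``min_separation`` µm, subpixel-refined by a 3x3 intensity-weighted
    centroid, ordered by descending peak intensity.  Returns centres in µm;
    may return fewer than ``expected_n`` (caller flags the record).

    Parameters
    ----------
    smooth_sigma : float
        Gaussian pre-smoothing scale in µm.
    """
    if marker_channel.size == 0:
        return []
    if expected_n < 1:
        raise ValueError("expected_n must be >= 1")
    # wrap boundary keeps detection exactly equivariant under circular shifts
    smoothed = ndimage.gaussian_filter(marker_channel.astype(float),
                                       smooth_sigma / pixel_size, mode="wrap")
    thr = _robust_threshold(smoothed, k)
    if not np.any(smoothed > thr):  # uniform or featureless image
        return []
    min_dist_px = max(1, int(round(min_separation / pixel_size)))
    peaks = peak_local_max(smoothed, min_distance=min_dist_px,
                           threshold_abs=thr, exclude_border=False)
    if len(peaks) == 0:
        return []
    order = np.argsort(-smoothed[peaks[:, 0], peaks[:, 1]])
    peaks = peaks[order]
    centers: list[np.ndarray] = []
    for p in peaks:
        c = _subpixel_centroid(smoothed, p) * pixel_size
        if all(np.linalg.norm(c - q) >= min_separation for q in centers):
            centers.append(c)
        if len(centers) == expected_n:
            break
    return centers


def build_frames(centers: list[np.ndarray],
                 cell_id: int = 0) -> list[CentrosomeFrame]:
    """Construct the two signed spindle→astral frames of a metaphase cell.

    Requires exactly two centres; each frame's axis is the unit vector from
    the partner centrosome through its own centre, pointing away from the
    midpoint (the metaphase plate).
    """
    if len(centers) != 2:
        raise ValueError(
            f"cell {cell_id}: expected exactly 2 centrosome centers, "
            f"got {len(centers)}"
        )
    frames = []
    for i, (own, partner) in enumerate(((centers[0], centers[1]),
                                        (centers[1], centers[0]))):
        own = np.asarray(own, dtype=float)
        partner = np.asarray(partner, dtype=float)
        axis = own - partner
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError(f"cell {cell_id}: coincident centrosome centers")
        frames.append(CentrosomeFrame(center=own, partner_center=partner,
                                      axis=axis / norm, cell_id=cell_id,
                                      centrosome_id=i))
    return frames


def detect_spots(rna_channel: np.ndarray, pixel_size: float,
                 psf_sigma: float = 0.12, k: float = 5.0) -> list[Spot]:
    """Detect diffraction-limited spots with a Laplacian-of-Gaussian filter.

    The scale-normalised LoG response at scale ``psf_sigma`` is thresholded
    at median + k·MAD (robust, default k = 5); local maxima are refined to
    subpixel by a 3x3 intensity-weighted centroid.  Spots are returned
    sorted by descending filter score.  Intensity is the background-
    subtracted (image − median) value at the peak pixel.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    if k <= 0:
        raise ValueError("k must be > 0")
    img = rna_channel.astype(float)
    sigma_px = psf_sigma / pixel_size
    response = -(sigma_px**2) * ndimage.gaussian_laplace(img, sigma_px,
                                                         mode="wrap")
    thr = _robust_threshold(response, k)
    if not np.any(response > thr):
        return []
    peaks = peak_local_max(response, min_distance=max(1, int(round(sigma_px))),
                           threshold_abs=thr, exclude_border=False)
    background = float(np.median(img))
    spots = []
    for p in peaks:
        pos = _subpixel_centroid(response, p) * pixel_size
        spots.append(Spot(position=pos,
                          intensity=float(img[p[0], p[1]] - background),
                          score=float(response[p[0], p[1]])))
    spots.sort(key=lambda s: -s.score)
    return spots


def match_spots(detected: list[Spot], truth_positions: np.ndarray,
                match_radius: float) -> tuple[int, int, int]:
    """Hungarian matching of detections to ground truth within a radius.

    Returns (true positives, false positives, false negatives).  This is an
    evaluation utility (optimal one-to-one assignment), independent of the
    detection path.
    """
    from scipy.optimize import linear_sum_assignment

    if len(detected) == 0:
        return 0, 0, len(truth_positions)
    if len(truth_positions) == 0:
        return 0, len(detected), 0
    det = np.array([s.position for s in detected])
    cost = np.linalg.norm(det[:, None, :] - truth_positions[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    tp = int(np.sum(cost[rows, cols] <= match_radius))
    return tp, len(detected) - tp, len(truth_positions) - tp
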