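"""Ground-truthed synthetic microscopy scenes of mitotic cells.

Each scene is a 4-channel 2-D image (marker, rna, protein, dna) of one cell
in metaphase-like geometry: two centrosomes ``centrosome_separation`` µm
apart, each with a ring of diffraction-limited RNA spots whose angular
positions follow a von Mises law centred on that centrosome's astral
direction, a protein blob displaced by ``protein_offset`` µm along the signed
spindle→astral axis, and a chromatin band at the metaphase plate.  Pixel
values are Poisson(signal + background) + Normal(0, read_noise_sd), clipped
at zero.  Identical (config, seed) gives bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CHANNELS, SceneConfig, WashoutKinetics, spawn_seeds


@dataclass
class GroundTruth:
    """Simulation ground truth, all positions in µm, (y, x) order."""

    centrosome_centers: np.ndarray        # (2, 2): two (y, x) points
    spindle_axes: np.ndarray              # (2, 2): unit vectors, astral = +
    rna_positions: np.ndarray             # (N, 2) all RNA spot positions
    rna_centrosome_ids: np.ndarray        # (N,) 0/1 for ring spots, -1 free
    protein_offset_true: float            # µm, signed
    stage_label: str
    rna_astral_bias: float = 0.0
    timepoint: float | None = None        # hours, set by the time-course
    cell_id: int = 0

    @property
    def midpoint(self) -> np.ndarray:
        return self.centrosome_centers.mean(axis=0)


def _add_gaussian(image: np.ndarray, center_px: np.ndarray, sigma_px: float,
                  amplitude: float, n_sigma: float = 6.0) -> None:
    """Add ``amplitude * exp(-r^2 / 2 sigma^2)`` in-place, windowed for speed."""
    cy, cx = center_px
    r = int(np.ceil(n_sigma * sigma_px)) + 1
    y0, y1 = max(0, int(cy) - r), min(image.shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(image.shape[1], int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1, dtype=float)[:, None]
    xx = np.arange(x0, x1, dtype=float)[None, :]
    image[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma_px**2)
    )


def _scene_geometry(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Centrosome centres and signed astral unit axes, in µm.

    The spindle axis lies along x through the image centre; each astral
    direction points away from the inter-centrosome midpoint.
    """
    ey, ex = config.field_extent
    mid = np.array([ey / 2.0, ex / 2.0])
    half = config.centrosome_separation / 2.0
    centers = np.array([mid + [0.0, -half], mid + [0.0, +half]])
    axes = centers - mid
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    return centers, axes


def _sample_ring_spots(rng: np.random.Generator, config: SceneConfig,
                       center: np.ndarray, axis: np.ndarray,
                       n: int) -> np.ndarray:
    """RNA positions on the pericentrosomal ring, von Mises-biased astral."""
    mu = float(np.arctan2(axis[0], axis[1]))  # angle of the astral direction
    kappa = config.rna_astral_bias
    if kappa > 0:
        theta = rng.vonmises(mu, kappa, size=n)
    else:
        theta = rng.uniform(-np.pi, np.pi, size=n)
    radius = config.rna_ring_radius + rng.normal(0.0, config.rna_ring_jitter, n)
    radius = np.abs(radius)
    dy = radius * np.sin(theta)
    dx = radius * np.cos(theta)
    return center + np.column_stack([dy, dx])


def _sample_free_spots(rng: np.random.Generator, config: SceneConfig,
                       mid: np.ndarray, n: int) -> np.ndarray:
    """Cytoplasmic RNA uniform in the cell disk (rejection sampling)."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = rng.uniform(-1.0, 1.0, size=(2 * (n - filled) + 8, 2))
        cand = cand[(cand**2).sum(axis=1) <= 1.0]
        take = min(len(cand), n - filled)
        out[filled:filled + take] = mid + config.cell_radius * cand[:take]
        filled += take
    return out


def simulate_cell(config: SceneConfig, seed: int,
                  timepoint: float | None = None,
                  cell_id: int = 0) -> tuple[np.ndarray, GroundTruth]:
    """Render one cell; returns (stack of shape (4, Y, X), GroundTruth).

    Channel order is :data:`centrofish.config.CHANNELS`
    (marker, rna, protein, dna).
    """
    config.validate()
    rng = np.random.default_rng(int(seed))
    px = config.pixel_size
    centers, axes = _scene_geometry(config)
    mid = centers.mean(axis=0)

    ring, ring_ids = [], []
    for i in range(2):
        pts = _sample_ring_spots(rng, config, centers[i], axes[i],
                                 config.n_rna_centrosomal)
        ring.append(pts)
        ring_ids.append(np.full(len(pts), i))
    free = _sample_free_spots(rng, config, mid, config.n_rna_free)
    rna_positions = np.concatenate(ring + [free], axis=0)
    rna_ids = np.concatenate(ring_ids + [np.full(len(free), -1)], axis=0)

    amp = config.channel_amplitudes
    stack = np.zeros((len(CHANNELS),) + tuple(config.image_shape), dtype=float)
    marker, rna, protein, dna = stack

    for c in centers:
        _add_gaussian(marker, c / px, config.marker_sigma / px, amp["marker"])
    for p in rna_positions:
        _add_gaussian(rna, p / px, config.psf_sigma / px, amp["rna"])
    for c, a in zip(centers, axes):
        blob = c + config.protein_offset * a
        _add_gaussian(protein, blob / px, config.protein_sigma / px, amp["protein"])

    # Metaphase plate: chromatin band at the midplane, elongated
    # perpendicular to the spindle axis.
    if config.stage_label == "metaphase" and amp["dna"] > 0:
        along = 0.6  # µm thickness along the spindle axis
        across = 3.0  # µm half-extent across it
        for t in np.linspace(-across, across, 25):
            perp = np.array([axes[1][1], -axes[1][0]])
            _add_gaussian(dna, (mid + t * perp) / px, along / px, amp["dna"])

    # Cell-interior background, then photon statistics.
    yy = (np.arange(config.image_shape[0]) + 0.0)[:, None] * px
    xx = (np.arange(config.image_shape[1]) + 0.0)[None, :] * px
    in_cell = (yy - mid[0]) ** 2 + (xx - mid[1]) ** 2 <= config.cell_radius**2
    stack += config.background_level * in_cell

    if config.noise:
        stack = rng.poisson(stack).astype(float)
        stack += rng.normal(0.0, config.read_noise_sd, size=stack.shape)
        np.clip(stack, 0.0, None, out=stack)

    truth = GroundTruth(
        centrosome_centers=centers,
        spindle_axes=axes,
        rna_positions=rna_positions,
        rna_centrosome_ids=rna_ids,
        protein_offset_true=config.protein_offset,
        stage_label=config.stage_label,
        rna_astral_bias=config.rna_astral_bias,
        timepoint=timepoint,
        cell_id=cell_id,
    )
    return stack, truth


def cell_mask(config: SceneConfig) -> np.ndarray:
    """Boolean mask of pixels whose centres lie inside the cell disk."""
    px = config.pixel_size
    ey, ex = config.field_extent
    mid = np.array([ey / 2.0, ex / 2.0])
    yy = np.arange(config.image_shape[0])[:, None] * px
    xx = np.arange(config.image_shape[1])[None, :] * px
    return (yy - mid[0]) ** 2 + (xx - mid[1]) ** 2 <= config.cell_radius**2


def centrosomal_rna_count(config: SceneConfig, kinetics: WashoutKinetics,
                          t: float) -> int:
    """Ring spots per centrosome at washout time ``t`` (hours)."""
    return int(round(config.n_rna_centrosomal * kinetics.recovered_fraction(t)))


def simulate_timecourse(
    config: SceneConfig,
    kinetics: WashoutKinetics,
    n_cells_per_timepoint: int,
    seed: int,
) -> list[tuple[float, np.ndarray, GroundTruth]]:
    """Washout time-course: cells fixed at each timepoint of the kinetics grid.

    At time ``t`` the ring-spot count per centrosome is
    ``round(n_rna_centrosomal * r(t))`` with r(t) the lag-then-ramp recovery;
    the free (cytoplasmic) RNA count is constant.  Deterministic per seed.

    Returns a flat list of (timepoint_hours, stack, truth) with
    ``truth.timepoint`` and ``truth.cell_id`` set.
    """
    config.validate()
    kinetics.validate()
    if n_cells_per_timepoint < 1:
        raise ValueError("n_cells_per_timepoint must be >= 1")

    from dataclasses import replace

    timepoints = [float(t) for t in kinetics.timepoints]
    seeds = spawn_seeds(seed, len(timepoints) * n_cells_per_timepoint)
    out = []
    k = 0
    for t in timepoints:
        n_ring = centrosomal_rna_count(config, kinetics, t)
        cfg_t = replace(config, n_rna_centrosomal=n_ring)
        for cell in range(n_cells_per_timepoint):
            stack, truth = simulate_cell(cfg_t, seeds[k], timepoint=t,
                                         cell_id=cell)
            out.append((t, stack, truth))
            k += 1
    return out
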