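"""Configuration objects for the synthetic scene generator and the pipeline.

All physical quantities are in micrometres (µm) and photons; times in hours.
Images follow the (y, x) axis order with the origin at the image corner and
physical position = pixel index × ``pixel_size`` at pixel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

STAGE_LABELS = ("G2", "prometaphase", "metaphase")

#: Default channel order of every simulated stack.
CHANNELS = ("marker", "rna", "protein", "dna")


class ConfigError(ValueError):
    """Raised when a configuration field violates its contract; names the field."""


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {message}")


@dataclass
class SceneConfig:
    """Parameters of one simulated mitotic cell.

    The scene is a 2-D maximum-intensity-projection analogue: two centrosomes
    on a spindle axis, diffraction-limited RNA spots ringing each centrosome
    with a von Mises angular bias toward the astral side, a protein blob
    displaced along the signed spindle→astral axis, and a DNA band at the
    metaphase plate.  Amplitudes are photon counts; noise is Poisson shot
    noise plus Gaussian read noise.
    """

    image_shape: tuple[int, int] = (224, 224)  # (Y, X) pixels
    pixel_size: float = 0.1          # µm / pixel
    psf_sigma: float = 0.12          # µm, isotropic Gaussian PSF
    centrosome_separation: float = 8.0   # µm between the two poles
    cell_radius: float = 10.0        # µm
    n_rna_centrosomal: int = 15      # spots ringing each centrosome
    n_rna_free: int = 40             # cytoplasmic spots per cell
    rna_ring_radius: float = 0.6     # µm, ring radius about each centrosome
    rna_ring_jitter: float = 0.1     # µm, radial SD about the ring
    rna_astral_bias: float = 2.0     # von Mises κ toward the astral direction
    protein_offset: float = -0.3     # µm along the axis; negative = spindle side
    protein_sigma: float = 0.5       # µm, protein blob SD
    marker_sigma: float = 0.25       # µm, pericentriolar-material blob SD
    channel_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"marker": 800.0, "rna": 150.0,
                                 "protein": 800.0, "dna": 100.0}
    )
    background_level: float = 20.0   # photons / pixel inside the cell
    read_noise_sd: float = 2.0       # photons
    noise: bool = True               # Poisson + read noise; False = noiseless render
    stage_label: str = "metaphase"

    def validate(self) -> "SceneConfig":
        _require(len(self.image_shape) == 2 and min(self.image_shape) > 0,
                 "image_shape", "must be a positive (Y, X) pair")
        _require(self.pixel_size > 0, "pixel_size", "must be > 0")
        _require(self.psf_sigma > 0, "psf_sigma", "must be > 0")
        _require(self.rna_ring_radius >= 0, "rna_ring_radius", "must be >= 0")
        _require(self.rna_ring_jitter >= 0, "rna_ring_jitter", "must be >= 0")
        _require(self.rna_astral_bias >= 0, "rna_astral_bias",
                 "von Mises concentration must be >= 0")
        _require(self.cell_radius > 0, "cell_radius", "must be > 0")
        _require(self.centrosome_separation > 0, "centrosome_separation",
                 "must be > 0")
        _require(self.centrosome_separation < 2 * self.cell_radius,
                 "centrosome_separation", "poles must fit inside the cell")
        _require(self.n_rna_centrosomal >= 0, "n_rna_centrosomal", "must be >= 0")
        _require(self.n_rna_free >= 0, "n_rna_free", "must be >= 0")
        _require(self.protein_sigma > 0, "protein_sigma", "must be > 0")
        _require(self.marker_sigma > 0, "marker_sigma", "must be > 0")
        _require(self.background_level >= 0, "background_level", "must be >= 0")
        _require(self.read_noise_sd >= 0, "read_noise_sd", "must be >= 0")
        _require(self.stage_label in STAGE_LABELS, "stage_label",
                 f"must be one of {STAGE_LABELS}")
        missing = [c for c in CHANNELS if c not in self.channel_amplitudes]
        _require(not missing, "channel_amplitudes", f"missing channels {missing}")
        _require(all(v >= 0 for v in self.channel_amplitudes.values()),
                 "channel_amplitudes", "must be >= 0")
        return self

    @property
    def field_extent(self) -> tuple[float, float]:
        """Physical (Y, X) extent of the image in µm."""
        return (self.image_shape[0] * self.pixel_size,
                self.image_shape[1] * self.pixel_size)

    def to_dict(self) -> dict:
        return asdict(self)


# Grid of fixation times after removal of the translation inhibitor, in
# hours: 0, 10, 45 min, then 1, 2, 3, 4 h.
WASHOUT_TIMEPOINTS_H = (0.0, 10 / 60, 45 / 60, 1.0, 2.0, 3.0, 4.0)


@dataclass
class WashoutKinetics:
    """Recovery of centrosomal RNA after translation-inhibitor washout.

    The recovered fraction r(t) is 0 up to and including ``lag`` and rises
    linearly to ``recover_fraction`` at ``end_time``.  Defaults encode a
    partial (60 %) recovery whose first visible grid timepoint is 3 h: the
    ramp starts at 2.5 h, between the 2 h and 3 h fixation points.
    """

    lag: float = 2.5              # hours; r(t) = 0 for t <= lag
    recover_fraction: float = 0.6  # fraction of pre-treatment count at end_time
    end_time: float = 4.0          # hours
    timepoints: tuple[float, ...] = WASHOUT_TIMEPOINTS_H

    def validate(self) -> "WashoutKinetics":
        _require(0.0 <= self.recover_fraction <= 1.0, "recover_fraction",
                 "must lie in [0, 1]")
        _require(self.lag <= self.end_time, "lag", "must be <= end_time")
        tp = tuple(float(t) for t in self.timepoints)
        _require(len(tp) >= 1 and tp[0] == 0.0, "timepoints",
                 "first timepoint must be 0")
        _require(all(a < b for a, b in zip(tp, tp[1:])), "timepoints",
                 "must be strictly ascending")
        return self

    def recovered_fraction(self, t: float) -> float:
        """r(t): 0 through the lag, then a linear ramp to recover_fraction."""
        if t <= self.lag:
            return 0.0
        if t >= self.end_time:
            return self.recover_fraction
        if self.end_time == self.lag:
            return self.recover_fraction
        return self.recover_fraction * (t - self.lag) / (self.end_time - self.lag)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (images → detections → stats)."""

    images_dir: str = "."
    out_dir: str = "out"
    channel_map: dict[str, int] = field(
        default_factory=lambda: {name: i for i, name in enumerate(CHANNELS)}
    )
    pixel_size: float | None = None   # µm override when metadata is absent
    seed: int = 0
    alpha: float = 0.05
    roi_radius: float = 2.0           # µm disk about the centrosome
    half_length: float = 1.0          # µm, line-profile half length
    profile_step: float = 0.05        # µm
    line_width: float = 0.5           # µm, perpendicular averaging width
    analysis_channel: str = "rna"
    expected_centrosomes: int = 2
    min_separation: float = 2.0       # µm between detected centrosomes

    def validate(self) -> "RunConfig":
        _require("marker" in self.channel_map, "channel_map",
                 "must map the 'marker' channel")
        _require(len(self.channel_map) >= 2, "channel_map",
                 "must map at least one signal channel besides the marker")
        for name in ("alpha", "roi_radius", "half_length", "profile_step",
                     "line_width", "min_separation"):
            _require(getattr(self, name) > 0, name, "must be > 0")
        if self.pixel_size is not None:
            _require(self.pixel_size > 0, "pixel_size", "must be > 0")
        _require(self.alpha < 1, "alpha", "must be < 1")
        _require(self.expected_centrosomes >= 1, "expected_centrosomes",
                 "must be >= 1")
        _require(self.analysis_channel in self.channel_map, "analysis_channel",
                 "must be a mapped channel")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of every analysis parameter; stamped on all
        outputs.  The output directory is excluded — it does not affect
        the computation."""
        import hashlib
        import json

        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) for s in ss.generate_state(n) % (2**31)]
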