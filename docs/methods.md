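# Methods

## Scope and model

`centrofish` quantifies the spatial relationship between an RNA, its encoded
protein, and the mitotic centrosome in 2-D fluorescence images. All analysis
operates on maximum-intensity-projection-equivalent 2-D planes; the optical
model is an isotropic Gaussian point-spread function. The package treats one
mitotic cell per analyzed field, with exactly two centrosomes (the metaphase
assumption); multi-cell fields need a prior crop or cell map.

### Geometry: the signed spindle→astral frame

A metaphase cell has two centrosomes flanking the metaphase plate. For each
centrosome the package defines a signed 1-D coordinate along the unit vector
from its partner through itself. Positive coordinates face the cell cortex
(astral microtubules), negative coordinates face the plate/spindle. Every
peak-position statistic is reported in this frame, so "RNA astral, protein
spindle-side" appears as mean RNA peak > 0 and mean protein peak < 0.

### Synthetic scenes

The generator renders what the analysis assumes, with ground truth:

| parameter | default | meaning |
|---|---|---|
| `pixel_size` | 0.1 µm/px | typical 60–100× camera sampling |
| `psf_sigma` | 0.12 µm | diffraction-limited Gaussian PSF |
| `image_shape` | 224 × 224 px | 22.4 µm field holding one cell |
| `cell_radius` | 10 µm | HeLa-like mitotic cell |
| `centrosome_separation` | 8 µm | metaphase pole-to-pole distance |
| `marker_sigma` | 0.25 µm | pericentriolar-material blob width |
| `n_rna_centrosomal` | 15 /centrosome | ring spot count (not calibrated by data; tunable) |
| `rna_ring_radius` | 0.6 µm (jitter SD 0.1) | pericentrosomal ring radius |
| `rna_astral_bias` | κ = 2 | von Mises concentration toward the astral direction |
| `n_rna_free` | 40 /cell | cytoplasmic RNA spots |
| `protein_offset` | −0.3 µm | protein blob displacement (spindle side) |
| `protein_sigma` | 0.5 µm | protein blob width |
| amplitudes | marker 800, rna 150, protein 800, dna 100 photons | peak photons per object |
| `background_level` | 20 photons/px | cytoplasmic autofluorescence inside the cell |
| `read_noise_sd` | 2 photons | camera read noise |

RNA ring angles are drawn from a von Mises law centred on each centrosome's
astral direction; κ = 0 reduces to uniform. Pixel values are
Poisson(signal + background) + N(0, read_noise²), clipped at zero. Identical
(config, seed) gives bitwise-identical output.

Washout time-courses use a lag-then-ramp recovery: the centrosomal ring spot
count per centrosome at time *t* is `round(n · r(t))` with r(t) = 0 for
t ≤ lag, rising linearly to `recover_fraction` at `end_time`; cytoplasmic
spot counts are constant. A ramp (rather than a sigmoid or exponential) is
the weakest assumption consistent with a monotone, partial recovery;
`recover_fraction` defaults to 0.6 < 1 because the system does not return to
baseline within 4 h. The default lag is **2.5 h** with the fixation grid
0, 10, 45 min, 1, 2, 3, 4 h, so the first fixation timepoint with any
recovered RNA is 3 h — the observable the recovery-onset statistic is
designed to reproduce. (A lag placed exactly on the 3 h grid point would,
under the r(lag) = 0 ramp convention, push the first nonzero fixation point
to 4 h.)

**What the generator does not emulate:** spot brightness heterogeneity
(amplitudes are constant per channel, keeping detection benchmarks sharp),
optical aberrations and z-dependent blur, deconvolution artifacts,
photobleaching, neighbouring cells, and any cell-cycle structure beyond the
stage label. Green tests therefore establish correctness of the measurement
procedures on images matching these assumptions, not detector performance on
real micrographs.

## Detection

Centrosomes: the marker channel is Gaussian-smoothed (0.2 µm), local maxima
above a robust threshold are ranked by intensity, subject to a mutual
minimum separation (default 2 µm), and refined to subpixel precision with a
3×3 intensity-weighted centroid.

Spots: scale-normalized Laplacian-of-Gaussian response at the PSF scale;
local maxima above `median + k · 1.4826 · MAD` of the response image are
kept (default k = 5) and centroid-refined. The 1.4826 factor makes the MAD a
consistent estimate of the noise SD, so k is an effective sigma-multiple;
with k = 5 a blank 224² noise image yields ≪ 1 false detection on average
while spots at peak-SNR ≈ 5 are recovered with F1 > 0.9. Filters use wrap
(circular) boundary handling, which also makes detection exactly
equivariant under circular integer-pixel shifts away from the seam.

## Quantification

**Disk enrichment.** The measurement disk contains every pixel whose centre
lies within the radius (default 2 µm, read as a radius; configurable if a
diameter reading is preferred) — pixel-centre membership, no partial-pixel
weighting, matching common ROI-tool behaviour and enabling exact brute-force
verification. Background is the median of 10 seeded random placements of
the *identical translated pixel stencil* inside the cell mask, each at
least 2× radius from every centrosome and fully inside the image; the
stencil reuse guarantees equal pixel counts (uniform image → enrichment
exactly 0) and sidesteps floating-point boundary flips for pixels at
exactly the radius (a 20 px radius hits 12-16-20 Pythagorean boundary
pixels). The median (not mean) is robust to a background disk landing on a
bright cytoplasmic spot cluster. Enrichment = disk − background and may be
negative.

**Line profiles.** The profile is centred on the marker peak re-refined
along the axis (±0.5 µm search at the profile step), then all channels are
sampled by bilinear interpolation from −1 to +1 µm at 0.05 µm steps,
averaged over a 0.5 µm perpendicular width — the analogue of a wide
hand-drawn line ROI, which both suppresses single-pixel noise at the peak
and lets a discrete RNA ring register even when no spot lies exactly on the
axis. The peak position is the grid argmax; exact ties resolve to the
smallest |position|, then the spindle (negative) side. The tie rule
matters only for degenerate (constant or symmetric) profiles.

## Statistics

- **Two-sample test:** Welch's unequal-variance t-test, two-sided. Welch is
  the safer default when only "two-sided t-test" is specified; the
  zero-variance degenerate case returns p = 1 for equal means.
- **Sample sizing:** smallest integer per-group n whose noncentral-t power
  meets the target (default α = 0.05, power 0.8), verified by simulation.
- **Recovery onset:** each post-0 timepoint vs the 0-minute group; onset is
  the earliest with p < α *and* a positive mean difference (relocalization
  is directional; the two-sided test is gated rather than replaced by a
  one-sided one). No multiple-testing correction by default, matching common
  reporting practice for such time-courses; a Holm option exists
  (`holm=True`) and is the appropriate choice when the cost of a false
  early onset matters — with five pre-recovery timepoints at α = 0.05,
  ~1 replicate in 8 shows a spurious early onset uncorrected.
- **Translation time:** ORF codons / (rate aa s⁻¹) / 60, with a convenience
  rounding to the nearest 5 minutes; the packaged ASPM ORF constant is
  3477 codons, giving 9.66 ≈ 10 min at the standard 6 aa/s.

## Probe design

All windows of 26–32 nt with GC in [0.40, 0.60] (inclusive) are enumerated;
N counts as non-GC. Selection is a deterministic greedy left-to-right scan:
the earliest admissible start wins, the window at that start with GC closest
to 0.50 (ties: shorter, then enumeration order) is taken, and subsequent
probes must start at least `min_spacing` (default 2 nt) past the previous
end, up to 48 probes. Thermodynamic (ΔG) scoring of full probe-design
pipelines is deliberately not reimplemented — only the stated length/GC
rules — so probe sets here are tilings, not specificity-screened designs.
Probes are reported in transcript (sense) coordinates with an option to emit
reverse complements (the hybridizing strand). Every emitted oligo is the
probe sequence plus the shared secondary-hybridization overhang; the
secondary oligo is mixed at a 20 % molar excess over the total primary
concentration (20 µM → 24 µM).

## Numerical and degenerate-input conventions

- Coordinates: (y, x) order, 0-based pixel indices, physical position =
  index × pixel_size at pixel centres; origin at the image corner.
- Seeds: every stochastic step takes an explicit seed; time-courses and
  multi-cell runs derive child seeds via `numpy.random.SeedSequence`
  spawning, keeping all derived seeds below 2³¹.
- Fewer than the expected number of centrosomes → the cell is flagged and
  skipped by the pipeline (fatal only when no cell quantifies).
- A line profile (including its perpendicular width) leaving the image is an
  error naming the centrosome; an all-NaN channel is an error.
- Background ROI placement failing 1000 times (tiny cell mask) raises
  "cell too small for background ROI".

## Known limitations

- 2-D only; the 0.5 µm line width and disk ROI will mix z-structure that a
  3-D analysis would separate.
- The ring-spot count per centrosome is a free parameter, not calibrated
  against any measured RNA count.
- The uncorrected onset rule inherits the per-timepoint false-positive rate
  of its α; see the Holm note above.
- Probe selection maximizes neither coverage nor thermodynamic uniformity;
  it is the printed-rule reduction described above.
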