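"""Seeded synthetic endoscope videos and fluorescence pairs with ground truth.

The clinical recordings behind the applicator-stability study — ten-minute
intraoral endoscope videos of a fiducial ink mark, and pre/post-irradiation
PpIX fluorescence photographs — are not publicly deposited. This module
generates stand-ins with the statistical structure those analyses assume, and
returns the exact ground truth alongside, so every downstream stage
(k-means marker tracking, displacement statistics, photobleached-area
quantification) can be validated by parameter recovery.

Motion model
------------
The marker centroid follows

    position(t) = baseline + drift_rate * t + jitter(t) + sum_e pulse_e(t)

with isotropic per-frame Gaussian jitter, a constant slow drift, and sporadic
"swallow" excursions: raised-cosine pulses of finite support whose start
frames form a discretised Poisson process. Swallowing moves the cheek
predominantly horizontally, so the horizontal pulse amplitude is configured
independently of (and by default larger than) the vertical one.

Determinism
-----------
Every generator is a pure function of its parameters. A single integer seed
drives all draws via numpy ``SeedSequence``-style stream splitting:
stream 0 = marker motion, stream 1 = frame rendering noise,
stream 2 = fluorescence pair noise. Two calls with equal inputs produce
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as _draw_ellipse

from .exceptions import InvalidParameterError, OutOfBoundsError
from .frames import FrameSequence, read_frames, write_frames  # noqa: F401  (re-export)

_MOTION_STREAM = 0
_RENDER_STREAM = 1
_FLUOR_STREAM = 2


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class MotionParams:
    """Marker motion model parameters (pixel units unless noted).

    ``swallow_rate`` is an expected event count per *minute*; default frame
    geometry elsewhere is 15 frames/s over a 10-minute recording, but any
    positive ``frame_rate``/``n_frames`` combination is accepted.
    """

    baseline_position: tuple[float, float] = (320.0, 240.0)  # (x, y) px
    jitter_sd: float = 2.0                   # px, isotropic Gaussian per frame
    drift_rate: tuple[float, float] = (0.0, 0.0)  # px/frame
    swallow_rate: float = 1.0                # expected events / minute
    swallow_amplitude_h: float = 30.0        # px, peak horizontal excursion
    swallow_amplitude_v: float = 15.0        # px, peak vertical excursion
    swallow_duration: int = 20               # frames per pulse
    frame_rate: float = 15.0                 # frames / s
    n_frames: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise InvalidParameterError(f"n_frames must be >= 1, got {self.n_frames}")
        if not self.frame_rate > 0:
            raise InvalidParameterError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.swallow_duration < 1:
            raise InvalidParameterError("swallow_duration must be a positive frame count")
        for name in ("jitter_sd", "swallow_rate", "swallow_amplitude_h",
                     "swallow_amplitude_v"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")


@dataclass
class SceneParams:
    """Scene appearance: three color classes (ink mark, tissue, applicator).

    Defaults render a dark blue-black ink mark on pink mucosa framed by a
    white applicator band. All colors are RGB triples in [0, 255] and must be
    pairwise distinct so that color clustering is well posed.
    """

    frame_size: tuple[int, int] = (480, 640)          # (height, width) px
    marker_color: tuple[int, int, int] = (30, 30, 120)
    tissue_color: tuple[int, int, int] = (225, 160, 160)
    applicator_color: tuple[int, int, int] = (245, 245, 245)
    marker_diameter_px: float = 20.0
    marker_aspect: float = 1.0        # vertical/horizontal semi-axis ratio
    applicator_band_px: int = 32      # border band width drawn on every edge
    color_noise_sd: float = 4.0       # Gaussian per channel, clipped to [0,255]
    vignette_strength: float = 0.0    # 0 = none; 1 = black at the corners

    def __post_init__(self):
        colors = [tuple(self.marker_color), tuple(self.tissue_color),
                  tuple(self.applicator_color)]
        if len(set(colors)) != 3:
            raise InvalidParameterError("marker, tissue and applicator colors must be pairwise distinct")
        for c in colors:
            if any(not 0 <= v <= 255 for v in c):
                raise InvalidParameterError(f"color {c} outside [0, 255]")
        if not self.marker_diameter_px > 0:
            raise InvalidParameterError("marker_diameter_px must be > 0")
        if not 0 < self.marker_aspect <= 1.5:
            raise InvalidParameterError("marker_aspect must be in (0, 1.5]")
        if self.color_noise_sd < 0:
            raise InvalidParameterError("color_noise_sd must be non-negative")
        if not 0 <= self.vignette_strength <= 1:
            raise InvalidParameterError("vignette_strength must be in [0, 1]")


@dataclass
class GroundTruthTrajectory:
    """True marker-centre positions per frame, with swallow event bookkeeping."""

    positions: np.ndarray                 # (n_frames, 2) float, (x, y) px
    swallow_event_frames: list[int]       # pulse start frames
    params: MotionParams

    def to_jsonable(self) -> dict:
        return {
            "positions": self.positions.tolist(),
            "swallow_event_frames": [int(f) for f in self.swallow_event_frames],
        }


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def _raised_cosine(duration: int) -> np.ndarray:
    """Unit-peak smooth pulse over ``duration`` frames (0 at both ends)."""
    t = np.arange(duration)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 0.5) / duration))


def simulate_trajectory(params: MotionParams) -> GroundTruthTrajectory:
    """Simulate the fiducial-mark centre over a recording.

    Positions are baseline + cumulative drift + per-frame Gaussian jitter +
    additive raised-cosine swallow excursions at Poisson-distributed start
    times. Each event carries one random sign shared by its horizontal and
    vertical components (the cheek moves as a unit); amplitudes are the
    configured per-axis peaks. Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng([params.seed, _MOTION_STREAM])
    n = params.n_frames
    base = np.asarray(params.baseline_position, dtype=float)
    drift = np.outer(np.arange(n), np.asarray(params.drift_rate, dtype=float))
    jitter = rng.normal(0.0, params.jitter_sd, size=(n, 2)) if params.jitter_sd > 0 \
        else np.zeros((n, 2))

    positions = base + drift + jitter

    # discretised Poisson process: per-frame event-start probability
    p_event = params.swallow_rate / (60.0 * params.frame_rate)
    event_frames: list[int] = []
    if params.swallow_rate > 0 and p_event > 0:
        starts = np.flatnonzero(rng.random(n) < p_event)
        pulse = _raised_cosine(params.swallow_duration)
        amp = np.array([params.swallow_amplitude_h, params.swallow_amplitude_v])
        for f in starts:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            stop = min(n, f + params.swallow_duration)
            positions[f:stop] += sign * np.outer(pulse[: stop - f], amp)
            event_frames.append(int(f))

    return GroundTruthTrajectory(positions, event_frames, params)


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------

def render_frames(truth: GroundTruthTrajectory, scene: SceneParams) -> FrameSequence:
    """Rasterise a ground-truth trajectory into an endoscope-like video.

    Each frame paints tissue background, an applicator-colored border band,
    and an ellipse of ``marker_color`` centred at the true position; then
    applies an optional radial vignette and i.i.d. Gaussian color noise
    clipped to [0, 255]. With zero noise and zero vignette, the pixel at the
    (rounded) true centre is exactly ``marker_color``.

    Raises :class:`OutOfBoundsError` (naming the frame) if the marker ellipse
    would not fit fully inside the frame.
    """
    h, w = scene.frame_size
    a = scene.marker_diameter_px / 2.0            # horizontal semi-axis
    b = a * scene.marker_aspect                   # vertical semi-axis
    band = scene.applicator_band_px

    for i, (x, y) in enumerate(truth.positions):
        if not (a <= x <= w - 1 - a and b <= y <= h - 1 - b):
            raise OutOfBoundsError(i)

    template = np.empty((h, w, 3), dtype=float)
    template[:] = scene.tissue_color
    if band > 0:
        template[:band] = scene.applicator_color
        template[-band:] = scene.applicator_color
        template[:, :band] = scene.applicator_color
        template[:, -band:] = scene.applicator_color

    if scene.vignette_strength > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        r2 = ((xx - (w - 1) / 2) ** 2 + (yy - (h - 1) / 2) ** 2)
        vignette = 1.0 - scene.vignette_strength * (r2 / r2.max())
    else:
        vignette = None

    rng = np.random.default_rng([truth.params.seed, _RENDER_STREAM])
    frames = np.empty((len(truth.positions), h, w, 3), dtype=np.uint8)
    for i, (x, y) in enumerate(truth.positions):
        img = template.copy()
        # +eps includes boundary lattice points, matching the continuous area
        rr, cc = _draw_ellipse(y, x, b + 1e-7, a + 1e-7, shape=(h, w))
        img[rr, cc] = scene.marker_color
        if vignette is not None:
            img *= vignette[..., None]
        if scene.color_noise_sd > 0:
            img += rng.normal(0.0, scene.color_noise_sd, size=img.shape)
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    metadata = {
        "ground_truth": truth.to_jsonable(),
        "scene": {
            "marker_diameter_px": scene.marker_diameter_px,
            "marker_color": list(scene.marker_color),
        },
    }
    return FrameSequence(frames, truth.params.frame_rate, metadata=metadata)


def simulate_video(motion: MotionParams, scene: SceneParams | None = None) -> FrameSequence:
    """Convenience: :func:`simulate_trajectory` then :func:`render_frames`."""
    return render_frames(simulate_trajectory(motion), scene or SceneParams())


# ---------------------------------------------------------------------------
# fluorescence pairs
# ---------------------------------------------------------------------------

@dataclass
class FluorescenceParams:
    """Synthetic pre/post PpIX fluorescence pair parameters.

    The pre-irradiation image shows an elevated-intensity elliptical lesion
    on a dim tissue background; after irradiation every pixel inside a larger
    concentric "bleached" ellipse loses ``drop_fraction`` of its intensity
    (photobleaching extends beyond the lesion, as the treatment margins
    require). Areas are requested in cm² and rasterised at ``pixels_per_cm``.
    """

    image_size: tuple[int, int] = (480, 640)
    pixels_per_cm: float = 100.0
    lesion_area_cm2: float = 1.2
    bleach_area_cm2: float = 4.9
    lesion_aspect: float = 0.75
    bleach_aspect: float = 0.85
    background_intensity: float = 40.0
    lesion_intensity: float = 180.0
    drop_fraction: float = 0.5
    noise_sd: float = 3.0
    center: tuple[float, float] | None = None   # (x, y) px; image centre if None

    def __post_init__(self):
        if not self.pixels_per_cm > 0:
            raise InvalidParameterError("pixels_per_cm must be > 0")
        if not self.lesion_area_cm2 > 0:
            raise InvalidParameterError("lesion_area_cm2 must be > 0")
        if self.bleach_area_cm2 < self.lesion_area_cm2:
            raise InvalidParameterError(
                "bleach_area_cm2 must be >= lesion_area_cm2 "
                f"({self.bleach_area_cm2} < {self.lesion_area_cm2})"
            )
        if not 0 <= self.drop_fraction < 1:
            raise InvalidParameterError("drop_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")


@dataclass
class SyntheticFluorescenceTruth:
    """Exact masks and areas behind a synthetic fluorescence pair."""

    lesion_mask: np.ndarray        # bool, HxW
    bleach_mask: np.ndarray        # bool, HxW; superset of lesion_mask
    lesion_area_cm2: float         # pixel count / pixels_per_cm^2
    bleach_area_cm2: float
    pixels_per_cm: float


def _ellipse_mask(shape, center_xy, area_px, aspect) -> np.ndarray:
    """Axis-aligned filled ellipse of (approximately) ``area_px`` pixels."""
    a = np.sqrt(area_px / (np.pi * aspect))   # horizontal semi-axis
    b = a * aspect
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _draw_ellipse(center_xy[1], center_xy[0], b + 1e-7, a + 1e-7, shape=shape)
    mask[rr, cc] = True
    return mask


def generate_fluorescence_pair(params: FluorescenceParams, seed: int = 0):
    """Generate a registered pre/post fluorescence image pair with ground truth.

    Returns ``(pair, truth)`` where ``pair`` is a
    :class:`~oralpdt.photobleach.FluorescencePair` (grayscale uint8 images,
    lesion outline attached) and ``truth`` records the exact lesion and
    bleach masks and their areas.

    The noise field is a single draw added to *both* images — it emulates
    fixed-pattern tissue texture, which dominates frame-to-frame variation in
    these photographs — so a zero ``drop_fraction`` yields bit-identical
    pre/post images.
    """
    from .photobleach import FluorescencePair  # local import to avoid a cycle

    h, w = params.image_size
    ppc = params.pixels_per_cm
    cx, cy = params.center if params.center is not None else ((w - 1) / 2, (h - 1) / 2)

    lesion = _ellipse_mask((h, w), (cx, cy), params.lesion_area_cm2 * ppc ** 2,
                           params.lesion_aspect)
    bleach = _ellipse_mask((h, w), (cx, cy), params.bleach_area_cm2 * ppc ** 2,
                           params.bleach_aspect)
    bleach |= lesion    # containment by construction, whatever the aspects

    pre = np.full((h, w), params.background_intensity, dtype=float)
    pre[lesion] = params.lesion_intensity
    post = pre.copy()
    post[bleach] *= (1.0 - params.drop_fraction)

    rng = np.random.default_rng([seed, _FLUOR_STREAM])
    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, size=(h, w))
        pre = pre + noise
        post = post + noise

    pre_u8 = np.clip(np.round(pre), 0, 255).astype(np.uint8)
    post_u8 = np.clip(np.round(post), 0, 255).astype(np.uint8)

    truth = SyntheticFluorescenceTruth(
        lesion_mask=lesion,
        bleach_mask=bleach,
        lesion_area_cm2=lesion.sum() / ppc ** 2,
        bleach_area_cm2=bleach.sum() / ppc ** 2,
        pixels_per_cm=ppc,
    )
    pair = FluorescencePair(pre_u8, post_u8, lesion_outline=lesion, pixels_per_cm=ppc)
    return pair, truth
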