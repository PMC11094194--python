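"""Synthetic body-pressure frames for the 24 x 11 air-spring grid.

No public recording of the original 26-subject air-mattress cohort
exists, so the package ships a generative stand-in that reproduces the
structure the feature pipeline exploits: a frame is a sum of anisotropic
Gaussian bumps placed at the body's support landmarks (head, shoulder,
back, waist, hip, thigh, calf), scaled by a per-subject weight factor,
plus additive Gaussian sensor noise clipped at zero and independent
per-cell dropout (a sensor occasionally reading nothing).

Supine frames concentrate mass in wide bumps centred on the spinal
midline column, with distinct shoulder / back / waist / hip row bands.
Lateral frames use narrower bumps offset 2.5 columns to one side, with
the shoulder and hip carrying more of the load and the back band less —
the load-bearing geometry of side-lying.  Left- and right-lateral frames
are both generated and pooled under the lateral label (-1).

Two further effects emulate how an air-spring array actually reads.
Air springs adjacent to, but not under, the body are displaced and
register spurious pressure: a smoothed copy of the body surface,
modulated by a per-cell random gain, is added as a *spill field*
(this redundant clutter is exactly what the neighborhood filter in
preprocessing removes).  And a subject never lies identically twice:
each frame jitters the bump centres (position) and each bump's
amplitude independently.

The default cohort protocol is 26 subjects x 40 frames each, 20 supine +
20 lateral, giving 1040 frames (520 per class).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .data_model import FRAME_SHAPE, LATERAL, SUPINE, PressureFrame, RegionLayout, validate_frame

POSTURES = ("supine", "lateral_left", "lateral_right")

#: Column index of the spinal midline on the 11-column grid.
MIDLINE_COL = 5.0


@dataclass(frozen=True)
class Bump:
    """One anisotropic Gaussian pressure bump.

    ``row`` is the centre row in frame coordinates; ``col_offset`` the
    centre column relative to the midline; sigmas are the Gaussian widths
    in cells; ``amplitude`` the peak pressure in sensor units.
    """

    row: float
    col_offset: float
    sigma_row: float
    sigma_col: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"bump amplitude must be > 0, got {self.amplitude}")
        if self.sigma_row <= 0 or self.sigma_col <= 0:
            raise ValueError("bump widths must be > 0")


# Support-landmark templates, in sensor units on the 24-row grid
# (head rows 0-3, trunk rows 4-14, legs rows 15-23).
_SUPINE_BUMPS = (
    Bump(row=1.5, col_offset=0.0, sigma_row=1.0, sigma_col=1.8, amplitude=25.0),   # head
    Bump(row=5.5, col_offset=0.0, sigma_row=1.2, sigma_col=2.4, amplitude=55.0),   # shoulder
    Bump(row=8.0, col_offset=0.0, sigma_row=1.5, sigma_col=2.0, amplitude=45.0),   # back
    Bump(row=10.5, col_offset=0.0, sigma_row=1.2, sigma_col=1.6, amplitude=38.0),  # waist
    Bump(row=13.0, col_offset=0.0, sigma_row=1.3, sigma_col=2.4, amplitude=60.0),  # hip
    Bump(row=17.5, col_offset=0.0, sigma_row=1.6, sigma_col=1.8, amplitude=30.0),  # thigh
    Bump(row=21.0, col_offset=0.0, sigma_row=1.5, sigma_col=1.5, amplitude=20.0),  # calf
)

# Lateral template at unit (left) side; col offsets are multiplied by the
# side sign and the configured lateral shift.  Narrower columns, heavier
# shoulder/hip, lighter back.
_LATERAL_BUMPS = (
    Bump(row=1.5, col_offset=-0.6, sigma_row=1.0, sigma_col=1.2, amplitude=28.0),  # head
    Bump(row=5.5, col_offset=-1.0, sigma_row=1.0, sigma_col=1.1, amplitude=65.0),  # shoulder
    Bump(row=8.0, col_offset=-1.0, sigma_row=1.5, sigma_col=1.0, amplitude=28.0),  # back
    Bump(row=10.5, col_offset=-1.0, sigma_row=1.2, sigma_col=1.0, amplitude=35.0), # waist
    Bump(row=13.0, col_offset=-1.0, sigma_row=1.2, sigma_col=1.2, amplitude=65.0), # hip
    Bump(row=17.5, col_offset=-0.8, sigma_row=1.6, sigma_col=1.2, amplitude=30.0), # thigh
    Bump(row=21.0, col_offset=-0.6, sigma_row=1.5, sigma_col=1.1, amplitude=18.0), # calf
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for frames and cohorts.

    ``lateral_shift`` scales the lateral template's column offsets (a unit
    shift moves the body 2.5 columns off the midline).  ``noise_sigma``
    is the additive sensor noise in the same units as the bump
    amplitudes; ``dropout`` the probability that a cell reads 0.  Each
    subject draws one weight factor from ``weight_range`` that scales all
    their bump amplitudes.

    Per-frame variability: bump centres shift by N(0, pos_jitter_row) rows
    and N(0, pos_jitter_col) columns, and each bump's amplitude is scaled
    by N(1, amp_jitter).  Displaced-spring redundancy: a Gaussian-smoothed
    copy of the body surface (width ``spill_sigma`` cells), multiplied by
    a per-cell uniform gain in [0, spill_gain], is added before noise.

    Barometric readings also drift with mattress inflation and
    temperature: every frame draws a multiplicative gain from
    ``frame_gain_range`` and an additive baseline from ``baseline_range``
    (uniformly), applied to the whole frame.  Rank-based features are
    invariant to this monotone re-scaling; absolute-value features are
    not.  Setting the jitters, spill, drift ranges ((1, 1) and (0, 0)),
    noise and dropout to neutral gives the deterministic template
    surface.
    """

    layout: RegionLayout = field(default_factory=RegionLayout)
    supine_bumps: tuple[Bump, ...] = _SUPINE_BUMPS
    lateral_bumps: tuple[Bump, ...] = _LATERAL_BUMPS
    lateral_shift: float = 2.5
    noise_sigma: float = 6.0
    dropout: float = 0.05
    pos_jitter_row: float = 0.5
    pos_jitter_col: float = 0.3
    amp_jitter: float = 0.15
    spill_gain: float = 0.6
    spill_sigma: float = 1.5
    frame_gain_range: tuple[float, float] = (0.7, 1.4)
    baseline_range: tuple[float, float] = (0.0, 6.0)
    weight_range: tuple[float, float] = (0.8, 1.25)
    n_subjects: int = 26
    frames_per_subject: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.frames_per_subject % 2:
            raise ValueError("frames_per_subject must be even for balanced classes")
        if self.weight_range[0] <= 0 or self.weight_range[1] < self.weight_range[0]:
            raise ValueError(f"invalid weight_range {self.weight_range}")
        if self.frame_gain_range[0] <= 0 or self.frame_gain_range[1] < self.frame_gain_range[0]:
            raise ValueError(f"invalid frame_gain_range {self.frame_gain_range}")
        if self.baseline_range[0] < 0 or self.baseline_range[1] < self.baseline_range[0]:
            raise ValueError(f"invalid baseline_range {self.baseline_range}")


def _render_bumps(bumps: tuple[Bump, ...], side_scale: float,
                  d_row: float = 0.0, d_col: float = 0.0,
                  amp_factors: np.ndarray | None = None) -> np.ndarray:
    rows = np.arange(FRAME_SHAPE[0])[:, None]
    cols = np.arange(FRAME_SHAPE[1])[None, :]
    surface = np.zeros(FRAME_SHAPE)
    for k, b in enumerate(bumps):
        center_row = b.row + d_row
        center_col = MIDLINE_COL + side_scale * b.col_offset + d_col
        amp = b.amplitude * (1.0 if amp_factors is None else amp_factors[k])
        surface += amp * np.exp(
            -((rows - center_row) ** 2) / (2 * b.sigma_row ** 2)
            - ((cols - center_col) ** 2) / (2 * b.sigma_col ** 2)
        )
    return surface


def simulate_frame(posture: str, config: SimulationConfig, rng: np.random.Generator,
                   weight_factor: float = 1.0, subject_id: str | None = None) -> PressureFrame:
    """Draw one frame for a posture in {supine, lateral_left, lateral_right}.

    Both lateral postures are labeled -1.  Noise and dropout are drawn
    from ``rng``; with ``noise_sigma=0`` and ``dropout=0`` the frame is
    the deterministic bump surface.
    """
    if posture == "supine":
        bumps, side_scale, label = config.supine_bumps, 0.0, SUPINE
    elif posture == "lateral_left":
        bumps, side_scale, label = config.lateral_bumps, config.lateral_shift, LATERAL
    elif posture == "lateral_right":
        bumps, side_scale, label = config.lateral_bumps, -config.lateral_shift, LATERAL
    else:
        raise ValueError(f"unknown posture {posture!r}; expected one of {POSTURES}")
    d_row = rng.normal(0.0, config.pos_jitter_row) if config.pos_jitter_row > 0 else 0.0
    d_col = rng.normal(0.0, config.pos_jitter_col) if config.pos_jitter_col > 0 else 0.0
    amp_factors = None
    if config.amp_jitter > 0:
        amp_factors = np.clip(rng.normal(1.0, config.amp_jitter, size=len(bumps)), 0.2, None)
    surface = _render_bumps(bumps, side_scale, d_row=d_row, d_col=d_col,
                            amp_factors=amp_factors)
    if config.spill_gain > 0:
        smooth = gaussian_filter(surface, sigma=config.spill_sigma)
        surface = surface + smooth * rng.uniform(0.0, config.spill_gain, size=FRAME_SHAPE)
    values = surface * weight_factor
    lo_g, hi_g = config.frame_gain_range
    if (lo_g, hi_g) != (1.0, 1.0):
        values = values * rng.uniform(lo_g, hi_g)
    lo_b, hi_b = config.baseline_range
    if (lo_b, hi_b) != (0.0, 0.0):
        values = values + rng.uniform(lo_b, hi_b)
    if config.noise_sigma > 0:
        values = values + rng.normal(0.0, config.noise_sigma, size=FRAME_SHAPE)
    values = np.clip(values, 0.0, None)
    if config.dropout > 0:
        values = np.where(rng.random(FRAME_SHAPE) < config.dropout, 0.0, values)
    return validate_frame(PressureFrame(values, label=label, subject_id=subject_id))


def simulate_cohort(config: SimulationConfig | None = None
                    ) -> tuple[list[PressureFrame], pd.DataFrame]:
    """Generate the full cohort: balanced supine/lateral frames per subject.

    Each subject draws one weight factor; lateral frames alternate between
    the left and right side.  Returns the frames and a manifest table with
    columns (index, subject_id, posture, label, weight_factor).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    half = config.frames_per_subject // 2
    frames: list[PressureFrame] = []
    records = []
    for s in range(config.n_subjects):
        subject_id = f"S{s:02d}"
        weight_factor = float(rng.uniform(*config.weight_range))
        postures = ["supine"] * half + [
            "lateral_left" if k % 2 == 0 else "lateral_right" for k in range(half)
        ]
        for posture in postures:
            frame = simulate_frame(posture, config, rng,
                                   weight_factor=weight_factor, subject_id=subject_id)
            records.append({
                "index": len(frames),
                "subject_id": subject_id,
                "posture": posture,
                "label": frame.label,
                "weight_factor": weight_factor,
            })
            frames.append(frame)
    manifest = pd.DataFrame(records)
    return frames, manifest


def trunk_column_com(frame: PressureFrame, layout: RegionLayout | None = None) -> float:
    """Column centre of mass of the trunk region, in column units."""
    layout = layout or RegionLayout()
    start, stop = layout.trunk_rows
    trunk = frame.values[start:stop, :]
    total = trunk.sum()
    if total <= 0:
        raise ValueError("no trunk mass")
    return float((trunk.sum(axis=0) * np.arange(trunk.shape[1])).sum() / total)
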