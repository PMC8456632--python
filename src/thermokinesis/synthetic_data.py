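"""Ground-truth fixture generator.

Produces parameterized bout sequences from the two-Markov-chain
generator at fixed per-temperature presets, and renders them into 25-fps
frame-level tracking tables (burst-and-coast speed profile, discrete
heading changes, rest intervals), together with the planted ground
truth. Every quantity the analysis pipeline estimates therefore has a
known true value.

Continuous per-bout draws use shifted gamma / normal distributions whose
supports stay clear of the detection and classification cutoffs, so the
planted batch means are recoverable without selection bias: interbout
intervals exceed the 0.4-s refractory period, displacements exceed the
0.3-mm rejection cutoff, and turn amplitudes exceed the 0.17-rad
forward/turn threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bout_pipeline import TURN_DISPLACEMENT_FACTOR
from .presets import KinematicPreset, preset_by_name, preset_for
from .tracking_io import ArenaConfig, DEFAULT_COLUMNS

__all__ = [
    "RenderConfig",
    "generate_bout_sequence",
    "render_frames",
    "make_cohort",
]

MIN_IBI = 0.6  # s, shift of the interbout-interval gamma
MIN_DISP = 0.35  # mm, shift of the displacement gamma
MIN_TURN_ANGLE = 0.25  # rad, shift of the turn-amplitude gamma
IBI_SHAPE = 4.0
DISP_SHAPE = 4.0
TURN_SHAPE = 3.0


@dataclass(frozen=True)
class RenderConfig:
    """Frame-level rendering parameters (bouts last ~100 ms)."""

    fps: float = 25.0
    bout_duration: float = 0.12  # s
    speed_profile: str = "triangular"  # peak mid-bout
    centroid_noise_sd: float = 0.02  # mm
    heading_noise_sd: float = 0.0  # rad

    def __post_init__(self) -> None:
        if self.bout_duration >= MIN_IBI:
            raise ValueError("bout_duration must be below the minimum interbout interval")
        if self.centroid_noise_sd < 0 or self.heading_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")


def _shifted_gamma(rng, mean: float, shift: float, shape: float, size: int) -> np.ndarray:
    if mean <= shift:
        raise ValueError(f"mean {mean} must exceed the distribution shift {shift}")
    return shift + rng.gamma(shape, (mean - shift) / shape, size=size)


@dataclass
class _OuDrift:
    """Slow log-normal modulation of the continuous bout parameters.

    Fixture feature for emulating intra-individual drift: an OU process
    X with relaxation time tau and stationary sd sigma multiplies ibi,
    displacement and turn amplitude by exp(X - sigma^2 / 2) (mean 1).
    """

    tau: float  # s
    sigma: float = 0.3

    def sample_path(self, times: np.ndarray, rng) -> np.ndarray:
        x = np.empty(len(times))
        x[0] = rng.normal(0.0, self.sigma)
        for i in range(1, len(times)):
            a = np.exp(-(times[i] - times[i - 1]) / self.tau)
            x[i] = a * x[i - 1] + self.sigma * np.sqrt(1 - a * a) * rng.standard_normal()
        return np.exp(x - self.sigma**2 / 2)


def generate_bout_sequence(
    preset: KinematicPreset,
    duration: float | None = None,
    n_bouts: int | None = None,
    rng=None,
    arena: ArenaConfig | None = None,
    start: tuple[float, float] | None = None,
    heading0: float | None = None,
    ou_drift: _OuDrift | None = None,
) -> pd.DataFrame:
    """Ground-truth bout sequence from the two-chain generator.

    Either ``duration`` (seconds of simulated time) or ``n_bouts`` must
    be given. Positions evolve translate-then-rotate inside the full
    arena with specular wall reflections. ``displacement`` is the
    post-correction value; turn bouts physically travel 1.6x further
    (``raw_displacement``).
    """
    if (duration is None) == (n_bouts is None):
        raise ValueError("give exactly one of duration or n_bouts")
    rng = np.random.default_rng(rng)
    arena = arena or ArenaConfig()
    if n_bouts is None:
        n_bouts = int(np.ceil(duration / MIN_IBI)) + 10

    dts = _shifted_gamma(rng, preset.mean_ibi, MIN_IBI, IBI_SHAPE, n_bouts)
    d_true = _shifted_gamma(rng, preset.mean_disp, MIN_DISP, DISP_SHAPE, n_bouts)
    is_turn = rng.random(n_bouts) < preset.p_turn
    # the hidden L/R state flips at every bout (turn or forward) with
    # probability p_flip; turn bouts merely expose it
    flips = rng.random(n_bouts) < preset.p_flip
    state = int(rng.choice([-1, 1])) * np.cumprod(np.where(flips, -1, 1))
    turn_amp = _shifted_gamma(rng, preset.mean_turn_angle, MIN_TURN_ANGLE, TURN_SHAPE, n_bouts)
    fwd_angle = rng.normal(0.0, preset.fwd_angle_sd, n_bouts)
    dthetas = np.where(is_turn, state * turn_amp, fwd_angle)

    onsets = np.concatenate(([1.0], 1.0 + np.cumsum(dts[:-1])))
    if duration is not None:
        keep = onsets < duration - 1.0
        n_bouts = int(np.sum(keep))
        dts, d_true, is_turn, dthetas = (
            a[:n_bouts] for a in (dts, d_true, is_turn, dthetas)
        )
        onsets = onsets[:n_bouts]

    if ou_drift is not None:
        mult = ou_drift.sample_path(onsets, rng)
        dts = MIN_IBI + (dts - MIN_IBI) * mult
        d_true = MIN_DISP + (d_true - MIN_DISP) * mult
        onsets = np.concatenate(([1.0], 1.0 + np.cumsum(dts[:-1])))
        if duration is not None:
            keep = onsets < duration - 1.0
            n_bouts = int(np.sum(keep))
            dts, d_true, is_turn, dthetas, onsets = (
                a[:n_bouts] for a in (dts, d_true, is_turn, dthetas, onsets)
            )

    d_raw = np.where(is_turn, d_true / TURN_DISPLACEMENT_FACTOR, d_true)

    # sequential position update with specular reflections
    xmin, xmax = 0.0, arena.width
    ymin, ymax = 0.0, arena.height
    if start is None:
        start = (
            rng.uniform(arena.width * 0.2, arena.width * 0.8),
            rng.uniform(arena.height * 0.2, arena.height * 0.8),
        )
    theta = rng.uniform(-np.pi, np.pi) if heading0 is None else float(heading0)
    x, y = float(start[0]), float(start[1])
    xs = np.empty(n_bouts)
    ys = np.empty(n_bouts)
    headings = np.empty(n_bouts)
    pre_x = np.empty(n_bouts)
    pre_y = np.empty(n_bouts)
    pre_h = np.empty(n_bouts)
    for i in range(n_bouts):
        pre_x[i], pre_y[i], pre_h[i] = x, y, theta
        x += d_raw[i] * np.cos(theta)
        y += d_raw[i] * np.sin(theta)
        if not xmin <= x <= xmax:
            x = 2 * xmin - x if x < xmin else 2 * xmax - x
            theta = np.pi - theta
        if not ymin <= y <= ymax:
            y = 2 * ymin - y if y < ymin else 2 * ymax - y
            theta = -theta
        theta += dthetas[i]
        xs[i], ys[i], headings[i] = x, y, theta

    return pd.DataFrame(
        {
            "onset_t": onsets,
            "delta_t": dts,
            "raw_displacement": d_raw,
            "displacement": d_true,
            "delta_theta": dthetas,
            "bout_class": np.where(is_turn, "turn", "forward"),
            "pre_x": pre_x,
            "pre_y": pre_y,
            "pre_heading": pre_h,
            "x": xs,
            "y": ys,
            "heading": headings,
        }
    )


def _profile_fraction(u: np.ndarray, profile: str) -> np.ndarray:
    """Fraction of the bout displacement completed at phase u in [0, 1]."""
    if profile == "triangular":
        return np.where(u < 0.5, 2 * u * u, 1 - 2 * (1 - u) ** 2)
    if profile == "gaussian-burst":
        # error-function ramp centered mid-bout
        from scipy.special import erf

        raw = 0.5 * (1 + erf((u - 0.5) / (0.18 * np.sqrt(2))))
        lo, hi = 0.5 * (1 + erf(-0.5 / (0.18 * np.sqrt(2)))), 0.5 * (
            1 + erf(0.5 / (0.18 * np.sqrt(2)))
        )
        return (raw - lo) / (hi - lo)
    raise ValueError(f"unknown speed profile {profile!r}")


def render_frames(
    bouts: pd.DataFrame,
    config: RenderConfig | None = None,
    duration: float | None = None,
    animal_id: int = 0,
    rng=None,
) -> pd.DataFrame:
    """Render a ground-truth bout sequence into a 25-fps frame table.

    Between bouts the fish is stationary up to centroid noise; during
    each bout the position runs from the pre- to the post-bout point
    under the speed profile while the heading rotates by delta_theta.
    """
    config = config or RenderConfig()
    rng = np.random.default_rng(rng)
    onsets = bouts["onset_t"].to_numpy()
    if np.any(np.diff(onsets) < config.bout_duration):
        raise ValueError("overlapping bouts cannot be rendered")
    if duration is None:
        duration = float(onsets[-1]) + 2.0 if len(onsets) else 10.0

    n_frames = int(np.floor(duration * config.fps)) + 1
    t = np.arange(n_frames) / config.fps

    if len(onsets) == 0:
        x = np.full(n_frames, 50.0)
        y = np.full(n_frames, 22.5)
        heading = np.zeros(n_frames)
    else:
        post_x = bouts["x"].to_numpy()
        post_y = bouts["y"].to_numpy()
        post_h = bouts["heading"].to_numpy()
        pre_x = bouts["pre_x"].to_numpy()
        pre_y = bouts["pre_y"].to_numpy()
        pre_h = bouts["pre_heading"].to_numpy()
        dtheta = bouts["delta_theta"].to_numpy()

        # resting state: position/heading after the last *completed* bout
        completed = np.searchsorted(onsets + config.bout_duration, t, side="right") - 1
        x = np.where(completed >= 0, post_x[np.clip(completed, 0, None)], pre_x[0])
        y = np.where(completed >= 0, post_y[np.clip(completed, 0, None)], pre_y[0])
        heading = np.where(completed >= 0, post_h[np.clip(completed, 0, None)], pre_h[0])

        # frames inside a bout
        j = np.searchsorted(onsets, t, side="right") - 1
        jc = np.clip(j, 0, None)
        u = (t - onsets[jc]) / config.bout_duration
        in_bout = (j >= 0) & (u >= 0) & (u < 1)
        if np.any(in_bout):
            jb = jc[in_bout]
            frac = _profile_fraction(u[in_bout], config.speed_profile)
            x[in_bout] = pre_x[jb] + frac * (post_x[jb] - pre_x[jb])
            y[in_bout] = pre_y[jb] + frac * (post_y[jb] - pre_y[jb])
            # heading rotates by dtheta over the bout; reflections make
            # pre_h + dtheta differ from post_h, so interpolate to post_h
            heading[in_bout] = pre_h[jb] + u[in_bout] * (post_h[jb] - pre_h[jb])

    if config.centroid_noise_sd > 0:
        x = x + rng.normal(0.0, config.centroid_noise_sd, n_frames)
        y = y + rng.normal(0.0, config.centroid_noise_sd, n_frames)
    if config.heading_noise_sd > 0:
        heading = heading + rng.normal(0.0, config.heading_noise_sd, n_frames)

    return pd.DataFrame(
        {
            DEFAULT_COLUMNS["frame"]: np.arange(n_frames),
            DEFAULT_COLUMNS["x"]: x,
            DEFAULT_COLUMNS["y"]: y,
            DEFAULT_COLUMNS["heading"]: heading,
            DEFAULT_COLUMNS["id"]: animal_id,
        }
    )


def make_cohort(
    preset,
    n_fish: int,
    duration: float,
    seed=None,
    render_config: RenderConfig | None = None,
    arena: ArenaConfig | None = None,
    ou_tau: float | None = None,
    ou_sigma: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Frame tables plus ground truth for a cohort of synthetic fish.

    ``preset`` is a :class:`~thermokinesis.presets.KinematicPreset`, a
    preset label like ``"18C"``, or a temperature. ``ou_tau`` switches on
    the slow OU modulation of the continuous parameters (single-fish
    drift emulation; a fixture feature, not a generative claim).
    Deterministic under a fixed seed.
    """
    if isinstance(preset, str):
        preset = preset_by_name(preset)
    elif isinstance(preset, (int, float)):
        preset = preset_for(float(preset))
    rng = np.random.default_rng(seed)
    render_config = render_config or RenderConfig()
    arena = arena or ArenaConfig(fps=render_config.fps)
    drift = _OuDrift(tau=ou_tau, sigma=ou_sigma) if ou_tau else None

    frames, truths = [], []
    for fish in range(n_fish):
        bouts = generate_bout_sequence(
            preset, duration=duration, rng=rng, arena=arena, ou_drift=drift
        )
        frames.append(
            render_frames(bouts, render_config, duration=duration, animal_id=fish, rng=rng)
        )
        truth = bouts.copy()
        truth.insert(0, "animal_id", fish)
        truths.append(truth)
    if not frames:
        empty_cols = list(DEFAULT_COLUMNS.values())
        return pd.DataFrame(columns=empty_cols), pd.DataFrame()
    return pd.concat(frames, ignore_index=True), pd.concat(truths, ignore_index=True)
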