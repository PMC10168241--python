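"""Illusion stimuli: contrast-contrast (static) and apparent motion (dynamic).

Contrast-contrast: a 1D sinusoidal luminance grating whose central patch
is modulated at a lower contrast than the surround.  Positions are in
arbitrary units matching the analysis conventions: the low-contrast patch
starts at position 3200, the surround region is everything to its left
(from the displayed boundary at 2900), and the center analysis window is
3200 < j < 3300.  The generated array extends beyond the displayed window
on both sides (surround-contrast grating) so that kernel convolution near
the region boundaries is free of edge artifacts.

Apparent motion: two bars at positions separated by 340 units flash in
alternation.  Each flash lasts SD time-steps, the inter-stimulus interval
equals SD, so the stimulus onset asynchrony is b = 2*SD and one full
alternation cycle is 4*SD time-steps.  One time-step represents 4.44 ms,
so an SD of 18 steps corresponds to a presentation frequency of
1000 / (4*18*4.44) = 3.12 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContrastContrastStimulus",
    "ApparentMotionStimulus",
    "CCStimulusConfig",
    "AMStimulusConfig",
    "make_cc_stimulus",
    "make_am_stimulus",
    "sd_to_frequency",
    "DT_MS",
    "STANDARD_SD_GRID",
]

DT_MS = 4.44  # duration of one stimulus time-step, milliseconds

# SD grid (time-steps) spanning presentation frequencies 0.75 .. 9.37 Hz.
# Note: SD=12 (not 11) yields 4.69 Hz under f = 1000/(4*SD*4.44); the grid
# is anchored to the frequency list.
STANDARD_SD_GRID = (75, 54, 41, 33, 24, 18, 15, 12, 9, 6)


@dataclass(frozen=True)
class CCStimulusConfig:
    """Geometry and contrasts of the contrast-contrast grating."""

    center_contrast: float = 0.40
    surround_contrast: float = 0.95
    mean_luminance: float = 0.5
    spatial_period: float = 118.0
    patch_start: int = 3200
    patch_width: int = 200
    display_start: int = 2900
    display_stop: int = 3700
    pad: int = 300  # extra grating on each side, absorbs kernel edge effects
    center_window: tuple[int, int] = (3200, 3300)

    def __post_init__(self) -> None:
        if not 0 <= self.center_contrast <= 1 or not 0 <= self.surround_contrast <= 1:
            raise ValueError("contrasts must lie in [0, 1]")
        if self.center_contrast > self.surround_contrast:
            raise ValueError("center contrast must not exceed surround contrast")
        if not (
            self.display_start <= self.patch_start
            and self.patch_start + self.patch_width <= self.display_stop
        ):
            raise ValueError("low-contrast patch must lie inside the display window")


@dataclass(frozen=True)
class ContrastContrastStimulus:
    """Generated grating plus its annotated analysis regions."""

    intensities: np.ndarray
    positions: np.ndarray
    config: CCStimulusConfig

    @property
    def surround_indices(self) -> np.ndarray:
        """Indices of the surround region: displayed positions left of the patch."""
        c = self.config
        return np.nonzero(
            (self.positions >= c.display_start) & (self.positions < c.patch_start)
        )[0]

    @property
    def center_indices(self) -> np.ndarray:
        """Indices of the center analysis window (exclusive bounds)."""
        lo, hi = self.config.center_window
        return np.nonzero((self.positions > lo) & (self.positions < hi))[0]

    def contrast_at(self, position: int) -> float:
        c = self.config
        in_patch = c.patch_start <= position < c.patch_start + c.patch_width
        return c.center_contrast if in_patch else c.surround_contrast


def make_cc_stimulus(config: CCStimulusConfig | None = None) -> ContrastContrastStimulus:
    """Build the contrast-contrast grating.

    intensity(i) = mean + contrast(i) * mean * sin(2*pi*i/period), with
    contrast(i) equal to the center contrast inside the patch and the
    surround contrast everywhere else (including the padding margins).
    """
    c = config or CCStimulusConfig()
    positions = np.arange(c.display_start - c.pad, c.display_stop + c.pad)
    contrast = np.full(positions.shape, c.surround_contrast, dtype=float)
    in_patch = (positions >= c.patch_start) & (positions < c.patch_start + c.patch_width)
    contrast[in_patch] = c.center_contrast
    intensities = c.mean_luminance * (
        1.0 + contrast * np.sin(2.0 * math.pi * positions / c.spatial_period)
    )
    return ContrastContrastStimulus(intensities=intensities, positions=positions, config=c)


@dataclass(frozen=True)
class AMStimulusConfig:
    """Geometry and timing of the two-flash apparent-motion stimulus."""

    zeta: int = 46          # left edge of the first bar
    separation: int = 340   # xi - zeta, distance between the two bars
    bar_width: int = 40
    amplitude: float = 5.0
    t_on: int = 20          # first flash onset, time-steps
    n_cycles: int = 3       # alternation cycles (first discarded as transient)
    n_positions: int = 512
    dt_ms: float = DT_MS

    @property
    def xi(self) -> int:
        """Left edge of the second bar."""
        return self.zeta + self.separation

    def __post_init__(self) -> None:
        if self.bar_width <= 0 or self.amplitude <= 0:
            raise ValueError("bar width and amplitude must be positive")
        if self.zeta + self.bar_width > self.xi:
            raise ValueError("the two bars must not overlap")
        if self.xi + self.bar_width > self.n_positions:
            raise ValueError("second bar exceeds the simulated window")


@dataclass(frozen=True)
class ApparentMotionStimulus:
    """Time-indexed intensity frames plus the flash timing annotations."""

    frames: np.ndarray  # (time, position)
    SD: int
    config: AMStimulusConfig

    @property
    def ISI(self) -> int:
        return self.SD  # ISI equals SD by construction

    @property
    def soa(self) -> int:
        """Stimulus onset asynchrony b = SD + ISI."""
        return 2 * self.SD

    @property
    def cycle_length(self) -> int:
        return 4 * self.SD

    @property
    def first_edge(self) -> int:
        """Right edge position of the first bar."""
        c = self.config
        return c.zeta + c.bar_width

    @property
    def second_edge(self) -> int:
        """Right edge position of the second bar."""
        c = self.config
        return c.xi + c.bar_width

    def analysis_window(self, cycle: int = 1) -> tuple[int, int]:
        """Time-step bounds of one alternation cycle (0-based cycle index)."""
        c = self.config
        start = c.t_on + cycle * self.cycle_length
        return start, start + self.cycle_length


def make_am_stimulus(SD: int, config: AMStimulusConfig | None = None) -> ApparentMotionStimulus:
    """Build the two-flash stimulus for one stimulus duration.

    Within each 4*SD cycle the first bar is lit for time-steps
    [0, SD), both bars are dark during [SD, 2*SD) (the ISI), the second bar
    is lit during [2*SD, 3*SD), and both are dark again during
    [3*SD, 4*SD).  The pattern starts at ``t_on`` and repeats ``n_cycles``
    times, followed by a decay tail of one cycle.
    """
    if SD < 1:
        raise ValueError(f"SD must be >= 1 time-step, got {SD}")
    c = config or AMStimulusConfig()
    cycle = 4 * SD
    n_t = c.t_on + (c.n_cycles + 1) * cycle
    frames = np.zeros((n_t, c.n_positions))
    bar1 = slice(c.zeta, c.zeta + c.bar_width + 1)
    bar2 = slice(c.xi, c.xi + c.bar_width + 1)
    for k in range(c.n_cycles):
        start = c.t_on + k * cycle
        frames[start : start + SD, bar1] = c.amplitude
        frames[start + 2 * SD : start + 3 * SD, bar2] = c.amplitude
    return ApparentMotionStimulus(frames=frames, SD=SD, config=c)


def sd_to_frequency(SD: int, dt_ms: float = DT_MS) -> float:
    """Presentation frequency (Hz) of a 4*SD alternation cycle.

    f = 1000 / (4 * SD * dt_ms), truncated (not rounded) to two decimals;
    truncation reproduces the conventional printed pairs such as SD=18 ->
    3.12 Hz and SD=6 -> 9.37 Hz.
    """
    if SD < 1:
        raise ValueError(f"SD must be >= 1 time-step, got {SD}")
    if dt_ms <= 0:
        raise ValueError(f"dt_ms must be > 0, got {dt_ms}")
    f = 1000.0 / (4.0 * SD * dt_ms)
    return math.floor(f * 100.0) / 100.0
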