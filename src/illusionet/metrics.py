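"""Illusion-representation statistics.

Contrast-contrast: the model's illusion strength is the center-surround
response difference r = s1 - s2, where s1 is the maximum layer-2 response
over the surround region and s2 the maximum over the center analysis
window.  Larger r means stronger modeled surround suppression of the
low-contrast patch.

Apparent motion: the model's illusion strength is the temporal overlap
between the layer-2 response time courses at the right edges of the two
bars.  Treating the (non-negative) curves xp(t) and xq(t) as unnormalized
densities of random times U and V, the statistic is

    Phi = c1 * c2 * P(U > V) = sum_{u > v} xp(u) * xq(v) * dt^2,

with c1 = integral of xp and c2 = integral of xq; equivalently the
one-sided correlation integral of the two curves.  Phi grows when the
response to the first flash persists into the response to the second,
i.e. when the model carries activity across the blank interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import NetworkConfig, SimulationTrace, run_loop_dynamic
from .stimuli import (
    AMStimulusConfig,
    ApparentMotionStimulus,
    ContrastContrastStimulus,
    make_am_stimulus,
    sd_to_frequency,
)

__all__ = [
    "CCRepresentation",
    "AMRepresentation",
    "compute_r",
    "extract_edge_responses",
    "compute_phi",
    "phi_frequency_profile",
    "EDGE_SEARCH_HALF_WIDTH",
]

# peak search window around the geometric right edge of each bar
EDGE_SEARCH_HALF_WIDTH = 4


class DegenerateTraceError(RuntimeError):
    """The simulation trace has no identifiable response structure."""


@dataclass(frozen=True)
class CCRepresentation:
    """Center-surround response difference and its two components."""

    r: float
    s1: float  # max layer-2 response in the surround region
    s2: float  # max layer-2 response in the center window


@dataclass(frozen=True)
class AMRepresentation:
    """Overlap statistic and the ingredients it was computed from."""

    phi: float
    c1: float
    c2: float
    p: int
    q: int
    xp_t: np.ndarray
    xq_t: np.ndarray
    clipped_mass: float = 0.0
    degenerate: bool = False


def compute_r(trace: SimulationTrace, stim: ContrastContrastStimulus) -> CCRepresentation:
    """Center-surround response difference from a settled static run."""
    if trace.x_l2 is None:
        raise ValueError("trace has no final layer-2 state; run the static loop first")
    x2 = trace.x_l2
    surround = stim.surround_indices
    center = stim.center_indices
    if len(surround) == 0 or len(center) == 0:
        raise ValueError("empty analysis region; check the stimulus geometry")
    s1 = float(x2[surround].max())
    s2 = float(x2[center].max())
    return CCRepresentation(r=s1 - s2, s1=s1, s2=s2)


def extract_edge_responses(
    trace: SimulationTrace,
    stim: ApparentMotionStimulus,
    cycle: int = 1,
    half_width: int = EDGE_SEARCH_HALF_WIDTH,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Locate the edge peaks and return their time courses over one cycle.

    The tracked positions p and q maximize, within +/- ``half_width``
    positions of the geometric right edge of each bar, the layer-2
    response during that bar's flash-ON interval of the analysis cycle
    (the peak response *to* the stimulus; off-rebounds outside the flash
    do not define the tracked position).  The returned curves cover the
    whole ``cycle``-th steady alternation cycle (0-based; the default
    skips the first, transient, cycle).
    """
    if trace.x_l2_t is None:
        raise ValueError("trace has no layer-2 time course; run the dynamic loop first")
    x2t = trace.x_l2_t
    t0, t1 = stim.analysis_window(cycle)
    if t1 > x2t.shape[0]:
        raise ValueError("analysis cycle extends beyond the simulated trace")
    window = x2t[t0:t1]

    def locate(edge: int, on_start: int, on_stop: int) -> int:
        lo = max(edge - half_width, 0)
        hi = min(edge + half_width + 1, x2t.shape[1])
        local = window[on_start:on_stop, lo:hi].max(axis=0)
        if float(local.max()) <= 0.0:
            raise DegenerateTraceError(
                f"no positive response near position {edge} during the flash; "
                "cannot track the edge peak"
            )
        return lo + int(np.argmax(local))

    sd = stim.SD
    p = locate(stim.first_edge, 0, sd)
    q = locate(stim.second_edge, 2 * sd, 3 * sd)
    return window[:, p].copy(), window[:, q].copy(), p, q


def compute_phi(
    xp_t: np.ndarray,
    xq_t: np.ndarray,
    dt: float = 1.0,
    p: int = -1,
    q: int = -1,
) -> AMRepresentation:
    """Overlap statistic Phi from the two edge-response time courses.

    Negative samples (possible, since shunting activity may reach -C) are
    clipped to zero first, because the statistic treats the curves as
    unnormalized probability densities; the clipped mass is reported.
    Ties (u == v) carry no mass: the ordered-pair region is strictly
    u > v, so Phi is computed as sum_u xp(u) * (sum_{v < u} xq(v)) * dt^2.
    """
    xp = np.asarray(xp_t, float)
    xq = np.asarray(xq_t, float)
    if xp.shape != xq.shape or xp.ndim != 1:
        raise ValueError("the two response curves must be 1D and share a time grid")
    clipped = float(np.clip(-xp, 0, None).sum() + np.clip(-xq, 0, None).sum()) * dt
    xp = np.clip(xp, 0.0, None)
    xq = np.clip(xq, 0.0, None)
    c1 = float(xp.sum()) * dt
    c2 = float(xq.sum()) * dt
    if c1 == 0.0 or c2 == 0.0:
        return AMRepresentation(
            phi=0.0, c1=c1, c2=c2, p=p, q=q, xp_t=xp, xq_t=xq,
            clipped_mass=clipped, degenerate=True,
        )
    # exclusive cumulative sum of xq: mass of {v < u} at each u
    cum_q = np.concatenate(([0.0], np.cumsum(xq)[:-1]))
    phi = float(np.dot(xp, cum_q)) * dt * dt
    return AMRepresentation(
        phi=phi, c1=c1, c2=c2, p=p, q=q, xp_t=xp, xq_t=xq, clipped_mass=clipped,
    )


def phi_for_stimulus(
    stim: ApparentMotionStimulus,
    config: NetworkConfig,
    cycle: int = 1,
) -> AMRepresentation:
    """Run the dynamic simulation for one stimulus and compute Phi.

    Only the frames up to the end of the analysis cycle are integrated;
    later cycles cannot influence the earlier response.  A trace with no
    positive flash response (possible when excitation is scaled far
    down) yields Phi = 0 with the degeneracy flag set rather than an
    error, so parameter sweeps can cross the degenerate region.
    """
    n_needed = stim.analysis_window(cycle)[1]
    trace = run_loop_dynamic(stim.frames[:n_needed], config)
    try:
        xp_t, xq_t, p, q = extract_edge_responses(trace, stim, cycle=cycle)
    except DegenerateTraceError:
        n = stim.analysis_window(cycle)[1] - stim.analysis_window(cycle)[0]
        zero = np.zeros(n)
        return AMRepresentation(phi=0.0, c1=0.0, c2=0.0, p=stim.first_edge,
                                q=stim.second_edge, xp_t=zero, xq_t=zero,
                                degenerate=True)
    return compute_phi(xp_t, xq_t, p=p, q=q)


def phi_frequency_profile(
    config: NetworkConfig,
    sd_list,
    am_config: AMStimulusConfig | None = None,
    cycle: int = 1,
):
    """Phi across presentation frequencies.

    Runs the two-flash stimulus, dynamic simulation, and overlap statistic
    for every stimulus duration in ``sd_list``.  Returns a list of
    ``(SD, frequency_Hz, phi)`` tuples ordered as given, plus the peak
    ``(frequency, phi)`` pair.
    """
    sd_list = list(sd_list)
    if not sd_list:
        raise ValueError("sd_list must be nonempty")
    rows = []
    for sd in sd_list:
        stim = make_am_stimulus(sd, am_config)
        rep = phi_for_stimulus(stim, config, cycle=cycle)
        rows.append((sd, sd_to_frequency(sd, (am_config or AMStimulusConfig()).dt_ms), rep.phi))
    peak_idx = int(np.argmax([r[2] for r in rows]))
    peak_frequency = rows[peak_idx][1]
    peak_phi = rows[peak_idx][2]
    return rows, peak_frequency, peak_phi
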