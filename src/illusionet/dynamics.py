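"""Shunting dynamics for the two-layer feedforward-feedback network.

Each layer is a 1D array of model neurons obeying a shunting
(membrane-style) equation

    dx/dt = -A*x + (B - x) * (I (*) GEx) - (C + x) * (I (*) GInh),

where ``(*)`` is spatial convolution with the excitatory/inhibitory
subfield kernels, ``A`` is the passive decay rate, and ``B``/``C`` are the
upper/lower activation bounds.  Because excitation is gated by the
headroom ``(B - x)`` and inhibition by ``(C + x)``, the continuous-time
trajectory can never leave ``[-C, B]``.

Layer 1 (model LGN) is driven by the stimulus plus ``alpha`` times the
layer-2 activity fed back from above; layer 2 (model V1) is driven by the
layer-1 output.  Static stimuli are processed by alternately settling the
two layers through the five-stage loop; time-varying stimuli are processed
by co-integrating both layers continuously.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import convolve1d

from .kernels import DiscreteKernel

__all__ = [
    "LayerParams",
    "NetworkConfig",
    "SimulationTrace",
    "conv_kernel",
    "shunting_rhs",
    "integrate_to_steady",
    "run_loop_static",
    "run_loop_dynamic",
]


@dataclass(frozen=True)
class LayerParams:
    """Decay, bounds, and (already normalized) subfield kernels of one layer."""

    A: float
    B: float
    C: float
    g_ex: DiscreteKernel
    g_inh: DiscreteKernel

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"decay rate A must be > 0, got {self.A}")
        if not self.B > 0:
            raise ValueError(f"upper bound B must be > 0, got {self.B}")
        if not self.C >= 0:
            raise ValueError(f"lower bound C must be >= 0, got {self.C}")


@dataclass(frozen=True)
class NetworkConfig:
    """Both layers plus the loop/integration controls.

    ``alpha`` is the top-down feedback gain: after the first feedforward
    sweep, the input to layer 1 becomes ``I + alpha * xL2``.  ``dt_integ``
    subdivides one stimulus time-step (4.44 ms) for the forward-Euler
    integrator; ``n_loops`` counts the feedback sweeps of the static
    five-stage loop.

    ``rectify_transmission`` optionally half-wave rectifies the signals
    passed between layers (the layer-1 output driving layer 2, and the
    fed-back layer-2 output).  The default transmits the signed
    activation: the negative off-surround flanks of the layer-1 response
    are part of the signal layer 2 integrates, and they carry the
    inhibitory-width effects the model studies.  Signed transmission
    means convolved drives can be negative, so the shunting form is only
    conditionally contractive (total rate A + E + I > 0 must hold); the
    integrator detects violation and reports divergence instead of
    silently clipping.  Rectified transmission restores the
    unconditional bound guarantee at the cost of distorting the
    zero-mean inter-layer signal.
    """

    layer1: LayerParams
    layer2: LayerParams
    alpha: float = 0.3
    dt_integ: float = 0.1
    n_loops: int = 2
    settle_tol: float = 1e-7
    max_settle_steps: int = 200_000
    boundary: str = "replicate"  # or "periodic"
    rectify_transmission: bool = False

    def __post_init__(self) -> None:
        if not self.alpha >= 0:
            raise ValueError(f"feedback strength alpha must be >= 0, got {self.alpha}")
        if not self.n_loops >= 1:
            raise ValueError(f"n_loops must be >= 1, got {self.n_loops}")
        if not self.dt_integ > 0:
            raise ValueError(f"dt_integ must be > 0, got {self.dt_integ}")
        if self.boundary not in ("replicate", "periodic"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")


@dataclass
class SimulationTrace:
    """Recorded activations of both layers, with convergence metadata.

    For static runs ``x_l1``/``x_l2`` hold the final settled states and
    ``stages`` the per-stage snapshots (keys like ``"stage1"``,
    ``"loop1_stage4"``).  For dynamic runs ``x_l1_t``/``x_l2_t`` hold one
    row per stimulus time-step.
    """

    x_l1: np.ndarray | None = None
    x_l2: np.ndarray | None = None
    x_l1_t: np.ndarray | None = None
    x_l2_t: np.ndarray | None = None
    stages: dict = field(default_factory=dict)
    converged: bool = True
    settle_steps: dict = field(default_factory=dict)
    config: NetworkConfig | None = None


_BOUNDARY_MODE = {"replicate": "nearest", "periodic": "wrap"}


def _rectifier(config: NetworkConfig):
    """Inter-layer signal function: half-wave rectified or identity."""
    if config.rectify_transmission:
        return lambda x: np.clip(x, 0.0, None)
    return lambda x: x


class _LayerConvolver:
    """FFT convolution with both subfield kernels of one layer.

    Precomputes the kernel spectra at a common padded length so the
    per-step cost is one forward transform of the (explicitly padded)
    signal plus two inverse transforms.  Numerically equivalent to
    direct convolution with the same boundary padding.
    """

    def __init__(self, params: LayerParams, n_pos: int, boundary: str):
        from scipy.fft import next_fast_len

        self.radius = max(params.g_ex.radius, params.g_inh.radius)
        self.n_pos = n_pos
        self.boundary = boundary
        self.n_pad = n_pos + 2 * self.radius
        self.n_fft = next_fast_len(self.n_pad + 2 * self.radius)
        self._wrap_idx = (
            np.arange(-self.radius, n_pos + self.radius) % n_pos
            if boundary == "periodic"
            else None
        )
        self._spectra = {}
        self._slices = {}
        for name, kern in (("ex", params.g_ex), ("inh", params.g_inh)):
            k = np.zeros(self.n_fft)
            k[: 2 * kern.radius + 1] = kern.values
            self._spectra[name] = np.fft.rfft(k)
            lo = self.radius + kern.radius
            self._slices[name] = slice(lo, lo + n_pos)

    def __call__(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.boundary == "replicate":
            padded = np.empty(self.n_pad)
            padded[: self.radius] = x[0]
            padded[self.radius : self.radius + self.n_pos] = x
            padded[self.radius + self.n_pos :] = x[-1]
        else:
            padded = x[self._wrap_idx]
        fx = np.fft.rfft(padded, self.n_fft)
        e = np.fft.irfft(fx * self._spectra["ex"], self.n_fft)[self._slices["ex"]]
        i = np.fft.irfft(fx * self._spectra["inh"], self.n_fft)[self._slices["inh"]]
        return e, i


def conv_kernel(signal: np.ndarray, kernel: DiscreteKernel, boundary: str = "replicate") -> np.ndarray:
    """Convolve a position vector with a subfield kernel.

    ``replicate`` extends the edge value beyond the simulated window (the
    padding used for the illusion inputs); ``periodic`` wraps, which makes
    translation-equivariance exact and is used by the property tests.
    """
    mode = _BOUNDARY_MODE[boundary]
    # kernels are symmetric, so correlation == convolution
    return convolve1d(np.asarray(signal, float), kernel.values, mode=mode)


def shunting_rhs(
    x: np.ndarray,
    input_vec: np.ndarray,
    params: LayerParams,
    boundary: str = "replicate",
) -> np.ndarray:
    """Right-hand side of the shunting equation for one layer."""
    x = np.asarray(x, float)
    input_vec = np.asarray(input_vec, float)
    if x.shape != input_vec.shape:
        raise ValueError(
            f"activation and input grids differ: {x.shape} vs {input_vec.shape}"
        )
    e = conv_kernel(input_vec, params.g_ex, boundary)
    i = conv_kernel(input_vec, params.g_inh, boundary)
    return -params.A * x + (params.B - x) * e - (params.C + x) * i


def _euler_settle(
    x0: np.ndarray,
    e: np.ndarray,
    i: np.ndarray,
    params: LayerParams,
    dt: float,
    tol: float,
    max_steps: int,
) -> tuple[np.ndarray, bool, int]:
    """Forward-Euler relaxation with the convolved drives held fixed.

    With frozen drives the equation is linear per position,
    dx/dt = -(A+e+i)*x + (B*e - C*i), so the Euler step preserves the
    shunting bound whenever dt*(A+e+i) <= 1; the step size is halved until
    that holds.
    """
    rate = params.A + e + i
    drive = params.B * e - params.C * i
    step = dt
    while step * float(rate.max()) > 1.0:
        step *= 0.5
    guard = 10.0 * (params.B + params.C + 1.0)
    x = np.asarray(x0, float).copy()
    for n in range(1, max_steps + 1):
        dxdt = drive - rate * x
        x += step * dxdt
        if float(np.abs(dxdt).max()) < tol:
            return x, True, n
        # signed drives can make the local rate non-positive, in which
        # case the stage has no stable fixed point: stop before overflow
        if n % 500 == 0 and float(np.abs(x).max()) > guard:
            return x, False, n
    return x, False, max_steps


def integrate_to_steady(
    x0: np.ndarray,
    input_vec: np.ndarray,
    params: LayerParams,
    dt: float = 0.1,
    tol: float = 1e-7,
    max_steps: int = 200_000,
    boundary: str = "replicate",
) -> tuple[np.ndarray, bool, int]:
    """Relax one layer to steady state under a constant input.

    Returns ``(x, converged, n_steps)``.  Non-convergence within
    ``max_steps`` is reported in the flag, not raised.
    """
    input_vec = np.asarray(input_vec, float)
    x0 = np.asarray(x0, float)
    if x0.shape != input_vec.shape:
        raise ValueError(
            f"activation and input grids differ: {x0.shape} vs {input_vec.shape}"
        )
    e = conv_kernel(input_vec, params.g_ex, boundary)
    i = conv_kernel(input_vec, params.g_inh, boundary)
    return _euler_settle(x0, e, i, params, dt, tol, max_steps)


def run_loop_static(stimulus: np.ndarray, config: NetworkConfig) -> SimulationTrace:
    """Five-stage feedforward-feedback loop for a static stimulus.

    Stage 1 settles layer 1 on the stimulus alone (no feedback yet, xL2=0);
    stage 2 settles layer 2 on the layer-1 output.  Each subsequent loop
    iteration settles layer 1 on ``I + alpha*xL2`` (stages 3/4) and layer 2
    on the updated layer-1 output (stage 5); ``n_loops`` such feedback
    sweeps are run.
    """
    stim = np.asarray(stimulus, float)
    trace = SimulationTrace(config=config)
    transmit = _rectifier(config)
    kw = dict(
        dt=config.dt_integ,
        tol=config.settle_tol,
        max_steps=config.max_settle_steps,
        boundary=config.boundary,
    )

    x1, ok, n = integrate_to_steady(np.zeros_like(stim), stim, config.layer1, **kw)
    trace.converged &= ok
    trace.settle_steps["stage1"] = n
    trace.stages["stage1"] = x1.copy()

    x2, ok, n = integrate_to_steady(np.zeros_like(stim), transmit(x1), config.layer2, **kw)
    trace.converged &= ok
    trace.settle_steps["stage2"] = n
    trace.stages["stage2"] = x2.copy()

    for loop in range(1, config.n_loops + 1):
        fed_input = stim + config.alpha * transmit(x2)
        x1, ok, n = integrate_to_steady(x1, fed_input, config.layer1, **kw)
        trace.converged &= ok
        trace.settle_steps[f"loop{loop}_stage4"] = n
        trace.stages[f"loop{loop}_stage4"] = x1.copy()

        x2, ok, n = integrate_to_steady(x2, transmit(x1), config.layer2, **kw)
        trace.converged &= ok
        trace.settle_steps[f"loop{loop}_stage5"] = n
        trace.stages[f"loop{loop}_stage5"] = x2.copy()

    trace.x_l1 = x1
    trace.x_l2 = x2
    return trace


def run_loop_dynamic(stimulus_t: np.ndarray, config: NetworkConfig) -> SimulationTrace:
    """Co-integrate both layers under a time-varying stimulus.

    ``stimulus_t`` has one row per stimulus time-step (4.44 ms each) and is
    held constant within a step; ``dt_integ`` subdivides each step for the
    forward-Euler update.  Layer 1 is driven by ``I(t) + alpha*xL2(t)`` and
    layer 2 by ``xL1(t)`` continuously (no staged settling).  Both layers'
    states are recorded once per stimulus time-step, after the step's
    update.
    """
    frames = np.asarray(stimulus_t, float)
    if frames.ndim != 2:
        raise ValueError("dynamic stimulus must be (time, position)")
    n_t, n_pos = frames.shape
    p1, p2 = config.layer1, config.layer2
    alpha = config.alpha
    boundary = config.boundary
    transmit = _rectifier(config)

    n_sub = max(1, int(round(1.0 / config.dt_integ)))
    dt = 1.0 / n_sub
    # worst-case local rate bound keeps forward Euler inside the shunting box
    k1 = float(p1.g_ex.values.sum() + p1.g_inh.values.sum())
    k2 = float(p2.g_ex.values.sum() + p2.g_inh.values.sum())
    in_max = float(np.abs(frames).max()) + alpha * max(p2.B, p2.C)
    rate_bound = max(
        p1.A + in_max * k1,
        p2.A + max(p1.B, p1.C) * k2,
    )
    while dt * rate_bound > 1.0:
        n_sub *= 2
        dt = 1.0 / n_sub

    x1 = np.zeros(n_pos)
    x2 = np.zeros(n_pos)
    rec1 = np.empty((n_t, n_pos))
    rec2 = np.empty((n_t, n_pos))
    guard = 10.0 * (max(p1.B, p2.B) + max(p1.C, p2.C) + 1.0)
    diverged = False
    conv1 = _LayerConvolver(p1, n_pos, boundary)
    conv2 = _LayerConvolver(p2, n_pos, boundary)

    for t in range(n_t):
        stim = frames[t]
        for _ in range(n_sub):
            drive1 = stim + alpha * transmit(x2)
            out1 = transmit(x1)
            e1, i1 = conv1(drive1)
            e2, i2 = conv2(out1)
            dx1 = -p1.A * x1 + (p1.B - x1) * e1 - (p1.C + x1) * i1
            dx2 = -p2.A * x2 + (p2.B - x2) * e2 - (p2.C + x2) * i2
            x1 += dt * dx1
            x2 += dt * dx2
        rec1[t] = x1
        rec2[t] = x2
        if float(np.abs(x1).max()) > guard or float(np.abs(x2).max()) > guard:
            # no stable trajectory under these drives; freeze and flag
            rec1[t:] = x1
            rec2[t:] = x2
            diverged = True
            break

    trace = SimulationTrace(config=config)
    trace.converged = not diverged
    trace.x_l1_t = rec1
    trace.x_l2_t = rec2
    trace.x_l1 = rec1[-1]
    trace.x_l2 = rec2[-1]
    return trace


def feedforward_once(stimulus: np.ndarray, config: NetworkConfig) -> SimulationTrace:
    """Pure two-stage feedforward pass (no feedback), for cross-checks."""
    cfg = replace(config, alpha=0.0, n_loops=1)
    return run_loop_static(stimulus, cfg)
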