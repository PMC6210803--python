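"""Synthetic pen traces and simulated sEMG feature streams.

The study inventory is 14 basic one-stroke shapes plus the 10 numeric
characters, each drawn as a single stroke sampled every 50 ms.  Shapes are
parametric curves (lines, half-sine arch, circle/ellipse, piecewise-linear
square and triangle); digits are Catmull-Rom splines through hand-placed
control points.  Trial-to-trial variability is emulated by jittering the
arc-length parameterization and adding smooth coordinate noise with SD 2% of
the symbol scale.

Features are produced by a known, recoverable forward model mapping the
instantaneous increment (Δx, Δy) to 7 nonnegative channel activations:

    g_c(Δ) = |a_c Δx + b_c Δy| + o_c + d_c · sin(e_c · u_c),   u_c ∈ {Δx, Δy}

i.e. a rectified linear drive (antagonist-pair style) plus a sinusoidal
nonlinearity, with additive Gaussian noise clipped at zero because RMS
amplitudes are nonnegative.  Sinusoid axes are mixed across channels so the
map (Δx, Δy) -> (g_1..g_7) is injective on the working velocity range.  A
purely linear variant (no rectification, positive offsets) is provided for
solvable-limit checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence, Tuple

import numpy as np

# ---------------------------------------------------------------------------
# symbol inventory
# ---------------------------------------------------------------------------

SHAPE_IDS: Tuple[str, ...] = (
    "h_line",
    "v_line",
    "fwd_slash",
    "backslash",
    "arch",
    "circle",
    "ellipse",
    "rev_h_line",
    "rev_v_line",
    "rev_fwd_slash",
    "rev_backslash",
    "rev_arch",
    "square",
    "triangle",
)
DIGIT_IDS: Tuple[str, ...] = tuple(f"digit_{d}" for d in range(10))
SYMBOL_IDS: Tuple[str, ...] = SHAPE_IDS + DIGIT_IDS


def _polyline(vertices) -> Callable[[np.ndarray], np.ndarray]:
    """Arc-length parameterized piecewise-linear curve through ``vertices``."""
    v = np.asarray(vertices, dtype=float)
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]

    def curve(s: np.ndarray) -> np.ndarray:
        d = np.asarray(s) * total
        x = np.interp(d, cum, v[:, 0])
        y = np.interp(d, cum, v[:, 1])
        return np.column_stack([x, y])

    return curve


def _catmull_rom(control, samples_per_seg: int = 24) -> Callable[[np.ndarray], np.ndarray]:
    """Arc-length parameterized Catmull-Rom spline through ``control`` points
    (equivalent to a chain of cubic Bezier segments)."""
    p = np.asarray(control, dtype=float)
    ext = np.vstack([2 * p[0] - p[1], p, 2 * p[-1] - p[-2]])
    dense = []
    t = np.linspace(0.0, 1.0, samples_per_seg, endpoint=False)
    for i in range(len(p) - 1):
        p0, p1, p2, p3 = ext[i], ext[i + 1], ext[i + 2], ext[i + 3]
        t2, t3 = t * t, t * t * t
        pts = (
            0.5
            * (
                (2 * p1)[None, :]
                + np.outer(t, -p0 + p2)
                + np.outer(t2, 2 * p0 - 5 * p1 + 4 * p2 - p3)
                + np.outer(t3, -p0 + 3 * p1 - 3 * p2 + p3)
            )
        )
        dense.append(pts)
    dense.append(p[-1][None, :])
    return _polyline(np.vstack(dense))


def _trig(fx, fy) -> Callable[[np.ndarray], np.ndarray]:
    def curve(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return np.column_stack([fx(s), fy(s)])

    return curve


#: unit-scale curves, each starting at (0, 0); x right, y up
_CURVES: Dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "h_line": _polyline([(0, 0), (1, 0)]),
    "v_line": _polyline([(0, 0), (0, -1)]),          # drawn top to bottom
    "fwd_slash": _polyline([(0, 0), (1, 1)]),        # bottom-left to top-right
    "backslash": _polyline([(0, 0), (1, -1)]),       # top-left to bottom-right
    "arch": _trig(lambda s: s, lambda s: 0.5 * np.sin(np.pi * s)),
    "circle": _trig(
        lambda s: 0.5 * np.sin(2 * np.pi * s),
        lambda s: 0.5 * (np.cos(2 * np.pi * s) - 1.0),
    ),
    "ellipse": _trig(
        lambda s: 0.65 * np.sin(2 * np.pi * s),
        lambda s: 0.4 * (np.cos(2 * np.pi * s) - 1.0),
    ),
    "rev_h_line": _polyline([(0, 0), (-1, 0)]),
    "rev_v_line": _polyline([(0, 0), (0, 1)]),
    "rev_fwd_slash": _polyline([(0, 0), (-1, -1)]),
    "rev_backslash": _polyline([(0, 0), (-1, 1)]),
    "rev_arch": _trig(lambda s: -s, lambda s: 0.5 * np.sin(np.pi * s)),
    "square": _polyline([(0, 0), (1, 0), (1, -1), (0, -1), (0, 0)]),
    "triangle": _polyline([(0, 0), (1, 0), (0.5, 0.85), (0, 0)]),
    "digit_0": _trig(
        lambda s: -0.35 * np.sin(2 * np.pi * s),
        lambda s: 0.5 * (np.cos(2 * np.pi * s) - 1.0),
    ),
    "digit_1": _polyline([(0, 0), (0, -1)]),
    "digit_2": _catmull_rom(
        [(0.0, -0.18), (0.12, 0.0), (0.38, -0.02), (0.42, -0.28),
         (0.2, -0.6), (0.0, -0.95), (0.25, -0.93), (0.5, -0.95)]
    ),
    "digit_3": _catmull_rom(
        [(0.0, -0.08), (0.25, 0.0), (0.42, -0.2), (0.22, -0.45),
         (0.45, -0.7), (0.25, -0.97), (0.0, -0.88)]
    ),
    "digit_4": _polyline(
        [(0.3, 0), (0.0, -0.6), (0.5, -0.6), (0.42, -0.35), (0.42, -1.0)]
    ),
    "digit_5": _catmull_rom(
        [(0.45, 0.0), (0.05, 0.0), (0.02, -0.42), (0.25, -0.38),
         (0.48, -0.55), (0.42, -0.85), (0.15, -1.0), (0.0, -0.9)]
    ),
    "digit_6": _catmull_rom(
        [(0.42, 0.0), (0.15, -0.3), (0.03, -0.65), (0.1, -0.92),
         (0.35, -1.0), (0.45, -0.72), (0.25, -0.55), (0.06, -0.68)]
    ),
    "digit_7": _polyline([(0, 0), (0.5, 0), (0.18, -1.0)]),
    "digit_8": _trig(
        lambda s: 0.22 * np.sin(4 * np.pi * s),
        lambda s: 0.5 * (np.cos(2 * np.pi * s) - 1.0),
    ),
    "digit_9": _catmull_rom(
        [(0.45, -0.1), (0.2, 0.0), (0.02, -0.2), (0.1, -0.42),
         (0.38, -0.45), (0.45, -0.15), (0.42, -0.6), (0.35, -1.0)]
    ),
}

assert set(_CURVES) == set(SYMBOL_IDS)


# ---------------------------------------------------------------------------
# trace generation
# ---------------------------------------------------------------------------

@dataclass
class SymbolSpec:
    """One symbol to draw: identity, sampling density, size, start point."""

    symbol_id: str
    n_points: int = 30
    scale: float = 100.0
    start_point: Tuple[float, float] = (0.0, 0.0)
    jitter_sd_frac: float = 0.02  # coordinate jitter SD as a fraction of scale

    def validate(self) -> None:
        if self.symbol_id not in _CURVES:
            raise ValueError(
                f"unknown symbol_id {self.symbol_id!r}; known symbols: "
                f"{', '.join(SYMBOL_IDS)}"
            )
        if self.n_points < 4:
            raise ValueError("n_points must be >= 4")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.jitter_sd_frac < 0:
            raise ValueError("jitter_sd_frac must be nonnegative")


def _smooth_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Moving-average-smoothed Gaussian noise, rescaled to the target SD, so
    consecutive samples stay close (no teleports)."""
    if sd == 0 or n < 2:
        return np.zeros((n, 2))
    raw = rng.normal(size=(n + 4, 2))
    kernel = np.ones(5) / 5.0
    sm = np.column_stack(
        [np.convolve(raw[:, j], kernel, mode="valid") for j in range(2)]
    )
    sm *= sd / np.sqrt(np.mean(kernel**2))  # restore unit variance then scale
    return sm[:n]


def generate_trace(spec: SymbolSpec, rng_seed: int) -> np.ndarray:
    """Draw one trial of a symbol: (n_points, 2) coordinates at 50 ms steps.

    The stroke follows the symbol's canonical direction, starts exactly at
    ``spec.start_point``, and carries small smooth jitter (timing warp plus
    coordinate noise) controlled by ``rng_seed``.
    """
    spec.validate()
    rng = np.random.default_rng(rng_seed)
    n = spec.n_points
    # monotone warp of the arc-length parameter (timing variability)
    inc = np.abs(rng.normal(1.0, 0.15, size=n - 1)) + 1e-3
    s = np.concatenate([[0.0], np.cumsum(inc)])
    s /= s[-1]
    pts = _CURVES[spec.symbol_id](s) * spec.scale
    pts = pts + _smooth_noise(rng, n, spec.jitter_sd_frac * spec.scale)
    pts = pts - pts[0] + np.asarray(spec.start_point, dtype=float)
    return pts


# ---------------------------------------------------------------------------
# forward model: increments -> channel activations
# ---------------------------------------------------------------------------

@dataclass
class ForwardModel:
    """Known trace->feature map used to simulate the 7 sEMG RMS channels.

    Channel c (rectified form):  ``|coef_c . Δ| + offset_c +
    sin_amp_c * sin(sin_freq_c * Δ[sin_axis_c])``; with ``rectify=False``
    the linear drive enters signed (purely linear model).
    """

    coef: np.ndarray            # (7, 2)
    offset: np.ndarray          # (7,)
    sin_amp: np.ndarray         # (7,)
    sin_freq: np.ndarray        # (7,)
    sin_axis: np.ndarray        # (7,) values in {0, 1}
    rectify: bool = True
    noise_sd: float = 0.0
    description: str = ""

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float).reshape(7, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(7)
        self.sin_amp = np.asarray(self.sin_amp, dtype=float).reshape(7)
        self.sin_freq = np.asarray(self.sin_freq, dtype=float).reshape(7)
        self.sin_axis = np.asarray(self.sin_axis, dtype=int).reshape(7)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def evaluate(self, deltas: np.ndarray) -> np.ndarray:
        """Noiseless channel activations for (k, 2) increments -> (k, 7)."""
        d = np.atleast_2d(np.asarray(deltas, dtype=float))
        lin = d @ self.coef.T
        if self.rectify:
            lin = np.abs(lin)
        osc = self.sin_amp[None, :] * np.sin(
            self.sin_freq[None, :] * d[:, self.sin_axis]
        )
        return lin + self.offset[None, :] + osc


def default_forward_model(noise_sd: float = 1.0) -> ForwardModel:
    """The repository's fixed planted model: rectified antagonist-style drives
    plus mixed-axis sinusoids (nonlinear, injective on |Δ| ≲ 12)."""
    coef = np.array(
        [
            [0.5, 0.0],
            [0.5, 0.2],
            [0.0, 0.5],
            [0.3, -0.5],
            [0.4, 0.4],
            [0.4, -0.4],
            [0.2, 0.6],
        ]
    )
    sin_amp = np.array([3.0, 2.0, 3.0, 2.0, 1.5, 1.5, 1.0])
    sin_freq = np.array([0.25, 0.15, 0.25, 0.15, 0.2, 0.2, 0.3])
    sin_axis = np.array([0, 0, 1, 1, 0, 1, 0])
    return ForwardModel(
        coef=coef,
        offset=sin_amp.copy(),  # keeps noiseless activations nonnegative
        sin_amp=sin_amp,
        sin_freq=sin_freq,
        sin_axis=sin_axis,
        rectify=True,
        noise_sd=noise_sd,
        description=(
            "g_c = |a_c dx + b_c dy| + o_c + d_c sin(e_c u_c), u_c in {dx, dy}"
        ),
    )


def linear_forward_model(noise_sd: float = 0.0) -> ForwardModel:
    """Purely linear antagonist-pair model (offsets keep channels positive);
    the solvable limit in which every decoder should be near-perfect."""
    coef = np.array(
        [
            [0.5, 0.0],
            [-0.5, 0.0],
            [0.0, 0.5],
            [0.0, -0.5],
            [0.25, 0.25],
            [0.25, -0.25],
            [0.1, 0.3],
        ]
    )
    return ForwardModel(
        coef=coef,
        offset=np.full(7, 15.0),
        sin_amp=np.zeros(7),
        sin_freq=np.zeros(7),
        sin_axis=np.zeros(7, dtype=int),
        rectify=False,
        noise_sd=noise_sd,
        description="g_c = o_c + a_c dx + b_c dy (no rectification)",
    )


def simulate_features(
    trace: np.ndarray, fm: ForwardModel, rng_seed: int
) -> np.ndarray:
    """Per-window RMS feature matrix for one trial: (n_points - 1, 7).

    Row i is the forward model applied to increment i plus Gaussian noise of
    SD ``fm.noise_sd``, clipped at zero (RMS amplitudes are nonnegative).
    Deterministic given ``rng_seed``.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[0] < 2:
        raise ValueError("trace must be (n >= 2, 2) to form increments")
    deltas = np.diff(trace, axis=0)
    g = fm.evaluate(deltas)
    if fm.noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        g = g + rng.normal(0.0, fm.noise_sd, size=g.shape)
    return np.clip(g, 0.0, None)


# ---------------------------------------------------------------------------
# raw 1000 Hz signal synthesis
# ---------------------------------------------------------------------------

TRIGGER_PEAK_UV = 120.0
QUIESCENT_AMPLITUDE_UV = 5.0


def simulate_raw_semg(
    trace: np.ndarray,
    fm: ForwardModel,
    fs: float = 1000.0,
    rng_seed: int = 0,
    pre_onset_s: float = 0.3,
) -> np.ndarray:
    """Amplitude-modulated noise whose 50 ms window RMS matches the feature
    stream; returns (n_samples, 8): column 0 is the trigger channel.

    The trigger is quiescent (< 30 µV) before the stroke and carries a
    deterministic 120 µV peak at onset, so threshold-crossing onset detection
    recovers the construction exactly.  Each post-onset window of channels
    1..7 is renormalized to its exact target RMS.
    """
    nw = fs * 0.05
    if abs(nw - round(nw)) > 1e-9 or round(nw) < 1:
        raise ValueError(f"fs={fs} Hz does not give an integer 50 ms window")
    nw = int(round(nw))
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[0] < 2:
        raise ValueError("trace must be (n >= 2, 2)")
    feats = simulate_features(trace, fm, rng_seed)
    k = feats.shape[0]
    pre = int(round(pre_onset_s * fs))
    total = pre + k * nw
    rng = np.random.default_rng(rng_seed + 1)

    out = rng.uniform(-QUIESCENT_AMPLITUDE_UV, QUIESCENT_AMPLITUDE_UV, size=(total, 8))
    # channels 1..7: per-window exact-RMS modulated noise after onset
    for w in range(k):
        sl = slice(pre + w * nw, pre + (w + 1) * nw)
        z = rng.normal(size=(nw, 7))
        norm = np.sqrt(np.mean(z**2, axis=0))
        norm[norm == 0] = 1.0
        out[sl, 1:] = z * (feats[w] / norm)[None, :]
    # trigger: active burst capped below the onset peak
    burst = np.clip(rng.normal(0.0, 45.0, size=k * nw), -100.0, 100.0)
    out[pre:, 0] = burst
    out[pre, 0] = TRIGGER_PEAK_UV
    return out


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class Trial:
    """One recorded trial: a trace and its aligned feature stream."""

    symbol_id: str
    trial_id: int
    trace: np.ndarray      # (n, 2)
    features: np.ndarray   # (n - 1, 7)


def generate_dataset(
    symbols: Sequence[str] = SYMBOL_IDS,
    trials_per_symbol: int = 40,
    n_points: int = 30,
    scale: float = 100.0,
    forward_model: ForwardModel | None = None,
    rng_seed: int = 0,
) -> list:
    """Simulate a full study dataset: ``trials_per_symbol`` trials of each
    symbol, with per-trial seeds derived deterministically from ``rng_seed``."""
    if trials_per_symbol < 1:
        raise ValueError("trials_per_symbol must be >= 1")
    fm = forward_model if forward_model is not None else default_forward_model()
    master = np.random.default_rng(rng_seed)
    trials = []
    for sym in symbols:
        spec = SymbolSpec(symbol_id=sym, n_points=n_points, scale=scale)
        for t in range(trials_per_symbol):
            seed = int(master.integers(0, 2**31 - 1))
            trace = generate_trace(spec, seed)
            feats = simulate_features(trace, fm, seed + 1)
            trials.append(Trial(symbol_id=sym, trial_id=t, trace=trace, features=feats))
    return trials
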