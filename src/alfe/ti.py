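"""Thermodynamic integration with on-the-fly convergence control.

The free energy of one alchemical leg is the Gauss-Legendre quadrature of the
ensemble-averaged coupling-potential derivative <dU/dlambda> over the coupling
parameter lambda in [0, 1].  Each lambda-window's gradient time series is

1. truncated at an automatically detected equilibration point t0 (the point
   maximizing the effective number of uncorrelated samples),
2. decorrelated by subsampling at the statistical inefficiency g, and
3. accepted only when the two chronological halves of the equilibrated series
   agree in distribution, judged by the Jensen-Shannon distance against a
   fixed criterion (default 0.1, base-2 logs so the distance lies in [0, 1]).

Unconverged windows request additional sampling in fixed increments until a
total-time budget is exhausted; replicates of one window are equilibrated and
decorrelated independently and pooled before averaging.  The relative binding
free energy of a transformation is ddG = dG_complex - dG_solvent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

JS_CRITERION_DEFAULT = 0.1
INIT_LENGTH_NS = 2.5
INCREMENT_NS = 0.5
FAST_INIT_LENGTH_NS = 1.0
FAST_INCREMENT_NS = 0.25
T0_GRID_POINTS = 50


class TIError(ValueError):
    """Raised for invalid TI inputs (schedules, series, leg mismatches)."""


class Leg(str, Enum):
    COMPLEX = "complex"
    SOLVENT = "solvent"


class Decision(str, Enum):
    ACCEPT = "accept"
    EXTEND = "extend"
    GIVE_UP = "give_up"


@dataclass(frozen=True)
class LambdaSchedule:
    """Quadrature nodes and weights on (0, 1)."""

    nodes: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, float)
        weights = np.asarray(self.weights, float)
        if nodes.shape != weights.shape or nodes.ndim != 1:
            raise TIError("nodes and weights must be 1-D and equal length")
        if not np.all(np.diff(nodes) > 0):
            raise TIError("nodes must be strictly increasing")
        if np.any(nodes <= 0) or np.any(nodes >= 1):
            raise TIError("nodes must lie strictly inside (0, 1)")
        if abs(weights.sum() - 1.0) > 1e-12:
            raise TIError("weights must sum to 1")
        if np.max(np.abs(nodes + nodes[::-1] - 1.0)) > 1e-12:
            raise TIError("nodes must be symmetric about 0.5")

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class GradientSeries:
    """dU/dlambda samples (kcal/mol) for one lambda-window of one leg."""

    leg: Leg
    lambda_index: int
    samples: np.ndarray
    dt: float  # ns per sample
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.leg = Leg(self.leg)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise TIError("samples must be a nonempty 1-D array")
        if self.dt <= 0:
            raise TIError("dt must be positive")

    @property
    def total_time(self) -> float:
        return self.samples.size * self.dt


@dataclass
class WindowEstimate:
    """Equilibrated, decorrelated summary of one lambda-window."""

    t0: int
    g: float
    n_eff: float
    mean: float
    stderr: float
    converged: bool
    total_time: float  # ns


@dataclass
class TIResult:
    """Relative binding free energy of one alchemical transformation."""

    dg_complex: float
    dg_solvent: float
    ddg: float
    ddg_stderr: float
    all_converged: bool
    window_flags: dict[str, list[bool]] = field(default_factory=dict)


def gauss_legendre_schedule(n: int = 9) -> LambdaSchedule:
    """Gauss-Legendre nodes/weights mapped affinely from [-1, 1] to [0, 1].

    The n-point rule integrates polynomials of degree <= 2n - 1 exactly; the
    default 9-point rule is the production lambda-schedule.
    """
    if n < 1:
        raise TIError("n must be >= 1")
    x, w = np.polynomial.legendre.leggauss(n)
    return LambdaSchedule(nodes=tuple((x + 1.0) / 2.0), weights=tuple(w / 2.0))


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    """Normalized autocorrelation function via FFT; rho[0] == 1."""
    n = x.size
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var <= 0:
        return np.ones(n)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    return acov / var


def statistical_inefficiency(x: np.ndarray) -> float:
    """g = 1 + 2 * sum_t (1 - t/N) * rho(t), truncated at the first negative
    autocorrelation value; constant series return g = 1."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 or np.ptp(x) == 0:
        return 1.0
    rho = _autocorrelation(x)
    g = 1.0
    for t in range(1, n):
        if rho[t] < 0:
            break
        g += 2.0 * (1.0 - t / n) * rho[t]
    return max(g, 1.0)


def _t0_grid(n: int, n_points: int = T0_GRID_POINTS) -> np.ndarray:
    """Candidate truncation points: evenly spaced over the first half."""
    upper = max(n - 10, 1)
    return np.unique(np.linspace(0, min(upper, n // 2), n_points).astype(int))


def detect_equilibration(
    series: "GradientSeries | np.ndarray",
) -> tuple[int, float, float]:
    """Choose the truncation point maximizing the effective sample count.

    Scans a grid of candidate t0 values; for each, the statistical
    inefficiency g(t0) of samples[t0:] gives n_eff(t0) = (N - t0)/g(t0).
    Returns (t0, g, n_eff) at the maximizing candidate.  A constant series is
    the degenerate case (0, 1, N).
    """
    x = series.samples if isinstance(series, GradientSeries) else np.asarray(series, float)
    n = x.size
    if n < 10:
        raise TIError("equilibration detection needs >= 10 samples")
    if np.ptp(x) == 0:
        return 0, 1.0, float(n)
    best = (0, 1.0, -np.inf)
    for t0 in _t0_grid(n):
        g = statistical_inefficiency(x[t0:])
        n_eff = (n - t0) / g
        if n_eff > best[2]:
            best = (int(t0), g, n_eff)
    return best


def subsample_decorrelated(
    series: "GradientSeries | np.ndarray", t0: int, g: float
) -> np.ndarray:
    """Post-t0 samples thinned with stride ceil(g); always >= 1 value."""
    x = series.samples if isinstance(series, GradientSeries) else np.asarray(series, float)
    if not 0 <= t0 < x.size:
        raise TIError(f"t0={t0} outside series of length {x.size}")
    if g < 1:
        raise TIError("statistical inefficiency must be >= 1")
    stride = int(math.ceil(g))
    return x[t0::stride]


def default_n_bins(n_pooled: int) -> int:
    """Shared-histogram bin count: max(10, ceil(sqrt(N)))."""
    return max(10, int(math.ceil(math.sqrt(n_pooled))))


def js_distance(a: Sequence[float], b: Sequence[float], n_bins: int | None = None) -> float:
    """Jensen-Shannon distance between histograms of two samples.

    Both samples are histogrammed on shared equal-width bins spanning the
    pooled range; the divergence uses base-2 logarithms so the distance is
    bounded by 1, with the 0 * log 0 = 0 convention for empty bins.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise TIError("both samples must be nonempty")
    if n_bins is None:
        n_bins = default_n_bins(a.size + b.size)
    if n_bins < 2:
        raise TIError("n_bins must be >= 2")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:  # identical constants: identical distributions
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    d = float(jensenshannon(pa, pb, base=2))
    return 0.0 if np.isnan(d) else d


def js_distance_discrete(p: Sequence[float], q: Sequence[float]) -> float:
    """Jensen-Shannon distance between two discrete distributions (base 2)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.size != q.size or p.size == 0:
        raise TIError("distributions must be nonempty and equal length")
    d = float(jensenshannon(p, q, base=2))
    return 0.0 if np.isnan(d) else d


def window_converged(
    series: GradientSeries,
    criterion: float = JS_CRITERION_DEFAULT,
    n_bins: int | None = None,
) -> bool:
    """Chronological-halves convergence test of the equilibrated portion.

    Converged iff js_distance(first half, second half) <= criterion.  Fewer
    than 4 equilibrated samples cannot be split meaningfully and count as not
    converged.
    """
    t0, _, _ = detect_equilibration(series)
    eq = series.samples[t0:]
    if eq.size < 4:
        return False
    half = eq.size // 2
    return js_distance(eq[:half], eq[half:], n_bins=n_bins) <= criterion


def extend_policy(
    window: WindowEstimate,
    series: GradientSeries,
    init_len: float = INIT_LENGTH_NS,
    increment: float = INCREMENT_NS,
    criterion: float = JS_CRITERION_DEFAULT,
    max_total: float = 10.0,
) -> Decision:
    """Accept a converged window, else request exactly one increment while the
    budget allows, else give up (the unconverged flag propagates to the
    transformation result)."""
    if series.total_time + 1e-9 < init_len:
        raise TIError(
            f"series covers {series.total_time:.3f} ns, below the initial "
            f"length {init_len} ns"
        )
    if window.converged:
        return Decision.ACCEPT
    if series.total_time + increment <= max_total + 1e-9:
        return Decision.EXTEND
    return Decision.GIVE_UP


def estimate_window(
    series: GradientSeries,
    criterion: float = JS_CRITERION_DEFAULT,
    n_bins: int | None = None,
) -> WindowEstimate:
    """Equilibrate, decorrelate and summarize a single gradient series."""
    t0, g, n_eff = detect_equilibration(series)
    values = subsample_decorrelated(series, t0, g)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    stderr = sd / math.sqrt(values.size) if values.size > 0 else 0.0
    return WindowEstimate(
        t0=t0,
        g=g,
        n_eff=n_eff,
        mean=mean,
        stderr=stderr,
        converged=window_converged(series, criterion=criterion, n_bins=n_bins),
        total_time=series.total_time,
    )


def combine_replicates(
    series_list: Sequence[GradientSeries],
    criterion: float = JS_CRITERION_DEFAULT,
) -> WindowEstimate:
    """Ensemble estimate for one (leg, lambda) window.

    Each replicate is equilibrated and decorrelated independently; the
    decorrelated values of all replicates are pooled, and the pooled sample
    gives the window mean and stderr = sd / sqrt(n_pooled).  The window counts
    as converged only if every replicate passes the halves test.
    """
    if not series_list:
        raise TIError("combine_replicates requires at least one series")
    leg, lam = series_list[0].leg, series_list[0].lambda_index
    for s in series_list[1:]:
        if s.leg is not leg or s.lambda_index != lam:
            raise TIError("all replicates must share leg and lambda_index")
    pooled: list[np.ndarray] = []
    t0s, gs, flags, total = [], [], [], 0.0
    for s in series_list:
        t0, g, _ = detect_equilibration(s)
        pooled.append(subsample_decorrelated(s, t0, g))
        t0s.append(t0)
        gs.append(g)
        flags.append(window_converged(s, criterion=criterion))
        total += s.total_time
    values = np.concatenate(pooled)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return WindowEstimate(
        t0=t0s[0],
        g=float(np.mean(gs)),
        n_eff=float(values.size),
        mean=mean,
        stderr=sd / math.sqrt(values.size),
        converged=all(flags),
        total_time=total,
    )


def integrate_leg(
    window_means: Sequence[float],
    schedule: LambdaSchedule,
    window_stderrs: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Quadrature of per-window means: dG = sum_i w_i * mean_i.

    The stderr propagates as sqrt(sum w_i^2 sigma_i^2) when sigmas are given
    (windows are independent simulations), else 0.
    """
    means = np.asarray(window_means, float)
    if means.size != len(schedule):
        raise TIError(
            f"{means.size} window means do not match the {len(schedule)}-point schedule"
        )
    w = np.asarray(schedule.weights)
    dg = float(np.dot(w, means))
    if window_stderrs is None:
        return dg, 0.0
    sig = np.asarray(window_stderrs, float)
    if sig.size != len(schedule):
        raise TIError("stderr vector length must match the schedule")
    return dg, float(np.sqrt(np.sum(w**2 * sig**2)))


def compute_rbfe(
    complex_windows: Sequence[WindowEstimate],
    solvent_windows: Sequence[WindowEstimate],
    schedule: LambdaSchedule,
) -> TIResult:
    """ddG = dG_complex - dG_solvent with quadrature-propagated stderr."""
    if len(complex_windows) != len(schedule) or len(solvent_windows) != len(schedule):
        raise TIError("each leg must supply one window estimate per lambda node")
    dg_c, se_c = integrate_leg(
        [w.mean for w in complex_windows], schedule, [w.stderr for w in complex_windows]
    )
    dg_s, se_s = integrate_leg(
        [w.mean for w in solvent_windows], schedule, [w.stderr for w in solvent_windows]
    )
    flags = {
        Leg.COMPLEX.value: [w.converged for w in complex_windows],
        Leg.SOLVENT.value: [w.converged for w in solvent_windows],
    }
    return TIResult(
        dg_complex=dg_c,
        dg_solvent=dg_s,
        ddg=dg_c - dg_s,
        ddg_stderr=math.sqrt(se_c**2 + se_s**2),
        all_converged=all(flags[Leg.COMPLEX.value]) and all(flags[Leg.SOLVENT.value]),
        window_flags=flags,
    )


def adaptive_window(
    sampler: Callable[[int], np.ndarray],
    dt: float,
    leg: Leg,
    lambda_index: int,
    init_len: float = INIT_LENGTH_NS,
    increment: float = INCREMENT_NS,
    criterion: float = JS_CRITERION_DEFAULT,
    max_total: float = 10.0,
    replicate_id: int = 0,
) -> tuple[WindowEstimate, GradientSeries, int]:
    """Drive one window to convergence by repeated extension.

    ``sampler(n)`` yields the next n gradient samples of the (stateful)
    simulation stream.  Returns the final window estimate, the accumulated
    series, and the number of extensions performed.  The accumulated time
    never exceeds ``max_total``.
    """
    n_init = int(round(init_len / dt))
    n_inc = max(int(round(increment / dt)), 1)
    samples = np.asarray(sampler(n_init), float)
    n_ext = 0
    while True:
        series = GradientSeries(
            leg=leg, lambda_index=lambda_index, samples=samples, dt=dt,
            replicate_id=replicate_id,
        )
        window = estimate_window(series, criterion=criterion)
        decision = extend_policy(
            window, series, init_len=init_len, increment=increment,
            criterion=criterion, max_total=max_total,
        )
        if decision is not Decision.EXTEND:
            return window, series, n_ext
        samples = np.concatenate([samples, np.asarray(sampler(n_inc), float)])
        n_ext += 1


def read_gradient_csv(path: str | Path) -> list[GradientSeries]:
    """Long-format CSV: leg,lambda_index,replicate,dt_ns,sample_kcal_per_mol_per_lambda."""
    df = pd.read_csv(path)
    out: list[GradientSeries] = []
    for (leg, lam, rep), grp in df.groupby(
        ["leg", "lambda_index", "replicate"], sort=True
    ):
        out.append(
            GradientSeries(
                leg=Leg(leg),
                lambda_index=int(lam),
                samples=grp["sample_kcal_per_mol_per_lambda"].to_numpy(),
                dt=float(grp["dt_ns"].iloc[0]),
                replicate_id=int(rep),
            )
        )
    return out


def write_gradient_csv(series_list: Sequence[GradientSeries], path: str | Path) -> None:
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "leg": s.leg.value,
                    "lambda_index": s.lambda_index,
                    "replicate": s.replicate_id,
                    "dt_ns": s.dt,
                    "sample_kcal_per_mol_per_lambda": s.samples,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def estimate_transformation(
    series_list: Sequence[GradientSeries],
    schedule: LambdaSchedule,
    criterion: float = JS_CRITERION_DEFAULT,
) -> TIResult:
    """Full TI estimate from a bag of gradient series covering both legs.

    Series are grouped by (leg, lambda_index); replicates of one window are
    pooled with :func:`combine_replicates`.
    """
    grouped: dict[tuple[Leg, int], list[GradientSeries]] = {}
    for s in series_list:
        grouped.setdefault((s.leg, s.lambda_index), []).append(s)
    windows: dict[Leg, list[WindowEstimate]] = {Leg.COMPLEX: [], Leg.SOLVENT: []}
    for leg in (Leg.COMPLEX, Leg.SOLVENT):
        for i in range(len(schedule)):
            if (leg, i) not in grouped:
                raise TIError(f"missing window: leg={leg.value} lambda_index={i}")
            windows[leg].append(combine_replicates(grouped[(leg, i)], criterion=criterion))
    return compute_rbfe(windows[Leg.COMPLEX], windows[Leg.SOLVENT], schedule)
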