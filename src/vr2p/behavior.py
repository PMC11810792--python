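"""Behavioral statistics for VR visual-learning and immersion experiments.

Covers four analyses:

* the abyss (virtual cliff) immersion test: edge detection with failure
  rules and the before/after-edge velocity ratio;
* a label-shuffle bootstrap learning score that compares aversive- and
  control-zone velocity curves with dynamic time warping (DTW) in the 1.5-s
  window before the (scheduled) first airpuff;
* anticipatory licking rates before zone entries;
* a Gaussian fit of the velocity frequency distribution used to check
  normality assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import optimize, stats

__all__ = [
    "VelocityTrace",
    "AbyssOutcome",
    "BootstrapResult",
    "GaussianFitResult",
    "detect_edge",
    "velocity_ratio",
    "dtw_distance",
    "bootstrap_learning",
    "quarter_day",
    "anticipatory_licking",
    "fit_velocity_gaussian",
]


# --------------------------------------------------------------------------
# Abyss (immersion) test
# --------------------------------------------------------------------------

@dataclass
class VelocityTrace:
    """Treadmill velocity sampled on a uniform time grid.

    The rotary encoder reports displacement every 3 ms; negative velocity
    (recoil) is allowed.  ``position`` is the integrated corridor coordinate.
    """

    time: np.ndarray       # s, uniform step
    velocity: np.ndarray   # cm/s
    position: np.ndarray   # corridor units
    edge_coord: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.time.size < 2:
            raise ValueError("trace needs at least two samples")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time step must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class AbyssOutcome:
    """Classification of one abyss run."""

    classification: str          # 'crossed' | 'stopped_at_view' | 'failed'
    edge_time: float | None
    ratio: float | None = None

    def __post_init__(self) -> None:
        if self.classification == "failed" and self.ratio is not None:
            raise ValueError("failed runs carry no velocity ratio")


def detect_edge(
    trace: VelocityTrace,
    edge_coord: float,
    visibility_coord: float,
    timeout: float = 20.0,
    stop_window: float = 2.0,
    stop_threshold: float = 0.0,
) -> AbyssOutcome:
    """Find the moment a run 'reaches' the virtual cliff edge.

    The edge time is the first time the position passes ``edge_coord``.  If
    the edge is never crossed, it is the start of the first stop of at least
    ``stop_window`` seconds (velocity <= ``stop_threshold``) at a position
    from which the edge is already visible (``>= visibility_coord``).  Runs
    where neither happens within ``timeout`` seconds are classified failed
    (and excluded from ratio statistics downstream).
    """
    if visibility_coord > edge_coord:
        raise ValueError("visibility_coord must be <= edge_coord")
    t, v, x = trace.time, trace.velocity, trace.position
    within = t - t[0] <= timeout

    crossed = within & (x >= edge_coord)
    if crossed.any():
        return AbyssOutcome("crossed", float(t[np.argmax(crossed)]))

    stopped = (v <= stop_threshold) & (x >= visibility_coord)
    n_win = int(round(stop_window / trace.dt))
    run = 0
    for i in range(len(t)):
        run = run + 1 if stopped[i] else 0
        if run >= n_win:
            start = i - n_win + 1
            if within[start]:
                return AbyssOutcome("stopped_at_view", float(t[start]))
    return AbyssOutcome("failed", None)


def velocity_ratio(
    trace: VelocityTrace,
    edge_time: float,
    window: float = 2.0,
    orientation: str = "after_before",
) -> float:
    """Ratio of mean velocity after vs before the edge in ``window``-s intervals.

    Oriented so that slowing at the edge gives a ratio < 1 and recoil
    (backing away) gives a negative ratio; ``orientation='before_after'``
    flips the convention.  The before-interval is ``[edge-window, edge)``
    and the after-interval ``(edge, edge+window]``.
    """
    t, v = trace.time, trace.velocity
    before = (t >= edge_time - window) & (t < edge_time)
    after = (t > edge_time) & (t <= edge_time + window)
    if not before.any() or not after.any():
        raise ValueError("trace does not cover the +/- window around edge_time")
    mean_before = float(v[before].mean())
    mean_after = float(v[after].mean())
    if orientation == "after_before":
        num, den = mean_after, mean_before
    elif orientation == "before_after":
        num, den = mean_before, mean_after
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if den == 0:
        raise ZeroDivisionError("denominator mean velocity is zero; ratio undefined")
    return num / den


# --------------------------------------------------------------------------
# Dynamic time warping
# --------------------------------------------------------------------------

@njit(cache=True)
def _dtw_cost(a: np.ndarray, b: np.ndarray) -> float:  # pragma: no cover - jit
    n, m = a.shape[0], b.shape[0]
    big = 1e300
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    for j in range(m + 1):
        prev[j] = big
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[0] = big
        ai = a[i - 1]
        for j in range(1, m + 1):
            c = abs(ai - b[j - 1])
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        prev, cur = cur, prev
    return prev[m]


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Classical DTW distance between two 1-D series.

    Absolute-difference local cost, symmetric step pattern (insert, delete,
    match), no window constraint, unnormalized accumulated cost.  Symmetric
    and zero iff the series are identical up to repeats along the warping
    path.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("dtw_distance requires nonempty series")
    return float(_dtw_cost(a, b))


# --------------------------------------------------------------------------
# Shuffle bootstrap learning score
# --------------------------------------------------------------------------

CTRL, AVER = 1, 2


@dataclass
class BootstrapResult:
    """Result of the label-shuffle bootstrap.

    ``score`` is the proportion of shuffled group differences below the
    original difference (ties counted half), so chance level is 0.5 and
    values near 1 indicate a real speed difference between zones.
    """

    original_diff: float
    shuffled_diffs: np.ndarray
    score: float
    n_shuffles: int


def _group_diff(curves: np.ndarray, labels: np.ndarray, statistic: str) -> float:
    mean_ctrl = curves[labels == CTRL].mean(axis=0)
    mean_aver = curves[labels == AVER].mean(axis=0)
    if statistic == "dtw":
        return dtw_distance(mean_ctrl, mean_aver)
    if statistic == "mean_diff":
        return float(np.abs(mean_aver - mean_ctrl).mean())
    raise ValueError(f"unknown statistic {statistic!r}")


def bootstrap_learning(
    curves: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    statistic: str = "dtw",
) -> BootstrapResult:
    """Label-shuffle bootstrap of the zone velocity difference.

    ``curves`` holds per-trial velocity segments (trials x samples) cropped
    to the 1.5-s interval ending at the scheduled first-airpuff time (zone
    entry + grace period), excluding the airpuff's direct effect; control
    trials use the same schedule.  Labels are 1 for control and 2 for
    aversive trials.  The original statistic is the DTW distance between the
    two label-group mean curves; each shuffle permutes the label vector and
    recomputes it.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    labels = np.asarray(labels)
    if curves.shape[0] != labels.shape[0]:
        raise ValueError("one label per trial curve required")
    for lab, name in ((CTRL, "CTRL"), (AVER, "AVER")):
        if np.sum(labels == lab) < 2:
            raise ValueError(f"need >= 2 trials with label {name} ({lab})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    original = _group_diff(curves, labels, statistic)
    shuffled = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(labels)
        shuffled[s] = _group_diff(curves, perm, statistic)
    below = np.sum(shuffled < original)
    ties = np.sum(shuffled == original)
    score = (below + 0.5 * ties) / n_shuffles
    return BootstrapResult(original, shuffled, float(score), n_shuffles)


def quarter_day(trial_times: np.ndarray) -> list[np.ndarray]:
    """Split a training day into four equal parts by session time.

    Returns, for each quarter, the indices of trials whose time falls into
    it; used to run the bootstrap separately across the day.
    """
    times = np.asarray(trial_times, dtype=float)
    if times.size == 0:
        return [np.array([], dtype=int)] * 4
    lo, hi = times.min(), times.max()
    edges = np.linspace(lo, hi, 5)
    idx = np.arange(times.size)
    parts = []
    for q in range(4):
        upper_ok = times <= edges[q + 1] if q == 3 else times < edges[q + 1]
        parts.append(idx[(times >= edges[q]) & upper_ok])
    return parts


# --------------------------------------------------------------------------
# Anticipatory licking
# --------------------------------------------------------------------------

def anticipatory_licking(
    licks: np.ndarray,
    zone_entries: dict[str, np.ndarray],
    window_pre: float,
) -> dict[str, float | None]:
    """Mean lick rate in the ``window_pre`` seconds before zone entry.

    Counts licks in the half-open interval ``[entry - window_pre, entry)``
    per entry and averages over entries of each zone type.  Zone types with
    no entries map to None.
    """
    if window_pre <= 0:
        raise ValueError("window_pre must be > 0")
    licks = np.asarray(licks, dtype=float)
    rates: dict[str, float | None] = {}
    for zone, entries in zone_entries.items():
        entries = np.asarray(entries, dtype=float)
        if entries.size == 0:
            rates[zone] = None
            continue
        counts = [
            np.sum((licks >= t0 - window_pre) & (licks < t0)) for t0 in entries
        ]
        rates[zone] = float(np.mean(counts)) / window_pre
    return rates


# --------------------------------------------------------------------------
# Gaussian fit of the velocity frequency distribution
# --------------------------------------------------------------------------

@dataclass
class GaussianFitResult:
    """Fitted parameters of the FWHM-parameterized Gaussian.

    The fitted model is

        y = y0 + A / (w * (pi / (4 ln 2))^-0.5) * exp(-4 ln2 (x-xc)^2 / w^2)

    with ``w`` the full width at half maximum.  Per-parameter p-values are
    two-tailed t-tests of the estimates against zero.
    """

    y0: float
    A: float
    w: float
    xc: float
    r_squared: float
    p_values: dict[str, float]

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError("fitted width w must be > 0")


_LN2_4 = 4.0 * np.log(2.0)
_W_COEF = (np.pi / _LN2_4) ** -0.5  # the printed w-normalization


def _gauss_fwhm(x: np.ndarray, y0: float, A: float, w: float, xc: float) -> np.ndarray:
    return y0 + A / (w * _W_COEF) * np.exp(-_LN2_4 * (x - xc) ** 2 / w**2)


def fit_velocity_gaussian(
    velocities: np.ndarray,
    bins: int | str | np.ndarray = "auto",
    max_restarts: int = 5,
) -> GaussianFitResult:
    """Fit a Gaussian to the frequency count of velocity samples.

    Used to confirm approximate normality of the velocity distribution
    (failed trials should be excluded by the caller).  Nonlinear least
    squares over (y0, A, w, xc) with moment-based initialization and random
    restarts on nonconvergence.
    """
    v = np.asarray(velocities, dtype=float)
    counts, edges = np.histogram(v, bins=bins)
    x = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(counts) < 10:
        raise ValueError(
            f"need >= 10 histogram bins with counts, got {np.count_nonzero(counts)}"
        )
    y = counts.astype(float)
    std0 = max(float(v.std()), 1e-6)
    p0 = np.array([0.0, y.sum() * (edges[1] - edges[0]), 2.355 * std0, float(v.mean())])
    rng = np.random.default_rng(0)
    last_err: Exception | None = None
    for attempt in range(max_restarts):
        try:
            start = p0 if attempt == 0 else p0 * rng.uniform(0.5, 1.5, size=4)
            popt, pcov = optimize.curve_fit(
                _gauss_fwhm, x, y, p0=start, maxfev=20000
            )
            if popt[2] < 0:  # width sign is unidentified; canonicalize
                popt[2] = -popt[2]
            resid = y - _gauss_fwhm(x, *popt)
            ss_res = float(np.sum(resid**2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            dof = max(len(x) - 4, 1)
            stderr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
            with np.errstate(divide="ignore", invalid="ignore"):
                tvals = np.where(stderr > 0, popt / stderr, np.inf)
            pvals = 2 * stats.t.sf(np.abs(tvals), dof)
            names = ("y0", "A", "w", "xc")
            return GaussianFitResult(
                *map(float, popt), r2, dict(zip(names, map(float, pvals)))
            )
        except (RuntimeError, ValueError) as err:  # nonconvergence
            last_err = err
    raise RuntimeError(
        f"Gaussian fit failed after {max_restarts} restarts: {last_err}"
    )
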