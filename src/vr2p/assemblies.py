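"""Assembly-level analyses: hub cells, decoders, trial clusters, lead--lag.

Learning recruits most of the population, but a small subpopulation sits
above a jump in the ramp-amplitude distribution.  These "hub" cells ramp
earlier and higher, cluster spatially, and show elevated spontaneous
cross-correlation -- a functional-connectivity proxy.  A decoder built from
the average activity of just a handful of top cells separates aversive
from control trials; trial-to-trial fluctuation splits trials into high-
and low-ramp groups with opposite neural-vs-running lead--lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .learning_metrics import AlignedResponses, ramp_amplitude

__all__ = [
    "HubAssignment",
    "Decoder",
    "TrialClassification",
    "detect_amplitude_threshold",
    "hub_spatial_clustering",
    "spontaneous_crosscorr",
    "build_and_apply_decoder",
    "cluster_trials",
    "lead_lag",
    "onset_time",
]


# --------------------------------------------------------------------------
# Amplitude threshold / hub detection
# --------------------------------------------------------------------------

@dataclass
class HubAssignment:
    """Jump detection in the sorted ramp-amplitude distribution."""

    sorted_amplitudes: np.ndarray
    order: np.ndarray             # argsort of the input
    jump_index: int | None        # position of the gap in the sorted vector
    threshold: float | None
    hub_ids: np.ndarray
    nonhub_ids: np.ndarray
    no_jump: bool


def detect_amplitude_threshold(
    amplitudes: np.ndarray,
    top_quartile: float = 0.75,
    gap_factor: float = 2.0,
) -> HubAssignment:
    """Place the hub threshold at the largest amplitude gap near the top.

    Sorts amplitudes ascending, takes first differences, and finds the
    largest gap among those whose upper neighbor lies in the top quartile
    of ranks (the jump sits "at the top of the amplitude range").  If no
    candidate gap exceeds ``gap_factor`` times the median gap, the
    distribution is considered jump-free and the hub set is empty.
    Invariant under affine transforms a*x + b with a > 0.
    """
    amp = np.asarray(amplitudes, dtype=float)
    if amp.size < 10:
        raise ValueError(f"need >= 10 neurons, got {amp.size}")
    order = np.argsort(amp, kind="stable")
    a = amp[order]
    gaps = np.diff(a)
    cutoff = int(np.ceil(top_quartile * amp.size)) - 1
    candidates = np.arange(len(gaps))[np.arange(1, amp.size) >= cutoff]
    j = candidates[np.argmax(gaps[candidates])]
    med = float(np.median(gaps))
    if gaps[j] <= gap_factor * med or gaps[j] == 0:
        return HubAssignment(
            sorted_amplitudes=a, order=order, jump_index=None, threshold=None,
            hub_ids=np.array([], dtype=int), nonhub_ids=order.copy(),
            no_jump=True,
        )
    threshold = 0.5 * (a[j] + a[j + 1])
    hubs = order[j + 1:]
    return HubAssignment(
        sorted_amplitudes=a, order=order, jump_index=int(j),
        threshold=float(threshold), hub_ids=np.sort(hubs),
        nonhub_ids=np.sort(order[:j + 1]), no_jump=False,
    )


def hub_spatial_clustering(
    soma_xyz: np.ndarray,
    hub_ids: np.ndarray,
    coding_ids: np.ndarray,
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Test whether hub cells sit closer together than random coding cells.

    Compares the mean pairwise Euclidean distance among hub somata to a
    null of ``n_draws`` random equally sized subsets of the coding
    population.  The normalized ratio (hub mean / null mean) is < 1 for
    clustered hubs; the permutation p-value is one-sided for clustering.
    """
    xyz = np.asarray(soma_xyz, dtype=float)
    hub_ids = np.asarray(hub_ids, dtype=int)
    coding_ids = np.asarray(coding_ids, dtype=int)
    if hub_ids.size < 3:
        raise ValueError(f"need >= 3 hub cells, got {hub_ids.size}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hub_mean = float(pdist(xyz[hub_ids]).mean())
    null = np.empty(n_draws)
    for d in range(n_draws):
        pick = rng.choice(coding_ids, size=hub_ids.size, replace=False)
        null[d] = pdist(xyz[pick]).mean()
    null_mean = float(null.mean())
    p = (1 + np.sum(null <= hub_mean)) / (n_draws + 1)
    return {
        "hub_mean_distance": hub_mean,
        "null_mean_distance": null_mean,
        "ratio": hub_mean / null_mean if null_mean > 0 else np.inf,
        "p_value": float(p),
        "null_distances": null,
    }


# --------------------------------------------------------------------------
# Spontaneous cross-correlation
# --------------------------------------------------------------------------

def spontaneous_crosscorr(
    dff: np.ndarray,
    frame_times: np.ndarray,
    exclusion_intervals: list[tuple[float, float]],
    hub_ids: np.ndarray | None = None,
    low_ids: np.ndarray | None = None,
    normalize: bool = False,
    min_duration: float = 30.0,
) -> dict:
    """Zero-lag pairwise correlation of activity outside the aversive zone.

    "Spontaneous" samples are all frames outside the given exclusion
    intervals (the aversive-zone visits; control zones can be added by the
    caller).  Group summaries average the off-diagonal correlations within
    the hub set, the ``low_ids`` set (e.g. the ten lowest-ramp cells) and
    the rest; ``normalize=True`` rescales group means to the largest one.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    frame_times = np.asarray(frame_times, dtype=float)
    keep = np.ones(frame_times.size, dtype=bool)
    for lo, hi in exclusion_intervals:
        keep &= ~((frame_times >= lo) & (frame_times <= hi))
    dt = np.median(np.diff(frame_times)) if frame_times.size > 1 else 0.0
    if keep.sum() * dt < min_duration:
        raise ValueError(
            f"only {keep.sum() * dt:.1f} s of spontaneous samples; "
            f"need >= {min_duration} s"
        )
    corr = np.corrcoef(dff[:, keep])
    n = corr.shape[0]
    out: dict = {"matrix": corr, "n_samples": int(keep.sum())}

    def group_mean(ids: np.ndarray) -> float:
        sub = corr[np.ix_(ids, ids)]
        off = sub[~np.eye(len(ids), dtype=bool)]
        return float(off.mean()) if off.size else np.nan

    if hub_ids is not None:
        groups = {"hub": np.asarray(hub_ids, dtype=int)}
        if low_ids is not None:
            groups["low"] = np.asarray(low_ids, dtype=int)
        rest = np.setdiff1d(np.arange(n), np.concatenate(list(groups.values())))
        groups["rest"] = rest
        means = {k: group_mean(v) for k, v in groups.items() if v.size >= 2}
        if normalize and means:
            top = max(means.values())
            if top > 0:
                means = {k: v / top for k, v in means.items()}
        out["group_means"] = means
    return out


# --------------------------------------------------------------------------
# Few-cell trial decoder
# --------------------------------------------------------------------------

@dataclass
class Decoder:
    """Average-activity decoder built from 3--7 top cells.

    The decoder function is the mean dF/F of the member cells; a trial is
    called aversive when the decision statistic (window mean over
    (-4, -2.5) s before the zone end) exceeds the threshold, the midpoint
    of the two training-class means.
    """

    members: np.ndarray
    window: tuple[float, float]
    threshold: float

    def __post_init__(self) -> None:
        if not 3 <= len(self.members) <= 7:
            raise ValueError(f"decoder needs 3-7 member cells, got {len(self.members)}")


def _decoder_statistic(aligned: AlignedResponses, members: np.ndarray,
                       window: tuple[float, float]) -> np.ndarray:
    mask = aligned.window_mask(window)
    return aligned.data[np.ix_(members, np.flatnonzero(mask))].mean(axis=(0, 1))


def build_and_apply_decoder(
    aligned: AlignedResponses,
    train_trials: np.ndarray,
    test_trials: np.ndarray,
    k: int | None = None,
    window: tuple[float, float] = (-4.0, -2.5),
    ramp_window: tuple[float, float] = (-1.0, -0.4),
    seed: int = 0,
) -> dict:
    """Train a few-cell decoder on one trial split and score the other.

    Member cells are the top-k neurons by aversive-minus-control ramp
    difference on the training trials.  ``k=None`` picks the smallest k in
    3..7 that classifies the training trials perfectly (else 7).  Returns
    the decoder, per-trial test labels and the held-out reliability
    (fraction correct).
    """
    train_trials = np.asarray(train_trials, dtype=int)
    test_trials = np.asarray(test_trials, dtype=int)
    train_labels = aligned.labels[train_trials]
    if not {"AVER", "CTRL"} <= set(train_labels):
        raise ValueError("training split must contain both AVER and CTRL trials")
    if k is not None and not 3 <= k <= 7:
        raise ValueError(f"k must be in 3..7, got {k}")

    amp = ramp_amplitude(aligned, window=ramp_window).per_trial
    aver_mean = amp[:, train_trials[train_labels == "AVER"]].mean(axis=1)
    ctrl_mean = amp[:, train_trials[train_labels == "CTRL"]].mean(axis=1)
    ranking = np.argsort(ctrl_mean - aver_mean, kind="stable")  # descending diff

    def fit(k_try: int) -> tuple[Decoder, float]:
        members = ranking[:k_try]
        stat = _decoder_statistic(aligned, members, window)
        mu_aver = stat[train_trials[train_labels == "AVER"]].mean()
        mu_ctrl = stat[train_trials[train_labels == "CTRL"]].mean()
        thr = 0.5 * (mu_aver + mu_ctrl)
        pred = np.where(stat[train_trials] > thr, "AVER", "CTRL")
        acc = float(np.mean(pred == train_labels))
        return Decoder(members, window, float(thr)), acc

    if k is None:
        decoder, acc = None, 0.0
        for k_try in range(3, 8):
            decoder, acc = fit(k_try)
            if acc == 1.0:
                break
    else:
        decoder, acc = fit(k)

    stat = _decoder_statistic(aligned, decoder.members, decoder.window)
    test_pred = np.where(stat[test_trials] > decoder.threshold, "AVER", "CTRL")
    reliability = float(np.mean(test_pred == aligned.labels[test_trials]))
    return {
        "decoder": decoder,
        "train_accuracy": acc,
        "test_labels": test_pred,
        "reliability": reliability,
    }


# --------------------------------------------------------------------------
# Trial clustering and lead--lag
# --------------------------------------------------------------------------

@dataclass
class TrialClassification:
    """High-/low-ramp split of trials with the velocity coupling."""

    scores: np.ndarray
    cluster: np.ndarray          # 'high_ramp' | 'low_ramp' per trial
    pearson_r: float | None
    pearson_p: float | None
    single_cluster: bool


def cluster_trials(
    ramp_scores: np.ndarray,
    velocity_summaries: np.ndarray | None = None,
    seed: int = 0,
    n_restarts: int = 10,
) -> TrialClassification:
    """2-means clustering of per-trial ramp scores into high/low groups.

    The cluster with the larger center is labeled high_ramp.  When
    per-trial velocity summaries are given, the Pearson correlation between
    velocity and ramp score is reported.  Labels are invariant under
    rescaling of the scores by any positive constant.
    """
    scores = np.asarray(ramp_scores, dtype=float)
    if scores.size < 6:
        raise ValueError(f"need >= 6 trials, got {scores.size}")
    if np.ptp(scores) == 0:
        return TrialClassification(scores, np.full(scores.size, "high_ramp", dtype=object),
                                   None, None, True)
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict((scores / np.abs(scores).max())[:, None])
    high_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    labels = np.where(raw == high_cluster, "high_ramp", "low_ramp").astype(object)
    r = p = None
    if velocity_summaries is not None:
        vel = np.asarray(velocity_summaries, dtype=float)
        res = stats.pearsonr(vel, scores)
        r, p = float(res.statistic), float(res.pvalue)
    return TrialClassification(scores, labels, r, p, False)


def lead_lag(
    population: np.ndarray,
    velocity: np.ndarray,
    rate: float,
    max_lag: float,
) -> float:
    """Lag of maximal cross-correlation; positive means V1 leads running.

    Both series share the sampling ``rate``.  The normalized
    cross-correlation is evaluated on integer-sample lags within
    ``+/- max_lag`` seconds; the returned lag is positive when the
    population trace rises before the velocity does.
    """
    x = np.asarray(population, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if x.shape != v.shape:
        raise ValueError("population and velocity must share the time base")
    max_shift = int(round(max_lag * rate))
    if max_shift >= x.size // 2:
        raise ValueError("max_lag must be < half the trace length")
    if np.ptp(x) == 0 or np.ptp(v) == 0:
        raise ValueError("flat trace; lead-lag undefined")
    xc = x - x.mean()
    vc = v - v.mean()
    best_lag, best_val = 0, -np.inf
    for shift in range(-max_shift, max_shift + 1):
        # shift > 0: compare population now with velocity `shift` samples later
        if shift >= 0:
            a, bseg = xc[:x.size - shift], vc[shift:]
        else:
            a, bseg = xc[-shift:], vc[:x.size + shift]
        denom = np.std(a) * np.std(bseg)
        if denom == 0:
            continue
        val = float(np.mean(a * bseg) / denom)
        if val > best_val:
            best_val, best_lag = val, shift
    return best_lag / rate


def onset_time(
    trace: np.ndarray,
    rate: float,
    frac: float = 0.2,
    smooth_s: float = 0.2,
) -> float | None:
    """First crossing of ``frac`` of the peak above baseline, on a smoothed trace.

    Baseline is the trace minimum after 0.2-s Gaussian smoothing.  Used for
    hub-vs-population onset timing; returns None for flat traces.
    """
    y = ndimage.gaussian_filter1d(np.asarray(trace, dtype=float), sigma=smooth_s * rate)
    lo, hi = y.min(), y.max()
    if hi <= lo:
        return None
    thresh = lo + frac * (hi - lo)
    idx = np.flatnonzero(y >= thresh)
    return float(idx[0] / rate) if idx.size else None
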