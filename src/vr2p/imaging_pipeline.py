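"""From chessboard-scan movies and pixel masks to neuropil-corrected dF/F.

Chessboard scanning acquires one small rectangular subfield ("chessboard
piece") around each soma at an arbitrary 3D location, instead of a full
frame.  This has two consequences the pipeline must handle:

* each subfield is rigidly motion corrected separately, against the maximum
  projection of the first measurement unit, and pixels uncovered after the
  shift are marked with a fill value (zero or NaN);
* automatic segmentation masks produced by full-field tools spill across
  subfield borders, so soma pixels whose traces contain fill values and
  neuropil pixels outside a neuron's home subfield (or overlapping any
  soma) must be discarded before trace formation.

After cleaning, 60% of the neuropil trace is subtracted from the raw soma
trace, and dF/F is computed against an 8th-percentile baseline of the full
day trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "ChessboardMovie",
    "Roi",
    "RoiSet",
    "FluorescenceTraces",
    "register_subfields",
    "clean_roi_pixels",
    "clean_neuropil_pixels",
    "neuropil_correct",
    "compute_dff",
    "extract_traces",
]


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class ChessboardMovie:
    """Per-subfield frame stacks from a chessboard scan.

    ``frames`` maps a (row, col) grid position to a (n_frames, h, w) stack in
    arbitrary intensity units.  All subfields share the frame count and
    frame rate.  ``fill_value`` marks invalid pixels created by motion
    correction (0.0 or NaN).
    """

    grid_shape: tuple[int, int]
    frames: dict[tuple[int, int], np.ndarray]
    frame_rate: float
    subfield_center_xyz: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        counts = {stack.shape[0] for stack in self.frames.values()}
        if len(counts) > 1:
            raise ValueError(f"subfields disagree on frame count: {sorted(counts)}")
        for pos, stack in self.frames.items():
            if stack.ndim != 3 or stack.shape[1] == 0 or stack.shape[2] == 0:
                raise ValueError(f"subfield {pos} must be (frames, h, w) with h,w > 0")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return next(iter(self.frames.values())).shape[0]

    @property
    def subfield_shape(self) -> tuple[int, int]:
        stack = next(iter(self.frames.values()))
        return stack.shape[1], stack.shape[2]

    def _is_fill(self, values: np.ndarray) -> np.ndarray:
        if np.isnan(self.fill_value):
            return np.isnan(values)
        # zero and NaN both count as invalid: both conventions occur in
        # motion-corrected exports.
        return (values == self.fill_value) | np.isnan(values)


@dataclass
class Roi:
    """One soma with its neuropil surround, in subfield-local pixel coords."""

    soma_pixels: np.ndarray        # (n, 2) int row, col
    soma_weights: np.ndarray       # (n,) >= 0, not all zero
    neuropil_pixels: np.ndarray    # (m, 2) int
    neuropil_weights: np.ndarray   # (m,)
    home_subfield: tuple[int, int]
    soma_xyz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.soma_pixels = np.asarray(self.soma_pixels, dtype=int).reshape(-1, 2)
        self.soma_weights = np.asarray(self.soma_weights, dtype=float).ravel()
        self.neuropil_pixels = np.asarray(self.neuropil_pixels, dtype=int).reshape(-1, 2)
        self.neuropil_weights = np.asarray(self.neuropil_weights, dtype=float).ravel()
        if np.any(self.soma_weights < 0) or np.any(self.neuropil_weights < 0):
            raise ValueError("pixel weights must be >= 0")
        if self.soma_weights.size and self.soma_weights.sum() == 0:
            raise ValueError("soma weights must not all be zero")


@dataclass
class RoiSet:
    rois: list[Roi]

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, i: int) -> Roi:
        return self.rois[i]


@dataclass
class FluorescenceTraces:
    """Raw, corrected and normalized traces for one ROI."""

    raw_soma: np.ndarray
    raw_neuropil: np.ndarray
    corrected: np.ndarray
    dff: np.ndarray
    f0: float


# --------------------------------------------------------------------------
# Motion correction
# --------------------------------------------------------------------------

def _shift_frame(frame: np.ndarray, shift: tuple[float, float], cval: float) -> np.ndarray:
    dy, dx = shift
    if float(dy).is_integer() and float(dx).is_integer():
        out = np.full_like(frame, cval, dtype=float)
        h, w = frame.shape
        dy, dx = int(dy), int(dx)
        ys = slice(max(dy, 0), min(h + dy, h))
        xs = slice(max(dx, 0), min(w + dx, w))
        ys_src = slice(max(-dy, 0), min(h - dy, h))
        xs_src = slice(max(-dx, 0), min(w - dx, w))
        out[ys, xs] = frame[ys_src, xs_src]
        return out
    return ndimage.shift(frame.astype(float), (dy, dx), order=1, mode="constant", cval=cval)


def _integer_shifts(
    ref: np.ndarray,
    stack: np.ndarray,
    valid: np.ndarray,
    max_shift: int,
) -> np.ndarray:
    """Integer (dy, dx) per frame maximizing masked correlation with ``ref``.

    Bounded search over |dy|,|dx| <= max_shift (motion beyond a quarter
    subfield is physically implausible and makes registration ill-posed),
    with the Pearson correlation computed only on valid (non-fill) pixels
    of the overlap; vectorized over frames.
    """
    n = stack.shape[0]
    best_corr = np.full(n, -np.inf)
    best = np.zeros((n, 2))
    h, w = ref.shape
    for dy in range(-max_shift, max_shift + 1):
        ys_ref = slice(max(dy, 0), h + min(dy, 0))
        ys_frm = slice(max(-dy, 0), h + min(-dy, 0))
        for dx in range(-max_shift, max_shift + 1):
            xs_ref = slice(max(dx, 0), w + min(dx, 0))
            xs_frm = slice(max(-dx, 0), w + min(-dx, 0))
            r = ref[ys_ref, xs_ref]
            f = stack[:, ys_frm, xs_frm]
            v = valid[:, ys_frm, xs_frm]
            nv = v.sum(axis=(1, 2)).astype(float)
            ok = nv > 1
            nv[~ok] = 1.0
            fm = (f * v).sum(axis=(1, 2)) / nv
            rm = (r * v).sum(axis=(1, 2)) / nv
            fd = (f - fm[:, None, None]) * v
            rd = (r[None] - rm[:, None, None]) * v
            cov = (fd * rd).sum(axis=(1, 2))
            denom = np.sqrt((fd**2).sum(axis=(1, 2)) * (rd**2).sum(axis=(1, 2)))
            corr = np.where((denom > 0) & ok, cov / np.where(denom == 0, 1, denom), -np.inf)
            better = corr > best_corr
            best_corr[better] = corr[better]
            best[better] = (dy, dx)
    return best


def register_subfields(
    movie: ChessboardMovie,
    reference: dict[tuple[int, int], np.ndarray] | None = None,
    upsample_factor: int = 10,
    reference_frames: int | None = None,
) -> tuple[dict[tuple[int, int], np.ndarray], ChessboardMovie, dict]:
    """Rigid per-subfield motion correction by cross-correlation.

    Each subfield is registered separately, frame by frame, against the
    maximum-intensity projection of the first measurement unit (the first
    ``reference_frames`` frames; all frames if None) using subpixel
    cross-correlation.  Estimated shifts are removed; uncovered pixels are
    set to the movie's fill value.

    Returns
    -------
    shifts : dict mapping subfield -> (n_frames, 2) array of (dy, dx)
    corrected : ChessboardMovie
    summary : dict with 'mean_abs_shift', 'max_abs_shift' and the set of
        'flat_subfields' for which the shift was pinned to (0, 0).
    """
    shifts: dict[tuple[int, int], np.ndarray] = {}
    corrected: dict[tuple[int, int], np.ndarray] = {}
    flat: list[tuple[int, int]] = []
    for pos, stack in movie.frames.items():
        if reference is not None:
            ref = np.asarray(reference[pos], dtype=float)
        else:
            n_ref = stack.shape[0] if reference_frames is None else reference_frames
            ref = stack[:n_ref].max(axis=0).astype(float)
        sub_shifts = np.zeros((stack.shape[0], 2))
        out = np.empty_like(stack, dtype=float)
        if np.ptp(ref) == 0:
            flat.append(pos)
            warnings.warn(f"subfield {pos} is flat; shifts pinned to (0, 0)")
            out[:] = stack
        else:
            h, w = stack.shape[1], stack.shape[2]
            margin = max(min(h, w) // 4, 1)
            can_refine = upsample_factor > 1 and min(h, w) > 2 * margin + 2
            stackf = stack.astype(float)
            valid = ~movie._is_fill(stackf)
            int_shifts = _integer_shifts(ref, stackf, valid, max_shift=margin)
            for i, frame in enumerate(stackf):
                if np.ptp(frame[valid[i]]) == 0:
                    shift = np.zeros(2)
                else:
                    shift = int_shifts[i]
                    if can_refine:
                        # subpixel residual: upsampled cross-correlation on a
                        # central crop free of fill pixels
                        coarse = _shift_frame(frame, tuple(shift), movie.fill_value)
                        sl = (slice(margin, -margin),) * 2
                        resid, _, _ = phase_cross_correlation(
                            ref[sl], coarse[sl], upsample_factor=upsample_factor,
                        )
                        shift = shift + resid
                sub_shifts[i] = shift
                if shift[0] == 0 and shift[1] == 0:
                    out[i] = frame
                else:
                    out[i] = _shift_frame(frame, tuple(shift), movie.fill_value)
        shifts[pos] = sub_shifts
        corrected[pos] = out
    all_shifts = np.concatenate(list(shifts.values()), axis=0)
    summary = {
        "mean_abs_shift": float(np.abs(all_shifts).mean()) if all_shifts.size else 0.0,
        "max_abs_shift": float(np.abs(all_shifts).max()) if all_shifts.size else 0.0,
        "flat_subfields": flat,
    }
    movie_out = ChessboardMovie(
        grid_shape=movie.grid_shape,
        frames=corrected,
        frame_rate=movie.frame_rate,
        subfield_center_xyz=movie.subfield_center_xyz,
        fill_value=movie.fill_value,
    )
    return shifts, movie_out, summary


# --------------------------------------------------------------------------
# Pixel cleaning
# --------------------------------------------------------------------------

@dataclass
class CleanedRoi:
    """Valid soma pixels of one ROI after fill-value screening."""

    pixels: np.ndarray
    weights: np.ndarray            # renormalized to sum 1 over valid pixels
    pixel_traces: np.ndarray       # (n_valid, n_frames)
    n_dropped: int
    valid: bool


def clean_roi_pixels(movie: ChessboardMovie, roiset: RoiSet) -> list[CleanedRoi]:
    """Drop soma pixels whose trace ever touches the fill value.

    After per-subfield motion correction, pixels shifted out of the imaging
    frame carry fill values; a single contaminated sample invalidates the
    whole pixel trace.  Remaining weights are renormalized to sum to 1.  An
    ROI losing all its pixels is flagged invalid (``valid=False``) rather
    than raising, so callers can exclude it downstream.
    """
    out: list[CleanedRoi] = []
    for roi in roiset:
        stack = movie.frames[roi.home_subfield]
        h, w = stack.shape[1], stack.shape[2]
        rows, cols = roi.soma_pixels[:, 0], roi.soma_pixels[:, 1]
        inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        traces = np.full((len(roi.soma_pixels), stack.shape[0]), movie.fill_value)
        traces[inside] = stack[:, rows[inside], cols[inside]].T
        contaminated = movie._is_fill(traces).any(axis=1)
        keep = inside & ~contaminated
        n_dropped = int((~keep).sum())
        weights = roi.soma_weights[keep]
        total = weights.sum()
        if keep.sum() == 0 or total == 0:
            out.append(CleanedRoi(
                pixels=roi.soma_pixels[:0], weights=np.empty(0),
                pixel_traces=np.empty((0, stack.shape[0])),
                n_dropped=n_dropped, valid=False,
            ))
            continue
        out.append(CleanedRoi(
            pixels=roi.soma_pixels[keep],
            weights=weights / total,
            pixel_traces=traces[keep],
            n_dropped=n_dropped,
            valid=True,
        ))
    return out


@dataclass
class CleanedNeuropil:
    """Valid neuropil pixels of one ROI, equal-weighted after cleaning."""

    pixels: np.ndarray
    n_dropped: int
    empty: bool


def clean_neuropil_pixels(
    roiset: RoiSet,
    subfield_shape: tuple[int, int],
) -> list[CleanedNeuropil]:
    """Restrict each neuropil mask to its home subfield and soma-free pixels.

    Automatic segmentation does not know about chessboard borders, so
    neuropil annuli spill into neighboring subfields that sit elsewhere in
    the scanned volume.  Pixels outside the home subfield's rectangle, or
    overlapping the soma pixels of any ROI in the same subfield (including
    the ROI's own), are removed; survivors are averaged with equal weight.
    """
    h, w = subfield_shape
    soma_by_subfield: dict[tuple[int, int], set[tuple[int, int]]] = {}
    for roi in roiset:
        soma_by_subfield.setdefault(roi.home_subfield, set()).update(
            map(tuple, roi.soma_pixels)
        )
    out: list[CleanedNeuropil] = []
    for roi in roiset:
        soma_px = soma_by_subfield.get(roi.home_subfield, set())
        keep = []
        for px in map(tuple, roi.neuropil_pixels):
            r, c = px
            if 0 <= r < h and 0 <= c < w and px not in soma_px:
                keep.append(px)
        n_dropped = len(roi.neuropil_pixels) - len(keep)
        out.append(CleanedNeuropil(
            pixels=np.array(keep, dtype=int).reshape(-1, 2),
            n_dropped=n_dropped,
            empty=len(keep) == 0,
        ))
    return out


# --------------------------------------------------------------------------
# Trace arithmetic
# --------------------------------------------------------------------------

def neuropil_correct(f_roi: np.ndarray, f_np: np.ndarray, mix: float = 0.6) -> np.ndarray:
    """Subtract a fixed fraction of the neuropil trace from the soma trace.

    corrected(t) = F_roi(t) - mix * F_np(t), with mix = 0.6 by default.
    """
    f_roi = np.asarray(f_roi, dtype=float)
    f_np = np.asarray(f_np, dtype=float)
    if f_roi.shape != f_np.shape:
        raise ValueError(
            f"trace length mismatch: soma {f_roi.shape} vs neuropil {f_np.shape}"
        )
    if not 0.0 <= mix <= 1.0:
        raise ValueError(f"mix must be in [0, 1], got {mix}")
    return f_roi - mix * f_np


def compute_dff(
    f: np.ndarray,
    baseline_percentile: float = 8.0,
    method: str = "linear",
    roi_id: int | str | None = None,
) -> tuple[np.ndarray, float]:
    """dF/F against a low-percentile baseline of the full day trace.

    F0 is the ``baseline_percentile``-th percentile (8% by default) of all
    samples of the (neuropil-corrected) trace; dff = (F - F0) / F0.  The
    percentile uses linear interpolation between order statistics by
    default; ``method='nearest'`` switches to the nearest-rank convention.
    """
    f = np.asarray(f, dtype=float)
    if f.size < 2:
        raise ValueError("need at least 2 samples to define a baseline")
    interp = {"linear": "linear", "nearest": "nearest"}[method]
    f0 = float(np.percentile(f, baseline_percentile, method=interp))
    if f0 <= 0:
        label = "" if roi_id is None else f" for ROI {roi_id}"
        raise ValueError(
            f"baseline F0={f0:.4g}{label} is nonpositive; corrected trace "
            "went nonpositive at baseline, dF/F undefined"
        )
    return (f - f0) / f0, f0


def extract_traces(
    movie: ChessboardMovie,
    roiset: RoiSet,
    mix: float = 0.6,
    baseline_percentile: float = 8.0,
) -> list[FluorescenceTraces | None]:
    """Full trace pipeline: clean pixels, form traces, correct, normalize.

    Returns one FluorescenceTraces per ROI, or None for ROIs invalidated by
    pixel cleaning.  ROIs whose neuropil empties after cleaning fall back to
    a zero neuropil trace (the correction then reduces to the identity).
    """
    cleaned = clean_roi_pixels(movie, roiset)
    neuropils = clean_neuropil_pixels(roiset, movie.subfield_shape)
    out: list[FluorescenceTraces | None] = []
    for roi, soma, npil in zip(roiset, cleaned, neuropils):
        if not soma.valid:
            out.append(None)
            continue
        f_roi = soma.weights @ soma.pixel_traces
        stack = movie.frames[roi.home_subfield]
        if npil.empty:
            f_np = np.zeros(movie.n_frames)
        else:
            f_np = stack[:, npil.pixels[:, 0], npil.pixels[:, 1]].mean(axis=1)
        corrected = neuropil_correct(f_roi, f_np, mix=mix)
        dff, f0 = compute_dff(corrected, baseline_percentile)
        out.append(FluorescenceTraces(f_roi, f_np, corrected, dff, f0))
    return out
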