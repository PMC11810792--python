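"""Non-negative CP tensor decomposition of trial-aligned responses.

Trial-aligned dF/F (neurons x time x trials, cropped to the 5 s before the
zone end and Gaussian-smoothed) is factorized as a sum of rank-one
non-negative components, each a neuron loading vector, a temporal profile
and a per-trial weight.  The alternating optimization solves each factor
matrix exactly with non-negativity-constrained least squares via block
principal pivoting (an active-set exchange method that satisfies the KKT
conditions at termination), so the reconstruction error is monotone
nonincreasing across iterations.  Components are then interpreted by
correlating trial weights with the per-trial motion integral and testing
aversive-vs-control differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import linear_sum_assignment

from .learning_metrics import AlignedResponses

__all__ = [
    "TrialTensor",
    "CPFactors",
    "build_tensor",
    "nnls_bpp",
    "cp_decompose_nonneg",
    "interpret_factors",
    "factor_congruence",
]


# --------------------------------------------------------------------------
# Tensor construction
# --------------------------------------------------------------------------

@dataclass
class TrialTensor:
    """Non-negative neurons x time x trials array with trial metadata."""

    data: np.ndarray
    time: np.ndarray
    zone_labels: np.ndarray
    motion_integral: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        if np.any(np.isnan(self.data)):
            raise ValueError("tensor contains NaN")
        if np.any(self.data < 0):
            raise ValueError("tensor must be non-negative")


def build_tensor(
    aligned: AlignedResponses,
    crop: float = 5.0,
    sigma: float = 0.15,
    negative_handling: str = "clip",
) -> TrialTensor:
    """Smooth, crop and clip aligned responses into a trial tensor.

    Gaussian filtering along time (sigma in seconds, truncated kernel,
    reflect padding) precedes cropping to the last ``crop`` seconds before
    the zone end.  Negative dF/F is clipped at zero by default
    (``negative_handling='shift'`` instead subtracts the minimum), since
    the decomposition requires a non-negative array.  The per-trial motion
    integral (integral of the aligned velocity over the cropped window) is
    attached for factor interpretation.
    """
    data = aligned.data
    bad = np.unique(np.argwhere(np.isnan(data))[:, 2]) if np.isnan(data).any() else []
    if len(bad):
        raise ValueError(f"NaN in input for trials {list(map(int, bad))}")
    rate = aligned.frame_rate
    if sigma > 0:
        data = gaussian_filter1d(data, sigma=sigma * rate, axis=1, mode="reflect")
    n_crop = int(round(crop * rate))
    if n_crop > data.shape[1]:
        raise ValueError(
            f"crop of {crop} s needs {n_crop} samples but only "
            f"{data.shape[1]} are aligned"
        )
    data = data[:, -n_crop:, :]
    time = aligned.time[-n_crop:]
    if negative_handling == "clip":
        data = np.clip(data, 0.0, None)
    elif negative_handling == "shift":
        data = data - min(data.min(), 0.0)
    else:
        raise ValueError(f"unknown negative_handling {negative_handling!r}")
    vel = aligned.velocity[-n_crop:, :]
    motion = vel.sum(axis=0) / rate
    return TrialTensor(
        data=data, time=time, zone_labels=aligned.labels,
        motion_integral=motion, sigma=sigma,
    )


# --------------------------------------------------------------------------
# Non-negative least squares via block principal pivoting
# --------------------------------------------------------------------------

def _solve_bpp_column(
    C: np.ndarray, d: np.ndarray, max_iter: int = 100
) -> np.ndarray:
    """Solve min ||Ax - b||^2 s.t. x >= 0 given C = A'A and d = A'b.

    Block principal pivoting: maintain a passive set F (x free, y = 0) and
    active set G (x = 0, y = Cx - d free); exchange all KKT-violating
    variables at once while that shrinks the violation set, falling back to
    single-variable (largest index) exchanges to guarantee termination.
    """
    q = C.shape[0]
    F = np.zeros(q, dtype=bool)          # start all-active
    x = np.zeros(q)
    y = -d.copy()
    p_backup = 3
    min_violations = q + 1
    for _ in range(max_iter):
        H1 = F & (x < 0)
        H2 = ~F & (y < 0)
        n_viol = int(H1.sum() + H2.sum())
        if n_viol == 0:
            break
        if n_viol < min_violations:
            min_violations = n_viol
            p_backup = 3
            exchange = H1 | H2
        elif p_backup > 0:
            p_backup -= 1
            exchange = H1 | H2
        else:
            # backup rule: flip only the infeasible variable of largest index
            exchange = np.zeros(q, dtype=bool)
            exchange[np.max(np.flatnonzero(H1 | H2))] = True
        F = F ^ exchange
        x = np.zeros(q)
        y = -d.copy()
        if F.any():
            Fi = np.flatnonzero(F)
            CFF = C[np.ix_(Fi, Fi)]
            try:
                xf = np.linalg.solve(CFF, d[Fi])
            except np.linalg.LinAlgError:
                xf = np.linalg.lstsq(CFF, d[Fi], rcond=None)[0]
            x[Fi] = xf
            Gi = np.flatnonzero(~F)
            if Gi.size:
                y[Gi] = C[np.ix_(Gi, Fi)] @ xf - d[Gi]
            y[Fi] = 0.0
    x[np.abs(x) < 1e-14] = 0.0
    return np.clip(x, 0.0, None)


def nnls_bpp(A: np.ndarray, B: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Columnwise non-negative least squares: argmin_{X>=0} ||A X - B||_F^2.

    Exact KKT-satisfying solutions per column via block principal pivoting.
    A rank-deficient Gram matrix triggers a small ridge regularization with
    a warning (``ridge`` can also be set explicitly).  Coincides with the
    unconstrained least-squares solution whenever that is non-negative.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    C = A.T @ A
    q = C.shape[0]
    cond = np.linalg.cond(C) if q else 0.0
    if ridge == 0.0 and (not np.isfinite(cond) or cond > 1e12):
        import warnings
        ridge = 1e-10 * max(np.trace(C) / max(q, 1), 1.0)
        warnings.warn(
            f"Gram matrix ill-conditioned (cond={cond:.2e}); "
            f"applying ridge {ridge:.2e}"
        )
    if ridge > 0:
        C = C + ridge * np.eye(q)
    D = A.T @ B
    X = np.empty((q, B.shape[1]))
    for j in range(B.shape[1]):
        X[:, j] = _solve_bpp_column(C, D[:, j])
    return X


# --------------------------------------------------------------------------
# CP decomposition
# --------------------------------------------------------------------------

@dataclass
class CPFactors:
    """Factor matrices of a non-negative CP model.

    Neuron and time factor columns are unit L2-normalized with all scale
    absorbed into the trial factors, so component magnitudes are directly
    comparable across trials.  ``error`` is the relative reconstruction
    error ||T - T_hat||_F / ||T||_F.
    """

    neuron: np.ndarray
    time: np.ndarray
    trial: np.ndarray
    rank: int
    error: float
    n_iterations: int = 0
    zero_tensor: bool = False
    objective_history: list = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return np.einsum("ir,jr,kr->ijk", self.neuron, self.time, self.trial)


def _unfold(T: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(T, mode, 0).reshape(T.shape[mode], -1)


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    r = a.shape[1]
    return (a[:, None, :] * b[None, :, :]).reshape(-1, r)


def cp_decompose_nonneg(
    tensor: TrialTensor | np.ndarray,
    rank: int,
    n_restarts: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> CPFactors:
    """Alternating NNLS-BPP updates of the three CP factor matrices.

    Each mode update solves the exact non-negativity-constrained least
    squares subproblem on the matricized tensor, so the Frobenius objective
    never increases.  Converges when the relative error changes by less
    than ``tol``; the best of ``n_restarts`` random initializations is
    kept.  Deterministic given ``seed``.  A zero tensor short-circuits to
    zero factors with a flag.
    """
    T = tensor.data if isinstance(tensor, TrialTensor) else np.asarray(tensor, float)
    if rank < 1:
        raise ValueError("rank must be >= 1")
    norm_T = float(np.linalg.norm(T))
    dims = T.shape
    if norm_T == 0:
        return CPFactors(
            neuron=np.zeros((dims[0], rank)), time=np.zeros((dims[1], rank)),
            trial=np.zeros((dims[2], rank)), rank=rank, error=0.0,
            zero_tensor=True,
        )
    unfoldings = [_unfold(T, m) for m in range(3)]
    rng_master = np.random.default_rng(seed)
    best: CPFactors | None = None
    for _ in range(n_restarts):
        rng = np.random.default_rng(rng_master.integers(2**31))
        factors = [rng.random((d, rank)) + 0.1 for d in dims]
        prev_err = np.inf
        history: list[float] = []
        for it in range(max_iter):
            for mode in range(3):
                others = [factors[m] for m in range(3) if m != mode][::-1]
                kr = _khatri_rao(others[1], others[0])  # consistent with unfold order
                factors[mode] = nnls_bpp(kr, unfoldings[mode].T).T
            # kr now corresponds to the last updated mode (2)
            err = float(
                np.linalg.norm(unfoldings[2] - factors[2] @ kr.T) / norm_T
            )
            history.append(err)
            if err > prev_err + 1e-10:
                raise RuntimeError(
                    f"objective increased at iteration {it}: {prev_err} -> {err}"
                )
            if abs(prev_err - err) < tol:
                prev_err = err
                break
            prev_err = err
        result = CPFactors(
            neuron=factors[0], time=factors[1], trial=factors[2],
            rank=rank, error=prev_err, n_iterations=len(history),
            objective_history=history,
        )
        if best is None or result.error < best.error:
            best = result
    # normalization convention: unit neuron/time columns, scale in trials
    for mat in (best.neuron, best.time):
        scale = np.linalg.norm(mat, axis=0)
        nonzero = scale > 0
        mat[:, nonzero] /= scale[nonzero]
        best.trial[:, nonzero] *= scale[nonzero]
    return best


# --------------------------------------------------------------------------
# Interpretation
# --------------------------------------------------------------------------

def _kinetic_tag(time_factor: np.ndarray) -> str:
    y = np.asarray(time_factor, dtype=float)
    n = y.size
    if np.ptp(y) == 0:
        return "flat"
    peak = int(np.argmax(y))
    rho = stats.spearmanr(np.arange(n), y).statistic
    if peak >= 0.8 * (n - 1) and rho > 0.7:
        return "ramp"
    if peak <= 0.3 * (n - 1):
        return "on"
    return "other"


def interpret_factors(
    factors: CPFactors,
    motion_integral: np.ndarray,
    zone_labels: np.ndarray,
) -> list[dict]:
    """Per-component motion correlation, zone preference and kinetic tag.

    For every component: Pearson r between the trial factor and the
    per-trial motion integral; aversive-vs-control comparison of the trial
    weights with both a two-sample t-test and a Mann--Whitney U-test; and a
    kinetic tag read off the temporal profile (monotone rise to the end ->
    ramp, early peak -> on).  All-zero trial factors are flagged with
    undefined correlations.
    """
    motion = np.asarray(motion_integral, dtype=float)
    labels = np.asarray(zone_labels)
    out = []
    for r in range(factors.rank):
        w = factors.trial[:, r]
        entry: dict = {"component": r, "kinetic": _kinetic_tag(factors.time[:, r])}
        if np.ptp(w) == 0:
            entry.update(flagged=True, motion_r=None, t_p=None, mw_p=None)
            out.append(entry)
            continue
        entry["flagged"] = False
        if np.ptp(motion) == 0:
            entry["motion_r"] = None
        else:
            entry["motion_r"] = float(stats.pearsonr(w, motion).statistic)
        aver, ctrl = w[labels == "AVER"], w[labels == "CTRL"]
        if aver.size >= 2 and ctrl.size >= 2:
            entry["t_p"] = float(stats.ttest_ind(aver, ctrl).pvalue)
            entry["mw_p"] = float(stats.mannwhitneyu(aver, ctrl).pvalue)
            entry["aver_mean"] = float(aver.mean())
            entry["ctrl_mean"] = float(ctrl.mean())
        else:
            entry["t_p"] = entry["mw_p"] = None
        out.append(entry)
    return out


def factor_congruence(a: CPFactors, b: CPFactors) -> np.ndarray:
    """Best-matched per-component congruence between two CP models.

    The congruence of two components is the product over modes of the
    cosine similarity of their factor columns; components are matched by
    maximizing the total congruence (Hungarian assignment).  Returns the
    per-component congruence after matching.
    """

    def cols_cos(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xn = x / np.maximum(np.linalg.norm(x, axis=0, keepdims=True), 1e-300)
        yn = y / np.maximum(np.linalg.norm(y, axis=0, keepdims=True), 1e-300)
        return xn.T @ yn

    sim = (cols_cos(a.neuron, b.neuron)
           * cols_cos(a.time, b.time)
           * cols_cos(a.trial, b.trial))
    row, col = linear_sum_assignment(-sim)
    return sim[row, col]
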