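"""Stochastic dynamic operator (SDO) estimation and application.

The SDO is an ``n × n`` matrix ``L`` that maps a pre-event state probability
distribution ``p(x0)`` to the *change* in distribution: ``Δp(x) = L p(x0)``,
so the post-event distribution is predicted as ``p̂(x1) = p(x0) + L p(x0)``.
It generalizes the spike-triggered average to a state-dependent probability
flow.  A valid SDO (left-stochastic convention: columns carry the
normalization) satisfies four constraints:

1. nonpositive diagonal,
2. nonnegative off-diagonal,
3. every column sums to zero,
4. the positive elements in each column sum to at most one.

The direct linear estimator used throughout is

    L = (1/k) (P1 · P0ᵀ − diag(Σ_s p(x0)_s))

— the average over spikes of the per-spike operator
``p(x1) p(x0)ᵀ − diag(p(x0))``, which is compliant by construction for any
simplex inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

CONSTRAINT_TOL = 1e-9

__all__ = [
    "SpikeTrain",
    "DistributionEnsemble",
    "SDOMatrix",
    "state_prefix_counts",
    "window_distributions",
    "perievent_distributions",
    "estimate_sdo_linear",
    "estimate_sdo_optim",
    "check_sdo_constraints",
    "normalize_sdo",
    "rescale_sdo",
    "predict_post",
    "solve_sdo_lsq_oracle",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike event times of one unit in one trial.

    ``times`` are in seconds.  Use :meth:`indices` to get sample indices for
    a given sampling rate, or :meth:`from_indices` to build a train from
    sample indices directly (as the simulators do).
    """

    times: np.ndarray
    unit_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError("spike times must be sorted ascending")

    @property
    def k(self) -> int:
        return self.times.size

    def indices(self, fs: float) -> np.ndarray:
        """Sample index of the time bin containing each spike."""
        return np.floor(self.times * fs).astype(np.int64)

    @classmethod
    def from_indices(cls, idx: np.ndarray, fs: float, **kw) -> "SpikeTrain":
        return cls(times=np.asarray(idx, dtype=float) / fs, **kw)


@dataclass(frozen=True)
class DistributionEnsemble:
    """Per-spike pre/post state distributions stacked over k events.

    ``P0`` and ``P1`` are ``n × k`` column-stochastic matrices (one simplex
    column per retained spike); ``dP = P1 − P0``.  ``n_dropped`` counts spikes
    whose perievent window crossed a trial boundary and were excluded.
    ``spike_indices`` are the sample indices of the retained spikes (when the
    ensemble came from a state series).
    """

    P0: np.ndarray
    P1: np.ndarray
    n_states: int
    n_dropped: int = 0
    spike_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        P0 = np.asarray(self.P0, dtype=float)
        P1 = np.asarray(self.P1, dtype=float)
        object.__setattr__(self, "P0", P0)
        object.__setattr__(self, "P1", P1)
        if P0.shape != P1.shape or P0.shape[0] != self.n_states:
            raise ValueError("P0/P1 must both be (n_states, k)")
        for name, P in (("P0", P0), ("P1", P1)):
            if P.size and (P.min() < -1e-12 or np.abs(P.sum(axis=0) - 1.0).max() > 1e-9):
                raise ValueError(f"columns of {name} must be probability distributions")

    @property
    def k(self) -> int:
        return self.P0.shape[1]

    @property
    def dP(self) -> np.ndarray:
        return self.P1 - self.P0

    @property
    def p0_bar(self) -> np.ndarray:
        """Ensemble-average pre-spike distribution."""
        return self.P0.mean(axis=1)

    @property
    def p1_bar(self) -> np.ndarray:
        return self.P1.mean(axis=1)

    @property
    def joint(self) -> np.ndarray:
        """Average joint pre/post distribution ``(1/k) P1 · P0ᵀ`` (post on rows)."""
        return self.P1 @ self.P0.T / self.k

    @property
    def Rxx(self) -> np.ndarray:
        return self.P0 @ self.P0.T

    @property
    def Rxy(self) -> np.ndarray:
        return self.dP @ self.P0.T


@dataclass(frozen=True)
class SDOMatrix:
    """An SDO with its bookkeeping.

    ``form`` is ``raw`` (as estimated; reflects the pre-spike sampling),
    ``normalized`` (columns divided by the ensemble-average pre-spike
    probability: the conditional form used for prediction) or ``rescaled``
    (a normalized SDO re-multiplied by a reference pre-spike distribution,
    used to put spike-triggered / shuffled / background operators on a common
    footing before comparing them).
    """

    L: np.ndarray
    form: str = "raw"
    n_spikes: int = 0
    p0_bar: np.ndarray | None = None
    zeroed_columns: np.ndarray | None = None

    def __post_init__(self) -> None:
        L = np.asarray(self.L, dtype=float)
        object.__setattr__(self, "L", L)
        if L.ndim != 2 or L.shape[0] != L.shape[1]:
            raise ValueError("L must be square")
        if self.form not in ("raw", "normalized", "rescaled"):
            raise ValueError(f"unknown form {self.form!r}")

    @property
    def n_states(self) -> int:
        return self.L.shape[0]


def state_prefix_counts(states: np.ndarray, n_states: int) -> np.ndarray:
    """Cumulative one-hot state counts: ``C[t, i]`` = #{s < t : state_s = i+1}.

    Windowed state histograms then cost O(n) per window via
    ``C[stop] - C[start]``, which is what makes the shuffle batteries cheap.
    """
    states = np.asarray(states)
    T = states.size
    C = np.zeros((T + 1, n_states), dtype=np.int32)
    C[np.arange(1, T + 1), states - 1] = 1
    np.cumsum(C, axis=0, out=C)
    return C


def window_distributions(
    C: np.ndarray, starts: np.ndarray, stops: np.ndarray
) -> np.ndarray:
    """State histograms over half-open sample windows ``[start, stop)``.

    Returns an array of shape ``starts.shape + (n_states,)`` of normalized
    distributions.
    """
    counts = C[stops] - C[starts]
    width = (stops - starts).astype(float)
    return counts / width[..., None]


def perievent_windows(
    spike_idx: np.ndarray, pre_bins: int, post_bins: int, n_samples: int
) -> np.ndarray:
    """Boolean mask of spikes whose pre and post windows fit in the series."""
    s = np.asarray(spike_idx)
    return (s >= pre_bins - 1) & (s + post_bins < n_samples)


def perievent_distributions(
    states,
    spikes,
    pre_bins: int = 20,
    post_bins: int = 20,
    _prefix: np.ndarray | None = None,
) -> DistributionEnsemble:
    """Extract per-spike pre/post state distributions.

    The pre-spike window covers the ``pre_bins`` samples ending at (and
    including) the bin containing the spike; the post-spike window covers the
    ``post_bins`` samples after it.  Spikes whose windows cross the series
    boundaries are dropped and counted in ``n_dropped``.

    Parameters
    ----------
    states : StateSeries
        Quantized signal.
    spikes : SpikeTrain or ndarray
        Spike train (times in s) or spike sample indices directly.
    """
    if pre_bins < 1 or post_bins < 1:
        raise ValueError("pre_bins and post_bins must be >= 1")
    if hasattr(spikes, "indices"):
        idx = spikes.indices(states.fs)
    else:
        idx = np.asarray(spikes, dtype=np.int64)
    T = states.n_samples
    keep = perievent_windows(idx, pre_bins, post_bins, T)
    kept = idx[keep]
    n_dropped = int(idx.size - kept.size)
    if kept.size == 0:
        raise ValueError("no spikes with complete perievent windows")
    C = _prefix if _prefix is not None else state_prefix_counts(states.states, states.n_states)
    # pre window samples [s-pre+1, s] -> prefix slice [s-pre+1, s+1)
    P0 = window_distributions(C, kept - pre_bins + 1, kept + 1).T
    P1 = window_distributions(C, kept + 1, kept + post_bins + 1).T
    return DistributionEnsemble(
        P0=P0, P1=P1, n_states=states.n_states, n_dropped=n_dropped, spike_indices=kept
    )


def estimate_sdo_linear(ens: DistributionEnsemble) -> SDOMatrix:
    """Direct linear SDO estimate ``L = (1/k)(P1·P0ᵀ − diag ΣP0)``.

    Equals the spike-wise average of ``p(x1)p(x0)ᵀ − diag(p(x0))`` and is a
    compliant SDO for any ensemble of simplex columns.
    """
    if ens.k < 1:
        raise ValueError("ensemble must contain at least one spike")
    k = ens.k
    L = (ens.P1 @ ens.P0.T - np.diag(ens.P0.sum(axis=1))) / k
    return SDOMatrix(L=L, form="raw", n_spikes=k, p0_bar=ens.p0_bar)


def check_sdo_constraints(L: np.ndarray, tol: float = CONSTRAINT_TOL) -> list[str]:
    """Return a list of violated SDO constraints (empty list = valid)."""
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValueError("L must be a square matrix")
    violations: list[str] = []
    d = np.diag(L)
    off = L - np.diag(d)
    if np.any(d > tol):
        violations.append("diagonal nonpositive")
    if np.any(off < -tol):
        violations.append("off-diagonal nonnegative")
    if np.any(np.abs(L.sum(axis=0)) > tol):
        violations.append("columns sum to zero")
    pos_sum = np.where(L > 0, L, 0.0).sum(axis=0)
    if np.any(pos_sum > 1.0 + tol):
        violations.append("positive column mass at most one")
    return violations


def normalize_sdo(sdo: SDOMatrix, p0_bar: np.ndarray | None = None) -> SDOMatrix:
    """Divide column ``j`` by the average pre-spike probability of state ``j``.

    This converts the raw (joint-scaled) SDO into its conditional form
    ``Δp(x1|x0)``, the form used for event-wise prediction.  Columns whose
    pre-spike probability is zero are set to zero and flagged in
    ``zeroed_columns``.
    """
    if sdo.form != "raw":
        raise ValueError("normalize_sdo expects a raw-form SDO")
    p0 = np.asarray(p0_bar if p0_bar is not None else sdo.p0_bar, dtype=float)
    if p0 is None or p0.shape != (sdo.n_states,):
        raise ValueError("p0_bar of length n_states required")
    zero = p0 <= 0.0
    scale = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, p0))
    L = sdo.L * scale[None, :]
    return SDOMatrix(
        L=L, form="normalized", n_spikes=sdo.n_spikes, p0_bar=p0, zeroed_columns=zero
    )


def rescale_sdo(sdo: SDOMatrix, p0_target: np.ndarray) -> SDOMatrix:
    """Multiply column ``j`` of a normalized SDO by ``p0_target[j]``.

    Rescaling shuffled and background operators by the spike-triggered
    ensemble's average pre-spike distribution simulates what they would look
    like under the spike-triggered pre-state sampling; rescaling an operator
    by its own ``p0_bar`` reproduces the raw matrix.
    """
    if sdo.form != "normalized":
        raise ValueError("rescale_sdo expects a normalized-form SDO")
    p0 = np.asarray(p0_target, dtype=float)
    L = sdo.L * p0[None, :]
    return SDOMatrix(
        L=L,
        form="rescaled",
        n_spikes=sdo.n_spikes,
        p0_bar=p0,
        zeroed_columns=sdo.zeroed_columns,
    )


def predict_post(M, p0: np.ndarray, tol: float = CONSTRAINT_TOL) -> np.ndarray:
    """Apply the common update ``p̂(x1) = p0 + M·p0``.

    ``M`` may be an :class:`SDOMatrix`, a hypothesis matrix wrapper, or a bare
    array; it must satisfy the SDO constraints (which guarantee the output is
    a probability distribution).  Tiny floating-point drift in the output sum
    is renormalized.
    """
    L = M.L if hasattr(M, "L") else np.asarray(M, dtype=float)
    violations = check_sdo_constraints(L, tol=1e-8)
    if violations:
        raise ValueError(f"matrix violates SDO constraints: {violations}")
    p0 = np.asarray(p0, dtype=float)
    p1 = p0 + L @ p0
    p1 = np.maximum(p1, 0.0)
    err = abs(p1.sum() - 1.0)
    if err > 1e-9:
        raise ValueError(f"prediction does not sum to 1 (|err|={err:.3g})")
    if err > 1e-12:
        p1 = p1 / p1.sum()
    return p1


def predict_post_batch(L: np.ndarray, P0: np.ndarray) -> np.ndarray:
    """Vectorized ``p̂(x1)`` for a column-stacked batch ``P0`` (n × k)."""
    P1 = P0 + L @ P0
    P1 = np.maximum(P1, 0.0)
    return P1 / P1.sum(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# alternative estimators


def estimate_sdo_optim(
    ens: DistributionEnsemble,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> SDOMatrix:
    """Constraint-satisfying SDO minimizing the mean squared residual.

    Minimizes ``mean_s ||dP_s − L p(x0)_s||²`` over matrices satisfying the
    four SDO constraints, starting from the direct linear estimate.  The free
    parameters are the off-diagonal elements (bounded below by 0); each
    diagonal element is minus its column's off-diagonal sum, which enforces
    the zero-column-sum and nonpositive-diagonal constraints structurally,
    and the positive column mass is capped at one by inequality constraints.

    If the solver fails to improve on the linear estimate, the linear
    estimate is returned with a warning.
    """
    n, k = ens.n_states, ens.k
    if k < 1:
        raise ValueError("ensemble must contain at least one spike")
    off_mask = ~np.eye(n, dtype=bool)

    def unpack(theta: np.ndarray) -> np.ndarray:
        L = np.zeros((n, n))
        L[off_mask] = theta
        np.fill_diagonal(L, -L.sum(axis=0))
        return L

    P0, dP = ens.P0, ens.dP

    def objective(theta: np.ndarray) -> float:
        R = unpack(theta) @ P0 - dP
        return float((R * R).sum() / k)

    def grad(theta: np.ndarray) -> np.ndarray:
        L = unpack(theta)
        R = (L @ P0 - dP) @ P0.T * (2.0 / k)  # dJ/dL full matrix
        # chain rule through the structural diagonal: dL_jj/dtheta_ij = -1
        G = R - np.diag(R)[None, :]
        return G[off_mask]

    linear = estimate_sdo_linear(ens)
    theta0 = linear.L[off_mask]
    result = optimize.minimize(
        objective,
        theta0,
        jac=grad,
        bounds=[(0.0, 1.0)] * theta0.size,
        constraints=[{"type": "ineq", "fun": lambda th: _col_pos_mass_slack(th, n, off_mask)}],
        method="SLSQP",
        options={"maxiter": max_iter, "ftol": tol},
    )
    if not result.success:
        logger.warning("SDO optimizer did not converge: %s", result.message)
    L = unpack(result.x)
    if objective(result.x) > objective(theta0) + tol:
        logger.warning("optimizer failed to improve on the linear estimate; returning it")
        return linear
    return SDOMatrix(L=L, form="raw", n_spikes=k, p0_bar=ens.p0_bar)


def _col_pos_mass_slack(theta: np.ndarray, n: int, off_mask: np.ndarray) -> np.ndarray:
    L = np.zeros((n, n))
    L[off_mask] = theta
    return 1.0 - L.sum(axis=0)


def solve_sdo_lsq_oracle(ens: DistributionEnsemble):
    """Classical least-squares route ``L = Rxy · Rxx⁻¹`` (reference oracle).

    Returns ``(L, True)`` when the pre-spike covariance ``Rxx`` is
    invertible, else ``(None, False)``: with few spikes or little pre-state
    diversity ``Rxx`` is rank deficient and this route is ill-posed, which is
    why the direct linear estimator exists.  Used only as a small-instance
    test oracle.
    """
    Rxx = ens.Rxx
    n = ens.n_states
    if np.linalg.matrix_rank(Rxx, tol=1e-10) < n:
        return None, False
    cond = np.linalg.cond(Rxx)
    if not np.isfinite(cond) or cond > 1e12:
        return None, False
    return ens.Rxy @ np.linalg.inv(Rxx), True
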