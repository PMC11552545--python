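"""The seven predictor matrices H1–H7 sharing the update ``p̂(x1) = p0 + M·p0``.

Each hypothesis encodes a different statistical model of how a spike relates
to the signal:

=====  ====================================================================
H1     no effect, no drift (zero matrix)
H2     no effect, random drift (Gaussian diffusion of the prior)
H3     classical STA in state space: every prior maps to the average
       post-spike distribution
H4     background dynamics only: an SDO estimated over *all* time points
H5     Markov dynamics fitted to pre-spike transitions, iterated over the
       post window
H6     background dynamics plus a state-independent (STA-like) mean shift
H7     the spike-triggered SDO itself
=====  ====================================================================

All seven satisfy the SDO constraints, so their predictions are valid
probability distributions.  H4 and H7 are produced in conditional
(normalized) form for event-wise prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DistributionEnsemble,
    SDOMatrix,
    check_sdo_constraints,
    estimate_sdo_linear,
    normalize_sdo,
    perievent_windows,
    state_prefix_counts,
    window_distributions,
)

logger = logging.getLogger(__name__)

H_IDS = ("H1", "H2", "H3", "H4", "H5", "H6", "H7")

__all__ = [
    "HypothesisMatrix",
    "h1_null",
    "h2_diffusion",
    "h3_sta",
    "h4_background",
    "h5_markov",
    "h6_background_plus_sta",
    "h7_spike_sdo",
    "build_all_hypotheses",
]


@dataclass(frozen=True)
class HypothesisMatrix:
    """A change-operator matrix ``M`` with its hypothesis tag and provenance."""

    M: np.ndarray
    h_id: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        object.__setattr__(self, "M", M)
        violations = check_sdo_constraints(M, tol=1e-8)
        if violations:
            raise ValueError(f"{self.h_id} violates SDO constraints: {violations}")

    # alias so predict_post and friends accept either container
    @property
    def L(self) -> np.ndarray:
        return self.M

    @property
    def n_states(self) -> int:
        return self.M.shape[0]


def h1_null(n_states: int) -> HypothesisMatrix:
    """H1: no spike effect, no drift — the zero matrix."""
    return HypothesisMatrix(M=np.zeros((n_states, n_states)), h_id="H1")


def gaussian_band_matrix(n_states: int, sigma: float) -> np.ndarray:
    """Column-stochastic Gaussian band: identity convolved with a Gaussian.

    Column ``j`` is a discrete Gaussian centered on state ``j``; truncation at
    the edges is renormalized so every column still sums to one.
    """
    idx = np.arange(n_states)
    G = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / sigma) ** 2)
    return G / G.sum(axis=0, keepdims=True)


def h2_diffusion(n_states: int, sigma: float = 1.0) -> HypothesisMatrix:
    """H2: no effect with random drift; ``M = G − I``.

    ``sigma`` is the diffusion kernel width in states.  The prediction keeps
    the prior mean (away from the edges) and inflates its variance.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    G = gaussian_band_matrix(n_states, sigma)
    return HypothesisMatrix(
        M=G - np.eye(n_states), h_id="H2", provenance={"sigma": sigma}
    )


def h3_sta(p1_bar: np.ndarray) -> HypothesisMatrix:
    """H3: the classical STA in state space; ``M = P̄(x1)·1ᵀ − I``.

    For any prior simplex ``p0`` the prediction is exactly the average
    post-spike distribution — prior state carries no information.
    """
    p1 = np.asarray(p1_bar, dtype=float)
    if p1.min() < -1e-12 or abs(p1.sum() - 1.0) > 1e-9:
        raise ValueError("p1_bar must be a probability distribution")
    n = p1.size
    M = np.tile(p1[:, None], (1, n)) - np.eye(n)
    return HypothesisMatrix(M=M, h_id="H3", provenance={"p1_bar": p1.tolist()})


def background_sdo(
    states,
    pre_bins: int = 20,
    post_bins: int = 20,
    _prefix: np.ndarray | None = None,
) -> SDOMatrix:
    """Raw background SDO: every valid time index treated as an event.

    Computed directly from windowed prefix sums; with T time points this is
    the linear estimate over a T-column ensemble without materializing it.
    """
    T = states.n_samples
    if T <= pre_bins + post_bins:
        raise ValueError("state series shorter than pre+post windows")
    C = _prefix if _prefix is not None else state_prefix_counts(states.states, states.n_states)
    t = np.arange(pre_bins - 1, T - post_bins)
    P0 = window_distributions(C, t - pre_bins + 1, t + 1)  # (k, n)
    P1 = window_distributions(C, t + 1, t + post_bins + 1)
    k = t.size
    L = (P1.T @ P0 - np.diag(P0.sum(axis=0))) / k
    return SDOMatrix(L=L, form="raw", n_spikes=k, p0_bar=P0.mean(axis=0))


def h4_background(
    states, pre_bins: int = 20, post_bins: int = 20, _prefix: np.ndarray | None = None
) -> HypothesisMatrix:
    """H4: prior state only, spike-independent ("background") dynamics.

    The conditional (normalized) form of the background SDO.
    """
    raw = background_sdo(states, pre_bins, post_bins, _prefix=_prefix)
    norm = normalize_sdo(raw)
    return HypothesisMatrix(
        M=norm.L,
        h_id="H4",
        provenance={"pre_bins": pre_bins, "post_bins": post_bins, "raw": raw},
    )


def markov_transition_matrix(states, spike_indices: np.ndarray, pre_bins: int) -> np.ndarray:
    """First-order left-stochastic transition matrix from pre-spike windows.

    Counts successive transitions ``x_t → x_{t+1}`` inside every pre-spike
    window; column ``j`` holds ``p(next = i | current = j)``.  Source states
    never observed get an identity column (conservative self-transition).
    """
    n = states.n_states
    x = states.states
    counts = np.zeros((n, n))
    s = np.asarray(spike_indices)
    starts = np.maximum(s - pre_bins + 1, 0)
    for a, b in zip(starts, s):  # transitions within [a, b]
        seg = x[a : b + 1]
        if seg.size >= 2:
            np.add.at(counts, (seg[1:] - 1, seg[:-1] - 1), 1)
    col = counts.sum(axis=0)
    if col.sum() == 0:
        raise ValueError("no state transitions observed in pre-spike windows")
    M0 = np.where(col[None, :] > 0, counts / np.where(col == 0, 1, col)[None, :], 0.0)
    unobserved = col == 0
    M0[np.diag_indices(n)] = np.where(unobserved, 1.0, np.diag(M0))
    return M0


def h5_markov(states, spike_indices: np.ndarray, pre_bins: int = 20, T: int = 20) -> HypothesisMatrix:
    """H5: pre-spike Markov dynamics iterated over the post window.

    ``M = (1/T)·Σ_{t=1..T} M0ᵗ − I`` where ``M0`` is the transition matrix
    estimated from successive states in the pre-spike intervals and ``T`` is
    the number of time steps in the post window.
    """
    M0 = markov_transition_matrix(states, spike_indices, pre_bins)
    acc = np.zeros_like(M0)
    P = np.eye(M0.shape[0])
    for _ in range(T):
        P = M0 @ P
        acc += P
    M_dt = acc / T
    return HypothesisMatrix(
        M=M_dt - np.eye(M0.shape[0]), h_id="H5", provenance={"T": T, "pre_bins": pre_bins}
    )


def h6_background_plus_sta(
    lb: HypothesisMatrix, dp_bar: np.ndarray
) -> HypothesisMatrix:
    """H6: background dynamics plus a state-independent spike effect.

    ``M = LB + ΔP̄(x)·1ᵀ``: since ``1ᵀp0 = 1``, the rank-one term adds the
    average spike-triggered change in distribution on top of the H4 flow.
    The sum can leave the SDO constraint set (negative off-diagonal entries
    where the mean shift opposes the background flow); such entries are
    clipped to zero and the column rebalanced through its diagonal, with the
    repair magnitude logged and recorded in the provenance.
    """
    if lb.h_id != "H4":
        raise ValueError("H6 builds on an H4 background matrix")
    dp = np.asarray(dp_bar, dtype=float)
    n = lb.n_states
    if abs(dp.sum()) > 1e-9:
        raise ValueError("mean change distribution must sum to zero")
    M = lb.M + dp[:, None]
    # constraint repair: off-diagonal >= 0, diagonal <= 0, columns re-zeroed
    off_mask = ~np.eye(n, dtype=bool)
    clipped = np.where(off_mask & (M < 0), -M, 0.0)
    repair = float(clipped.sum())
    M = np.where(off_mask, np.maximum(M, 0.0), M)
    np.fill_diagonal(M, np.minimum(-M.sum(axis=0) + np.diag(M), 0.0))
    # cap positive column mass at 1 (rescale offending columns)
    pos = np.where(M > 0, M, 0.0).sum(axis=0)
    over = pos > 1.0
    if np.any(over):
        scale = np.where(over, 1.0 / np.where(over, pos, 1.0), 1.0)
        M = M * scale[None, :]
    if repair > 0:
        logger.debug("H6 constraint repair clipped %.3g of negative off-diagonal mass", repair)
    return HypothesisMatrix(M=M, h_id="H6", provenance={"repair_mass": repair})


def h7_spike_sdo(ens: DistributionEnsemble, estimator="linear") -> HypothesisMatrix:
    """H7: the spike-triggered SDO in conditional (normalized) form."""
    if estimator == "linear":
        raw = estimate_sdo_linear(ens)
    elif estimator == "optim":
        from .core import estimate_sdo_optim

        raw = estimate_sdo_optim(ens)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    norm = normalize_sdo(raw)
    return HypothesisMatrix(
        M=norm.L, h_id="H7", provenance={"estimator": estimator, "raw": raw}
    )


def build_all_hypotheses(
    states,
    ens: DistributionEnsemble,
    pre_bins: int = 20,
    post_bins: int = 20,
    h2_sigma: float = 1.0,
    _prefix: np.ndarray | None = None,
) -> dict[str, HypothesisMatrix]:
    """Fit all seven hypothesis matrices for one (unit, signal) pair."""
    n = states.n_states
    h4 = h4_background(states, pre_bins, post_bins, _prefix=_prefix)
    return {
        "H1": h1_null(n),
        "H2": h2_diffusion(n, h2_sigma),
        "H3": h3_sta(ens.p1_bar),
        "H4": h4,
        "H5": h5_markov(states, ens.spike_indices, pre_bins, T=post_bins),
        "H6": h6_background_plus_sta(h4, ens.dP.mean(axis=1)),
        "H7": h7_spike_sdo(ens),
    }
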