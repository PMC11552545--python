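"""Visualization transforms and report plumbing for SDO analyses.

* STIRPD — the spike-triggered impulse response probability distribution:
  the distribution of signal state at every perievent lag, a probabilistic
  generalization of the STA waveform.  Summing its columns over the
  pre-spike interval recovers the ensemble-average pre-spike distribution.
* shear — re-indexes the SDO so the matrix diagonal (maintain state) lies
  on a horizontal row; rows above it are transitions toward higher states.
* quiver summary — per input state, the summed probability mass flowing
  toward higher states, toward lower states, and the diagonal value.
* motif classification — a heuristic, rule-based labeling of common sparse
  SDO geometries (step up/down, convergence, divergence, increase,
  decrease, stabilize, destabilize, diffusion).  Advisory only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import perievent_windows, state_prefix_counts

MOTIFS = (
    "step_up",
    "step_down",
    "convergence",
    "divergence",
    "increase",
    "decrease",
    "stabilize",
    "destabilize",
    "diffusion",
)

__all__ = [
    "Stirpd",
    "MotifLabel",
    "compute_stirpd",
    "shear_sdo",
    "unshear_sdo",
    "quiver_summary",
    "classify_motif",
    "report",
]


@dataclass(frozen=True)
class Stirpd:
    """p(state | perievent lag) over states × lags, plus the mean-state trace."""

    matrix: np.ndarray           # (n_states, pre+post) columns sum to 1
    pre_bins: int
    post_bins: int
    n_spikes: int

    @property
    def overlay_mean(self) -> np.ndarray:
        states = np.arange(1, self.matrix.shape[0] + 1)
        return states @ self.matrix

    @property
    def lags(self) -> np.ndarray:
        return np.arange(-self.pre_bins + 1, self.post_bins + 1)


@dataclass(frozen=True)
class MotifLabel:
    label: str
    scores: dict = field(default_factory=dict)


def compute_stirpd(states, spikes, pre_bins: int = 20, post_bins: int = 20) -> Stirpd:
    """Distribution of state at each lag in ``(−pre, +post]`` across spikes.

    Lag 0 is the bin containing the spike (the last pre-window bin, matching
    the perievent ensemble convention), so summing lag columns over the pre
    window reproduces the ensemble-average ``p(x0)``.
    """
    if hasattr(spikes, "indices"):
        idx = spikes.indices(states.fs)
    else:
        idx = np.asarray(spikes, dtype=np.int64)
    keep = perievent_windows(idx, pre_bins, post_bins, states.n_samples)
    kept = idx[keep]
    if kept.size == 0:
        raise ValueError("no spikes with complete perievent windows")
    lags = np.arange(-pre_bins + 1, post_bins + 1)
    samples = states.states[kept[:, None] + lags[None, :]]  # (k, lags)
    n = states.n_states
    M = np.zeros((n, lags.size))
    for c in range(lags.size):
        M[:, c] = np.bincount(samples[:, c] - 1, minlength=n)
    M /= kept.size
    return Stirpd(matrix=M, pre_bins=pre_bins, post_bins=post_bins, n_spikes=kept.size)


def shear_sdo(L: np.ndarray) -> np.ndarray:
    """Shear so the diagonal sits on the central horizontal row.

    Element ``(i, j)`` maps to row ``i − j + n − 1`` of column ``j`` in a
    ``(2n−1) × n`` array (0-based); row ``n−1`` holds the original diagonal,
    rows above (larger index) hold transitions toward higher states.
    """
    L = np.asarray(L)
    n = L.shape[0]
    out = np.zeros((2 * n - 1, n))
    i, j = np.indices(L.shape)
    out[i - j + n - 1, j] = L
    return out


def unshear_sdo(S: np.ndarray) -> np.ndarray:
    """Inverse of :func:`shear_sdo`."""
    n = S.shape[1]
    i, j = np.indices((n, n))
    return S[i - j + n - 1, j]


def quiver_summary(L: np.ndarray) -> dict[str, np.ndarray]:
    """Per input state: up-flow, down-flow and diagonal (maintain) mass.

    ``up_mass[j] = Σ_{i>j} L[i,j]`` (toward higher states), ``down_mass[j] =
    Σ_{i<j} L[i,j]``; for a raw SDO ``up + down + diag = 0`` per column.
    """
    L = np.asarray(L)
    return {
        "up_mass": np.tril(L, -1).sum(axis=0),
        "down_mass": np.triu(L, 1).sum(axis=0),
        "diag_value": np.diag(L).copy(),
    }


def classify_motif(
    L_norm: np.ndarray,
    occupancy_threshold: float = 0.05,
    win_score: float = 0.6,
    margin: float = 0.1,
) -> MotifLabel:
    """Heuristic motif label from the geometry of a normalized SDO.

    Scores each motif from simple band geometry — which columns carry flow,
    whether positive mass sits above or below the diagonal, whether it is
    organized as a horizontal band (convergence toward fixed states), a
    vertical band (divergence from fixed states), diagonal bands (step /
    diffusion), or directed toward/away from a setpoint (stabilize /
    destabilize).  The best-scoring motif wins if its score reaches
    ``win_score`` and leads the runner-up by ``margin``; otherwise the label
    is ``unclassified``.  Advisory: these are qualitative classes.
    """
    L = np.asarray(L_norm, dtype=float)
    n = L.shape[0]
    total = np.abs(L).sum()
    if total < 1e-12:
        return MotifLabel("unclassified", {m: 0.0 for m in MOTIFS})
    pos = np.where(L > 0, L, 0.0)
    col_mass = pos.sum(axis=0)
    occupied = col_mass > occupancy_threshold * max(col_mass.max(), 1e-12)
    occ_frac = occupied.mean()
    up = np.tril(pos, -1).sum()
    down = np.triu(pos, 1).sum()
    flow = up + down
    if flow < 1e-12:
        return MotifLabel("unclassified", {m: 0.0 for m in MOTIFS})
    up_frac = up / flow

    # geometry descriptors of the positive mass
    i, j = np.indices(L.shape)
    w = pos / flow
    row_center = (i * w).sum()
    col_center = (j * w).sum()
    row_spread = np.sqrt((((i - row_center) ** 2) * w).sum())
    col_spread = np.sqrt((((j - col_center) ** 2) * w).sum())
    offset = i - j
    off_center = (offset * w).sum()
    off_spread = np.sqrt((((offset - off_center) ** 2) * w).sum())
    narrow = 0.08 * n

    scores = dict.fromkeys(MOTIFS, 0.0)
    band_like = float(np.clip(1.0 - off_spread / narrow / 2.0, 0.0, 1.0))
    horiz = float(np.clip(1.0 - row_spread / narrow, 0.0, 1.0))
    vert = float(np.clip(1.0 - col_spread / narrow, 0.0, 1.0))
    restricted = float(np.clip(1.0 - occ_frac / 0.5, 0.0, 1.0))
    # step: narrow diagonal-parallel band strictly one side, restricted columns
    scores["step_up"] = band_like * restricted * up_frac
    scores["step_down"] = band_like * restricted * (1.0 - up_frac)
    # convergence: horizontal positive band spanning many columns
    scores["convergence"] = horiz * (1.0 - restricted)
    # divergence: vertical band — flow out of few columns to many rows
    scores["divergence"] = vert * (1.0 - horiz) * (1.0 - band_like)
    # increase/decrease: broad one-sided flow, not a tight band
    broad = 1.0 - band_like
    scores["increase"] = broad * (1.0 - horiz) * up_frac * occ_frac
    scores["decrease"] = broad * (1.0 - horiz) * (1.0 - up_frac) * occ_frac
    # stabilize: up-flow below a setpoint row, down-flow above it
    qs = quiver_summary(L)
    states = np.arange(n)
    direction = np.sign(qs["up_mass"] - qs["down_mass"])
    if occupied.sum() >= 2:
        occ_states = states[occupied]
        crossing = np.where(np.diff(direction[occupied]) < 0)[0]
        toward = float(
            ((direction[occupied][:-1] > 0) & (occ_states[:-1] < row_center)).mean()
            if occupied.sum() > 1
            else 0.0
        )
        stab = 0.0
        destab = 0.0
        d_occ = direction[occupied]
        below = occ_states < row_center
        above = occ_states > row_center
        if below.any() and above.any():
            stab = 0.5 * (
                float((d_occ[below] > 0).mean()) + float((d_occ[above] < 0).mean())
            )
            destab = 0.5 * (
                float((d_occ[below] < 0).mean()) + float((d_occ[above] > 0).mean())
            )
        # a tight horizontal band reads as convergence, not feedback control
        balance2 = min(up_frac, 1 - up_frac) * 2
        scores["stabilize"] = stab * (1.0 - band_like) * (1.0 - horiz) * balance2
        scores["destabilize"] = destab * (1.0 - band_like) * (1.0 - horiz) * balance2
    # diffusion: symmetric diagonal-parallel bands on both sides
    balance = 1.0 - abs(up_frac - 0.5) * 2.0
    scores["diffusion"] = balance * float(np.clip(1.0 - abs(off_center) / narrow, 0, 1)) * (
        1.0 - horiz
    )

    ranked = sorted(scores.items(), key=lambda kv: kv[1], reverse=True)
    best, second = ranked[0], ranked[1]
    if best[1] >= win_score and best[1] - second[1] >= margin:
        return MotifLabel(best[0], scores)
    return MotifLabel("unclassified", scores)


# ---------------------------------------------------------------------------
# report rendering


def _save(fig, path: Path) -> str:
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return str(path)


def report(
    out_dir,
    sdo=None,
    stirpd: Stirpd | None = None,
    comparison=None,
    manifest: dict | None = None,
) -> dict:
    """Render available artifacts of a run into ``out_dir``.

    Missing artifacts are listed under ``skipped`` rather than raising, so a
    partial run still produces a report.  File naming is deterministic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, object] = {"figures": [], "skipped": []}

    if sdo is not None:
        L = sdo.L if hasattr(sdo, "L") else np.asarray(sdo)
        n = L.shape[0]
        vmax = np.abs(L).max() or 1.0
        fig, axes = plt.subplots(1, 3, figsize=(13, 4))
        im = axes[0].imshow(L, origin="lower", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        axes[0].set(title="SDO", xlabel="pre-spike state", ylabel="post-spike state")
        fig.colorbar(im, ax=axes[0], shrink=0.8)
        S = shear_sdo(L)
        axes[1].imshow(S, origin="lower", cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
        axes[1].axhline(n - 1, color="k", lw=0.5)
        axes[1].set(title="shear SDO", xlabel="pre-spike state", ylabel="Δstate + n−1")
        qs = quiver_summary(L)
        x = np.arange(1, n + 1)
        axes[2].bar(x, qs["up_mass"], color="tab:orange", label="toward higher")
        axes[2].bar(x, -qs["down_mass"], color="tab:purple", label="toward lower")
        axes[2].plot(x, qs["diag_value"], "k-", lw=1, label="diagonal")
        axes[2].axhline(0, color="k", lw=0.5)
        axes[2].set(title="quiver summary", xlabel="pre-spike state", ylabel="Δp mass")
        axes[2].legend(fontsize=7)
        written["figures"].append(_save(fig, out / "sdo_views.png"))
    else:
        written["skipped"].append("sdo")

    if stirpd is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.imshow(
            stirpd.matrix,
            origin="lower",
            aspect="auto",
            cmap="viridis",
            extent=[stirpd.lags[0], stirpd.lags[-1], 0.5, stirpd.matrix.shape[0] + 0.5],
        )
        ax.plot(stirpd.lags, stirpd.overlay_mean, "w-", lw=1.2, label="mean state")
        ax.axvline(0, color="r", lw=0.8)
        ax.set(title="STIRPD", xlabel="lag (bins)", ylabel="state")
        ax.legend(fontsize=7)
        written["figures"].append(_save(fig, out / "stirpd.png"))
    else:
        written["skipped"].append("stirpd")

    if comparison is not None:
        t = comparison.table.sort_values("e1_cum")
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        axes[0].errorbar(
            t.index,
            t["e1_cum"],
            yerr=[t["e1_cum"] - t["e1_ci_lo"], t["e1_ci_hi"] - t["e1_cum"]],
            fmt="o",
            capsize=3,
        )
        axes[0].set(title="cumulative |state error| (95% CI)", ylabel="e1 cumulative")
        axes[1].bar(t.index, t["kld_mean"])
        axes[1].set(title="mean KLD (observed ‖ predicted)")
        written["figures"].append(_save(fig, out / "model_comparison.png"))
        t.to_csv(out / "model_comparison.csv")
        written["tables"] = [str(out / "model_comparison.csv")]
    else:
        written["skipped"].append("comparison")

    if manifest is not None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        written["manifest"] = str(out / "manifest.json")

    with open(out / "report.json", "w") as fh:
        json.dump(written, fh, indent=2, sort_keys=True)
    return written
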