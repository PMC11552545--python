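"""Stochastic generators Y1–Y8 and the simulation validation study.

Eight generators produce time series with known ground truth about whether
spikes influence the signal, sharing one random spike train per simulation:

====  ===================================================================
Y1    low-pass filtered white noise (no spike effect)
Y2    Y1 plus higher-amplitude white noise during 10 ms after each spike
Y3    Y1 plus a consistent impulse response during 10 ms after each spike
Y4    stabilizing first-order dynamics toward 0 driven by the Y1 increments
      (no spike effect)
Y5    random walk of a 100-state Markov chain (Gaussian-banded transition
      matrix), mean-leveled (no spike effect)
Y6    Y4 dynamics plus the Y3 impulse responses
Y7    Y4 dynamics plus a second stabilizing equation toward a positive
      setpoint, active during 10 ms after each spike
Y8    stationary ARMA(3,2) noise, mean-leveled (no spike effect)
====  ===================================================================

Y2/Y3/Y6/Y7 carry a true spike effect; Y1/Y4/Y5/Y8 do not.  The validation
study runs the STA and SDO significance batteries over many realizations
and scores detection against this ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import SpikeTrain, state_prefix_counts
from .quantize import Signal, build_quantizer, quantize
from .significance import EFFECT_TESTS, sdo_significance_battery
from .sta import sta_any_significant, sta_battery

GEN_IDS = ("Y1", "Y2", "Y3", "Y4", "Y5", "Y6", "Y7", "Y8")
SPIKE_EFFECT_GENS = frozenset({"Y2", "Y3", "Y6", "Y7"})

__all__ = [
    "GeneratorSpec",
    "SimRealization",
    "GEN_IDS",
    "SPIKE_EFFECT_GENS",
    "gen_spike_train",
    "simulate",
    "simulate_suite",
    "run_validation_study",
    "detection_table",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Free parameters of the simulation study.

    Amplitude-like knobs are expressed relative to the background process SD
    so the study is scale free.  The spike-effect window is 10 ms.  See
    docs/methods.md for the rationale behind each default.
    """

    fs: float = 2000.0
    duration: float = 60.0
    noise_scale: float = 1.0
    lp_cutoff: float = 100.0          # Y1 low-pass corner (Hz), 4th-order Butterworth
    lp_order: int = 4
    spike_noise_scale: float = 3.0    # Y2: injected white-noise SD, × background SD
    impulse_peak: float = 6.0         # Y3/Y6: half-sine peak, × background SD
    k_stab: float = 0.05              # Y4/Y6/Y7 background stabilizing coefficient
    x0_bg: float = 0.0                # background setpoint
    k_spike: float = 0.2              # Y7: spike-triggered stabilizing coefficient
    x0_spike_sd: float = 0.0765       # Y7: spike setpoint, × background-process SD (> 0)
    markov_n: int = 100               # Y5: number of chain states
    markov_sigma: float = 2.0         # Y5: Gaussian kernel width (states)
    arima_ar: tuple = (0.5, -0.3, 0.1)
    arima_ma: tuple = (0.4, 0.2)
    effect_window_ms: float = 10.0
    n_spikes: int = 500
    min_gap_bins: int | None = None   # default: the effect window length

    def __post_init__(self) -> None:
        if not (0.0 < self.k_stab < 1.0):
            raise ValueError("stabilizing coefficient must satisfy 0 < k < 1")
        if not (0.0 < self.k_spike < 1.0):
            raise ValueError("spike stabilizing coefficient must satisfy 0 < k < 1")
        if self.x0_spike_sd <= 0.0:
            raise ValueError("Y7 spike setpoint must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @property
    def effect_bins(self) -> int:
        return int(round(self.effect_window_ms * self.fs / 1000.0))

    @property
    def gap_bins(self) -> int:
        return self.min_gap_bins if self.min_gap_bins is not None else self.effect_bins


@dataclass(frozen=True)
class SimRealization:
    """One generated signal with the simulation's common spike train."""

    signal: Signal
    spikes: SpikeTrain
    gen_id: str
    seed: int

    @property
    def spike_indices(self) -> np.ndarray:
        return self.spikes.indices(self.signal.fs)


def gen_spike_train(
    n_spikes: int,
    duration: float,
    fs: float,
    seed: int,
    min_gap: int = 20,
    margin: int = 256,
) -> SpikeTrain:
    """Uniform-random spike sample indices with an enforced minimum gap.

    ``margin`` keeps spikes clear of the series ends so perievent windows
    never cross a boundary (256 samples covers the longest analysis segment,
    the 140 ms ISA window, at 2 kHz).  Sampling draws sorted uniform indices from the
    gap-deflated range and re-inflates, which yields exact uniform placement
    subject to the spacing constraint.
    """
    T = int(round(duration * fs))
    if n_spikes == 0:
        return SpikeTrain(times=np.empty(0))
    usable = T - 2 * margin - (n_spikes - 1) * min_gap
    if usable <= n_spikes:
        raise ValueError("spike density infeasible for the requested minimum gap")
    rng = np.random.default_rng(seed)
    base = np.sort(rng.choice(usable, size=n_spikes, replace=False))
    idx = base + margin + np.arange(n_spikes) * min_gap
    return SpikeTrain.from_indices(idx, fs)


def _lowpass_noise(rng: np.random.Generator, spec: GeneratorSpec) -> np.ndarray:
    e = rng.standard_normal(spec.n_samples)
    sos = sps.butter(spec.lp_order, spec.lp_cutoff, btype="low", fs=spec.fs, output="sos")
    y = sps.sosfiltfilt(sos, e)
    return y * (spec.noise_scale / y.std())


def _effect_window_indices(spike_idx: np.ndarray, n_eff: int, T: int) -> np.ndarray:
    """Sample indices covered by the 10 ms windows after each spike."""
    offs = np.arange(1, n_eff + 1)
    win = (spike_idx[:, None] + offs[None, :]).ravel()
    return win[(win >= 0) & (win < T)]


def _half_sine_impulse(n_eff: int, peak: float) -> np.ndarray:
    return peak * np.sin(np.pi * (np.arange(1, n_eff + 1) - 0.5) / n_eff)


def _markov_walk(rng: np.random.Generator, spec: GeneratorSpec) -> np.ndarray:
    n = spec.markov_n
    idx = np.arange(n)
    K = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / spec.markov_sigma) ** 2)
    K /= K.sum(axis=0, keepdims=True)
    cdf = np.cumsum(K, axis=0)
    # inverse-CDF lookup table so the sequential walk stays cheap
    levels = 65536
    u_grid = (np.arange(levels) + 0.5) / levels
    lut = np.empty((n, levels), dtype=np.int16)
    for j in range(n):
        lut[j] = np.searchsorted(cdf[:, j], u_grid)
    T = spec.n_samples
    u = (rng.random(T) * levels).astype(np.int32)
    path = np.empty(T, dtype=np.int16)
    cur = n // 2
    lut_py = lut  # local for speed
    for t in range(T):
        cur = lut_py[cur, u[t]]
        path[t] = cur
    y = path.astype(float)
    return y - y.mean()


def _arma(rng: np.random.Generator, spec: GeneratorSpec) -> np.ndarray:
    ar = np.asarray(spec.arima_ar, dtype=float)
    ma = np.asarray(spec.arima_ma, dtype=float)
    a = np.concatenate(([1.0], -ar))
    b = np.concatenate(([1.0], ma))
    if np.any(np.abs(np.roots(a)) >= 1.0):
        raise ValueError("AR coefficients are not stationary")
    if np.any(np.abs(np.roots(b)) >= 1.0):
        raise ValueError("MA coefficients are not invertible")
    burn = 500
    e = rng.standard_normal(spec.n_samples + burn)
    y = sps.lfilter(b, a, e)[burn:]
    y = y - y.mean()
    return y * (spec.noise_scale / y.std())


def _stabilized(drive: np.ndarray, k: float) -> np.ndarray:
    """y[t] = (1 − k)·y[t−1] + drive[t] — first-order relaxation toward 0."""
    return sps.lfilter([1.0], [1.0, -(1.0 - k)], drive)


def _y7_series(
    d_y1: np.ndarray, spike_idx: np.ndarray, spec: GeneratorSpec, x0_spike: float
) -> np.ndarray:
    """Y4 dynamics with a second stabilizer active in post-spike windows."""
    T = d_y1.size
    w = np.zeros(T, dtype=bool)
    w[_effect_window_indices(spike_idx, spec.effect_bins, T)] = True
    k1, k2, x0b = spec.k_stab, spec.k_spike, spec.x0_bg
    y = np.empty(T)
    prev = 0.0
    drive_const = k1 * x0b
    for t in range(T):
        if w[t]:
            prev = prev + k1 * (x0b - prev) + k2 * (x0_spike - prev) + d_y1[t]
        else:
            prev = prev + drive_const - k1 * prev + d_y1[t]
        y[t] = prev
    return y


def simulate_suite(
    spec: GeneratorSpec,
    seed: int,
    gens: tuple[str, ...] = GEN_IDS,
) -> dict[str, SimRealization]:
    """Generate the requested generators with shared noise and spike train.

    All series derive from one Y1 white-noise realization (Y4/Y6/Y7 are
    driven by its increments, as in the generator definitions) and share one
    spike train, so spike-triggered contrasts across generators are paired.
    """
    ss = np.random.SeedSequence(seed)
    s_noise, s_spikes, s_markov, s_arma = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    ]
    spikes = gen_spike_train(
        spec.n_spikes, spec.duration, spec.fs, s_spikes, min_gap=spec.gap_bins
    )
    spike_idx = spikes.indices(spec.fs)
    T = spec.n_samples
    n_eff = spec.effect_bins

    rng_noise = np.random.default_rng(s_noise)
    y1 = _lowpass_noise(rng_noise, spec)
    sd1 = y1.std()
    d_y1 = np.diff(y1, prepend=0.0)
    win = _effect_window_indices(spike_idx, n_eff, T)

    out: dict[str, SimRealization] = {}

    def add(gen: str, samples: np.ndarray) -> None:
        out[gen] = SimRealization(
            signal=Signal(samples=samples, fs=spec.fs, channel_id=gen),
            spikes=spikes,
            gen_id=gen,
            seed=seed,
        )

    need = set(gens)
    y4 = None
    if need & {"Y4", "Y6", "Y7"}:
        y4 = _stabilized(d_y1, spec.k_stab) + spec.x0_bg
    if "Y1" in need:
        add("Y1", y1)
    if "Y2" in need:
        y2 = y1.copy()
        y2[win] += rng_noise.standard_normal(win.size) * spec.spike_noise_scale * sd1
        add("Y2", y2)
    impulse = _half_sine_impulse(n_eff, spec.impulse_peak * sd1)
    if "Y3" in need:
        y3 = y1.copy()
        y3[win] += np.tile(impulse, spike_idx.size)[: win.size]
        add("Y3", y3)
    if "Y4" in need:
        add("Y4", y4)
    if "Y5" in need:
        add("Y5", _markov_walk(np.random.default_rng(s_markov), spec))
    if "Y6" in need:
        y6 = y4.copy()
        y6[win] += np.tile(impulse, spike_idx.size)[: win.size]
        add("Y6", y6)
    if "Y7" in need:
        x0s = spec.x0_spike_sd * y4.std()
        add("Y7", _y7_series(d_y1, spike_idx, spec, x0s))
    if "Y8" in need:
        add("Y8", _arma(np.random.default_rng(s_arma), spec))
    return out


def simulate(spec: GeneratorSpec, gen_id: str, seed: int) -> SimRealization:
    """Generate a single realization of one generator."""
    if gen_id not in GEN_IDS:
        raise ValueError(f"unknown generator {gen_id!r}")
    return simulate_suite(spec, seed, gens=(gen_id,))[gen_id]


# ---------------------------------------------------------------------------
# validation study


def analyze_realization(
    real: SimRealization,
    n_states: int = 20,
    pre_bins: int = 20,
    post_bins: int = 20,
    n_shuffles: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    sdo_tests: tuple[str, ...] = EFFECT_TESTS,
    run_sdo: bool = True,
    run_sta: bool = True,
    sta_tests: tuple[str, ...] = ("simple_t", "isa", "bootstrap_sd"),
) -> dict[str, bool]:
    """Run the STA and SDO significance batteries on one realization.

    Returns ``{test_name: significant}`` including the combined ``sta_any``
    and ``sdo_any`` decisions.  Signal states are 20 linear bins over the
    realization's min..max, matching the simulated-data convention.
    """
    decisions: dict[str, bool] = {}
    idx = real.spike_indices
    if run_sta:
        res = sta_battery(real.signal, idx, alpha=alpha, seed=seed)
        res = {k: v for k, v in res.items() if k in sta_tests}
        for name, dec in res.items():
            decisions[f"sta_{name}"] = bool(dec.analyzed and dec.significant)
        decisions["sta_any"] = bool(sta_any_significant(res))
    if run_sdo:
        q = build_quantizer(real.signal.samples, n_states=n_states, scheme="linear")
        states = quantize(real.signal, q)
        results, decision = sdo_significance_battery(
            states,
            idx,
            pre_bins=pre_bins,
            post_bins=post_bins,
            n_shuffles=n_shuffles,
            seed=seed,
            alpha=alpha,
            n_corrections=n_states,
            tests=sdo_tests,
        )
        for r in results:
            decisions[f"sdo_{r.statistic_name}"] = bool(r.significant)
        decisions["sdo_any"] = bool(decision.effect)
    return decisions


def run_validation_study(
    n_sims: int,
    n_spikes: int = 500,
    n_shuffles: int = 1000,
    spec_overrides: dict | None = None,
    seed: int = 0,
    gens: tuple[str, ...] = GEN_IDS,
    n_states: int = 20,
    alpha: float = 0.05,
    sdo_tests: tuple[str, ...] = EFFECT_TESTS,
    run_sdo: bool = True,
    run_sta: bool = True,
    sta_tests: tuple[str, ...] = ("simple_t", "isa", "bootstrap_sd"),
) -> pd.DataFrame:
    """Monte-Carlo study of significance-test performance on Y1–Y8.

    Each simulation draws one spike train shared by all requested
    generators, runs the requested test batteries, and records one row per
    (simulation, generator, test) with the decision and its correctness
    (spike effect truly present only for Y2/Y3/Y6/Y7).
    """
    spec = GeneratorSpec(n_spikes=n_spikes, **(spec_overrides or {}))
    rows = []
    sim_seeds = np.random.SeedSequence(seed).spawn(n_sims)
    for i, ss in enumerate(sim_seeds):
        child = ss.generate_state(2) % (2**31)
        suite = simulate_suite(spec, int(child[0]), gens=gens)
        for gen in gens:
            decisions = analyze_realization(
                suite[gen],
                n_states=n_states,
                n_shuffles=n_shuffles,
                seed=int(child[1]),
                alpha=alpha,
                sdo_tests=sdo_tests,
                run_sdo=run_sdo,
                run_sta=run_sta,
                sta_tests=sta_tests,
            )
            truth = gen in SPIKE_EFFECT_GENS
            for test, sig in decisions.items():
                rows.append(
                    {
                        "sim": i,
                        "gen": gen,
                        "test": test,
                        "significant": sig,
                        "effect_present": truth,
                        "correct": sig == truth,
                    }
                )
    return pd.DataFrame(rows)


def detection_table(study: pd.DataFrame, value: str = "significant") -> pd.DataFrame:
    """Pivot a study frame to per-(test, generator) proportions."""
    return study.pivot_table(index="test", columns="gen", values=value, aggfunc="mean")


def synthesize_operator_ensemble(L_norm: np.ndarray, k: int, seed: int, m_draws: int = 20):
    """Ensemble generated by applying a known conditional SDO to sampled priors.

    Pre-spike states are drawn uniformly; each pre-distribution is the state
    indicator and the post-distribution is an ``m_draws``-sample multinomial
    realization of ``(I + L)·e_j`` — mimicking a finite perievent window.
    Normalizing the linear estimate on this ensemble should recover
    ``L_norm`` as ``k`` grows (element-wise RMSE ∝ 1/√k).
    """
    from .core import DistributionEnsemble

    L = np.asarray(L_norm, dtype=float)
    n = L.shape[0]
    rng = np.random.default_rng(seed)
    x0 = rng.integers(0, n, size=k)
    P0 = np.eye(n)[:, x0]
    targets = np.eye(n) + L
    P1 = np.empty((n, k))
    for s in range(k):
        P1[:, s] = rng.multinomial(m_draws, np.maximum(targets[:, x0[s]], 0)) / m_draws
    return DistributionEnsemble(P0=P0, P1=P1, n_states=n)


def run_prediction_study(
    n_sims: int,
    gens: tuple[str, ...],
    n_spikes: int = 2500,
    n_train: int = 1000,
    seed: int = 0,
    n_states: int = 20,
    pre_bins: int = 20,
    post_bins: int = 20,
    spec_overrides: dict | None = None,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """Out-of-sample prediction errors of H1–H7 on simulated data.

    Each simulation draws ``n_spikes`` spikes, fits all seven hypothesis
    matrices on a random subset of ``n_train`` spikes and scores event-wise
    predictions on the held-out remainder.  Returns one row per
    (sim, gen, hypothesis) with mean absolute single-state error, mean KLD
    and the bootstrap 95% CI of the cumulative absolute error.
    """
    from .core import perievent_distributions
    from .hypotheses import build_all_hypotheses
    from .predict import compare_models, predict_all, train_test_split_ensemble

    spec = GeneratorSpec(n_spikes=n_spikes, **(spec_overrides or {}))
    rows = []
    for i, ss in enumerate(np.random.SeedSequence(seed).spawn(n_sims)):
        child = ss.generate_state(2) % (2**31)
        suite = simulate_suite(spec, int(child[0]), gens=gens)
        for gen in gens:
            real = suite[gen]
            q = build_quantizer(real.signal.samples, n_states=n_states, scheme="linear")
            states = quantize(real.signal, q)
            ens = perievent_distributions(states, real.spike_indices, pre_bins, post_bins)
            train, test = train_test_split_ensemble(ens, n_train, seed=int(child[1]))
            hyps = build_all_hypotheses(states, train, pre_bins, post_bins)
            comp = compare_models(predict_all(hyps, test), n_boot=n_boot, seed=int(child[1]))
            for h_id, row in comp.table.iterrows():
                rows.append(
                    {
                        "sim": i,
                        "gen": gen,
                        "h_id": h_id,
                        "k_test": int(row["k"]),
                        "e1_mean": row["e1_cum"] / row["k"],
                        "e0_mean": row["e0_cum"] / row["k"],
                        "kld_mean": row["kld_mean"],
                        "e1_ci_lo": row["e1_ci_lo"],
                        "e1_ci_hi": row["e1_ci_hi"],
                    }
                )
    return pd.DataFrame(rows)
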