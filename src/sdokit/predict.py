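"""Event-wise prediction of post-spike state under H1–H7 and model comparison.

Every hypothesis matrix predicts the post-spike state distribution for each
spike via the common update ``p̂(x1) = p(x0) + M·p(x0)``.  Predictions are
scored two ways:

* distribution metrics — Kullback–Leibler divergence of the observed
  post-spike distribution from the predicted one (ε-smoothed) and the
  log-likelihood of the observed peak state under the prediction;
* single-state metrics — the predicted most likely state ``x̂1 = argmax p̂``
  against the observed most likely state: error frequency ``e0``, absolute
  error ``e1`` and squared error ``e2``.

Because single-state errors are integers, model comparison uses cumulative
errors with bootstrap confidence intervals; two hypotheses differ
significantly when their 95% CIs do not overlap, and effect sizes between
bootstrap distributions are reported as Cohen's D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DistributionEnsemble, predict_post_batch

KLD_EPS = 1e-6

__all__ = [
    "PredictionResult",
    "PredictionSummary",
    "ModelComparison",
    "predict_all",
    "score",
    "bootstrap_ci",
    "cohens_d",
    "compare_models",
    "train_test_split_ensemble",
]


@dataclass(frozen=True)
class PredictionResult:
    """Per-spike predictions of one hypothesis on one ensemble."""

    h_id: str
    P_hat: np.ndarray          # (n, k) predicted post-spike distributions
    x_hat: np.ndarray          # (k,) predicted best state, 1-based
    x_obs: np.ndarray          # (k,) observed best state, 1-based
    e0: np.ndarray             # (k,) 0/1 mismatch
    e1: np.ndarray             # (k,) |x_hat − x_obs|
    e2: np.ndarray             # (k,) squared error
    kld: np.ndarray            # (k,) D(observed ‖ predicted)
    loglik: np.ndarray         # (k,) log p̂(x1 = observed peak)

    @property
    def k(self) -> int:
        return self.x_hat.size


@dataclass(frozen=True)
class PredictionSummary:
    h_id: str
    k: int
    e0_cum: float
    e1_cum: float
    e2_cum: float
    kld_mean: float
    loglik_mean: float


@dataclass(frozen=True)
class ModelComparison:
    """Cumulative-error comparison across hypotheses."""

    table: pd.DataFrame               # per-hypothesis summary + CIs
    best_single_state: str            # argmin cumulative |error|
    best_distribution: str            # argmin mean KLD
    bootstrap: dict = field(default_factory=dict)   # h_id -> bootstrap e1 sums


def _argmax_lowest_tie(P: np.ndarray) -> np.ndarray:
    """Column-wise argmax with lowest-index tie-break (1-based states)."""
    return P.argmax(axis=0) + 1


def _kld_columns(P_obs: np.ndarray, P_hat: np.ndarray, eps: float = KLD_EPS) -> np.ndarray:
    p = P_obs + eps
    q = P_hat + eps
    p = p / p.sum(axis=0, keepdims=True)
    q = q / q.sum(axis=0, keepdims=True)
    return np.sum(p * np.log(p / q), axis=0)


def predict_all(
    hyps: dict,
    ens: DistributionEnsemble,
) -> dict[str, PredictionResult]:
    """Event-wise predictions of every hypothesis on an evaluation ensemble.

    Hypotheses should be fitted on spikes disjoint from ``ens`` when a
    train/test split is configured (see :func:`train_test_split_ensemble`).
    """
    results = {}
    x_obs = _argmax_lowest_tie(ens.P1)
    for h_id, hyp in hyps.items():
        M = hyp.L if hasattr(hyp, "L") else np.asarray(hyp)
        if M.shape[0] != ens.n_states:
            raise ValueError(f"{h_id}: state-count mismatch with ensemble")
        P_hat = predict_post_batch(M, ens.P0)
        x_hat = _argmax_lowest_tie(P_hat)
        e1 = np.abs(x_hat - x_obs).astype(float)
        ll = np.log(P_hat[x_obs - 1, np.arange(ens.k)] + KLD_EPS)
        results[h_id] = PredictionResult(
            h_id=h_id,
            P_hat=P_hat,
            x_hat=x_hat,
            x_obs=x_obs,
            e0=(x_hat != x_obs).astype(float),
            e1=e1,
            e2=e1**2,
            kld=_kld_columns(ens.P1, P_hat),
            loglik=ll,
        )
    return results


def score(pred: PredictionResult) -> PredictionSummary:
    """Cumulative single-state errors and mean distribution scores."""
    if pred.k < 1:
        raise ValueError("empty prediction set")
    return PredictionSummary(
        h_id=pred.h_id,
        k=pred.k,
        e0_cum=float(pred.e0.sum()),
        e1_cum=float(pred.e1.sum()),
        e2_cum=float(pred.e2.sum()),
        kld_mean=float(pred.kld.mean()),
        loglik_mean=float(pred.loglik.mean()),
    )


def bootstrap_ci(
    per_spike_errors: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
):
    """Percentile CI of the cumulative error under spike resampling.

    Returns ``(lo, hi, boot_sums)`` where ``boot_sums`` holds the ``n_boot``
    resampled cumulative errors.
    """
    e = np.asarray(per_spike_errors, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 per-spike errors to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, e.size, size=(n_boot, e.size))
    sums = e[idx].sum(axis=1)
    tail = 0.5 * (1.0 - ci)
    lo, hi = np.quantile(sums, [tail, 1.0 - tail])
    return float(lo), float(hi), sums


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Effect size between two bootstrap distributions: Δmean / pooled SD."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    va, vb = a.var(ddof=1) if a.size > 1 else 0.0, b.var(ddof=1) if b.size > 1 else 0.0
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / max(a.size + b.size - 2, 1))
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        return float(np.sign(diff) * np.inf) if diff else 0.0
    return float(diff / pooled)


def compare_models(
    preds: dict[str, PredictionResult],
    n_boot: int = 1000,
    seed: int = 0,
) -> ModelComparison:
    """Rank hypotheses by cumulative single-state error and by mean KLD.

    All hypotheses must have been scored on the identical spike set.  The
    single-state ranking (cumulative |x̂−x|) and the distribution ranking
    (mean KLD) are reported separately, with bootstrap 95% CIs on the
    cumulative absolute error.
    """
    if not preds:
        raise ValueError("no predictions to compare")
    ks = {p.k for p in preds.values()}
    if len(ks) != 1:
        raise ValueError("hypotheses scored on different spike sets")
    rows = []
    boots = {}
    for i, (h_id, pred) in enumerate(preds.items()):
        s = score(pred)
        lo, hi, sums = bootstrap_ci(pred.e1, n_boot=n_boot, seed=seed + i)
        boots[h_id] = sums
        rows.append(
            {
                "h_id": h_id,
                "k": s.k,
                "e0_cum": s.e0_cum,
                "e1_cum": s.e1_cum,
                "e2_cum": s.e2_cum,
                "e1_ci_lo": lo,
                "e1_ci_hi": hi,
                "kld_mean": s.kld_mean,
                "loglik_mean": s.loglik_mean,
            }
        )
    table = pd.DataFrame(rows).set_index("h_id")
    return ModelComparison(
        table=table,
        best_single_state=str(table["e1_cum"].idxmin()),
        best_distribution=str(table["kld_mean"].idxmin()),
        bootstrap=boots,
    )


def cis_overlap(comparison: ModelComparison, h_a: str, h_b: str) -> bool:
    """True if the bootstrap 95% CIs of the two hypotheses overlap."""
    t = comparison.table
    lo_a, hi_a = t.loc[h_a, "e1_ci_lo"], t.loc[h_a, "e1_ci_hi"]
    lo_b, hi_b = t.loc[h_b, "e1_ci_lo"], t.loc[h_b, "e1_ci_hi"]
    return not (hi_a < lo_b or hi_b < lo_a)


def train_test_split_ensemble(
    ens: DistributionEnsemble, n_train: int, seed: int = 0
) -> tuple[DistributionEnsemble, DistributionEnsemble]:
    """Split an ensemble's spikes into disjoint train/test subsets."""
    k = ens.k
    if not (0 < n_train < k):
        raise ValueError("n_train must be in (0, k)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(k)
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    def sub(cols):
        return DistributionEnsemble(
            P0=ens.P0[:, cols],
            P1=ens.P1[:, cols],
            n_states=ens.n_states,
            n_dropped=ens.n_dropped,
            spike_indices=None if ens.spike_indices is None else ens.spike_indices[cols],
        )
    return sub(tr), sub(te)
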