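"""Event labeling from SSIM, lag-aware detection scoring and group statistics.

Reconfiguration events are transitions whose SSIM falls below a per-subject
empirical quantile; thermodynamic and baseline scores are evaluated against
those labels with a lag tolerance of ``L`` windows (implemented as label
dilation), using threshold-free AUROC/AP, a quantile-matched spike rule with
Matthews correlation, and a seeded permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "EventSeries",
    "DetectionSummary",
    "label_low_ssim_events",
    "dilate_events",
    "lag_aware_detection",
    "transition_labels",
    "spike_binarize",
    "mcc",
    "permutation_test",
    "diff_alignment",
    "subject_variability",
    "group_compare",
    "node_energy_group_diff",
    "score_events",
]


@dataclass
class EventSeries:
    """Binary reconfiguration labels over transition indices."""

    labels: np.ndarray
    q: float | None = None
    tolerance: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(int)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_events(self) -> int:
        return int(self.labels.sum())


@dataclass
class DetectionSummary:
    """Metric bundle for one score-label pairing."""

    auroc: float
    ap: float
    mcc: float
    p_value: float
    n_events: int
    n_valid: int


def label_low_ssim_events(ssim: np.ndarray, q: float) -> EventSeries:
    """Mark transitions whose SSIM lies strictly below the empirical
    ``q``-quantile of the subject's own SSIM series.

    NaN entries (e.g. the undefined first transition) are never positive and
    are excluded from the quantile.  A constant series yields zero positives
    and is flagged degenerate.
    """
    if not 0 < q < 1:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    ssim = np.asarray(ssim, dtype=float)
    valid = ~np.isnan(ssim)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid SSIM values")
    cutoff = np.quantile(ssim[valid], q)
    labels = np.zeros(len(ssim), dtype=int)
    labels[valid] = ssim[valid] < cutoff
    return EventSeries(labels=labels, q=q, degenerate=labels.sum() == 0)


def dilate_events(e: EventSeries | np.ndarray, tol: int) -> EventSeries:
    """Binary dilation: an index is positive iff it lies within ``tol`` of an
    original positive (clipped at the ends).  ``tol=0`` is the identity."""
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    labels = np.asarray(e.labels if isinstance(e, EventSeries) else e).astype(int)
    out = labels.copy()
    for shift in range(1, tol + 1):
        out[shift:] |= labels[:-shift]
        out[:-shift] |= labels[shift:]
    q = e.q if isinstance(e, EventSeries) else None
    return EventSeries(labels=out, q=q, tolerance=tol)


def lag_aware_detection(
    score: np.ndarray,
    events: EventSeries | np.ndarray,
    tol: int = 0,
    *,
    mode: str = "dilate",
) -> tuple[float, float]:
    """Threshold-free AUROC and average precision with a ``±tol`` lag credit.

    ``mode="dilate"`` (default) dilates the labels by ``±tol`` and computes
    standard AUROC/AP against the dilated labels; under a structureless
    score this is unbiased (expected AUROC 0.5), which makes it the right
    choice for benchmark aggregation.  ``mode="event_max"`` is the
    event-centric reading of the tolerance criterion — each event becomes
    one positive scored by the maximum score in its neighborhood, negatives
    are the transitions outside all neighborhoods — so a single spike
    anywhere within ``±tol`` of the only event yields AUROC 1.0; its null
    expectation exceeds 0.5 (max of ``2 tol + 1`` draws), so it suits
    per-event detection statements rather than score comparison.

    NaN scores (degenerate transitions) are removed pairwise.  If either
    class is empty after masking, the result is undefined: ``(nan, nan)``.
    """
    score = np.asarray(score, dtype=float)
    labels = np.asarray(events.labels if isinstance(events, EventSeries) else events)
    labels = labels.astype(int)
    if len(score) != len(labels):
        raise ValueError("score and labels must have equal length")
    if mode == "dilate":
        dilated = dilate_events(EventSeries(labels=labels), tol).labels
        valid = ~np.isnan(score)
        y, x = dilated[valid], score[valid]
        if len(np.unique(y)) < 2:
            return float("nan"), float("nan")
    elif mode == "event_max":
        n = len(score)
        pos = []
        for i in np.flatnonzero(labels == 1):
            window = score[max(0, i - tol): min(n, i + tol + 1)]
            if not np.all(np.isnan(window)):
                pos.append(np.nanmax(window))
        neg_mask = (dilate_events(EventSeries(labels=labels), tol).labels == 0) \
            & ~np.isnan(score)
        neg = score[neg_mask]
        if not pos or neg.size == 0:
            return float("nan"), float("nan")
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        x = np.r_[pos, neg]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(roc_auc_score(y, x)), float(average_precision_score(y, x))


def transition_labels(n: int, change_points, tol: int = 0) -> EventSeries:
    """Ground-truth transition labels for known change points.

    ``change_points`` are 0-based indices of the first window of each new
    segment; the transition into window ``t`` is indexed by ``t`` itself, so
    a change point at window 15 labels transition 15.  ``tol`` dilates.
    """
    labels = np.zeros(n, dtype=int)
    labels[np.asarray(change_points, dtype=int)] = 1
    return dilate_events(EventSeries(labels=labels), tol)


def spike_binarize(score: np.ndarray, rate: float) -> np.ndarray:
    """Mark the top-``rate`` fraction of |score| as spikes (1), rest 0.

    Matching ``rate`` to the event rate gives both binary vectors the same
    positive count, removing the free threshold from the MCC analysis.  NaN
    scores are never spikes.  Returns a float array with NaN preserved at
    invalid positions.
    """
    if not 0 < rate < 1:
        raise ValueError(f"rate must be in (0, 1), got {rate}")
    score = np.abs(np.asarray(score, dtype=float))
    valid = np.flatnonzero(~np.isnan(score))
    if len(valid) == 0:
        raise ValueError("score is all-NaN")
    k = max(1, int(np.floor(rate * len(valid))))
    top = valid[np.argsort(score[valid], kind="stable")[::-1][:k]]
    out = np.zeros(len(score))
    out[np.isnan(score)] = np.nan
    out[top] = 1.0
    return out


def mcc(a: np.ndarray, b: np.ndarray) -> float:
    """Matthews correlation coefficient between two binary vectors.

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``, defined as 0
    when any factor of the denominator vanishes.  NaN entries in either
    vector are removed pairwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    valid = ~(np.isnan(a) | np.isnan(b))
    a, b = a[valid].astype(int), b[valid].astype(int)
    tp = int(np.sum((a == 1) & (b == 1)))
    tn = int(np.sum((a == 0) & (b == 0)))
    fp = int(np.sum((a == 1) & (b == 0)))
    fn = int(np.sum((a == 0) & (b == 1)))
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(den))


def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
    *,
    circular: bool = False,
) -> float:
    """One-sided permutation p-value for the MCC between two binary vectors.

    ``b`` is shuffled uniformly (or circularly shifted when ``circular=True``,
    a variant robust to autocorrelation); the add-one estimator
    ``p = (1 + #{MCC_perm >= MCC_obs}) / (n_perm + 1)`` is returned.
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    valid = ~(np.isnan(a) | np.isnan(b))
    a, b = a[valid], b[valid]
    observed = mcc(a, b)
    count = 0
    n = len(b)
    for _ in range(n_perm):
        if circular:
            perm = np.roll(b, rng.integers(1, n))
        else:
            perm = rng.permutation(b)
        if mcc(a, perm) >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


def diff_alignment(series_a: np.ndarray, series_b: np.ndarray) -> float:
    """Spearman rank correlation between the first differences of two series.

    Used to quantify how a truncated entropy series tracks (or anti-tracks)
    full-spectrum entropy dynamics.  NaN pairs are removed after differencing.
    """
    da = np.diff(np.asarray(series_a, dtype=float))
    db = np.diff(np.asarray(series_b, dtype=float))
    if da.shape != db.shape:
        raise ValueError("length mismatch")
    valid = ~(np.isnan(da) | np.isnan(db))
    if valid.sum() < 4:
        raise ValueError("need at least 4 valid differenced pairs")
    rho = scipy.stats.spearmanr(da[valid], db[valid]).statistic
    return float(rho)


def subject_variability(traj) -> tuple[float, float]:
    """Per-subject summary: sample standard deviations (ddof=1) of the
    internal-energy and entropy series over windows."""
    u = np.asarray(traj.U, dtype=float)
    s = np.asarray(traj.S, dtype=float)
    if len(u) < 2:
        raise ValueError("need at least 2 windows")
    return float(np.std(u, ddof=1)), float(np.std(s, ddof=1))


def group_compare(
    values_a,
    values_b,
    bins: int = 20,
    *,
    smoothing: float = 1e-9,
) -> tuple[float, float, float]:
    """Two-sample KS test plus a descriptive KL divergence.

    KL(A||B) is estimated from histogram densities on ``bins`` shared-width
    bins spanning the pooled range, with additive smoothing and natural log;
    it is reported as a descriptive complement only.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each group needs at least 5 subjects")
    ks = scipy.stats.ks_2samp(a, b)
    pooled = np.concatenate([a, b])
    edges = np.linspace(pooled.min(), pooled.max(), bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    pa = pa / pa.sum() + smoothing
    pb = pb / pb.sum() + smoothing
    pa, pb = pa / pa.sum(), pb / pb.sum()
    kl = float(np.sum(pa * np.log(pa / pb)))
    return float(ks.statistic), float(ks.pvalue), kl


def node_energy_group_diff(group_a: np.ndarray, group_b: np.ndarray, labels=None):
    """Per-node group-mean node-energy difference, ranked by magnitude.

    Parameters
    ----------
    group_a, group_b
        ``n_subjects x n_nodes`` arrays of per-subject mean node energies.
    labels
        Optional lookup table mapping node index to region label / function
        (a DataFrame or dict-of-dicts with columns ``label`` and ``function``).

    Returns a DataFrame with columns ``index``, ``diff`` (A minus B),
    ``abs_diff`` and ``rank`` (1 = largest magnitude), plus any joined label
    columns.
    """
    import pandas as pd

    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("node count mismatch between groups")
    diff = a.mean(axis=0) - b.mean(axis=0)
    table = pd.DataFrame({
        "index": np.arange(len(diff)),
        "diff": diff,
        "abs_diff": np.abs(diff),
    })
    table["rank"] = table["abs_diff"].rank(ascending=False, method="first").astype(int)
    if labels is not None:
        lab = pd.DataFrame(labels)
        if "index" in lab.columns:
            lab = lab.set_index("index")
        table = table.join(lab, on="index")
    return table.sort_values("rank").reset_index(drop=True)


def score_events(
    score: np.ndarray,
    events: EventSeries,
    tol: int = 2,
    n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
) -> DetectionSummary:
    """Full per-subject evaluation of one score against one event labeling:
    lag-aware AUROC/AP, quantile-matched spike MCC, and its permutation p."""
    score = np.asarray(score, dtype=float)
    auroc, ap = lag_aware_detection(score, events, tol)
    valid = ~np.isnan(score)
    labels = events.labels.astype(float).copy()
    labels[~valid] = np.nan
    rate = events.q if events.q else max(events.n_events, 1) / max(valid.sum(), 1)
    spikes = spike_binarize(score, rate)
    dilated = dilate_events(events, tol).labels.astype(float)
    dilated[~valid] = np.nan
    m = mcc(spikes, dilated)
    p = permutation_test(dilated, spikes, n_perm=n_perm, seed=seed)
    return DetectionSummary(
        auroc=auroc, ap=ap, mcc=m, p_value=p,
        n_events=events.n_events, n_valid=int(valid.sum()),
    )
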