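"""Sliding-window construction of time-varying graphs from multivariate time
series, and SSIM comparison of consecutive adjacency matrices.

A ``T x N`` matrix of regional signals is cut into overlapping length-``w``
segments at stride ``s``; each segment becomes a Pearson correlation graph
(zero diagonal), optionally binarized at a fixed threshold (strictly greater
than 0.5 by default).  Consecutive adjacency matrices, viewed as gray-scale
images, are compared with the structural similarity index; low SSIM marks
candidate reconfiguration events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NodeTimeSeries",
    "WindowedGraphSequence",
    "segment_windows",
    "correlation_graph",
    "binarize",
    "ssim_pair",
    "ssim_series",
    "build_dynamic_graph",
]


@dataclass
class NodeTimeSeries:
    """Multivariate regional time series: ``T`` time points x ``N`` regions."""

    values: np.ndarray
    subject_id: str = ""
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D T x N matrix")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 regions")
        if np.isnan(self.values).any():
            raise ValueError("time series contains NaN")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class WindowedGraphSequence:
    """Ordered adjacency matrices over a fixed node set, with window metadata.

    ``graphs`` is a ``(n_windows, N, N)`` array.  ``start_indices[k] = k * stride``
    is the first time point of window ``k``.
    """

    graphs: np.ndarray
    window_length: int = 0
    stride: int = 1
    binary: bool = True
    threshold: float = 0.5
    node_labels: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.graphs = np.asarray(self.graphs, dtype=float)
        if self.graphs.ndim != 3 or self.graphs.shape[1] != self.graphs.shape[2]:
            raise ValueError("graphs must be a (n_windows, N, N) array")

    def __len__(self) -> int:
        return self.graphs.shape[0]

    def __iter__(self):
        return iter(self.graphs)

    @property
    def n_nodes(self) -> int:
        return self.graphs.shape[1]

    @property
    def start_indices(self) -> np.ndarray:
        return np.arange(len(self)) * self.stride


def segment_windows(x: np.ndarray, w: int, s: int = 1) -> list[np.ndarray]:
    """Overlapping windows ``X[k*s : k*s + w, :]`` for ``k = 0 .. floor((T-w)/s)``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a T x N matrix")
    t_len = x.shape[0]
    if w < 2:
        raise ValueError(f"window length must be >= 2, got {w}")
    if s < 1:
        raise ValueError(f"stride must be >= 1, got {s}")
    if t_len < w:
        raise ValueError(f"series has T={t_len} time points, shorter than window w={w}")
    n_windows = (t_len - w) // s + 1
    return [x[k * s : k * s + w, :] for k in range(n_windows)]


def correlation_graph(segment: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of a windowed segment, diagonal set to zero.

    Columns with zero variance inside the window (constant signal) are
    functionally disconnected there: all their correlations are set to 0.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.shape[0] < 2:
        raise ValueError("need at least 2 time points to correlate")
    sd = segment.std(axis=0)
    flat = sd == 0
    if flat.any():
        logger.info("correlation_graph: %d zero-variance column(s) set to 0", flat.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(segment, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 0.0)
    # numerical symmetry + clipping of rounding overshoot
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return corr


def binarize(g: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Keep edges with weight strictly greater than ``threshold`` (as 0/1)."""
    g = np.asarray(g, dtype=float)
    out = (g > threshold).astype(float)
    np.fill_diagonal(out, 0.0)
    return out


def _global_ssim(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return float(num / den)


def ssim_pair(
    a: np.ndarray,
    b: np.ndarray,
    *,
    data_range: float | None = None,
    windowed: bool = False,
) -> float:
    """Structural similarity between two adjacency matrices viewed as images.

    The default is the global single-window SSIM formula applied to all
    matrix entries (both symmetric halves and the zero diagonal included),
    with stabilizers ``C1 = (0.01 L)^2`` and ``C2 = (0.03 L)^2`` where ``L``
    is the data range (1 for binary graphs, max minus min of the pair for
    weighted ones).  ``windowed=True`` switches to the local sliding-window
    SSIM of scikit-image for sensitivity checks.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if data_range is None:
        both = np.concatenate([a.ravel(), b.ravel()])
        data_range = float(both.max() - both.min())
        if data_range == 0:
            data_range = 1.0
    if windowed:
        from skimage.metrics import structural_similarity

        return float(structural_similarity(a, b, data_range=data_range))
    return _global_ssim(a, b, data_range)


def ssim_series(seq: WindowedGraphSequence, *, windowed: bool = False) -> np.ndarray:
    """SSIM between consecutive windows, aligned to the later window.

    Returns a length-``n_windows`` array with NaN at index 0;
    ``out[t] = SSIM(A_t, A_{t-1})`` for ``t >= 1``.  For binary sequences the
    data range is fixed at 1.
    """
    g = seq.graphs
    out = np.full(len(seq), np.nan)
    rng_fixed = 1.0 if seq.binary else None
    for t in range(1, len(seq)):
        out[t] = ssim_pair(g[t], g[t - 1], data_range=rng_fixed, windowed=windowed)
    return out


def build_dynamic_graph(
    x: NodeTimeSeries | np.ndarray,
    w: int = 5,
    s: int = 1,
    threshold: float = 0.5,
    *,
    keep_weighted: bool = False,
) -> WindowedGraphSequence:
    """Sliding-window graph sequence: segment, correlate, optionally binarize.

    With ``keep_weighted=True`` the raw signed correlations are stored and all
    downstream descriptors that require nonnegative weights must be applied
    with care; the default binary mode keeps edges with correlation > 0.5.
    """
    if not isinstance(x, NodeTimeSeries):
        x = NodeTimeSeries(values=x)
    segs = segment_windows(x.values, w, s)
    mats = [correlation_graph(seg) for seg in segs]
    if not keep_weighted:
        mats = [binarize(m, threshold) for m in mats]
    return WindowedGraphSequence(
        graphs=np.stack(mats),
        window_length=w,
        stride=s,
        binary=not keep_weighted,
        threshold=threshold,
        node_labels=x.region_labels,
        meta={"subject_id": x.subject_id},
    )
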