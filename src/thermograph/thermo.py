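"""Thermodynamics-inspired descriptors of a single graph and of graph sequences.

The framework treats an undirected graph as a closed accounting system: the
normalized-Laplacian eigenvalues, scaled by ``1/|V|``, play the role of
micro-state probabilities; their Shannon entropy is the graph's von Neumann
entropy (VNE), and truncating the sum to the top-``alpha`` eigenvalues gives
the Spectral Core Entropy (SCE).  Edge mass is the internal energy ``U`` (the
edge count for binary graphs), allocated to nodes by a locality rule
(node energy), and the discrete ratio ``T = dU/dS`` between consecutive
windows is a dimensionless reconfiguration index — not a physical
temperature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralConfig",
    "Spectrum",
    "ThermoTrajectory",
    "validate_adjacency",
    "normalized_laplacian",
    "laplacian_eigenvalues",
    "spectrum",
    "entropy_from_probabilities",
    "spectral_core_entropy",
    "von_neumann_entropy",
    "node_energy",
    "internal_energy",
    "temperature_series",
    "thermo_trajectory",
]

#: below this |dS| a temperature entry is considered degenerate and set to NaN
DS_EPS = 1e-12

#: dense eigendecomposition below this size (or when alpha > n/2)
_DENSE_CUTOFF = 512


@dataclass(frozen=True)
class SpectralConfig:
    """How the Laplacian spectrum is computed and turned into probabilities.

    Parameters
    ----------
    alpha
        Number of retained leading eigenvalues.  Default 20, the value used
        throughout the main analyses.
    renormalize
        If True, probabilities are ``lambda_i / sum(top-alpha lambda)``
        (within-core dispersion control); if False, the plain
        ``lambda_i / |V|`` normalization is kept and the omitted tail is
        simply dropped.
    solver
        ``"auto"`` (dense for small graphs, Lanczos otherwise), ``"dense"``
        or ``"lanczos"``.
    lanczos_tol
        Convergence tolerance passed to the Lanczos solver (0 = machine
        precision).
    """

    alpha: int = 20
    renormalize: bool = False
    solver: str = "auto"
    lanczos_tol: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError(f"alpha must be >= 1, got {self.alpha}")
        if self.solver not in ("auto", "dense", "lanczos"):
            raise ValueError(f"unknown solver {self.solver!r}")


@dataclass(frozen=True)
class Spectrum:
    """Top-``alpha`` normalized-Laplacian eigenvalues and their probabilities."""

    eigenvalues: np.ndarray  # descending
    probabilities: np.ndarray
    n_nodes: int


@dataclass
class ThermoTrajectory:
    """Per-window descriptors of a graph sequence.

    ``U``, ``S`` and ``T`` have one entry per window; ``T[0] = 0`` by
    definition and entries with a degenerate entropy difference
    (``|dS| < DS_EPS``) are NaN.  ``node_energy`` is ``n_windows x n_nodes``
    and each row sums to the corresponding ``U`` (energy conservation).
    """

    U: np.ndarray
    S: np.ndarray
    T: np.ndarray
    node_energy: np.ndarray
    VNE: np.ndarray | None = None
    n_degenerate_ds: int = 0
    alpha: int = 20
    meta: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.U)


def validate_adjacency(w: np.ndarray, *, name: str = "adjacency") -> np.ndarray:
    """Validate and return a symmetric, nonnegative, zero-diagonal matrix."""
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{name} must be square, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError(f"{name} contains non-finite entries")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    if np.any(w < 0):
        raise ValueError(f"{name} must be nonnegative")
    if np.any(np.diagonal(w) != 0):
        raise ValueError(f"{name} must have a zero diagonal")
    return w


def normalized_laplacian(w: np.ndarray) -> np.ndarray:
    """Symmetrically normalized Laplacian ``I - D^{-1/2} W D^{-1/2}``.

    Rows and columns of isolated nodes (zero weighted degree) are entirely
    zero, including the diagonal entry, so the trace equals the number of
    non-isolated nodes.
    """
    w = validate_adjacency(w)
    d = w.sum(axis=1)
    connected = d > 0
    inv_sqrt = np.zeros_like(d)
    inv_sqrt[connected] = 1.0 / np.sqrt(d[connected])
    lap = -w * np.outer(inv_sqrt, inv_sqrt)
    np.fill_diagonal(lap, np.where(connected, 1.0, 0.0))
    return lap


def laplacian_eigenvalues(w: np.ndarray) -> np.ndarray:
    """All normalized-Laplacian eigenvalues, descending, clipped to [0, 2]."""
    lap = normalized_laplacian(w)
    vals = scipy.linalg.eigvalsh(lap)
    return np.clip(vals[::-1], 0.0, 2.0)


def _top_alpha_lanczos(lap: np.ndarray, alpha: int, tol: float) -> np.ndarray:
    vals = scipy.sparse.linalg.eigsh(
        scipy.sparse.csr_matrix(lap), k=alpha, which="LA", tol=tol,
        return_eigenvectors=False,
    )
    return np.sort(vals)[::-1]


def spectrum(w: np.ndarray, cfg: SpectralConfig = SpectralConfig()) -> Spectrum:
    """Top-``alpha`` eigenvalues of the normalized Laplacian with micro-state
    probabilities.

    Plain normalization divides by ``|V|`` (so the retained probabilities sum
    to less than one when ``alpha < |V|`` or isolated nodes exist); the
    renormalized variant rescales within the retained set.
    """
    w = validate_adjacency(w)
    n = w.shape[0]
    if cfg.alpha > n:
        raise ValueError(f"alpha={cfg.alpha} exceeds n_nodes={n}")
    use_dense = (
        cfg.solver == "dense"
        or (cfg.solver == "auto" and (n <= _DENSE_CUTOFF or cfg.alpha > n // 2))
    )
    if use_dense:
        vals = laplacian_eigenvalues(w)[: cfg.alpha]
    else:
        lap = normalized_laplacian(w)
        try:
            vals = np.clip(_top_alpha_lanczos(lap, cfg.alpha, cfg.lanczos_tol), 0.0, 2.0)
        except (scipy.sparse.linalg.ArpackNoConvergence, scipy.sparse.linalg.ArpackError):
            logger.warning("Lanczos failed to converge; falling back to dense solver")
            vals = laplacian_eigenvalues(w)[: cfg.alpha]
    if cfg.renormalize:
        total = vals.sum()
        probs = vals / total if total > 0 else np.zeros_like(vals)
    else:
        probs = vals / n
    return Spectrum(eigenvalues=vals, probabilities=probs, n_nodes=n)


def entropy_from_probabilities(p: np.ndarray) -> float:
    """Shannon entropy ``-sum p ln p`` in nats with the ``0 ln 0 = 0`` convention."""
    p = np.asarray(p, dtype=float)
    pos = p[p > 0]
    return float(-(pos * np.log(pos)).sum() + 0.0)


def spectral_core_entropy(w: np.ndarray, cfg: SpectralConfig = SpectralConfig()) -> float:
    """Spectral Core Entropy: entropy of the top-``alpha`` micro-state weights.

    With ``alpha = |V|`` and ``renormalize=False`` this is exactly the full
    von Neumann entropy.
    """
    return entropy_from_probabilities(spectrum(w, cfg).probabilities)


def von_neumann_entropy(w: np.ndarray) -> float:
    """Full-spectrum von Neumann entropy with ``p_i = lambda_i / |V|``."""
    n = np.asarray(w).shape[0]
    return spectral_core_entropy(w, SpectralConfig(alpha=n, renormalize=False, solver="dense"))


def node_energy(w: np.ndarray) -> np.ndarray:
    """Locality-based allocation of edge mass to nodes.

    ``U_i = sum_j [d_i / (d_i + d_j)] w_ij`` over neighbors ``j``, with
    weighted degrees ``d_i = sum_j w_ij``.  Each unit of edge weight is split
    between its endpoints in proportion to their degrees, so the node
    energies sum exactly to the internal energy.  Isolated nodes get 0.
    """
    w = validate_adjacency(w)
    d = w.sum(axis=1)
    dsum = d[:, None] + d[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(w > 0, d[:, None] / dsum, 0.0)
    return (share * w).sum(axis=1)


def internal_energy(w: np.ndarray) -> float:
    """Total edge mass ``sum_{i<j} w_ij``; the edge count for binary graphs."""
    w = validate_adjacency(w)
    return float(np.triu(w, k=1).sum())


def temperature_series(
    u: np.ndarray, s: np.ndarray, *, ds_eps: float = DS_EPS
) -> tuple[np.ndarray, int]:
    """Discrete reconfiguration index ``T_n = dU_n / dS_n``.

    ``T[0] = 0`` by definition.  Entries where ``|dS| < ds_eps`` are NaN
    (degenerate transitions, excluded from downstream scoring); their count
    is returned alongside the series.
    """
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    if u.shape != s.shape:
        raise ValueError(f"length mismatch: U has {u.shape}, S has {s.shape}")
    t = np.zeros_like(u)
    if len(u) > 1:
        du = np.diff(u)
        ds = np.diff(s)
        degenerate = np.abs(ds) < ds_eps
        with np.errstate(divide="ignore", invalid="ignore"):
            t[1:] = np.where(degenerate, np.nan, du / ds)
        n_degenerate = int(degenerate.sum())
    else:
        n_degenerate = 0
    if n_degenerate:
        logger.info("temperature_series: %d degenerate |dS| < %g transitions set to NaN",
                    n_degenerate, ds_eps)
    return t, n_degenerate


def thermo_trajectory(
    graphs,
    cfg: SpectralConfig = SpectralConfig(),
    *,
    with_vne: bool = False,
) -> ThermoTrajectory:
    """Compute U, SCE, node energy, optional VNE and the temperature index for
    every window of a graph sequence.

    Parameters
    ----------
    graphs
        Iterable of adjacency matrices (or a ``WindowedGraphSequence``), all
        on the same node set.
    """
    mats = [np.asarray(g, dtype=float) for g in getattr(graphs, "graphs", graphs)]
    if not mats:
        raise ValueError("empty graph sequence")
    n = mats[0].shape[0]
    if any(m.shape != (n, n) for m in mats):
        raise ValueError("all graphs must share the same node set")
    u = np.array([internal_energy(m) for m in mats])
    s = np.empty(len(mats))
    vne = np.empty(len(mats)) if with_vne else None
    energies = np.empty((len(mats), n))
    for k, m in enumerate(mats):
        if with_vne or (cfg.solver != "lanczos" and n <= _DENSE_CUTOFF):
            # one dense decomposition serves both SCE and full VNE
            vals = laplacian_eigenvalues(m)
            s[k] = entropy_from_probabilities(
                vals[: cfg.alpha] / vals[: cfg.alpha].sum()
                if cfg.renormalize and vals[: cfg.alpha].sum() > 0
                else vals[: cfg.alpha] / n
            )
            if with_vne:
                vne[k] = entropy_from_probabilities(vals / n)
        else:
            s[k] = spectral_core_entropy(m, cfg)
        energies[k] = node_energy(m)
    t, n_deg = temperature_series(u, s)
    return ThermoTrajectory(
        U=u, S=s, T=t, node_energy=energies, VNE=vne,
        n_degenerate_ds=n_deg, alpha=cfg.alpha,
    )
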