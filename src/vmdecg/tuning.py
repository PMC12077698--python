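"""Bi-objective (K, alpha) tuning of the decomposition.

Decomposition quality is scored by two aggregate indicators computed over
the intrinsic mode functions:

* spectral kurtosis (SK): per frequency bin, the fourth-over-squared-second
  moment ratio of short-time spectral magnitudes minus 2 -- zero for
  stationary Gaussian content, -1 for a deterministic tone, elevated for
  impulsive content.  The scalar aggregate is the mean over the strictly
  positive, sub-Nyquist bins (DC and Nyquist carry a real-Gaussian bias of
  +1 and are excluded from the mean), averaged over modes.
* KL divergence: each mode's 64-bin amplitude histogram against the source
  signal's histogram on shared bin edges, natural log, summed over modes.

Both are minimized over integer K in [3, 8] and real alpha in [500, 5000]
by the multi-objective crayfish optimizer; K is searched continuously and
rounded at evaluation.  One point is selected from the Pareto front by
minimal Euclidean distance to the ideal point after min-max normalization
of both objectives over the front.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .coa import COAConfig, ParetoFront, mocoa
from .vmd import VMDConfig, VMDResult, vmd

__all__ = [
    "ObjectiveVector",
    "TuningSpace",
    "spectral_kurtosis",
    "kurtogram",
    "kl_divergence",
    "vmd_objectives",
    "tune_vmd",
    "sensitivity_sweep",
]

_KL_EPS = 1e-12


@dataclass(frozen=True)
class ObjectiveVector:
    """Aggregate (spectral kurtosis, KL divergence) for one candidate (K, alpha)."""

    sk: float
    dkl: float
    converged: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([self.sk, self.dkl])


@dataclass(frozen=True)
class TuningSpace:
    """Search ranges for the decomposition parameters."""

    K_range: tuple = (3, 8)
    alpha_range: tuple = (500.0, 5000.0)

    def __post_init__(self) -> None:
        if self.K_range[0] > self.K_range[1] or self.alpha_range[0] > self.alpha_range[1]:
            raise ValueError("ranges must be ordered (lo <= hi)")


def _stft_mags(x: np.ndarray, window_len: int, hop: int) -> np.ndarray:
    """Hann-windowed short-time spectral magnitudes, shape (n_frames, n_bins)."""
    win = hann(window_len, sym=False)
    n_frames = 1 + (x.size - window_len) // hop
    idx = np.arange(window_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return np.abs(np.fft.rfft(x[idx] * win, axis=1))


def spectral_kurtosis(signal, fs: float = 300.0, window_len: int = 32, hop=None):
    """Per-bin spectral kurtosis and its scalar aggregate.

    Returns ``(freqs_hz, sk_per_bin, aggregate)``.  Bins with zero power
    (e.g. an all-zero signal) are assigned SK = 0.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if window_len < 4:
        raise ValueError("window_len must be >= 4")
    if x.size < 2 * window_len:
        raise ValueError(f"signal length {x.size} < 2*window_len ({2 * window_len})")
    hop = hop or window_len // 2
    mags = _stft_mags(x, window_len, hop)
    m2 = np.mean(mags**2, axis=0)
    m4 = np.mean(mags**4, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sk = np.where(m2 > 0, m4 / np.maximum(m2, _KL_EPS) ** 2 - 2.0, 0.0)
    freqs = np.fft.rfftfreq(window_len, d=1.0 / fs)
    # aggregate over strictly positive sub-Nyquist bins (DC/Nyquist are
    # real-valued and carry a +1 Gaussian bias)
    interior = sk[1:-1] if sk.size > 2 else sk
    return freqs, sk, float(np.mean(interior))


def kurtogram(signal, fs: float = 300.0, window_lengths=(16, 32, 64, 128)):
    """Spectral-kurtosis map across analysis window lengths.

    Rows correspond to window lengths; per-window SK curves are linearly
    interpolated onto the interior frequency grid of the longest window
    (DC and Nyquist are excluded: they are real-valued bins with a +1
    Gaussian bias).  Returns ``(grid_hz, matrix, (best_window,
    best_freq_hz))`` where the argmax is taken over the whole map.
    """
    if len(window_lengths) == 0:
        raise ValueError("need at least one window length")
    x = np.asarray(signal, dtype=float).ravel()
    wmax = max(window_lengths)
    grid = np.fft.rfftfreq(wmax, d=1.0 / fs)[1:-1]
    rows = []
    for w in window_lengths:
        f, sk, _ = spectral_kurtosis(x, fs=fs, window_len=int(w))
        rows.append(np.interp(grid, f[1:-1], sk[1:-1]))
    mat = np.vstack(rows)
    i, j = np.unravel_index(np.argmax(mat), mat.shape)
    return grid, mat, (int(window_lengths[i]), float(grid[j]))


def kl_divergence(p, q) -> float:
    """Discrete KL divergence sum p_i (ln p_i - ln q_i), in nats.

    Zero-probability reference bins are floored at 1e-12; 0 ln 0 := 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have equal length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("probabilities must be non-negative")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1 (got {v.sum()})")
    qf = np.maximum(q, _KL_EPS)
    terms = np.where(p > 0, p * (np.log(np.maximum(p, _KL_EPS)) - np.log(qf)), 0.0)
    return float(terms.sum())


def _amplitude_hist(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(np.clip(x, edges[0], edges[-1]), bins=edges)
    total = counts.sum()
    return counts / total if total else np.full(len(counts), 1.0 / len(counts))


def vmd_objectives(signal, K, alpha, fs: float = 300.0, n_bins: int = 64,
                   vmd_defaults: VMDConfig | None = None) -> ObjectiveVector:
    """Evaluate the (SK, KL) objective pair for a candidate (K, alpha).

    K is rounded to the nearest integer.  If the decomposition hits its
    iteration cap, the objectives are computed from the last iterate and
    flagged via ``converged=False``.
    """
    x = np.asarray(signal, dtype=float).ravel()
    base = vmd_defaults or VMDConfig()
    cfg = VMDConfig(
        K=int(round(float(K))),
        alpha=float(alpha),
        tau=base.tau,
        eps=base.eps,
        max_iter=base.max_iter,
        omega_init=base.omega_init,
    )
    res: VMDResult = vmd(x, cfg)
    sks = [spectral_kurtosis(m, fs=fs)[2] for m in res.modes]
    edges = np.linspace(x.min(), x.max() + 1e-12, n_bins + 1)
    p_src = _amplitude_hist(x, edges)
    dkl = sum(kl_divergence(_amplitude_hist(m, edges), p_src) for m in res.modes)
    return ObjectiveVector(sk=float(np.mean(sks)), dkl=float(dkl), converged=res.converged)


def tune_vmd(
    signal,
    space: TuningSpace = TuningSpace(),
    N: int = 40,
    T: int = 60,
    seed: int = 0,
    fs: float = 300.0,
    vmd_defaults: VMDConfig | None = None,
):
    """Search (K, alpha) with MOCOA against the (SK, KL) objectives.

    Returns ``(front, (K_star, alpha_star), objectives_at_selection)``.
    The selected point minimizes the Euclidean distance to the ideal point
    after per-objective min-max normalization over the front.
    """
    x = np.asarray(signal, dtype=float).ravel()
    (k_lo, k_hi), (a_lo, a_hi) = space.K_range, space.alpha_range

    cache: dict = {}

    def _objs(pos) -> ObjectiveVector:
        Kr = int(round(min(max(pos[0], k_lo), k_hi)))
        a = float(min(max(pos[1], a_lo), a_hi))
        key = (Kr, round(a, 6))
        if key not in cache:
            cache[key] = vmd_objectives(x, Kr, a, fs=fs, vmd_defaults=vmd_defaults)
        return cache[key]

    if k_lo == k_hi and a_lo == a_hi:
        ov = _objs((k_lo, a_lo))
        return None, (int(k_lo), float(a_lo)), ov

    pad = 1e-9  # degenerate single-value ranges get a vanishing width
    cfg = COAConfig(
        N=N,
        T=T,
        lb=(float(k_lo), float(a_lo)),
        ub=(float(k_hi) + (pad if k_lo == k_hi else 0.0),
            float(a_hi) + (pad if a_lo == a_hi else 0.0)),
        seed=seed,
    )
    front, _ = mocoa([lambda p: _objs(p).sk, lambda p: _objs(p).dkl], cfg)

    F = front.fitnesses()
    lo, hi = F.min(axis=0), F.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Fn = (F - lo) / span
    sel = int(np.argmin(np.sqrt((Fn**2).sum(axis=1))))
    pos = front.members[sel].position
    K_star = int(round(min(max(pos[0], k_lo), k_hi)))
    alpha_star = float(min(max(pos[1], a_lo), a_hi))
    return front, (K_star, alpha_star), _objs((K_star, alpha_star))


def sensitivity_sweep(signal, fs: float = 300.0, K_values=range(3, 9),
                      alpha_fixed: float = 2500.0, alpha_values=None, K_fixed: int = 6):
    """(SK, KL) curves for a K sweep at fixed alpha and an alpha sweep at fixed K."""
    alpha_values = alpha_values if alpha_values is not None else np.linspace(500, 5000, 10)
    k_curve = [
        (int(K), vmd_objectives(signal, K, alpha_fixed, fs=fs)) for K in K_values
    ]
    a_curve = [
        (float(a), vmd_objectives(signal, K_fixed, a, fs=fs)) for a in alpha_values
    ]
    return k_curve, a_curve
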