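"""Variational mode decomposition (ADMM over the half-spectrum).

Decomposes a real signal f into K band-limited modes u_k with center
frequencies omega_k by minimizing the summed analytic-signal bandwidths
subject to sum_k u_k = f, via alternating updates:

* mode update: frequency-domain Wiener filter
  ``u_k <- (f - sum_{i!=k} u_i + lambda/2) / (1 + 2 alpha (w - w_k)^2)``
* center frequency: power-weighted mean of the mode's half-spectrum,
* multiplier: ``lambda <- lambda + tau (f - sum_k u_k)``,

iterated until the summed relative change of the modes drops below ``eps``
(default 1e-7) or ``max_iter`` is reached.  The signal is mirror-extended
to twice its length before transforming and trimmed after inversion, which
suppresses boundary artifacts; modes are returned sorted by ascending
center frequency (reported in cycles/sample, convert to Hz via fs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VMDConfig", "VMDResult", "vmd", "reconstruct"]


@dataclass(frozen=True)
class VMDConfig:
    """Decomposition parameters.

    K: number of modes (1..10); alpha: bandwidth penalty; tau: multiplier
    step (0 disables the multiplier, the noise-robust default); eps:
    convergence tolerance; omega_init: 'uniform' | 'zero' | 'random'.
    """

    K: int = 5
    alpha: float = 2000.0
    tau: float = 0.0
    eps: float = 1e-7
    max_iter: int = 500
    omega_init: str = "uniform"
    init_seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= int(self.K) <= 10):
            raise ValueError(f"K must be in [1, 10], got {self.K}")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not self.eps > 0:
            raise ValueError("eps must be positive")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.omega_init not in ("uniform", "zero", "random"):
            raise ValueError(f"unknown omega_init {self.omega_init!r}")


@dataclass
class VMDResult:
    modes: np.ndarray            # (K, N) time-domain modes
    omegas: np.ndarray           # (K,) final center frequencies, cycles/sample
    omega_history: np.ndarray    # (n_iter, K)
    n_iter: int
    converged: bool
    residual: np.ndarray         # f - sum_k u_k


def vmd(signal, config: VMDConfig) -> VMDResult:
    """Decompose ``signal`` into ``config.K`` modes."""
    f = np.asarray(signal, dtype=float).ravel()
    N = f.size
    K = int(config.K)
    if N < 2 * K:
        raise ValueError(f"signal length {N} too short for K={K}")

    if not np.any(f):
        # degenerate: all-zero input decomposes into zero modes exactly
        return VMDResult(
            modes=np.zeros((K, N)),
            omegas=np.zeros(K),
            omega_history=np.zeros((1, K)),
            n_iter=0,
            converged=True,
            residual=np.zeros(N),
        )

    # mirror extension to length 2N (half of the signal reflected each side)
    half = N // 2
    fm = np.concatenate([f[:half][::-1], f, f[half:][::-1]])
    M = fm.size  # == 2N

    freqs = np.fft.fftfreq(M)          # cycles/sample of the extended signal
    pos = slice(0, M // 2 + 1)         # non-negative half-spectrum
    w = freqs[pos].copy()
    w[-1] = 0.5
    f_hat = np.fft.fft(fm)[pos]

    if config.omega_init == "uniform":
        omega = (np.arange(K) + 0.5) * 0.5 / K
    elif config.omega_init == "zero":
        omega = np.zeros(K)
    else:
        omega = np.sort(np.random.default_rng(config.init_seed).uniform(0, 0.5, K))

    u_hat = np.zeros((K, w.size), dtype=complex)
    lam = np.zeros(w.size, dtype=complex)
    hist = [omega.copy()]
    converged = False
    n_iter = 0
    for n in range(config.max_iter):
        u_prev = u_hat.copy()
        sum_u = u_hat.sum(axis=0)
        for k in range(K):
            sum_u -= u_hat[k]
            u_hat[k] = (f_hat - sum_u + lam / 2.0) / (1.0 + 2.0 * config.alpha * (w - omega[k]) ** 2)
            power = np.abs(u_hat[k]) ** 2
            denom = power.sum()
            if denom > 0:
                omega[k] = float((w * power).sum() / denom)
            sum_u += u_hat[k]
        if config.tau > 0:
            lam = lam + config.tau * (f_hat - sum_u)
        hist.append(omega.copy())
        n_iter = n + 1
        num = np.sum(np.abs(u_hat - u_prev) ** 2, axis=1)
        den = np.sum(np.abs(u_prev) ** 2, axis=1) + 1e-16
        if float(np.sum(num / den)) < config.eps:
            converged = True
            break

    # back to time domain: rebuild full spectra with conjugate symmetry
    modes = np.empty((K, N))
    for k in range(K):
        full = np.zeros(M, dtype=complex)
        full[pos] = u_hat[k]
        full[M // 2 + 1:] = np.conj(u_hat[k][1:M - M // 2][::-1])
        uk = np.real(np.fft.ifft(full))
        modes[k] = uk[half:half + N]

    order = np.argsort(omega)
    modes = modes[order]
    omega = omega[order]
    hist = np.asarray(hist)[:, order]

    residual = f - modes.sum(axis=0)
    return VMDResult(
        modes=modes,
        omegas=omega,
        omega_history=hist,
        n_iter=n_iter,
        converged=converged,
        residual=residual,
    )


def reconstruct(result: VMDResult) -> np.ndarray:
    """Sample-wise sum of all modes (the decomposition's approximation of f)."""
    return result.modes.sum(axis=0)
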