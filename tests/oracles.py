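"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: matrix-exponential
propagation plus Prony (linear-prediction) exponential recovery for the
transverse exchange model, direct ODE integration for the coupled
longitudinal model, exhaustive search for 1-D k-means partitions, and
closed-form normal equations for OLS.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm


def propagate_total_signal(a: np.ndarray, m0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Total transverse signal by explicit matrix-exponential propagation."""
    return np.array([expm(a * t) @ m0 for t in times]).sum(axis=1)


def prony_exponentials(
    signal: np.ndarray, dt: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Recover n decay constants and amplitudes from uniform samples.

    Classic Prony: fit the linear-prediction recurrence, take the roots of
    its characteristic polynomial as e^(λ dt), then solve the linear
    amplitude system.  Exact for noiseless sums of n exponentials.
    Returns (tau, amplitudes) sorted ascending in tau.
    """
    s = np.asarray(signal, dtype=float)
    rows = np.column_stack([s[n - 1 - i : len(s) - 1 - i] for i in range(n)])
    coef, *_ = np.linalg.lstsq(rows, s[n:], rcond=None)
    roots = np.roots(np.concatenate([[1.0], -coef]))
    roots = np.real(roots[np.abs(roots.imag) < 1e-8 * np.abs(roots).max()])
    roots = roots[(roots > 0) & (roots < 1)]
    tau = -dt / np.log(roots)
    t = dt * np.arange(len(s))
    basis = np.exp(-t[:, None] / tau[None, :])
    amps, *_ = np.linalg.lstsq(basis, s, rcond=None)
    order = np.argsort(tau)
    return tau[order], amps[order]


def sir_signal_ode(
    m0: float,
    psr: float,
    kmf: float,
    r1: float,
    sf: float,
    sm: float,
    times: np.ndarray,
    pre_delay: float | None = None,
) -> np.ndarray:
    """Free-pool SIR signal by direct stiff ODE integration."""
    kfm = kmf * psr
    meq = np.array([m0, psr * m0])

    def rhs(_t, mz):
        return [
            r1 * (meq[0] - mz[0]) - kfm * mz[0] + kmf * mz[1],
            r1 * (meq[1] - mz[1]) - kmf * mz[1] + kfm * mz[0],
        ]

    recover = 1.0 if pre_delay is None else 1.0 - np.exp(-r1 * pre_delay)
    y0 = [sf * m0 * recover, sm * psr * m0 * recover]
    sol = solve_ivp(
        rhs, (0.0, float(times[-1])), y0, t_eval=times, method="LSODA",
        rtol=1e-11, atol=1e-13,
    )
    return sol.y[0]


def best_1d_partition_sse(values: np.ndarray, k: int) -> float:
    """Minimal within-cluster SSE over all contiguous 1-D k-partitions.

    The optimal 1-D k-means partition is contiguous in sorted order, so
    exhaustive search over split points is exact.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)

    def sse(seg: np.ndarray) -> float:
        return float(((seg - seg.mean()) ** 2).sum())

    best = np.inf
    for splits in itertools.combinations(range(1, n), k - 1):
        edges = (0, *splits, n)
        total = sum(sse(x[a:b]) for a, b in zip(edges[:-1], edges[1:]))
        best = min(best, total)
    return best


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS slope and intercept."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    slope = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
    return float(slope), float(ym - slope * xm)
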