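"""Forward models of relaxation with inter-compartmental exchange.

Two model families live here:

* **n-pool transverse relaxation with exchange** (Bloch–McConnell without
  off-resonance terms).  Magnetization in each water compartment decays with
  an intrinsic T2 while first-order exchange shuttles magnetization between
  compartments.  The observed decay is a sum of *apparent* exponential
  components whose time constants and amplitudes differ from the intrinsic
  (T2, fraction) pairs whenever exchange is active: the fast-relaxing
  component loses amplitude to the slow one as exchange speeds up.  This is
  the mechanism by which a long-T2 edema signal fraction can exceed the
  edema water volume fraction.

* **coupled two-pool longitudinal recovery** after a selective inversion of
  the free-water pool (the SIR-qMT signal model): free water and
  macromolecular protons recover with a shared R1 while exchanging at rates
  ``kmf`` (macromolecular → free) and ``kfm = kmf * psr``.

Units are SI throughout (seconds, s^-1) unless a name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PoolSystem",
    "ApparentComponents",
    "QMTParams",
    "apparent_transverse_components",
    "sir_recovery_signal",
]

_BALANCE_TOL = 1e-9


class ModelValidationError(ValueError):
    """Raised when a pool system or parameter set violates its invariants."""


@dataclass(frozen=True)
class PoolSystem:
    """An n-compartment water system with intrinsic relaxation and exchange.

    Parameters
    ----------
    fractions
        Equilibrium signal fraction of each pool; non-negative, sums to 1.
    t2
        Intrinsic transverse relaxation time of each pool, seconds.
    t1
        Intrinsic longitudinal relaxation time of each pool, seconds
        (optional; not used by the transverse model).
    k
        ``k[i, j]`` is the first-order rate (s^-1) of magnetization leaving
        pool *i* for pool *j*.  The diagonal is ignored.  Rates must satisfy
        detailed balance ``fractions[i] * k[i, j] == fractions[j] * k[j, i]``
        so that exchange conserves the equilibrium fractions.  The mean
        residence time of pool *i* is ``1 / sum_j k[i, j]``.
    """

    fractions: np.ndarray
    t2: np.ndarray
    t1: np.ndarray | None = None
    k: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        t2 = np.asarray(self.t2, dtype=float)
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "t2", t2)
        if f.ndim != 1 or t2.shape != f.shape:
            raise ModelValidationError("fractions and t2 must be 1-D and equal length")
        n = f.size
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ModelValidationError("fractions must be >= 0 and sum to 1")
        if np.any(t2 <= 0):
            raise ModelValidationError("all t2 must be > 0")
        if self.t1 is not None:
            t1 = np.asarray(self.t1, dtype=float)
            object.__setattr__(self, "t1", t1)
            if t1.shape != f.shape or np.any(t1 <= 0):
                raise ModelValidationError("t1 must match pool count and be > 0")
        if self.k is None:
            object.__setattr__(self, "k", np.zeros((n, n)))
        else:
            k = np.array(self.k, dtype=float)
            object.__setattr__(self, "k", k)
            if k.shape != (n, n):
                raise ModelValidationError(f"k must be {n}x{n}")
            off = k.copy()
            np.fill_diagonal(off, 0.0)
            if np.any(off < 0):
                raise ModelValidationError("exchange rates must be >= 0")
            # detailed balance: f_i k_ij == f_j k_ji (relative tolerance)
            lhs = f[:, None] * off
            imbalance = np.abs(lhs - lhs.T)
            scale = np.maximum(np.abs(lhs), np.abs(lhs.T))
            bad = imbalance > _BALANCE_TOL * np.maximum(scale, 1.0)
            if np.any(bad):
                raise ModelValidationError(
                    "exchange rates violate detailed balance f_i*k_ij = f_j*k_ji"
                )

    @property
    def n_pools(self) -> int:
        return self.fractions.size

    def residence_times(self) -> np.ndarray:
        """Mean residence time per pool (inf where a pool does not exchange)."""
        off = self.k.copy()
        np.fill_diagonal(off, 0.0)
        total = off.sum(axis=1)
        with np.errstate(divide="ignore"):
            return np.where(total > 0, 1.0 / total, np.inf)

    def scale_exchange(self, c: float) -> "PoolSystem":
        """Return a copy with all exchange rates multiplied by ``c``."""
        return replace(self, k=self.k * c)

    @classmethod
    def two_pool(
        cls,
        f_short: float,
        t2_short: float,
        t2_long: float,
        residence_long: float = np.inf,
        t1: Sequence[float] | None = None,
    ) -> "PoolSystem":
        """Convenience constructor for a short/long two-pool system.

        ``residence_long`` sets the mean residence time of the long-T2 pool;
        the reverse rate follows from detailed balance.
        """
        f = np.array([f_short, 1.0 - f_short])
        k = np.zeros((2, 2))
        if np.isfinite(residence_long):
            k_ls = 1.0 / residence_long
            k[1, 0] = k_ls
            k[0, 1] = k_ls * f[1] / f[0]
        return cls(fractions=f, t2=np.array([t2_short, t2_long]), t1=t1, k=k)

    def to_dict(self) -> dict:
        d: dict = {
            "fractions": self.fractions.tolist(),
            "t2_ms": (self.t2 * 1e3).tolist(),
            "k_per_s": self.k.tolist(),
        }
        if self.t1 is not None:
            d["t1_s"] = self.t1.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PoolSystem":
        return cls(
            fractions=np.asarray(d["fractions"], dtype=float),
            t2=np.asarray(d["t2_ms"], dtype=float) / 1e3,
            t1=np.asarray(d["t1_s"], dtype=float) if "t1_s" in d else None,
            k=np.asarray(d["k_per_s"], dtype=float) if "k_per_s" in d else None,
        )


@dataclass(frozen=True)
class ApparentComponents:
    """Apparent exponential components of an exchanging system's decay."""

    t2_app: np.ndarray  # seconds, ascending
    amplitudes: np.ndarray

    def signal(self, t: np.ndarray | float) -> np.ndarray | float:
        """Total signal sum_n a_n exp(-t / t2_app_n)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        s = np.exp(-t_arr[:, None] / self.t2_app[None, :]) @ self.amplitudes
        return float(s[0]) if np.isscalar(t) or np.ndim(t) == 0 else s


def evolution_matrix(system: PoolSystem) -> np.ndarray:
    """Transverse Bloch–McConnell matrix A with dM/dt = A M.

    ``A[i, i] = -(1/t2_i + sum_j k_ij)`` and ``A[i, j] = k_ji`` (inflow into
    pool *i* from pool *j*).
    """
    n = system.n_pools
    off = system.k.copy()
    np.fill_diagonal(off, 0.0)
    a = off.T.copy()
    a[np.diag_indices(n)] = -(1.0 / system.t2 + off.sum(axis=1))
    return a


def apparent_transverse_components(
    system: PoolSystem,
    m_init: np.ndarray | None = None,
    *,
    degenerate_rtol: float = 1e-10,
    amp_drop: float = 1e-12,
) -> ApparentComponents:
    """Eigen-decompose the exchange system into apparent decay components.

    Parameters
    ----------
    system
        Validated pool system.
    m_init
        Initial transverse magnetization per pool.  Defaults to the
        equilibrium fractions (a hard 90° pulse on a fully relaxed system).
    degenerate_rtol
        Eigenvalues closer than this relative tolerance are merged and their
        amplitudes summed.
    amp_drop
        Components with |amplitude| below ``amp_drop * sum(m_init)`` are
        dropped.

    Returns
    -------
    ApparentComponents
        Apparent time constants (ascending) and amplitudes such that
        ``S(t) = sum_n a_n exp(-t / t2_app_n)`` equals the exact propagated
        total magnetization for all t >= 0.
    """
    if m_init is None:
        m_init = system.fractions
    m_init = np.asarray(m_init, dtype=float)
    if m_init.shape != system.fractions.shape:
        raise ModelValidationError("m_init must have one entry per pool")
    if np.any(m_init < 0) or not np.any(m_init > 0):
        raise ModelValidationError("m_init entries must be >= 0 and not all zero")

    a = evolution_matrix(system)
    lam, vr = np.linalg.eig(a)
    # detailed balance makes A similar to a symmetric matrix -> real spectrum
    if np.max(np.abs(lam.imag)) > 1e-9 * np.max(np.abs(lam.real)):
        raise ModelValidationError("complex apparent rates; system is non-physical")
    lam = lam.real
    vr = vr.real
    proj = np.linalg.solve(vr, m_init)  # left-eigenvector projections
    amps = vr.sum(axis=0) * proj
    t2_app = -1.0 / lam

    order = np.argsort(t2_app)
    t2_app, amps = t2_app[order], amps[order]

    # merge (near-)degenerate eigenvalues
    merged_t2: list[float] = []
    merged_a: list[float] = []
    for tau, amp in zip(t2_app, amps):
        if merged_t2 and abs(tau - merged_t2[-1]) <= degenerate_rtol * abs(merged_t2[-1]):
            merged_a[-1] += amp
        else:
            merged_t2.append(tau)
            merged_a.append(amp)
    t2_app = np.array(merged_t2)
    amps = np.array(merged_a)

    keep = np.abs(amps) >= amp_drop * m_init.sum()
    t2_app, amps = t2_app[keep], amps[keep]
    if np.any(t2_app <= 0):
        raise ModelValidationError("non-positive apparent T2; system is non-physical")
    return ApparentComponents(t2_app=t2_app, amplitudes=amps)


@dataclass(frozen=True)
class QMTParams:
    """Parameters of the coupled two-pool selective-inversion-recovery model.

    Exactly five quantities are fitted: ``m0``, ``psr``, ``kmf``, ``r1`` and
    ``sf``.  ``sm``, the fractional longitudinal state of the macromolecular
    pool right after the (short, free-pool-selective) inversion pulse, is a
    fixed constant of the acquisition, not a fitted parameter.

    Attributes
    ----------
    m0 : equilibrium free-pool signal (arbitrary units), > 0.
    psr : macromolecular-to-free pool-size ratio, >= 0.
    kmf : macromolecular -> free exchange rate, s^-1.  The reverse rate is
        ``kfm = kmf * psr`` by detailed balance.
    r1 : shared longitudinal rate 1/T1 of both pools, s^-1.
    sf : free-pool inversion efficiency in [-1, 1] (-1 is a perfect inversion).
    sm : macromolecular-pool saturation factor (default 0.83 for a ~1.5 ms
        hard inversion pulse).
    """

    m0: float
    psr: float
    kmf: float
    r1: float
    sf: float
    sm: float = 0.83

    def __post_init__(self) -> None:
        if self.m0 <= 0:
            raise ModelValidationError("m0 must be > 0")
        if self.psr < 0 or self.kmf < 0:
            raise ModelValidationError("psr and kmf must be >= 0")
        if self.r1 <= 0:
            raise ModelValidationError("r1 must be > 0")
        if not -1.0 <= self.sf <= 1.0:
            raise ModelValidationError("sf must lie in [-1, 1]")

    @property
    def t1(self) -> float:
        """Longitudinal relaxation time 1/r1, seconds."""
        return 1.0 / self.r1

    def to_dict(self) -> dict:
        return {
            "m0": self.m0,
            "psr": self.psr,
            "kmf": self.kmf,
            "r1": self.r1,
            "sf": self.sf,
            "sm": self.sm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QMTParams":
        return cls(**{k: float(d[k]) for k in ("m0", "psr", "kmf", "r1", "sf", "sm") if k in d})


def sir_recovery_signal(
    params: QMTParams,
    times: np.ndarray,
    *,
    magnitude: bool = False,
    pre_delay: float | None = None,
) -> np.ndarray:
    """Free-pool longitudinal signal of the coupled two-pool SIR experiment.

    The free (f) and macromolecular (m) pools recover toward equilibrium
    ``(m0, psr*m0)`` with shared rate ``r1`` while exchanging at ``kfm =
    kmf*psr`` (f → m) and ``kmf`` (m → f).  The inversion prepares
    ``Mz_f(0) = sf*m0`` and ``Mz_m(0) = sm*psr*m0``.  The recovery is
    bi-exponential in t and converges monotonically to ``m0``.

    Parameters
    ----------
    params : model parameters.
    times : inversion times, seconds, positive and ascending.
    magnitude : if True return |S| (acquired data are magnitude images);
        default is the signed signal.
    pre_delay : optional finite repetition pre-delay, seconds.  When given,
        both pools are assumed saturated at the end of the previous readout
        and recover for ``pre_delay`` before the inversion, scaling the
        pre-inversion longitudinal state by ``1 - exp(-r1*pre_delay)``.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be positive and strictly ascending")

    m0, psr, kmf, r1, sf, sm = (
        params.m0,
        params.psr,
        params.kmf,
        params.r1,
        params.sf,
        params.sm,
    )
    kfm = kmf * psr
    meq = np.array([m0, psr * m0])
    recover = 1.0 if pre_delay is None else 1.0 - np.exp(-r1 * pre_delay)
    m_start = np.array([sf * m0 * recover, sm * psr * m0 * recover])

    a = np.array([[-(r1 + kfm), kmf], [kfm, -(r1 + kmf)]])
    lam, vr = np.linalg.eig(a)
    coef = np.linalg.solve(vr, m_start - meq)
    # free-pool row of V exp(lam t) coef + equilibrium
    sig = meq[0] + (vr[0] * coef) @ np.exp(lam[:, None] * t[None, :])
    sig = sig.real
    return np.abs(sig) if magnitude else sig
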