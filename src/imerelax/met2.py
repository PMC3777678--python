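"""Multi-exponential T2 (MET2) analysis of multi-echo decay curves.

A measured decay is modelled as the sum of up to three T2-spectral
components, each a Gaussian line on a log-spaced T2 grid with a
non-negative amplitude.  Fitting uses variable projection: an outer
bounded nonlinear search over the component centers (and optionally
widths) with an inner non-negative least-squares solve for the
amplitudes.  The number of components is chosen by sequential nested
F-tests on the χ² residuals, component T2s are pooled across ROIs and
clustered (k-means on log T2) into short / intermediate / long classes,
and the class signal fractions define the myelin water fraction (MWF,
short class) and the edema water fraction (EWF, long class).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Met2Options",
    "GaussianComponent",
    "ComponentFit",
    "WaterFractions",
    "fit_gaussian_components",
    "select_n_components",
    "met2_ladder",
    "cluster_t2_classes",
    "assign_t2_classes",
    "compute_water_fractions",
    "voxelwise_uncertainty",
]

CLASS_ORDER = ("short", "intermediate", "long")


class Met2FitError(RuntimeError):
    def __init__(self, msg: str, best: "ComponentFit | None" = None):
        super().__init__(msg)
        self.best = best


@dataclass(frozen=True)
class Met2Options:
    """Options of the spectral-component fit.

    ``width`` is the common Gaussian SD of each component in log10(T2)
    decades (fixed by default; set ``fit_width=True`` to fit a shared
    width within ``width_bounds``).  The T2 grid covers 1 ms – 3 s with
    256 log-spaced points.
    """

    grid_min_s: float = 1e-3
    grid_max_s: float = 3.0
    n_grid: int = 256
    width: float = 0.02
    fit_width: bool = False
    width_bounds: tuple[float, float] = (0.01, 0.2)
    n_det_starts: int = 5
    n_jitter_starts: int = 5
    seed: int = 0
    noise_floor: float = 0.0  # optional Rician-floor offset subtracted from signal

    def grid(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.grid_min_s), np.log10(self.grid_max_s), self.n_grid
        )

    @property
    def center_bounds(self) -> tuple[float, float]:
        lo, hi = np.log10(self.grid_min_s), np.log10(self.grid_max_s)
        pad = 0.02 * (hi - lo)
        return lo + pad, hi - pad


@dataclass(frozen=True)
class GaussianComponent:
    """A Gaussian T2-spectral line: center/width in log10(seconds)/decades."""

    center: float
    width: float
    amplitude: float

    @property
    def t2_s(self) -> float:
        """Geometric-mean T2 of the component, seconds."""
        return 10.0**self.center


@dataclass(frozen=True)
class ComponentFit:
    """Result of an n-component spectral fit."""

    components: tuple[GaussianComponent, ...]
    chi2: float
    n_params: int
    spectrum: np.ndarray  # amplitudes on the log-T2 grid
    grid: np.ndarray      # the T2 grid, seconds

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([c.amplitude for c in self.components])

    @property
    def t2s_s(self) -> np.ndarray:
        return np.array([c.t2_s for c in self.components])

    def predict(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        kern = np.exp(-times[:, None] / self.grid[None, :])
        return kern @ self.spectrum


@dataclass(frozen=True)
class WaterFractions:
    """Class signal fractions: short = MWF, long = EWF."""

    mwf: float
    intermediate: float
    ewf: float
    total: float

    def __post_init__(self) -> None:
        fr = (self.mwf, self.intermediate, self.ewf)
        if any(not 0.0 <= f <= 1.0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("fractions must lie in [0,1] and sum to 1")


def _component_weights(
    centers: np.ndarray, widths: np.ndarray, log_grid: np.ndarray
) -> np.ndarray:
    """(n_comp, n_grid) Gaussian line weights, each row summing to 1."""
    w = np.exp(-((log_grid[None, :] - centers[:, None]) ** 2) / (2.0 * widths[:, None] ** 2))
    return w / w.sum(axis=1, keepdims=True)


def _component_basis(
    times: np.ndarray,
    kern: np.ndarray,
    log_grid: np.ndarray,
    centers: np.ndarray,
    widths: np.ndarray,
) -> np.ndarray:
    """(n_times, n_comp) decay basis of the Gaussian spectral lines.

    Lines wider than the grid spacing are integrated by grid quadrature;
    narrower lines degenerate to a single exponential, which is evaluated
    analytically (the grid cannot resolve them and the quadrature would be
    piecewise constant in the center).
    """
    spacing = log_grid[1] - log_grid[0]
    basis = np.empty((times.size, centers.size))
    wide = widths >= spacing
    if wide.any():
        w = _component_weights(centers[wide], widths[wide], log_grid)
        basis[:, wide] = kern @ w.T
    if (~wide).any():
        basis[:, ~wide] = np.exp(-times[:, None] / 10.0 ** centers[None, ~wide])
    return basis


def _solve_amplitudes(basis: np.ndarray, signal: np.ndarray) -> tuple[np.ndarray, float]:
    amps, rnorm = optimize.nnls(basis, signal)
    return amps, rnorm**2


def _fit_from_centers(
    signal: np.ndarray,
    times: np.ndarray,
    kern: np.ndarray,
    log_grid: np.ndarray,
    centers0: np.ndarray,
    opts: Met2Options,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Variable-projection refinement from one starting point."""
    n = centers0.size
    lo, hi = opts.center_bounds

    if opts.fit_width:
        x0 = np.concatenate([centers0, [opts.width]])
        lb = np.concatenate([np.full(n, lo), [opts.width_bounds[0]]])
        ub = np.concatenate([np.full(n, hi), [opts.width_bounds[1]]])
    else:
        x0, lb, ub = centers0, np.full(n, lo), np.full(n, hi)

    def residual(x: np.ndarray) -> np.ndarray:
        centers = x[:n]
        widths = np.full(n, x[n] if opts.fit_width else opts.width)
        basis = _component_basis(times, kern, log_grid, centers, widths)
        amps, _ = _solve_amplitudes(basis, signal)
        return basis @ amps - signal

    sol = optimize.least_squares(
        residual, np.clip(x0, lb, ub), bounds=(lb, ub), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=200 * (n + 1),
    )
    centers = sol.x[:n]
    widths = np.full(n, sol.x[n] if opts.fit_width else opts.width)
    amps, chi2 = _solve_amplitudes(
        _component_basis(times, kern, log_grid, centers, widths), signal
    )
    return centers, np.column_stack([widths, amps]), chi2


def _starting_points(
    n: int, opts: Met2Options, warm_starts: list[np.ndarray] | None
) -> list[np.ndarray]:
    lo, hi = opts.center_bounds
    span = hi - lo
    windows = [(0.2, 0.8), (0.1, 0.6), (0.4, 0.9), (0.1, 0.9), (0.25, 0.75)]
    starts = [
        lo + span * np.linspace(a, b, n)
        for a, b in windows[: opts.n_det_starts]
    ]
    rng = np.random.default_rng(opts.seed)
    for _ in range(opts.n_jitter_starts):
        starts.append(np.sort(rng.uniform(lo + 0.05 * span, hi - 0.05 * span, n)))
    for w in warm_starts or []:
        w = np.clip(np.sort(np.asarray(w, dtype=float)), lo, hi)
        if w.size == n:
            starts.append(w)
    return starts


def fit_gaussian_components(
    signal: np.ndarray,
    times: np.ndarray,
    n_components: int,
    options: Met2Options | None = None,
    *,
    warm_starts: list[np.ndarray] | None = None,
) -> ComponentFit:
    """Fit ``n_components`` Gaussian T2-spectral components to a decay.

    Parameters
    ----------
    signal, times
        Decay samples and echo times in **seconds**; ``len(signal)`` must
        exceed the parameter count by at least 2 and the signal must be
        non-negative.
    n_components
        1, 2 or 3 components.
    warm_starts
        Extra center starting points (log10 seconds) appended to the
        deterministic quantile starts and the seeded jittered starts.

    Returns
    -------
    ComponentFit
        The best fit over all starts (ties broken toward fewer components
        with non-zero amplitude).  χ² is the unweighted sum of squared
        residuals.
    """
    opts = options or Met2Options()
    signal = np.asarray(signal, dtype=float)
    times = np.asarray(times, dtype=float)
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    n_params = (3 if opts.fit_width else 2) * n_components
    if signal.size != times.size or signal.size < n_params + 2:
        raise ValueError("need len(signal) == len(times) >= n_params + 2")
    if not np.any(signal > 0):
        raise Met2FitError("signal has no positive samples")
    if signal.max() < 10.0 * -signal.min():
        # noise can push late echoes slightly negative; a signal this
        # negative is not a decay
        raise ValueError("signal is predominantly negative")
    if opts.noise_floor:
        signal = np.sqrt(np.maximum(signal**2 - opts.noise_floor**2, 0.0))

    grid = opts.grid()
    log_grid = np.log10(grid)
    kern = np.exp(-times[:, None] / grid[None, :])

    best: tuple[float, int, np.ndarray, np.ndarray] | None = None
    failures = 0
    for start in _starting_points(n_components, opts, warm_starts):
        try:
            centers, wa, chi2 = _fit_from_centers(signal, times, kern, log_grid, start, opts)
        except Exception:
            failures += 1
            continue
        n_eff = int(np.sum(wa[:, 1] > 1e-12 * signal.max()))
        key = (chi2, n_eff)
        if best is None or key < (best[0], best[1]):
            best = (chi2, n_eff, centers, wa)
    if best is None:
        raise Met2FitError(f"all {failures} starts failed to converge")

    chi2, _, centers, wa = best
    order = np.argsort(centers)
    centers, wa = centers[order], wa[order]
    # merge components that collapsed onto the same center
    comps: list[list[float]] = []
    for c, (w, a) in zip(centers, wa):
        if comps and abs(c - comps[-1][0]) < 1e-6:
            comps[-1][2] += a
        else:
            comps.append([c, w, a])
    components = tuple(GaussianComponent(c, w, a) for c, w, a in comps)
    weights = _component_weights(
        np.array([c.center for c in components]),
        np.array([c.width for c in components]),
        log_grid,
    )
    spectrum = np.array([c.amplitude for c in components]) @ weights
    return ComponentFit(
        components=components, chi2=chi2, n_params=n_params,
        spectrum=spectrum, grid=grid,
    )


def select_n_components(
    fits: dict[int, ComponentFit],
    n_data: int,
    alpha: float = 0.05,
    *,
    ladder: str = "sequential",
) -> int:
    """Choose the component count by nested F-tests on χ².

    ``fits`` maps candidate counts (1, 2, 3 …) to their fits.  With the
    default sequential ladder each larger model is adopted iff the nested
    F-test against the current model gives P < ``alpha``:

        F = ((χ²_r − χ²_f) / Δp) / (χ²_f / (n_data − p_f)).

    A perfect larger fit (χ²_f = 0 with χ²_r > 0) is adopted directly.
    """
    ns = sorted(fits)
    if ladder not in ("sequential", "best"):
        raise ValueError("ladder must be 'sequential' or 'best'")
    current = ns[0]
    candidates = ns[1:] if ladder == "sequential" else ns[1:]
    for n in candidates:
        reduced, full = fits[current], fits[n]
        dp = full.n_params - reduced.n_params
        dof = n_data - full.n_params
        if dof <= 0 or dp <= 0:
            break
        if full.chi2 == 0.0:
            if reduced.chi2 > 0.0:
                current = n
            continue
        f_stat = max(reduced.chi2 - full.chi2, 0.0) / dp / (full.chi2 / dof)
        p = stats.f.sf(f_stat, dp, dof)
        if p < alpha:
            current = n
        elif ladder == "sequential":
            break
    return current


def met2_ladder(
    signal: np.ndarray,
    times: np.ndarray,
    options: Met2Options | None = None,
    alpha: float = 0.05,
    max_components: int = 3,
    *,
    early_stop: bool = False,
) -> tuple[dict[int, ComponentFit], int]:
    """Fit 1..max_components and select the count by sequential F-tests.

    Larger models are warm-started from the smaller model's centers (plus
    candidate extra centers), which also enforces the nested-model
    property χ²(1) ≥ χ²(2) ≥ χ²(3).  With ``early_stop`` the ladder stops
    fitting larger models as soon as a sequential F-test fails (same
    selection, fewer fits).
    """
    opts = options or Met2Options()
    lo, hi = opts.center_bounds
    signal = np.asarray(signal, dtype=float)
    times = np.asarray(times, dtype=float)
    grid = opts.grid()
    log_grid = np.log10(grid)
    kern = np.exp(-times[:, None] / grid[None, :])
    fits: dict[int, ComponentFit] = {}
    prev: ComponentFit | None = None
    for n in range(1, max_components + 1):
        warm = []
        if prev is not None:
            base = np.array([c.center for c in prev.components])
            while base.size < n - 1:  # prev fit may have merged components
                base = np.append(base, 0.5 * (lo + hi))
            base = base[: n - 1]
            # coarse global scan of the added component's center: NNLS
            # amplitudes at each candidate, refine from the best few
            cands = np.linspace(lo, hi, 48)
            chis = []
            for c in cands:
                centers = np.sort(np.append(base, c))
                widths = np.full(n, opts.width)
                basis = _component_basis(times, kern, log_grid, centers, widths)
                chis.append(_solve_amplitudes(basis, signal)[1])
            for i in np.argsort(chis)[:3]:
                warm.append(np.sort(np.append(base, cands[i])))
        fit = fit_gaussian_components(signal, times, n, opts, warm_starts=warm)
        if prev is not None and fit.chi2 > prev.chi2:
            # pad the smaller model with a zero-amplitude line: same χ²,
            # keeps the model sequence properly nested
            base = list(prev.components)
            extra_c = hi - 0.05 * (hi - lo)
            while len(base) < n:
                base.append(GaussianComponent(extra_c, opts.width, 0.0))
                extra_c -= 0.1
            base.sort(key=lambda c: c.center)
            fit = ComponentFit(
                components=tuple(base), chi2=prev.chi2,
                n_params=(3 if opts.fit_width else 2) * n,
                spectrum=prev.spectrum, grid=prev.grid,
            )
        fits[n] = fit
        if early_stop and select_n_components(fits, signal.size, alpha) < n:
            break
        prev = fit
    return fits, select_n_components(fits, signal.size, alpha)


def cluster_t2_classes(
    t2_values_s: np.ndarray, k: int = 3
) -> tuple[np.ndarray, dict[str, float]]:
    """Cluster pooled component T2s into short/intermediate/long classes.

    k-means on log10(T2 [s]), solved exactly: the optimal 1-D k-means
    partition is contiguous in sorted order, so dynamic programming over
    split points finds the global within-cluster-SSE minimum
    deterministically (no dependence on initialization or input order).
    Returns per-value class names (``'short'``, ``'intermediate'``,
    ``'long'`` for k = 3; the first k names for smaller k) and the class
    geometric-mean T2 centers in seconds.
    """
    t2 = np.asarray(t2_values_s, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("T2 values must be positive")
    x = np.log10(t2)
    if np.unique(x).size < k:
        raise ValueError(f"need at least {k} distinct T2 values")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    # prefix sums give O(1) segment SSE: sse(i,j) over xs[i:j]
    c1 = np.concatenate([[0.0], np.cumsum(xs)])
    c2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def sse(i: int, j: int) -> float:
        s, q, m = c1[j] - c1[i], c2[j] - c2[i], j - i
        return q - s * s / m

    cost = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            for i in range(m - 1, j):
                c = cost[m - 1, i] + sse(i, j)
                if c < cost[m, j] - 1e-15:
                    cost[m, j] = c
                    split[m, j] = i
    edges = [n]
    for m in range(k, 0, -1):
        edges.append(split[m, edges[-1]])
    edges = edges[::-1]  # k+1 boundaries in sorted order

    names = list(CLASS_ORDER[:k])
    labels_sorted = np.empty(n, dtype=object)
    centers: dict[str, float] = {}
    for ci, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        labels_sorted[a:b] = names[ci]
        centers[names[ci]] = float(10.0 ** xs[a:b].mean())
    labels = np.empty(n, dtype=object)
    labels[order] = labels_sorted
    return np.array([str(v) for v in labels]), centers


def assign_t2_classes(
    t2_values_s: np.ndarray, class_centers: dict[str, float]
) -> np.ndarray:
    """Assign T2 values to the nearest class center in log10 space."""
    names = list(class_centers)
    logc = np.log10(np.array([class_centers[n] for n in names]))
    idx = np.argmin(np.abs(np.log10(np.asarray(t2_values_s))[:, None] - logc[None, :]), axis=1)
    return np.array([names[i] for i in idx])


def compute_water_fractions(fit: ComponentFit, labels: np.ndarray) -> WaterFractions:
    """MWF / EWF from labelled components: class amplitude / total amplitude."""
    labels = np.asarray(labels)
    if labels.size != fit.n_components:
        raise ValueError("one label per component required")
    amps = fit.amplitudes
    total = float(amps.sum())
    if total <= 0:
        raise ValueError("total amplitude is zero")
    frac = {name: float(amps[labels == name].sum()) / total for name in CLASS_ORDER}
    return WaterFractions(
        mwf=frac["short"],
        intermediate=frac["intermediate"],
        ewf=frac["long"],
        total=total,
    )


def voxelwise_uncertainty(
    voxel_signals: np.ndarray,
    times: np.ndarray,
    n_components: int,
    class_centers: dict[str, float],
    options: Met2Options | None = None,
    *,
    warm_starts: list[np.ndarray] | None = None,
) -> dict:
    """Intra-ROI standard error of MWF/EWF by voxel-by-voxel fitting.

    Each voxel decay is fitted with the component count fixed to the
    ROI-level selection; voxel components are assigned to the ROI class
    centers and the SE of each fraction is SD(voxel values)/sqrt(N).
    Raises if more than half of the voxel fits fail.
    """
    v = np.asarray(voxel_signals, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("need a (n_voxels >= 2, n_times) signal array")
    if options is not None and warm_starts:
        # ROI-level centers are reliable starts; trim the multi-start
        # budget for the (many) per-voxel fits
        options = replace(options, n_det_starts=2, n_jitter_starts=1)
    mwf, ewf = [], []
    failures = 0
    for row in v:
        try:
            fit = fit_gaussian_components(
                row, times, n_components, options, warm_starts=warm_starts
            )
            labels = assign_t2_classes(fit.t2s_s, class_centers)
            wf = compute_water_fractions(fit, labels)
        except Exception:
            failures += 1
            continue
        mwf.append(wf.mwf)
        ewf.append(wf.ewf)
    if failures > 0.5 * v.shape[0]:
        raise Met2FitError(f"{failures}/{v.shape[0]} voxel fits failed")
    n = len(mwf)
    return {
        "n_voxels": n,
        "n_failures": failures,
        "mwf_values": np.array(mwf),
        "ewf_values": np.array(ewf),
        "se_mwf": float(np.std(mwf, ddof=1) / np.sqrt(n)),
        "se_ewf": float(np.std(ewf, ddof=1) / np.sqrt(n)),
    }
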