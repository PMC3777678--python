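"""Synthetic-study generators with known ground truth.

These generators emulate the acquisition and tissue conditions of a
hexachlorophene (HCP) intoxication study of intramyelinic edema in rat
cervical spinal cord:

* multi-echo T2 decays sampled on a 40-echo scheme (32 early echoes from
  7.4 ms at 9 ms spacing, 8 late echoes at 50 ms spacing) from 2–3
  compartment systems with optional inter-compartmental exchange and
  Rician noise;
* selective-inversion-recovery (SIR) series at 25 pseudo-logarithmic
  inversion times between 3.5 ms and 10 s;
* toluidine-blue-like histology fields (1600 × 1200 px over
  120 × 90 μm²) of myelinated axons with circular intramyelinic edema
  lesions (diameter ≈ 3.1 ± 0.4 μm) at tract- and dose-dependent
  densities;
* whole synthetic studies (three diet groups × four white-matter tracts)
  written to a run directory together with their ground-truth tables.

Every generator is a pure function of ``(params, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import stats

from .histology import (
    CLASS_EDEMA,
    CLASS_IE,
    CLASS_MYELIN,
    DEFAULT_RHO,
    HistologyLabelMap,
    water_content,
)
from .relaxometry import (
    PoolSystem,
    QMTParams,
    apparent_transverse_components,
    sir_recovery_signal,
)

__all__ = [
    "EchoScheme",
    "make_echo_times",
    "make_inversion_times",
    "simulate_roi_decay",
    "simulate_sir_series",
    "HistologyGenParams",
    "LESION_DENSITY_PRESETS",
    "generate_histology_image",
    "StudyTruth",
    "default_study_config",
    "generate_study",
]


# --------------------------------------------------------------------------
# sampling schemes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EchoScheme:
    """Dual-spacing multi-echo scheme (times in milliseconds).

    The default reproduces the study acquisition: 32 echoes from 7.4 ms at
    9 ms spacing followed by 8 echoes at 50 ms spacing (last echo 686.4 ms).
    """

    n1: int = 32
    te1: float = 7.4
    esp1: float = 9.0
    n2: int = 8
    esp2: float = 50.0

    def __post_init__(self) -> None:
        if min(self.n1, self.te1, self.esp1, self.esp2) <= 0 or self.n2 < 0:
            raise ValueError("echo scheme entries must be positive")

    def times_ms(self) -> np.ndarray:
        return make_echo_times(self)

    def times_s(self) -> np.ndarray:
        return make_echo_times(self) / 1e3


def make_echo_times(scheme: EchoScheme) -> np.ndarray:
    """Echo times in ms: n1 early echoes then n2 late echoes."""
    early = scheme.te1 + scheme.esp1 * np.arange(scheme.n1)
    late = early[-1] + scheme.esp2 * np.arange(1, scheme.n2 + 1)
    return np.concatenate([early, late])


def make_inversion_times(
    n: int = 25, tmin: float = 0.0035, tmax: float = 10.0
) -> np.ndarray:
    """Pseudo-logarithmic inversion times in seconds.

    ``n`` log-spaced times from ``tmin`` to ``tmax`` inclusive, rounded to
    0.1 ms (the "pseudo" step of a sequence timing table); must remain
    strictly increasing after rounding.
    """
    if n < 2:
        raise ValueError("need at least 2 inversion times")
    if not 0 < tmin < tmax:
        raise ValueError("require 0 < tmin < tmax")
    t = np.round(np.geomspace(tmin, tmax, n), 4)  # 0.1 ms = 1e-4 s
    if np.any(np.diff(t) <= 0):
        raise ValueError(
            "rounding to 0.1 ms collapsed inversion times; reduce n or widen the range"
        )
    return t


# --------------------------------------------------------------------------
# noisy signal simulators
# --------------------------------------------------------------------------

def _add_noise(
    signal: np.ndarray,
    scale: float,
    snr: float,
    rng: np.random.Generator,
    n_avg: int,
    noise: str,
) -> np.ndarray:
    if not snr > 0:
        raise ValueError("snr must be > 0 (np.inf for noiseless)")
    if np.isinf(snr):
        return signal.copy()
    sd = scale / snr / np.sqrt(n_avg)
    if noise == "rician":
        re = signal + rng.normal(0.0, sd, signal.shape)
        im = rng.normal(0.0, sd, signal.shape)
        return np.hypot(re, im)
    if noise == "gaussian":
        return signal + rng.normal(0.0, sd, signal.shape)
    raise ValueError("noise must be 'rician' or 'gaussian'")


def simulate_roi_decay(
    system: PoolSystem,
    times_s: np.ndarray,
    snr: float = np.inf,
    seed: int | np.random.Generator | None = 0,
    *,
    n_avg: int = 1,
    noise: str = "rician",
    m_init: np.ndarray | None = None,
    t1_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Noisy multi-echo decay of an exchanging pool system.

    The noiseless signal is the apparent-component decay evaluated at
    ``times_s``; noise is the magnitude of a complex Gaussian perturbation
    with per-channel SD ``S(0) / snr / sqrt(n_avg)`` (Rician, the default)
    or plain additive Gaussian noise for ROI-mean data.

    ``t1_weights`` optionally scales the initial per-pool magnetization
    (e.g. residual inversion-prepared T1 weighting); by default the decay
    starts from the equilibrium fractions.
    """
    times_s = np.asarray(times_s, dtype=float)
    if np.any(np.diff(times_s) <= 0):
        raise ValueError("times must be strictly ascending")
    if m_init is None:
        m_init = system.fractions
    if t1_weights is not None:
        m_init = np.asarray(m_init, float) * np.asarray(t1_weights, float)
    comps = apparent_transverse_components(system, m_init)
    clean = comps.signal(times_s)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _add_noise(clean, float(comps.signal(0.0)), snr, rng, n_avg, noise)


def simulate_sir_series(
    params: QMTParams,
    times_s: np.ndarray,
    snr: float = np.inf,
    seed: int | np.random.Generator | None = 0,
    *,
    n_avg: int = 1,
    noise: str = "rician",
    magnitude: bool = False,
    pre_delay: float | None = None,
) -> np.ndarray:
    """Noisy selective-inversion-recovery series (free-pool signal).

    Wraps the coupled two-pool recovery model; the noise SD is referenced
    to the equilibrium signal ``m0``.  ``pre_delay`` models a finite
    repetition pre-delay by scaling the pre-inversion longitudinal state
    (see :func:`imerelax.relaxometry.sir_recovery_signal`).
    """
    clean = sir_recovery_signal(params, times_s, magnitude=magnitude, pre_delay=pre_delay)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = _add_noise(clean, params.m0, snr, rng, n_avg, noise)
    return np.abs(noisy) if (magnitude and noise == "gaussian") else noisy


# --------------------------------------------------------------------------
# histology field generator
# --------------------------------------------------------------------------

#: mean lesion densities (per mm²) observed per tract and diet group,
#: usable as generator presets
LESION_DENSITY_PRESETS: dict[str, float] = {
    "dCST-HCP600": 1651.0,
    "FG-HCP600": 1291.0,
    "RST-HCP600": 545.0,
    "VST-HCP600": 497.0,
    "dCST-HCP300": 776.0,
    "FG-HCP300": 469.0,
    "RST-HCP300": 344.0,
    "VST-HCP300": 142.0,
}


@dataclass(frozen=True)
class HistologyGenParams:
    """Parameters of the toluidine-blue-like histology field generator.

    The default grid and field of view (1600 × 1200 px over 120 × 90 μm²,
    0.075 μm/px) match the digitization of the study's light-microscopy
    images; the default lesion geometry (circular, diameter 3.1 ± 0.4 μm)
    and density (dCST tract at the higher HCP dose) match its lesion
    statistics.
    """

    grid: tuple[int, int] = (1200, 1600)          # (rows, cols)
    fov_um: tuple[float, float] = (90.0, 120.0)   # (height, width), μm
    lesion_density: float = LESION_DENSITY_PRESETS["dCST-HCP600"]  # per mm²
    lesion_diameter_mean: float = 3.1             # μm
    lesion_diameter_sd: float = 0.4               # μm
    packing_fraction: float = 0.50                # axon (fibre) area fraction
    axon_radius_mean: float = 1.4                 # μm, outer fibre radius
    axon_radius_sd: float = 0.35                  # μm
    myelin_thickness_fraction: float = 0.28       # annulus / outer radius
    intensity_myelin: float = 0.20
    intensity_ie: float = 0.55
    intensity_edema: float = 0.90
    noise_sd: float = 0.05
    illumination_amplitude: float = 0.05
    max_attempts_per_lesion: int = 100000

    def __post_init__(self) -> None:
        if min(self.grid) <= 0 or min(self.fov_um) <= 0:
            raise ValueError("grid and fov must be positive")
        if self.lesion_density < 0:
            raise ValueError("lesion density must be >= 0")
        if self.lesion_diameter_mean <= 0:
            raise ValueError("lesion diameter must be > 0")
        for i in (self.intensity_myelin, self.intensity_ie, self.intensity_edema):
            if not 0.0 <= i <= 1.0:
                raise ValueError("class intensities must lie in [0, 1]")

    @property
    def pixel_size(self) -> float:
        """μm per pixel (isotropic by construction)."""
        return self.fov_um[1] / self.grid[1]

    @property
    def area_mm2(self) -> float:
        return self.fov_um[0] * self.fov_um[1] * 1e-6


class HistologyGenerationError(RuntimeError):
    def __init__(self, msg: str, achieved_density: float | None = None):
        super().__init__(msg)
        self.achieved_density = achieved_density


def _paint_disk(arr: np.ndarray, r0: float, c0: float, radius_px: float, value: int) -> None:
    rlo = max(int(np.floor(r0 - radius_px)), 0)
    rhi = min(int(np.ceil(r0 + radius_px)) + 1, arr.shape[0])
    clo = max(int(np.floor(c0 - radius_px)), 0)
    chi = min(int(np.ceil(c0 + radius_px)) + 1, arr.shape[1])
    if rlo >= rhi or clo >= chi:
        return
    rr, cc = np.ogrid[rlo:rhi, clo:chi]
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2
    arr[rlo:rhi, clo:chi][mask] = value


def generate_histology_image(
    p: HistologyGenParams, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, HistologyLabelMap, dict[str, float]]:
    """Render a histology field and its ground-truth label map.

    Myelinated fibres are laid out on a jittered hexagonal lattice (dense,
    near-crystalline packing as in spinal white matter): each fibre is a
    circular axon with a myelin annulus whose thickness is a fixed fraction
    of the outer radius.  Circular edema lesions (diameter ~ Normal,
    truncated positive) are then placed by rejection sampling of centers
    inside myelin — the vacuoles split the myelin sheath and expand into
    the adjacent space.  The rendered image is class intensities plus a
    linear illumination gradient plus Gaussian noise, clipped to [0, 1].

    Returns ``(image, labelmap, truth)`` where ``truth`` holds the achieved
    volume fractions and lesion statistics from the label map.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nrow, ncol = p.grid
    px = p.pixel_size
    labels = np.full((nrow, ncol), CLASS_IE, dtype=np.uint8)

    # --- fibre lattice ---------------------------------------------------
    r_mean_px = p.axon_radius_mean / px
    spacing = r_mean_px * np.sqrt(2.0 * np.pi / (np.sqrt(3.0) * p.packing_fraction))
    jitter = 0.05 * spacing
    r_cap = 0.5 * spacing - 2.0 * jitter - 1.0  # hard non-overlap cap
    row_step = spacing * np.sqrt(3.0) / 2.0
    n_rows = int(np.ceil(nrow / row_step)) + 2
    n_cols = int(np.ceil(ncol / spacing)) + 2
    g = 1.0 - p.myelin_thickness_fraction  # inner/outer radius ratio
    for i in range(n_rows):
        for j in range(n_cols):
            r0 = (i - 0.5) * row_step + rng.uniform(-jitter, jitter)
            c0 = (j - 0.5 + 0.5 * (i % 2)) * spacing + rng.uniform(-jitter, jitter)
            radius = rng.normal(p.axon_radius_mean, p.axon_radius_sd) / px
            radius = float(np.clip(radius, 0.3 * r_mean_px, r_cap))
            if not (-radius < r0 < nrow + radius and -radius < c0 < ncol + radius):
                continue
            _paint_disk(labels, r0, c0, radius, CLASS_MYELIN)
            _paint_disk(labels, r0, c0, radius * g, CLASS_IE)

    # --- lesions ---------------------------------------------------------
    n_lesions = int(round(p.lesion_density * p.area_mm2))
    d_dist = stats.truncnorm(
        -p.lesion_diameter_mean / p.lesion_diameter_sd,
        np.inf,
        loc=p.lesion_diameter_mean,
        scale=p.lesion_diameter_sd,
    )
    placed_diameters = []
    for i in range(n_lesions):
        diameter = float(d_dist.rvs(random_state=rng))
        rad_px = 0.5 * diameter / px
        for _ in range(p.max_attempts_per_lesion):
            r0 = rng.uniform(0, nrow)
            c0 = rng.uniform(0, ncol)
            if labels[int(r0), int(c0)] == CLASS_MYELIN:
                _paint_disk(labels, r0, c0, rad_px, CLASS_EDEMA)
                placed_diameters.append(diameter)
                break
        else:
            raise HistologyGenerationError(
                f"could not place lesion {i + 1}/{n_lesions} inside myelin",
                achieved_density=len(placed_diameters) / p.area_mm2,
            )

    labelmap = HistologyLabelMap(labels=labels, pixel_size=px)
    n_px = labels.size
    truth = {
        "v_my": float((labels == CLASS_MYELIN).sum()) / n_px,
        "v_ie": float((labels == CLASS_IE).sum()) / n_px,
        "v_ed": float((labels == CLASS_EDEMA).sum()) / n_px,
        "n_lesions_placed": float(len(placed_diameters)),
        "lesion_density_per_mm2": len(placed_diameters) / p.area_mm2,
        "mean_placed_diameter_um": float(np.mean(placed_diameters))
        if placed_diameters
        else 0.0,
    }

    # --- rendering -------------------------------------------------------
    intensity = np.zeros(4)
    intensity[CLASS_MYELIN] = p.intensity_myelin
    intensity[CLASS_IE] = p.intensity_ie
    intensity[CLASS_EDEMA] = p.intensity_edema
    img = intensity[labels]
    rr = np.linspace(-0.5, 0.5, nrow)[:, None]
    cc = np.linspace(-0.5, 0.5, ncol)[None, :]
    img = img + p.illumination_amplitude * (rr + cc)
    img = img + rng.normal(0.0, p.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0), labelmap, truth


# --------------------------------------------------------------------------
# whole-study generator
# --------------------------------------------------------------------------

TRACTS = ("dCST", "FG", "RST", "VST")
GROUPS = ("control", "HCP300", "HCP600")


def default_study_config() -> dict:
    """Default synthetic-study configuration (3 diet groups × 4 tracts).

    Tract-level edema load follows the observed lesion-density pattern
    (dCST > FG > RST > VST; higher dose > lower dose > control), scaled by
    an effective per-lesion edema area so that the top edema water
    fractions reach the ~0.75 / 0.25 non-myelin short/long split of the
    worked exchange example.  Myelin volume fractions differ modestly
    across tracts (thinner myelin in the dorsal tracts) and do not change
    with dose — intramyelinic edema forms at the expense of the
    intra/extra-axonal space.
    """
    return {
        "groups": list(GROUPS),
        "tracts": list(TRACTS),
        "n_animals": 8,
        "n_histology": 3,     # animals per group with histology, as in the study
        "echo_scheme": asdict(EchoScheme()),
        "n_inversion_times": 25,
        "ti_min_s": 0.0035,
        "ti_max_s": 10.0,
        "roi_snr": 1000.0,
        "voxel_snr": 150.0,
        "n_voxels": 48,
        "sir_snr": 500.0,
        "noise": "gaussian",  # ROI-mean decays: central-limit Gaussian noise
        "t2_ms": {"myelin": 15.0, "ie": 50.0, "edema": 300.0},
        "t1_s": {"myelin": 1.0, "ie": 1.8, "edema": 3.5},
        "edema_residence_s": 0.2,
        "v_my": {"dCST": 0.22, "FG": 0.24, "RST": 0.30, "VST": 0.28},
        "lesion_density_per_mm2": {
            "control": {t: 0.0 for t in TRACTS},
            "HCP300": {"dCST": 776.0, "FG": 469.0, "RST": 344.0, "VST": 142.0},
            "HCP600": {"dCST": 1651.0, "FG": 1291.0, "RST": 545.0, "VST": 497.0},
        },
        "edema_area_per_lesion_mm2": 8.2e-5,
        "rho": list(DEFAULT_RHO),
        "qmt": {
            "m0": 1.0,
            "psr_tract": {"dCST": 0.16, "FG": 0.17, "RST": 0.19, "VST": 0.18},
            "psr_group_scale": {"control": 1.0, "HCP300": 0.95, "HCP600": 0.88},
            "kmf": 12.0,
            "t1_tract_s": {"dCST": 1.5, "FG": 1.5, "RST": 1.45, "VST": 1.45},
            "t1_group_scale": {"control": 1.0, "HCP300": 1.04, "HCP600": 1.08},
            "sf": -0.95,
            "sm": 0.83,
        },
        "jitter": {"v_ed": 0.10, "v_my": 0.04, "psr": 0.04, "kmf": 0.06, "r1": 0.03},
        "histology": {
            "grid": [1200, 1600],
            "fov_um": [90.0, 120.0],
            "lesion_diameter_mean": 3.1,
            "lesion_diameter_sd": 0.4,
            "noise_sd": 0.05,
        },
    }


@dataclass(frozen=True)
class StudyTruth:
    """Ground truth of a generated study: per-ROI table, config and seed."""

    table: pd.DataFrame
    config: dict
    seed: int
    out_dir: Path | None = None


def _roi_system(cfg: dict, w_my: float, w_ie: float, w_ed: float) -> PoolSystem:
    """Pool system for a tract: water-content fractions with edema–ie exchange."""
    t2 = cfg["t2_ms"]
    t1 = cfg["t1_s"]
    if w_ed <= 0:
        f = np.array([w_my, w_ie]) / (w_my + w_ie)
        return PoolSystem(
            fractions=f,
            t2=np.array([t2["myelin"], t2["ie"]]) / 1e3,
            t1=np.array([t1["myelin"], t1["ie"]]),
        )
    f = np.array([w_my, w_ie, w_ed])
    f = f / f.sum()
    k = np.zeros((3, 3))
    k_ed_ie = 1.0 / cfg["edema_residence_s"]
    k[2, 1] = k_ed_ie
    k[1, 2] = k_ed_ie * f[2] / f[1]  # detailed balance
    return PoolSystem(
        fractions=f,
        t2=np.array([t2["myelin"], t2["ie"], t2["edema"]]) / 1e3,
        t1=np.array([t1["myelin"], t1["ie"], t1["edema"]]),
        k=k,
    )


def generate_study(
    config: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    *,
    overwrite: bool = False,
) -> StudyTruth:
    """Generate a full synthetic study and (optionally) write its bundle.

    For each (group, animal, tract) ROI the generator draws jittered
    tissue parameters, builds the exchanging pool system from the
    water-content fractions, and simulates the ROI-mean decay, a stack of
    voxel decays, and the SIR series.  For the first ``n_histology``
    animals of each group a histology field is rendered and the *achieved*
    label-map fractions replace the nominal ones, coupling the MRI and
    histology ground truths exactly as segmentation would see them.

    When ``out_dir`` is given the bundle is written as::

        out_dir/
          config.json            resolved configuration + seed
          truth_rois.csv         per-ROI ground truth
          decays/<id>_roi.csv    time_ms, signal
          decays/<id>_voxels.csv one row per voxel, columns = echo times
          sir/<id>.csv           time_s, signal
          histology/<id>.tif     rendered field (float32)
          histology/<id>_labels.tif
    """
    cfg = default_study_config()
    if config:
        _deep_update(cfg, config)
    rho = tuple(cfg["rho"])
    scheme = EchoScheme(**cfg["echo_scheme"])
    t_echo = scheme.times_s()
    t_inv = make_inversion_times(cfg["n_inversion_times"], cfg["ti_min_s"], cfg["ti_max_s"])
    lesion_area = cfg["edema_area_per_lesion_mm2"]

    writing = out_dir is not None
    if writing:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
            raise FileExistsError(f"{out_dir} exists and is not empty; pass overwrite=True")
        for sub in ("decays", "sir", "histology"):
            (out_dir / sub).mkdir(parents=True, exist_ok=True)

    rows = []
    for gi, group in enumerate(cfg["groups"]):
        for ai in range(cfg["n_animals"]):
            for ti, tract in enumerate(cfg["tracts"]):
                rng = np.random.default_rng([seed, gi, ai, ti])
                jit = cfg["jitter"]
                density = cfg["lesion_density_per_mm2"][group][tract]
                v_ed = density * lesion_area * max(
                    0.0, 1.0 + jit["v_ed"] * rng.standard_normal()
                )
                v_my = cfg["v_my"][tract] * (1.0 + jit["v_my"] * rng.standard_normal())
                v_ie = 1.0 - v_my - v_ed

                has_histology = ai < cfg["n_histology"]
                hist_density = v_ed / (
                    np.pi / 4.0
                    * (
                        cfg["histology"]["lesion_diameter_mean"] ** 2
                        + cfg["histology"]["lesion_diameter_sd"] ** 2
                    )
                    * 1e-6
                )
                lesion_stats = {}
                if has_histology:
                    hp = HistologyGenParams(
                        grid=tuple(cfg["histology"]["grid"]),
                        fov_um=tuple(cfg["histology"]["fov_um"]),
                        lesion_density=hist_density,
                        lesion_diameter_mean=cfg["histology"]["lesion_diameter_mean"],
                        lesion_diameter_sd=cfg["histology"]["lesion_diameter_sd"],
                        noise_sd=cfg["histology"]["noise_sd"],
                        myelin_thickness_fraction=_thickness_for_vmy(v_my, 0.50),
                    )
                    img, labelmap, truth = generate_histology_image(hp, rng)
                    v_my, v_ie, v_ed = truth["v_my"], truth["v_ie"], truth["v_ed"]
                    lesion_stats = {
                        "lesion_density_per_mm2": truth["lesion_density_per_mm2"],
                        "mean_lesion_diameter_um": truth["mean_placed_diameter_um"],
                    }
                    if writing:
                        rid = f"{group}_{ai:02d}_{tract}"
                        tifffile.imwrite(
                            out_dir / "histology" / f"{rid}.tif", img.astype(np.float32)
                        )
                        tifffile.imwrite(
                            out_dir / "histology" / f"{rid}_labels.tif", labelmap.labels
                        )

                wc = water_content((v_my, v_ie, v_ed), rho)
                system = _roi_system(cfg, *wc.wx)

                q = cfg["qmt"]
                psr = (
                    q["psr_tract"][tract]
                    * q["psr_group_scale"][group]
                    * (1.0 + jit["psr"] * rng.standard_normal())
                )
                t1 = q["t1_tract_s"][tract] * q["t1_group_scale"][group]
                r1 = 1.0 / t1 * (1.0 + jit["r1"] * rng.standard_normal())
                kmf = q["kmf"] * (1.0 + jit["kmf"] * rng.standard_normal())
                qparams = QMTParams(
                    m0=q["m0"], psr=max(psr, 0.0), kmf=max(kmf, 0.0), r1=r1,
                    sf=q["sf"], sm=q["sm"],
                )

                roi_decay = simulate_roi_decay(
                    system, t_echo, cfg["roi_snr"], rng, noise=cfg["noise"]
                )
                voxels = np.stack(
                    [
                        simulate_roi_decay(system, t_echo, cfg["voxel_snr"], rng)
                        for _ in range(cfg["n_voxels"])
                    ]
                )
                sir = simulate_sir_series(
                    qparams, t_inv, cfg["sir_snr"], rng, noise=cfg["noise"]
                )

                rid = f"{group}_{ai:02d}_{tract}"
                if writing:
                    pd.DataFrame(
                        {"time_ms": t_echo * 1e3, "signal": roi_decay}
                    ).to_csv(out_dir / "decays" / f"{rid}_roi.csv", index=False,
                             float_format="%.10g")
                    pd.DataFrame(
                        voxels, columns=[f"{t * 1e3:.10g}" for t in t_echo]
                    ).to_csv(out_dir / "decays" / f"{rid}_voxels.csv", index=False,
                             float_format="%.10g")
                    pd.DataFrame({"time_s": t_inv, "signal": sir}).to_csv(
                        out_dir / "sir" / f"{rid}.csv", index=False, float_format="%.10g"
                    )

                rows.append(
                    {
                        "group": group,
                        "animal": ai,
                        "tract": tract,
                        "roi_id": rid,
                        "histology": has_histology,
                        "v_my": v_my,
                        "v_ie": v_ie,
                        "v_ed": v_ed,
                        "w": wc.w,
                        "w_my": wc.w_my,
                        "w_ie": wc.w_ie,
                        "w_ed": wc.w_ed,
                        "t2_my_ms": cfg["t2_ms"]["myelin"],
                        "t2_ie_ms": cfg["t2_ms"]["ie"],
                        "t2_ed_ms": cfg["t2_ms"]["edema"],
                        "edema_residence_s": cfg["edema_residence_s"],
                        "psr": qparams.psr,
                        "kmf": qparams.kmf,
                        "r1": qparams.r1,
                        "t1_s": 1.0 / qparams.r1,
                        **lesion_stats,
                    }
                )

    table = pd.DataFrame(rows)
    if writing:
        table.to_csv(out_dir / "truth_rois.csv", index=False, float_format="%.10g")
        with open(out_dir / "config.json", "w") as fh:
            json.dump({"seed": seed, **cfg}, fh, indent=1)
    return StudyTruth(table=table, config=cfg, seed=seed,
                      out_dir=Path(out_dir) if writing else None)


def _thickness_for_vmy(v_my: float, packing: float) -> float:
    """Myelin annulus thickness fraction that targets a myelin volume fraction."""
    inner = 1.0 - min(max(v_my, 0.0) / packing, 0.95)
    return 1.0 - np.sqrt(inner)


def _deep_update(base: dict, upd: dict) -> None:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
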