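"""Study-level orchestration: per-ROI metric tables, group statistics and
MRI-vs-histology regressions.

``run_study`` consumes a data bundle (as produced by
:func:`imerelax.synthetic.generate_study`, or assembled from real data in
the same layout), runs the MET2 ladder, the SIR-qMT fit and the histology
quantification per (group, animal, tract) ROI, and emits a study table,
group comparisons with significance stars, and the
EWF–W_ed / MWF–W_my / PSR–V_my regressions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import histology as hq
from .met2 import (
    Met2Options,
    assign_t2_classes,
    cluster_t2_classes,
    compute_water_fractions,
    met2_ladder,
    voxelwise_uncertainty,
)
from .qmt import QMTFitOptions, fit_sir

__all__ = [
    "RegressionResult",
    "GroupComparison",
    "regress",
    "group_compare",
    "run_study",
    "StudyResult",
]


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary-least-squares line fit with r² and slope p-value."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample t-test between two groups of ROI values."""

    difference: float
    t: float
    p: float
    significant: bool


def regress(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS regression of y on x; r² = 1 − SSE/SST, two-sided p on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def group_compare(
    values_a: np.ndarray, values_b: np.ndarray, alpha: float = 0.05
) -> GroupComparison:
    """Welch (unequal-variance) t-test; degenerate zero-variance data give
    p = 1 when the means agree and p = 0 otherwise."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    diff = float(a.mean() - b.mean())
    if a.std() == 0.0 and b.std() == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
        return GroupComparison(difference=diff, t=0.0, p=p, significant=p < alpha)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        difference=diff, t=float(t), p=float(p), significant=bool(p < alpha)
    )


@dataclass(frozen=True)
class StudyResult:
    """Outputs of a study run: per-ROI table, group stats, regressions."""

    table: pd.DataFrame
    group_stats: pd.DataFrame
    regressions: dict[str, RegressionResult]


def _histology_from_image(path_img: Path, pixel_size: float) -> dict:
    import tifffile

    img = np.asarray(tifffile.imread(path_img), dtype=float)
    pre = hq.preprocess_image(img)
    seeds = hq.auto_seeds(pre, 3)
    labelmap = hq.segment_regions(pre, seeds, pixel_size=pixel_size)
    v = hq.volume_fractions(labelmap)
    wc = hq.water_content(v)
    lesions = hq.lesion_metrics(labelmap)
    return {
        "v_my": v[0], "v_ie": v[1], "v_ed": v[2],
        "w": wc.w, "w_my": wc.w_my, "w_ie": wc.w_ie, "w_ed": wc.w_ed,
        "lesion_density_per_mm2": lesions.density_per_mm2,
        "mean_lesion_diameter_um": lesions.mean_diameter_um,
    }


def run_study(config: dict) -> StudyResult:
    """Run the full analysis over a study bundle.

    Config keys
    -----------
    bundle : path to the bundle directory (required).
    out : optional output directory for the CSV reports.
    histology : ``'truth'`` (use the bundle's ground-truth table, the
        default when one is present), ``'segment'`` (re-segment the
        histology images) or ``'none'``.
    alpha : significance level of the group comparisons (default 0.05).
    holm : apply a Holm correction across the group comparisons
        (default False; raw P values, starred at alpha).
    voxelwise : compute intra-ROI standard errors from the voxel stacks
        (default True).
    seed : seed of the jittered multi-start fits (default 0).
    """
    bundle = Path(config["bundle"])
    alpha = float(config.get("alpha", 0.05))
    seed = int(config.get("seed", 0))
    voxelwise = bool(config.get("voxelwise", True))
    truth_path = bundle / "truth_rois.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    hist_mode = config.get("histology", "truth" if truth is not None else "segment")

    with open(bundle / "config.json") as fh:
        bundle_cfg = json.load(fh)

    roi_ids = sorted(p.name[: -len("_roi.csv")] for p in (bundle / "decays").glob("*_roi.csv"))
    if not roi_ids:
        raise FileNotFoundError(f"no decay files under {bundle / 'decays'}")

    opts = Met2Options(seed=seed)
    fits = {}
    warnings: list[str] = []
    for rid in roi_ids:
        d = pd.read_csv(bundle / "decays" / f"{rid}_roi.csv")
        t = d["time_ms"].to_numpy() / 1e3
        ladder, n_sel = met2_ladder(d["signal"].to_numpy(), t, opts, alpha)
        fits[rid] = {"times": t, "ladder": ladder, "n": n_sel}

    # pool component T2s across the whole study and cluster into classes;
    # a T2 class must be supported by more than a token number of ROIs
    # (one spurious 3-component fit must not create a long class)
    pooled = np.concatenate([fits[r]["ladder"][fits[r]["n"]].t2s_s for r in roi_ids])
    n_sel = np.array([fits[r]["n"] for r in roi_ids])
    k = 1
    for m in (2, 3):
        if np.mean(n_sel >= m) > 0.1:
            k = m
    k = min(k, np.unique(pooled).size)
    _, class_centers = cluster_t2_classes(pooled, k)

    rows = []
    for rid in roi_ids:
        group, animal, tract = rid.rsplit("_", 2)[0], *rid.rsplit("_", 2)[1:]
        fit = fits[rid]["ladder"][fits[rid]["n"]]
        labels = assign_t2_classes(fit.t2s_s, class_centers)
        wf = compute_water_fractions(fit, labels)
        row = {
            "group": group,
            "animal": int(animal),
            "tract": tract,
            "roi_id": rid,
            "n_components": fits[rid]["n"],
            "mwf": wf.mwf,
            "ewf": wf.ewf,
            "met2_chi2": fit.chi2,
        }

        vox_path = bundle / "decays" / f"{rid}_voxels.csv"
        if voxelwise and vox_path.exists():
            vox = pd.read_csv(vox_path).to_numpy()
            try:
                unc = voxelwise_uncertainty(
                    vox, fits[rid]["times"], fits[rid]["n"], class_centers, opts,
                    warm_starts=[np.log10(fit.t2s_s)],
                )
                row["se_mwf"] = unc["se_mwf"]
                row["se_ewf"] = unc["se_ewf"]
            except Exception as exc:  # pragma: no cover - diagnostic path
                warnings.append(f"{rid}: voxelwise SE failed ({exc})")

        sir_path = bundle / "sir" / f"{rid}.csv"
        if sir_path.exists():
            s = pd.read_csv(sir_path)
            res = fit_sir(s["signal"].to_numpy(), s["time_s"].to_numpy(),
                          QMTFitOptions(sm=bundle_cfg.get("qmt", {}).get("sm", 0.83)))
            row.update(
                psr=res.params.psr, kmf=res.params.kmf, t1_s=res.params.t1,
                se_psr=res.std_errors["psr"], se_kmf=res.std_errors["kmf"],
                qmt_converged=res.converged,
            )
        else:
            warnings.append(f"{rid}: no SIR series")

        if hist_mode == "truth" and truth is not None:
            tr = truth[truth["roi_id"] == rid]
            if len(tr) == 1 and bool(tr["histology"].iloc[0]):
                row.update({c: float(tr[c].iloc[0])
                            for c in ("v_my", "v_ie", "v_ed", "w", "w_my", "w_ie", "w_ed")})
        elif hist_mode == "segment":
            img_path = bundle / "histology" / f"{rid}.tif"
            if img_path.exists():
                px = bundle_cfg["histology"]["fov_um"][1] / bundle_cfg["histology"]["grid"][1]
                row.update(_histology_from_image(img_path, px))
        rows.append(row)

    table = pd.DataFrame(rows)

    # group comparisons per tract and metric, each HCP group vs control
    metrics = [m for m in ("mwf", "ewf", "psr", "kmf", "t1_s") if m in table]
    groups = list(dict.fromkeys(table["group"]))
    control = "control" if "control" in groups else groups[0]
    raw = []
    for tract in dict.fromkeys(table["tract"]):
        sub = table[table["tract"] == tract]
        for metric in metrics:
            for grp in groups:
                if grp == control:
                    continue
                a = sub.loc[sub["group"] == grp, metric].dropna().to_numpy()
                b = sub.loc[sub["group"] == control, metric].dropna().to_numpy()
                if a.size < 2 or b.size < 2:
                    continue
                cmp_ = group_compare(a, b, alpha)
                raw.append({
                    "tract": tract, "metric": metric, "group": grp,
                    "reference": control, "difference": cmp_.difference,
                    "t": cmp_.t, "p": cmp_.p,
                })
    group_stats = pd.DataFrame(raw)
    if not group_stats.empty:
        if config.get("holm", False):
            order = np.argsort(group_stats["p"].to_numpy())
            m = len(order)
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * group_stats["p"].iloc[idx])
                adj[idx] = min(running, 1.0)
            group_stats["p_adj"] = adj
            group_stats["significant"] = group_stats["p_adj"] < alpha
        else:
            group_stats["significant"] = group_stats["p"] < alpha

    regressions: dict[str, RegressionResult] = {}
    pairs = [("ewf", "w_ed"), ("mwf", "w_my"), ("psr", "v_my")]
    for ycol, xcol in pairs:
        if ycol in table and xcol in table:
            sub = table[[xcol, ycol]].dropna()
            if len(sub) >= 3 and np.ptp(sub[xcol].to_numpy()) > 0:
                regressions[f"{ycol}_vs_{xcol}"] = regress(
                    sub[xcol].to_numpy(), sub[ycol].to_numpy()
                )

    out = config.get("out")
    if out:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "study_table.csv", index=False, float_format="%.10g")
        group_stats.to_csv(out / "group_stats.csv", index=False, float_format="%.10g")
        pd.DataFrame(
            [{"pair": k, **r.__dict__} for k, r in regressions.items()]
        ).to_csv(out / "regressions.csv", index=False, float_format="%.10g")
        if warnings:
            (out / "warnings.txt").write_text("\n".join(warnings) + "\n")

    return StudyResult(table=table, group_stats=group_stats, regressions=regressions)
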