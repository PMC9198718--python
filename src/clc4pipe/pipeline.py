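"""End-to-end orchestration: simulate -> process -> metrics -> statistics.

``analyze_recording``/``analyze_cohort`` run the electrophysiology chain (P/8
subtraction, steady-state currents, Q_off integration, per-cell Boltzmann fit,
Q_off/current ratio); ``variant_summary`` aggregates per-variant statistics
including the current-fluorescence slope factor; ``run_pipeline`` drives all
stages from a config mapping and writes tidy CSV/JSON outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import metrics as tm
from . import traces
from .images import ImageSynthSpec, calibrate_overlap_prob, synth_image_pair
from .coloc import manders_overlap, threshold_channels
from .gels import GelBand, GelLaneSpec, synth_gel_lane
from .densitometry import glycosylation_fraction, heterodimer_fraction, quantify_roi
from .protocol import ProtocolSpec
from .recording import CohortDataset, Recording
from .simulate import CellPassiveSpec, simulate_cohort
from .stats import compare_groups
from .variants import VariantConfig, chimera_variants, full_length_variants

logger = logging.getLogger("clc4pipe")

__all__ = [
    "analyze_recording", "analyze_cohort", "variant_summary",
    "default_config", "run_pipeline",
]

I_NOISE_FLOOR_NA = 0.05  # currents below this are "at background"


def analyze_recording(
    rec: Recording,
    ref_prepulse: Optional[float] = None,
    subtract: bool = True,
) -> dict:
    """Full single-cell analysis; returns one tidy row of metrics.

    Flags (``fit_converged``, ``rho_defined``) propagate undefined quantities
    as NaN rather than zeros.
    """
    protocol = rec.protocol
    sub = traces.p8_subtract(rec) if (subtract and rec.p8_sweeps is not None) \
        else rec
    iv = traces.build_iv(sub)
    v = np.array([p.v for p in iv])
    i_ss = np.array([p.i_ss for p in iv])
    q_off = np.array([p.q_off for p in iv])

    if ref_prepulse is None:
        ref_prepulse = float(rec.meta.get("ref_prepulse", 135.0))
    fit = tm.fit_boltzmann(v, q_off, v_ref=protocol.holding)

    iref = int(np.argmin(np.abs(v - ref_prepulse)))
    rho = tm.qoff_current_ratio(q_off[iref], i_ss[iref], v_ref=float(v[iref]),
                                i_threshold=I_NOISE_FLOOR_NA)
    row = {
        "cell_id": rec.meta.get("cell_id", ""),
        "variant": rec.meta.get("variant", "unknown"),
        "fluorescence": rec.fluorescence,
        "i_ss_max_v": float(i_ss[-1]),          # at the most positive step
        "v_max": float(v[-1]),
        "q_off_ref": float(q_off[iref]),
        "i_ss_ref": float(i_ss[iref]),
        "ref_prepulse": float(v[iref]),
        "rho": rho.value,
        "rho_defined": rho.defined,
        "v_half": fit.v_half if fit.converged else np.nan,
        "k": fit.k if fit.converged else np.nan,
        "q_max": fit.q_max if fit.converged else np.nan,
        "fit_converged": fit.converged,
        "fit_residual": fit.residual_norm,
    }
    # Cells with no measurable transport have meaningless activation fits.
    if abs(row["i_ss_max_v"]) < I_NOISE_FLOOR_NA:
        row.update({"v_half": np.nan, "k": np.nan, "q_max": np.nan,
                    "fit_converged": False})
    return row


def analyze_cohort(cohort: CohortDataset, subtract: bool = True) -> pd.DataFrame:
    """Per-cell metrics table for a cohort."""
    rows = [analyze_recording(rec, subtract=subtract)
            for rec in cohort.recordings]
    return pd.DataFrame(rows)


def variant_summary(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-variant summary: mean +/- sem of V0.5 and rho, slope factor."""
    out = []
    for variant, sub in cells.groupby("variant", sort=True):
        row = {"variant": variant, "n_cells": len(sub)}
        for col in ("v_half", "k", "rho"):
            vals = sub[col].dropna()
            row[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{col}_sem"] = (vals.std(ddof=1) / np.sqrt(len(vals))
                                 if len(vals) > 1 else np.nan)
            row[f"{col}_n"] = len(vals)
        try:
            slope = tm.fluorescence_slope(sub["fluorescence"],
                                          sub["i_ss_max_v"])
            row["slope_factor"] = slope.slope
            row["slope_stderr"] = slope.stderr
        except ValueError:
            row["slope_factor"] = np.nan
            row["slope_stderr"] = np.nan
        out.append(row)
    return pd.DataFrame(out)


def transport_activity_table(
    cohort: CohortDataset, cells: pd.DataFrame
) -> pd.DataFrame:
    """Per-variant transport-activity curves (mean over cells).

    For each cell with a converged fit and a defined rho, the normalized Q-V
    curve is divided by the cell's rho; curves are then averaged per variant.
    """
    rows = []
    by_id = cells.set_index("cell_id")
    for rec in cohort.recordings:
        cid = rec.meta.get("cell_id", "")
        if cid not in by_id.index:
            continue
        info = by_id.loc[cid]
        if not (info["fit_converged"] and info["rho_defined"]):
            continue
        sub = traces.p8_subtract(rec) if rec.p8_sweeps is not None else rec
        iv = traces.build_iv(sub)
        v = np.array([p.v for p in iv])
        q = np.array([p.q_off for p in iv])
        norm_q = q / info["q_max"]
        ta = tm.transport_activity(norm_q, float(info["rho"]))
        for vv, t in zip(v, ta):
            rows.append({"variant": info["variant"], "cell_id": cid,
                         "v": vv, "transport_activity": t})
    if not rows:
        return pd.DataFrame(columns=["variant", "v", "transport_activity"])
    df = pd.DataFrame(rows)
    return (df.groupby(["variant", "v"])["transport_activity"]
            .agg(["mean", "sem", "count"]).reset_index())


# ----------------------------------------------------------------- pipeline
def default_config() -> dict:
    """Bundled configuration: the 13-construct design (WT + 12 variants)."""
    n_cells = {
        "WT": 19, "D15N": 19, "G78S": 10, "V212G": 10, "L221P": 12,
        "L221V": 12, "V275M": 15, "S534L": 7, "V536M": 12, "G544R": 10,
        "A555V": 15, "R718W": 12, "G731R": 11,
    }
    return {
        "simulate": {"variants": "full_length", "n_cells": n_cells},
        "ephys": {},
        "coloc": {"n_images": 11, "target_overlap": 0.83},
        "gel": {
            "roi_kda": [80, 140],
            "bands": [
                {"label": "nonglycosylated", "mw_kda": 100, "area": 75.0},
                {"label": "glycosylated", "mw_kda": 120, "area": 25.0},
            ],
        },
        "stats": {"metrics": ["v_half", "rho", "i_ss_max_v"],
                  "reference": "WT"},
    }


def _resolve_variants(spec) -> list[VariantConfig]:
    if spec == "full_length":
        return list(full_length_variants().values())
    if spec == "chimera":
        return list(chimera_variants().values())
    out = []
    for item in spec:
        if isinstance(item, str):
            from .variants import get_variant
            out.append(get_variant(item))
        elif isinstance(item, VariantConfig):
            out.append(item)
        else:
            out.append(VariantConfig(**item))
    return out


def run_pipeline(config: dict, seed: int = 0, out_dir=None) -> dict:
    """Execute the configured stages; fully deterministic given config+seed.

    Returns a dict of in-memory results; when ``out_dir`` is given also writes
    per-cell and per-variant CSVs, a JSON report, and a log of seeds used.
    Stages are independent: a config with only ``coloc`` runs only that stage.
    """
    results: dict = {"seed": seed}
    ss = np.random.SeedSequence(seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(("simulate", "coloc", "gel"),
                                      ss.spawn(3))}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    cohort = None
    if "simulate" in config:
        sim = config["simulate"]
        variants = _resolve_variants(sim.get("variants", "full_length"))
        protocol = ProtocolSpec(**sim.get("protocol", {}))
        passive = CellPassiveSpec(**sim.get("passive", {}))
        n_cells = sim.get("n_cells", 5)
        if isinstance(n_cells, dict):
            parts = []
            for i, v in enumerate(variants):
                n = int(n_cells.get(v.name, 0))
                if n > 0:
                    parts.append(simulate_cohort(
                        [v], n, protocol, passive,
                        seed=stage_seeds["simulate"] + i))
            cohort = CohortDataset(
                recordings=[r for p in parts for r in p.recordings],
                manifest=pd.concat([p.manifest for p in parts],
                                   ignore_index=True))
        else:
            cohort = simulate_cohort(variants, int(n_cells), protocol,
                                     passive, seed=stage_seeds["simulate"])
        results["cohort"] = cohort
        if out_dir is not None:
            cohort.manifest.to_csv(out_dir / "manifest.csv", index=False)

    if "ephys" in config and cohort is not None:
        cells = analyze_cohort(cohort)
        summary = variant_summary(cells)
        ta = transport_activity_table(cohort, cells)
        results["cells"] = cells
        results["variants"] = summary
        results["transport_activity"] = ta
        if out_dir is not None:
            cells.to_csv(out_dir / "cells.csv", index=False)
            summary.to_csv(out_dir / "variants.csv", index=False)
            ta.to_csv(out_dir / "transport_activity.csv", index=False)

    if "coloc" in config:
        cc = config["coloc"]
        spec = ImageSynthSpec(**cc.get("image_spec", {}))
        target = cc.get("target_overlap")
        if target is not None:
            p = calibrate_overlap_prob(float(target), spec,
                                       seed=stage_seeds["coloc"])
            spec = replace(spec, overlap_prob=p)
        n_images = int(cc.get("n_images", 11))
        rows = []
        children = np.random.SeedSequence(stage_seeds["coloc"]).spawn(n_images)
        for i, child in enumerate(children):
            pair = synth_image_pair(spec, seed=child)
            t1, t2, masks = threshold_channels(pair)
            res = manders_overlap(pair, masks, thresholds=(t1, t2))
            rows.append({"image": i, "overlap_coefficient":
                         res.overlap_coefficient, "m1": res.m1, "m2": res.m2,
                         "t1": t1, "t2": t2})
        coloc_df = pd.DataFrame(rows)
        results["coloc"] = coloc_df
        results["coloc_overlap_prob"] = spec.overlap_prob
        if out_dir is not None:
            coloc_df.to_csv(out_dir / "coloc.csv", index=False)

    if "gel" in config:
        gc = config["gel"]
        bands = tuple(GelBand(**b) if isinstance(b, dict) else GelBand(*b)
                      for b in gc.get("bands", ()))
        lane_spec = GelLaneSpec(bands=bands,
                                noise_sd=float(gc.get("noise_sd", 0.5)))
        lane = synth_gel_lane(lane_spec, seed=stage_seeds["gel"])
        lo, hi = gc.get("roi_kda", (80, 140))
        areas = quantify_roi(lane, lo, hi, bands=bands)
        gel_result = {"areas": {k: float(v) for k, v in areas.items()}}
        glyc = {b.label for b in bands if "glyc" in b.label
                and "non" not in b.label}
        nong = {b.label for b in bands if "nonglyc" in b.label}
        if glyc and nong:
            frac = glycosylation_fraction(
                sum(areas[l] for l in glyc), sum(areas[l] for l in nong))
            gel_result["glycosylated_fraction"] = frac.fraction
        if any("hetero" in b.label for b in bands):
            frac = heterodimer_fraction(
                {k: v for k, v in areas.items() if k != "total"})
            gel_result["heterodimer_fraction"] = frac.fraction
        results["gel"] = gel_result
        if out_dir is not None:
            (out_dir / "gel.json").write_text(json.dumps(gel_result, indent=1))

    if "stats" in config and "cells" in results:
        sc = config["stats"]
        reference = sc.get("reference", "WT")
        stats_out = {}
        for metric in sc.get("metrics", ["v_half"]):
            groups = {v: sub[metric].to_numpy()
                      for v, sub in results["cells"].groupby("variant")}
            groups = {g: vals for g, vals in groups.items()
                      if np.isfinite(vals).sum() >= 3}
            if reference not in groups or len(groups) < 2:
                continue
            cmp_res = compare_groups(groups, reference=reference,
                                     metric=metric)
            stats_out[metric] = {
                "method": cmp_res.method,
                "levene_p": cmp_res.levene_p,
                "anova_f": cmp_res.anova_f,
                "anova_p": cmp_res.anova_p,
                "comparisons": [c.__dict__ for c in cmp_res.comparisons],
            }
            logger.info("stats gate for %s: %s", metric, cmp_res.method)
        results["stats"] = stats_out
        if out_dir is not None:
            (out_dir / "stats.json").write_text(json.dumps(stats_out, indent=1))

    if out_dir is not None:
        report = {
            "seed": seed,
            "stage_seeds": stage_seeds,
            "stages_run": [k for k in ("simulate", "ephys", "coloc", "gel",
                                       "stats") if k in config],
        }
        if "variants" in results:
            report["variant_summary"] = json.loads(
                results["variants"].to_json(orient="records"))
        if "coloc" in results:
            report["coloc_mean_overlap"] = float(
                results["coloc"]["overlap_coefficient"].mean())
        if "gel" in results:
            report["gel"] = results["gel"]
        (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    return results
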