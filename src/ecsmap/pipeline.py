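"""End-to-end orchestration: simulate -> filter -> diffusion -> shape ->
orientation -> width -> report, driven by one declarative YAML configuration.

Every stage writes its tables before the next starts; identical configs (all
seeds are explicit) produce byte-identical outputs.  The run report records
per-stage row counts, filter counts, test results, the configuration hash and
the tool version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import SegmentSet, TrajectorySet
from .diffusion import (
    compare_groups,
    compute_msd,
    confinement_by_recording,
    fit_diffusion_coefficient,
    percent_change_confinement,
)
from .io import filter_trajectories, write_image, write_results, write_trajectories
from .orientation import fit_orientation_models, orientation_histogram, select_model
from .shape import PolylineSegmentCV, classify_shape, extract_segments, fit_ellipse
from .synthetic import (
    DomainSpec,
    ImageSpec,
    SimulationConfig,
    generate_ecs_image,
    simulate_cohort,
)
from .width import compare_width_samples, measure_peak_widths, sample_line_profiles

__all__ = ["validate_config", "load_config", "save_config", "make_demo", "run_pipeline"]

logger = logging.getLogger(__name__)

_REQUIRED_TOP = ("seed", "output_dir", "dt", "regions", "conditions", "simulate")


def validate_config(cfg: dict) -> dict:
    """Check the declarative run configuration; returns it unchanged."""
    missing = [k for k in _REQUIRED_TOP if k not in cfg]
    if missing:
        raise ValueError(f"config missing required keys: {missing}")
    if not isinstance(cfg["seed"], int):
        raise ValueError("config seed must be an explicit integer")
    if cfg["dt"] <= 0:
        raise ValueError("dt must be positive")
    if not cfg["regions"]:
        raise ValueError("at least one region required")
    for name, reg in cfg["regions"].items():
        DomainSpec(**reg["domain"])  # raises on invalid geometry
        if "image" in reg:
            spec = dict(reg["image"])
            spec["shape_px"] = tuple(spec.get("shape_px", (512, 512)))
            ImageSpec(**spec)
        if reg.get("digestion_scale", 1.0) <= 0:
            raise ValueError(f"region {name!r}: digestion_scale must be positive")
    sim = cfg["simulate"]
    for key in ("n_recordings", "n_tracks", "n_frames"):
        if sim.get(key, 0) < 1:
            raise ValueError(f"simulate.{key} must be >= 1")
    return cfg


def load_config(path: str | Path) -> dict:
    return validate_config(yaml.safe_load(Path(path).read_text()))


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:16]


def make_demo(cfg_out_path: str | Path | None = None, output_dir: str = "ecsmap_demo_out") -> dict:
    """Write a self-contained demo configuration emulating the study design.

    Two regions x two conditions: "CA1-like" wide oriented channels vs
    "CA3-like" narrow domains with a dead-end stub; the "hyaluronidase"
    condition scales the CA3-like domain by sqrt(3) (tripling its confinement
    area) and the CA1-like domain only mildly, reproducing the
    region-dependent response to matrix digestion.
    """
    cfg = {
        "seed": 20260925,
        "output_dir": str(output_dir),
        "dt": 0.03,
        "conditions": ["control", "hyaluronidase"],
        "simulate": {
            "n_recordings": 4,
            "n_tracks": 8,
            "n_frames": 250,
            "d_free": 0.05,
            "sigma_loc": 0.02,
            "detection_prob": 0.97,
        },
        "filter": {"min_points": 12},
        "diffusion": {"n_fit": 4, "plateau": [0.8, 1.0]},
        "shape": {
            "k_max": 3,
            "cv_repeats": 2,
            "penalty": None,
            "min_cloud_points": 30,
            "max_areas": 6,
        },
        "orientation": {"bins": 18, "em_starts": 4},
        "width": {"n_lines": 6, "margin": 10},
        "regions": {
            "CA1-like": {
                "domain": {
                    "shape": "polyline_channel",
                    "centerline": [[0.0, 0.0], [1.73, 1.0]],
                    "channel_width": 0.4,
                },
                "digestion_scale": 1.1,
                "image": {
                    "geometry": "cell_mosaic",
                    "gap_law": "lognormal",
                    "gap_median_nm": 450.0,
                    "gap_sigma": 0.3,
                    "shape_px": [512, 512],
                },
            },
            "CA3-like": {
                "domain": {
                    # small enough to decorrelate well within the 0.8-1 s
                    # plateau window even after sqrt(3) scaling
                    "shape": "polyline_channel",
                    "centerline": [[0.0, 0.0], [0.32, 0.0]],
                    "channel_width": 0.24,
                    "dead_ends": [[[0.16, 0.0], [0.16, 0.2]]],
                },
                "digestion_scale": math.sqrt(3.0),
                "image": {
                    "geometry": "cell_mosaic",
                    "gap_law": "lognormal",
                    "gap_median_nm": 300.0,
                    "gap_sigma": 0.3,
                    "shape_px": [512, 512],
                },
            },
        },
    }
    validate_config(cfg)
    if cfg_out_path is not None:
        save_config(cfg, cfg_out_path)
    return cfg


def _domain_from_cfg(dom: dict) -> DomainSpec:
    dom = dict(dom)
    if "centerline" in dom and dom["centerline"] is not None:
        dom["centerline"] = tuple(tuple(p) for p in dom["centerline"])
    if "dead_ends" in dom and dom["dead_ends"]:
        dom["dead_ends"] = tuple(tuple(tuple(p) for p in stub) for stub in dom["dead_ends"])
    return DomainSpec(**dom)


def _simulate_stage(cfg: dict, out: Path, seeds: np.random.SeedSequence) -> dict:
    sim = cfg["simulate"]
    sets: dict[tuple[str, str], TrajectorySet] = {}
    images: dict[tuple[str, str], object] = {}
    children = iter(seeds.spawn(len(cfg["regions"]) * len(cfg["conditions"]) * 2))
    for region, reg in cfg["regions"].items():
        domain = _domain_from_cfg(reg["domain"])
        for condition in cfg["conditions"]:
            scale = reg.get("digestion_scale", 1.0) if condition != "control" else 1.0
            traj_seed = int(next(children).generate_state(1)[0] % (2**31))
            img_seed = int(next(children).generate_state(1)[0] % (2**31))
            rec_sets = []
            for r in range(sim["n_recordings"]):
                rec_sets.append(
                    simulate_cohort(
                        domain,
                        SimulationConfig(
                            d_free=sim["d_free"],
                            dt=cfg["dt"],
                            n_frames=sim["n_frames"],
                            sigma_loc=sim["sigma_loc"],
                            detection_prob=sim.get("detection_prob", 1.0),
                            seed=traj_seed + r,
                        ),
                        sim["n_tracks"],
                        scale=scale,
                        recording=f"{region}-{condition}-rec{r:02d}",
                        region=region,
                        condition=condition,
                    )
                )
            merged = TrajectorySet(
                [t for s in rec_sets for t in s],
                dt=cfg["dt"],
                metadata=rec_sets[0].metadata,
            )
            sets[(region, condition)] = merged
            stem = f"tracks_{region}_{condition}".replace(" ", "_")
            write_trajectories(merged, out / f"{stem}.csv")
            truth = {
                "region": region,
                "condition": condition,
                "scale": scale,
                "analytic_plateau_um2": merged.metadata["analytic_plateau_um2"],
                "domain": reg["domain"],
            }
            (out / f"{stem}.truth.json").write_text(json.dumps(truth, indent=1))
            if "image" in reg:
                spec = dict(reg["image"])
                spec["shape_px"] = tuple(spec.get("shape_px", (512, 512)))
                gen = generate_ecs_image(ImageSpec(**spec, seed=img_seed))
                images[(region, condition)] = gen
                img_stem = f"ecs_{region}_{condition}".replace(" ", "_")
                write_image(gen.image, out / f"{img_stem}.tif")
                (out / f"{img_stem}.truth.json").write_text(
                    json.dumps({"gap_widths_nm": gen.gap_widths_nm.tolist()})
                )
    return {"sets": sets, "images": images}


def _diffusion_stage(cfg: dict, out: Path, sets: dict, report: dict) -> dict:
    plateau = tuple(cfg.get("diffusion", {}).get("plateau", (0.8, 1.0)))
    n_fit = cfg.get("diffusion", {}).get("n_fit", 4)
    d_rows, conf_rows, pct_rows = [], [], []
    conf_by_region: dict[str, dict[str, list]] = {}
    for (region, condition), ts in sets.items():
        for t in ts:
            if t.n_points < n_fit + 1:
                continue
            est = fit_diffusion_coefficient(compute_msd(t, ts.dt, n_fit + 2), n_fit)
            d_rows.append(
                {
                    "recording": t.recording,
                    "track": t.track_id,
                    "region": region,
                    "condition": condition,
                    "n_points": t.n_points,
                    "D_um2_per_s": est.d,
                    "intercept_um2": est.intercept,
                    "negative_slope": est.negative_slope,
                }
            )
        records = confinement_by_recording(ts, plateau)
        conf_by_region.setdefault(region, {})[condition] = records
        for r in records:
            conf_rows.append(asdict(r))
    test_results = {}
    for region, by_cond in conf_by_region.items():
        conds = list(by_cond)
        if len(conds) == 2:
            treated = by_cond[[c for c in conds if c != "control"][0]]
            control = by_cond["control"]
            pct = percent_change_confinement(treated, control)
            for v, (tr, ur) in zip(pct.values, pct.pairs):
                pct_rows.append(
                    {"region": region, "treated": tr, "untreated": ur, "percent_change": v}
                )
            rep = compare_groups(
                {c: np.array([r.area_um2 for r in by_cond[c]]) for c in conds},
                design="two_group",
            )
            test_results[region] = {
                "percent_change_median": pct.median,
                "percent_change_iqr": pct.iqr,
                "mann_whitney_U": rep.statistic,
                "p_value": rep.pvalue,
            }
    write_results(pd.DataFrame(d_rows), out / "diffusion_per_track.csv")
    write_results(pd.DataFrame(conf_rows), out / "confinement_per_recording.csv")
    write_results(pd.DataFrame(pct_rows), out / "percent_change.csv")
    report["diffusion"] = {
        "n_tracks_fitted": len(d_rows),
        "n_recordings": len(conf_rows),
        "tests": test_results,
    }
    return {"conf_by_region": conf_by_region}


def _shape_stage(cfg: dict, out: Path, sets: dict, seeds, report: dict) -> dict:
    sh = cfg.get("shape", {})
    k_max = sh.get("k_max", 4)
    repeats = sh.get("cv_repeats", 2)
    min_pts = sh.get("min_cloud_points", 30)
    max_areas = sh.get("max_areas", 6)
    rows = []
    segments: dict[tuple[str, str], list[SegmentSet]] = {}
    fit_seed = int(seeds.generate_state(1)[0] % (2**31))
    for (region, condition), ts in sorted(sets.items()):
        n_done = 0
        for t in ts:
            if t.n_points < min_pts or n_done >= max_areas:
                continue
            n_done += 1
            area_id = f"{t.recording}/{t.track_id}"
            ellipse = fit_ellipse(t.positions)
            klass = classify_shape(ellipse)
            row = {
                "area": area_id,
                "region": region,
                "condition": condition,
                "n_points": t.n_points,
                "axis_ratio": ellipse.ratio,
                "orientation": ellipse.orientation,
                "class": klass.label,
                "k": 0,
                "segment_length_um": 0.0,
                "total_length_um": 0.0,
            }
            if klass.label == "1D" and t.n_points >= 8:
                cv = PolylineSegmentCV(
                    k_min=1,
                    k_max=k_max,
                    penalty=sh.get("penalty"),
                    n_repeats=repeats,
                    random_state=fit_seed + n_done,
                ).fit(t.positions)
                fit = cv.to_result()
                segs = extract_segments(fit, owner=area_id)
                segments.setdefault((region, condition), []).append(segs)
                row.update(
                    k=fit.k,
                    segment_length_um=fit.segment_length,
                    total_length_um=fit.total_length,
                )
            rows.append(row)
    write_results(pd.DataFrame(rows), out / "shape_per_area.csv")
    n_1d = sum(1 for r in rows if r["class"] == "1D")
    report["shape"] = {"n_areas": len(rows), "n_1d": n_1d, "n_0d": len(rows) - n_1d}
    return {"segments": segments, "rows": rows}


def _orientation_stage(cfg: dict, out: Path, segments: dict, report: dict) -> None:
    ori = cfg.get("orientation", {})
    bins = ori.get("bins", 18)
    em_starts = ori.get("em_starts", 4)
    area_rows, pooled_rows, hist_rows = [], [], []
    for (region, condition), seg_sets in sorted(segments.items()):
        for segs in seg_sets:
            fits = fit_orientation_models(segs, em_starts=em_starts)
            best = select_model(fits)
            area_rows.append(
                {
                    "area": segs.owner,
                    "region": region,
                    "condition": condition,
                    "n_segments": segs.n,
                    "model": best.model,
                    "mu": best.mu,
                    "kappa1": best.kappa1,
                    "kappa2": best.kappa2,
                    "weight": best.weight,
                    **{f"aic_{f.model}": f.aic for f in fits},
                }
            )
        pooled = SegmentSet.concatenate(seg_sets, owner=f"{region}/{condition}")
        if pooled.n >= 2:
            fits = fit_orientation_models(pooled, em_starts=em_starts)
            best = select_model(fits)
            pooled_rows.append(
                {
                    "region": region,
                    "condition": condition,
                    "n_segments": pooled.n,
                    "model": best.model,
                    "mu": best.mu,
                    **{f"aic_{f.model}": f.aic for f in fits},
                }
            )
            edges, mass = orientation_histogram(pooled, n_bins=bins)
            for lo, hi, m in zip(edges[:-1], edges[1:], mass):
                hist_rows.append(
                    {"region": region, "condition": condition,
                     "bin_lo": lo, "bin_hi": hi, "mass_um": m}
                )
    write_results(pd.DataFrame(area_rows), out / "orientation_per_area.csv")
    write_results(pd.DataFrame(pooled_rows), out / "orientation_pooled.csv")
    write_results(pd.DataFrame(hist_rows), out / "orientation_histograms.csv")
    report["orientation"] = {
        "n_areas": len(area_rows),
        "pooled_models": {f"{r['region']}/{r['condition']}": r["model"] for r in pooled_rows},
    }


def _width_stage(cfg: dict, out: Path, images: dict, report: dict) -> None:
    wcfg = cfg.get("width", {})
    rows = []
    samples = {}
    for (region, condition), gen in sorted(images.items()):
        profiles = sample_line_profiles(
            gen.image,
            axis="dendritic",
            n_lines=wcfg.get("n_lines", 6),
            margin=wcfg.get("margin", 10),
        )
        sample = measure_peak_widths(profiles, region=region, condition=condition)
        samples[(region, condition)] = sample
        for i, w in enumerate(sample.widths_nm):
            rows.append({"region": region, "condition": condition, "width_nm": w, "index": i})
    write_results(pd.DataFrame(rows), out / "widths.csv")
    tests = {}
    regions = sorted({k[0] for k in samples})
    for condition in sorted({k[1] for k in samples}):
        if len(regions) == 2:
            a, b = samples[(regions[0], condition)], samples[(regions[1], condition)]
            if a.n >= 2 and b.n >= 2:
                rep = compare_width_samples(a, b)
                tests[condition] = {
                    "regions": regions,
                    "U": rep.statistic,
                    "p": rep.pvalue,
                    "medians_nm": [float(np.median(a.widths_nm)), float(np.median(b.widths_nm))],
                }
    report["width"] = {"n_widths": len(rows), "tests": tests}


def run_pipeline(cfg: dict, output_dir: str | Path | None = None) -> dict:
    """Run all enabled stages in dependency order; returns the run report."""
    validate_config(cfg)
    out = Path(output_dir if output_dir is not None else cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg["seed"])
    sim_seeds, shape_seeds = seeds.spawn(2)
    report: dict = {"version": __version__, "config_hash": config_hash(cfg)}

    logger.info("stage: simulate")
    sim = _simulate_stage(cfg, out, sim_seeds)
    n_in = {k: len(v) for k, v in sim["sets"].items()}
    report["simulate"] = {
        "n_tracks": {f"{r}/{c}": n for (r, c), n in n_in.items()},
        "n_images": len(sim["images"]),
    }

    logger.info("stage: filter")
    min_points = cfg.get("filter", {}).get("min_points", 12)
    filtered = {k: filter_trajectories(v, min_points) for k, v in sim["sets"].items()}
    report["filter"] = {
        "min_points": min_points,
        "kept": {f"{r}/{c}": len(v) for (r, c), v in filtered.items()},
        "removed": {
            f"{r}/{c}": n_in[(r, c)] - len(filtered[(r, c)]) for (r, c) in filtered
        },
    }

    logger.info("stage: diffusion")
    _diffusion_stage(cfg, out, filtered, report)

    logger.info("stage: shape")
    shp = _shape_stage(cfg, out, filtered, shape_seeds, report)

    logger.info("stage: orientation")
    _orientation_stage(cfg, out, shp["segments"], report)

    logger.info("stage: width")
    _width_stage(cfg, out, sim["images"], report)

    (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
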