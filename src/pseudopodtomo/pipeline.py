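"""Stage orchestration: the polarity and receptor pipelines.

Two entry levels:

* in-memory studies (``run_polarity_study``, ``run_receptor_study``)
  generate synthetic scenes and run the full analysis -- what the
  acceptance experiments and most tests use;
* file-based stages (``run_pipeline`` with ``simulate`` / ``polarity`` /
  ``receptors`` / ``fsc`` / ``report``) that communicate through plain
  MRC + TSV artifacts in an output directory, for shell use. Every stage
  logs the (in, kept, rejected) count of each filter and writes a frozen
  copy of the resolved config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .averaging import BoxOrientation, split_half_fsc
from .config import PipelineConfig, save_config
from .filament_calls import (calls_from_records, summarize_fractions,
                             tip_direction)
from .polarity import (PolarityError, assign_votes, classify_2d,
                       model_projection_bank, polarity_of_class, project_slab,
                       rotate_to_axis, select_classes)
from .receptors import (align_average, classify_3d, estimate_normals,
                        extract_stack, measure_height, pick_densities)
from .scene import SceneGroundTruth, generate_scene
from .segments import extract_segments
from .volume import TomogramVolume

log = logging.getLogger("pseudopodtomo")


class DependencyError(FileNotFoundError):
    """A stage was started before its upstream artifact exists."""


# ---------------------------------------------------------------------------
# in-memory polarity pipeline


def polarity_scene_analysis(tomo: TomogramVolume, traces, cfg: PipelineConfig,
                            tomogram_id: int = 0,
                            tip_axis: np.ndarray | None = None,
                            membrane_mask: np.ndarray | None = None) -> dict:
    """Segments -> slab projections -> 2D classes -> votes for one scene.

    Returns a dict with the segment records, classes, per-filament calls
    under the default and the stringent confidence criterion, and the
    tip axis (estimated from the membrane mask unless given).
    """
    records, boxes = extract_segments(tomo, traces, cfg.spacing, cfg.box_edge)
    images, usable = [], []
    for i, (rec, box) in enumerate(zip(records, boxes)):
        if box is None:
            continue
        img = project_slab(box, cfg.slab_thickness, tomo.pixel_size,
                           tangent=rec.tangent)
        try:
            img, angle = rotate_to_axis(img, rec.tangent, rec.residual_offset,
                                        tomo.pixel_size)
        except PolarityError:
            rec.flags.append("steep_tangent")
            continue
        rec.inplane_angle = angle
        images.append(img)
        usable.append(i)
    n_rejected = len(records) - len(usable)
    log.info("scene %d: %d segments, %d usable, %d rejected",
             tomogram_id, len(records), len(usable), n_rejected)
    if len(images) < cfg.k_classes_2d:
        raise PolarityError(
            f"scene {tomogram_id}: only {len(images)} usable segments "
            f"for k={cfg.k_classes_2d}")
    seed = cfg.seed * 10007 + tomogram_id
    labels, flips, shifts, classes = classify_2d(
        images, cfg.k_classes_2d, cfg.classify_iterations, seed=seed)
    model_plus, model_minus = model_projection_bank(
        cfg.scene.helical, cfg.box_edge, tomo.pixel_size, cfg.slab_thickness)
    for c in classes:
        polarity_of_class(c, model_plus, model_minus, cfg.margin)
    try:
        select_classes(classes, cfg.margin, cfg.min_members)
    except PolarityError:
        log.info("scene %d: no class average passed selection; votes fall "
                 "back to per-segment model matching", tomogram_id)
    assign_votes(records, labels, flips, classes, usable,
                 images=images, model_plus=model_plus, model_minus=model_minus)
    if tip_axis is None:
        tip_axis = tip_direction(membrane_mask, tomo.pixel_size)
    calls = calls_from_records(records, cfg.alpha, cfg.n_min_votes)
    calls_stringent = calls_from_records(records, cfg.alpha_stringent,
                                         cfg.n_min_votes)
    trace_map = {tr.filament_id: tr for tr in traces}
    return {
        "tomogram_id": tomogram_id,
        "records": records,
        "images": images,
        "usable": usable,
        "labels": labels,
        "flips": flips,
        "classes": classes,
        "calls": calls,
        "calls_stringent": calls_stringent,
        "traces": trace_map,
        "tip_axis": np.asarray(tip_axis, dtype=float),
    }


def run_polarity_study(cfg: PipelineConfig, n_scenes: int | None = None,
                       progress: bool = False) -> dict:
    """Generate ``n_scenes`` synthetic tomograms and recover the tip-ward
    / cell-ward composition.

    Returns summaries under both confidence criteria plus the per-scene
    analyses."""
    n = cfg.n_scenes if n_scenes is None else n_scenes
    entries, entries_stringent, analyses = [], [], []
    for i in range(n):
        spec = cfg.scene_for(i)
        tomo, gt = generate_scene(spec)
        res = polarity_scene_analysis(tomo, gt.traces, cfg, tomogram_id=i,
                                      membrane_mask=gt.membrane_mask)
        entries.append({"tomogram_id": i, "calls": res["calls"],
                        "traces": res["traces"], "tip_axis": res["tip_axis"]})
        entries_stringent.append({"tomogram_id": i,
                                  "calls": res["calls_stringent"],
                                  "traces": res["traces"],
                                  "tip_axis": res["tip_axis"]})
        res.pop("images")
        analyses.append(res)
        if progress:
            print(f"  scene {i + 1}/{n} done", flush=True)
    summary = summarize_fractions(entries, criterion="default")
    summary_stringent = summarize_fractions(entries_stringent,
                                            criterion="stringent")
    return {"summary": summary, "summary_stringent": summary_stringent,
            "scenes": analyses}


# ---------------------------------------------------------------------------
# in-memory receptor pipeline


def receptor_scene_analysis(tomo: TomogramVolume, gt: SceneGroundTruth,
                            cfg: PipelineConfig, tomogram_id: int = 0) -> dict:
    """Pick -> box -> average -> classify -> measure for one scene."""
    membrane = estimate_normals(gt.membrane_mask, tomo.pixel_size,
                                support_z=gt.support_z)
    picks = pick_densities(tomo, membrane, cfg.attach_band, cfg.height_band,
                           cfg.tilt_max, cfg.min_separation)
    kept = [p for p in picks if p.kept]
    log.info("scene %d: %d candidates, %d kept, %d rejected",
             tomogram_id, len(picks), len(kept), len(picks) - len(kept))
    stack = extract_stack(tomo, picks, cfg.box_edge)
    initial_model = align_average(stack)
    seed = cfg.seed * 10007 + 31 * tomogram_id
    labels, class_vols, selected = classify_3d(stack, cfg.k_classes_3d,
                                               cfg.classify_iterations,
                                               seed=seed)
    height, flagged = measure_height(class_vols[selected],
                                     stack.membrane_z_index, tomo.pixel_size,
                                     cfg.measure_level)
    return {
        "tomogram_id": tomogram_id,
        "membrane": membrane,
        "picks": picks,
        "stack": stack,
        "initial_model": initial_model,
        "labels": labels,
        "class_volumes": class_vols,
        "selected_class": selected,
        "height_nm": height,
        "height_flagged": flagged,
    }


def run_receptor_study(cfg: PipelineConfig, n_scenes: int | None = None,
                       progress: bool = False) -> dict:
    n = cfg.n_scenes if n_scenes is None else n_scenes
    results = []
    for i in range(n):
        spec = cfg.scene_for(i)
        tomo, gt = generate_scene(spec)
        results.append(receptor_scene_analysis(tomo, gt, cfg, tomogram_id=i))
        if progress:
            print(f"  scene {i + 1}/{n} done", flush=True)
    heights = [r["height_nm"] for r in results if not r["height_flagged"]]
    return {
        "scenes": results,
        "mean_height_nm": float(np.mean(heights)) if heights else float("nan"),
        "sd_height_nm": float(np.std(heights, ddof=1)) if len(heights) > 1 else 0.0,
    }


# ---------------------------------------------------------------------------
# file-based stages


def _scene_dir(outdir: Path, i: int) -> Path:
    return outdir / f"scene_{i:03d}"


def run_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, outdir / "config_frozen.yaml")
    for i in range(cfg.n_scenes):
        spec = cfg.scene_for(i)
        tomo, gt = generate_scene(spec)
        d = _scene_dir(outdir, i)
        d.mkdir(exist_ok=True)
        pio.write_mrc(tomo, d / "tomogram.mrc")
        pio.write_table(pio.traces_to_frame(gt.traces), d / "traces.tsv", "traces")
        mask_vol = TomogramVolume(gt.membrane_mask.astype(np.float32),
                                  tomo.pixel_size)
        pio.write_mrc(mask_vol, d / "membrane_mask.mrc")
        meta = {"tip_axis": gt.tip_axis.tolist(), "support_z": gt.support_z,
                "seed": spec.seed, "tilt_range": spec.tilt_range,
                "n_receptors": len(gt.receptor_placements)}
        (d / "scene.json").write_text(json.dumps(meta, indent=1))
        if gt.receptor_placements:
            rows = [{"x": p["position"][0], "y": p["position"][1],
                     "z": p["position"][2], "nx": p["normal"][0],
                     "ny": p["normal"][1], "nz": p["normal"][2],
                     "height_above_support": p["height_above_support"],
                     "normal_tilt": 0.0, "kept": 1}
                    for p in gt.receptor_placements]
            pio.write_table(pd.DataFrame(rows), d / "receptors_truth.tsv", "picks")
        log.info("simulate: wrote scene %d (%d filaments, %d receptors)",
                 i, len(gt.traces), len(gt.receptor_placements))


def _load_scene(d: Path, need_tomo: bool = True):
    if not (d / "scene.json").exists():
        raise DependencyError(f"missing scene artifacts in {d}; run `simulate` first")
    meta = json.loads((d / "scene.json").read_text())
    tomo = pio.read_mrc(d / "tomogram.mrc", tilt_range=meta.get("tilt_range")) \
        if need_tomo else None
    return tomo, meta


def run_polarity_stage(cfg: PipelineConfig, outdir: Path) -> None:
    entries = []
    for i in range(cfg.n_scenes):
        d = _scene_dir(outdir, i)
        tomo, meta = _load_scene(d)
        traces = pio.frame_to_traces(pio.read_table(d / "traces.tsv", "traces"))
        res = polarity_scene_analysis(tomo, traces, cfg, tomogram_id=i,
                                      tip_axis=np.asarray(meta["tip_axis"]))
        pio.write_table(pio.segments_to_frame(res["records"]),
                        d / "segments.tsv", "segments")
        entries.append(res)
    df = pio.calls_to_frame({e["tomogram_id"]: e["calls"] for e in entries})
    pio.write_table(df, outdir / "calls.tsv", "calls")
    with open(outdir / "tips.json", "w") as fh:
        json.dump({str(e["tomogram_id"]): e["tip_axis"].tolist()
                   for e in entries}, fh)


def run_report(cfg: PipelineConfig, outdir: Path) -> None:
    calls_path = outdir / "calls.tsv"
    if not calls_path.exists():
        raise DependencyError("missing calls table; run `polarity` first")
    entries = []
    for i in range(cfg.n_scenes):
        d = _scene_dir(outdir, i)
        _, meta = _load_scene(d, need_tomo=False)
        traces = pio.frame_to_traces(pio.read_table(d / "traces.tsv", "traces"))
        seg = pio.read_table(d / "segments.tsv", "segments")
        records_votes = {fid: grp["polarity_vote"].astype(int).tolist()
                         for fid, grp in seg.groupby("filament_id")}
        from .filament_calls import vote_filament
        calls = {int(fid): vote_filament(v, cfg.alpha, cfg.n_min_votes, int(fid))
                 for fid, v in records_votes.items()}
        entries.append({"tomogram_id": i, "calls": calls,
                        "traces": {t.filament_id: t for t in traces},
                        "tip_axis": np.asarray(meta["tip_axis"])})
    summary = summarize_fractions(entries)
    rows = pd.DataFrame(summary.per_tomogram)
    pio.write_table(rows, outdir / "fraction_summary.tsv", "summary")
    # stacked-column chart data: one column per tomogram, tip/cell rows
    chart = pd.DataFrame({
        "tomogram_id": rows["tomogram_id"],
        "tip_ward_percent": 100 * rows["tip_ward_fraction"],
        "cell_ward_percent": 100 * (1 - rows["tip_ward_fraction"]),
    })
    chart.to_csv(outdir / "fraction_chart.csv", index=False)
    (outdir / "aggregate.json").write_text(json.dumps({
        "tip_ward_mean_percent": summary.aggregate_mean,
        "tip_ward_sd_percent": summary.aggregate_sd,
        "cell_ward_mean_percent": summary.cell_ward_mean,
    }, indent=1))
    log.info("report: tip-ward %.1f +/- %.1f %%", summary.aggregate_mean,
             summary.aggregate_sd)


def run_receptors_stage(cfg: PipelineConfig, outdir: Path) -> None:
    heights = []
    for i in range(cfg.n_scenes):
        d = _scene_dir(outdir, i)
        tomo, meta = _load_scene(d)
        mask_vol = pio.read_mrc(d / "membrane_mask.mrc")
        gt = SceneGroundTruth([], [], np.asarray(meta["tip_axis"]),
                              mask_vol.grid > 0.5, meta["support_z"],
                              np.zeros(3))
        res = receptor_scene_analysis(tomo, gt, cfg, tomogram_id=i)
        pio.write_table(pio.picks_to_frame(res["picks"]), d / "picks.star",
                        "picks", dialect="star")
        sel = res["class_volumes"][res["selected_class"]]
        pio.write_mrc(TomogramVolume(sel, tomo.pixel_size), d / "class_selected.mrc")
        pio.write_mrc(TomogramVolume(res["initial_model"], tomo.pixel_size),
                      d / "initial_model.mrc")
        if not res["height_flagged"]:
            heights.append(res["height_nm"])
    (outdir / "receptor_heights.json").write_text(json.dumps({
        "heights_nm": heights,
        "mean_height_nm": float(np.mean(heights)) if heights else None,
    }, indent=1))


def run_fsc_stage(cfg: PipelineConfig, outdir: Path) -> None:
    """Half-set FSC of the polarity-aligned actin segments of scene 0."""
    d = _scene_dir(outdir, 0)
    seg_path = d / "segments.tsv"
    if not seg_path.exists():
        raise DependencyError("missing segment table; run `polarity` first")
    tomo, _ = _load_scene(d)
    traces = pio.frame_to_traces(pio.read_table(d / "traces.tsv", "traces"))
    res = polarity_scene_analysis(tomo, traces, cfg, tomogram_id=0,
                                  tip_axis=np.array([1.0, 0, 0]))
    records, boxes = extract_segments(tomo, traces, cfg.spacing, cfg.box_edge)
    subvols, orients = [], []
    # reuse orientations from the analysed records
    rec_map = {(r.filament_id, r.segment_index): r for r in res["records"]}
    for rec, box in zip(records, boxes):
        r = rec_map.get((rec.filament_id, rec.segment_index))
        if box is None or r is None or r.inplane_angle is None \
                or r.polarity_vote == 0:
            continue
        subvols.append(box)
        orients.append(BoxOrientation(inplane_angle=r.inplane_angle,
                                      flip=r.polarity_vote < 0,
                                      shift_nm=r.residual_offset[:2]))
    if len(subvols) < 2:
        raise PolarityError("not enough voted segments for an FSC")
    curve = split_half_fsc(subvols, orients, tomo.pixel_size, seed=cfg.seed,
                           helical=cfg.scene.helical)
    df = pd.DataFrame({"frequency_inv_nm": curve.shell_frequencies,
                       "correlation": curve.correlations})
    pio.write_table(df, outdir / "fsc.tsv", "fsc")
    (outdir / "fsc.json").write_text(json.dumps({
        "resolution_at_0143_A": curve.resolution_at_0143,
        "resolution_at_05_A": curve.resolution_at_05,
        "n_segments": len(subvols),
    }, indent=1))


STAGES = {
    "simulate": run_simulate,
    "polarity": run_polarity_stage,
    "receptors": run_receptors_stage,
    "fsc": run_fsc_stage,
    "report": run_report,
}


def run_pipeline(cfg: PipelineConfig, stage: str, outdir: str | Path) -> None:
    """Run one named stage against an output directory."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(STAGES)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(level=logging.INFO)
    log.setLevel(logging.INFO)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setLevel(logging.INFO)
    log.addHandler(fh)
    try:
        save_config(cfg, outdir / "config_frozen.yaml")
        STAGES[stage](cfg, outdir)
    finally:
        log.removeHandler(fh)
        fh.close()
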