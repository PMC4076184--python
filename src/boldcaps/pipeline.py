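"""End-to-end orchestration: simulate -> preprocess -> QC -> extract ->
cluster -> compare, with config, caching and a reproducible run manifest.

A run is driven by a :class:`RunConfig` (YAML or JSON on disk).  One base
RNG seed fans out to per-stage seeds (seed + CRC32 of the stage name, mod
2**31) so each stage is independently reproducible.  Completed stages
leave compact caches under ``<output_dir>/cache``; re-running resumes from
the latest cache unless ``force`` is set.  The manifest contains no
timestamps, so identical config + seed reproduces it byte for byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import clustering, events, motion, preprocess, simulate, stats
from .session import BoldSession

log = logging.getLogger("boldcaps")

DEFAULT_CONFIG: dict = {
    "run_id": "run-0",
    "rng_seed": 0,
    "simulate": {
        "n_subjects": 6,
        "n_conditions": 4,
        "n_frames": 197,
        "tr_seconds": 2.46,
        "grid_dims": [20, 24, 20],
        "voxel_mm": [3.0, 3.0, 3.0],
        "k_true": 8,
        "event_rate": 0.15,
        "noise_sd": 1.0,
        "gains": None,  # (n_conditions, k_true); None -> all ones
    },
    "preprocess": {
        "detrend": {"order": 2},
        "bandpass": {"low": 0.005, "high": 0.1},
        "smooth": {"fwhm_mm": 8.0},
        "nuisance": {"include": ["motion"]},
    },
    "qc": {
        "fd_thresh": 0.5,
        "dvars_thresh": 0.5,
        "rule": "and",
        "head_radius_mm": 50.0,
        "apply_censoring": True,
    },
    "seed": {"center_mm": None, "edge_mm": 6.0},  # None -> simulated seed cube
    "select": {"threshold_sd": 1.0, "sign": "positive"},
    "cluster": {"k": 8, "n_restarts": 10},
    "stats": {"weights": [1.5, -0.5, -1.5, 0.5], "q": 0.05},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


@dataclass
class RunConfig:
    """Effective pipeline configuration (defaults merged with overrides)."""

    config: dict
    output_dir: Path

    @classmethod
    def from_file(cls, path: str | Path, output_dir: str | Path,
                  rng_seed: int | None = None) -> "RunConfig":
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        return cls.from_dict(user, output_dir, rng_seed=rng_seed)

    @classmethod
    def from_dict(cls, user: dict, output_dir: str | Path,
                  rng_seed: int | None = None) -> "RunConfig":
        cfg = _merge(DEFAULT_CONFIG, user or {})
        if rng_seed is not None:
            cfg["rng_seed"] = int(rng_seed)
        return cls(config=cfg, output_dir=Path(output_dir))

    def stage_seed(self, stage: str) -> int:
        return (int(self.config["rng_seed"]) + zlib.crc32(stage.encode())) % (2**31)

    def write_provenance(self) -> None:
        self.output_dir.mkdir(parents=True, exist_ok=True)
        with open(self.output_dir / "config_used.yaml", "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _build_cohort(cfg: dict, seed: int):
    import dataclasses

    sim = dict(cfg["simulate"])
    gains = sim.pop("gains", None)
    known = {f.name for f in dataclasses.fields(simulate.SimParams)}
    unknown = set(sim) - known
    if unknown:
        raise ValueError(f"unknown simulate config keys: {sorted(unknown)}")
    for key in ("grid_dims", "voxel_mm"):
        if key in sim:
            sim[key] = tuple(sim[key])
    params = simulate.SimParams(**{**sim, "rng_seed": seed})
    gains = None if gains is None else np.asarray(gains, float)
    return simulate.generate_cohort(params, gains=gains)


def run_pipeline(run_config: RunConfig, force: bool = False) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    cfg = run_config.config
    out_dir = run_config.output_dir
    cache_dir = out_dir / "cache"
    cache_dir.mkdir(parents=True, exist_ok=True)
    run_config.write_provenance()
    manifest: dict = {"run_id": cfg["run_id"], "rng_seed": cfg["rng_seed"], "stages": []}

    extract_cache = cache_dir / "extract.npz"
    extract_meta = cache_dir / "extract.json"

    if extract_cache.exists() and extract_meta.exists() and not force:
        log.info("resuming from cached extract stage")
        with open(extract_meta) as fh:
            meta = json.load(fh)
        payload = np.load(extract_cache, allow_pickle=False)
        records = []
        for i, rec in enumerate(meta["records"]):
            records.append(
                {
                    **rec,
                    "frames": payload[f"frames_{i}"],
                    "labels_true": None,
                }
            )
        condition_labels = meta["condition_labels"]
        qc_summary = meta["qc_summary"]
        select_summary = meta["select_summary"]
        manifest["stages"].append({"stage": "extract", "resumed": True})
    else:
        # --- simulate ---------------------------------------------------
        try:
            sessions, motion_params, truth = _build_cohort(cfg, run_config.stage_seed("simulate"))
        except Exception as exc:  # noqa: BLE001
            _abort(manifest, out_dir, "simulate", exc)
        condition_labels = list(truth.condition_labels)
        manifest["stages"].append({"stage": "simulate", "n_sessions": len(sessions)})

        # --- qc (on raw data, before standardization) -------------------
        qc_cfg = cfg["qc"]
        try:
            traces = [
                motion.MotionTrace.from_session(
                    mp,
                    sess,
                    head_radius_mm=float(qc_cfg["head_radius_mm"]),
                    fd_thresh=float(qc_cfg["fd_thresh"]),
                    dvars_thresh=float(qc_cfg["dvars_thresh"]),
                    rule=qc_cfg["rule"],
                )
                for mp, sess in zip(motion_params, sessions)
            ]
        except Exception as exc:  # noqa: BLE001
            _abort(manifest, out_dir, "qc", exc)
        qc_summary = _per_condition_censoring(sessions, traces, condition_labels)
        manifest["stages"].append({"stage": "qc", "censored_fraction": qc_summary})

        # --- preprocess -------------------------------------------------
        pp = cfg["preprocess"]
        try:
            clean = []
            for sess, mp in zip(sessions, motion_params):
                include = tuple(pp["nuisance"]["include"])
                nuis = None
                if include:
                    nuis = preprocess.build_nuisance(sess, motion_params=mp, include=include)
                clean.append(
                    preprocess.preprocess_session(
                        sess,
                        nuisance=nuis,
                        detrend_order=int(pp["detrend"]["order"]),
                        low_hz=float(pp["bandpass"]["low"]),
                        high_hz=float(pp["bandpass"]["high"]),
                        fwhm_mm=float(pp["smooth"]["fwhm_mm"]),
                    )
                )
        except Exception as exc:  # noqa: BLE001
            _abort(manifest, out_dir, "preprocess", exc)
        manifest["stages"].append({"stage": "preprocess", "n_sessions": len(clean)})

        # --- extract ----------------------------------------------------
        seed_cfg = cfg["seed"]
        center = seed_cfg["center_mm"] or list(truth.seed_center_mm)
        seed_spec = events.SeedSpec(
            center_mm=tuple(center), edge_mm=float(seed_cfg["edge_mm"]), space_tag="synthetic"
        )
        sel_cfg = cfg["select"]
        records = []
        try:
            for sess, trace in zip(clean, traces):
                keep = trace.keep_mask if qc_cfg["apply_censoring"] else None
                pp_proc = events.extract_point_process(
                    sess,
                    seed_spec,
                    threshold_sd=float(sel_cfg["threshold_sd"]),
                    sign=sel_cfg["sign"],
                    keep_mask=keep,
                )
                records.append(
                    {
                        "subject_id": sess.subject_id,
                        "condition_label": sess.condition_label,
                        "n_events": pp_proc.n_events,
                        "n_frames_total": pp_proc.n_frames_total,
                        "n_frames_kept": pp_proc.n_frames_kept,
                        "frames": pp_proc.frames,
                    }
                )
        except Exception as exc:  # noqa: BLE001
            _abort(manifest, out_dir, "extract", exc)
        select_summary = _per_condition_selection(records, condition_labels)
        manifest["stages"].append({"stage": "extract", "selected_fraction": select_summary})
        # cache
        meta = {
            "records": [
                {k: v for k, v in rec.items() if k != "frames"} for rec in records
            ],
            "condition_labels": condition_labels,
            "qc_summary": qc_summary,
            "select_summary": select_summary,
        }
        np.savez_compressed(
            extract_cache, **{f"frames_{i}": rec["frames"] for i, rec in enumerate(records)}
        )
        with open(extract_meta, "w") as fh:
            json.dump(meta, fh)

    # --- cluster --------------------------------------------------------
    cl_cfg = cfg["cluster"]
    k = int(cl_cfg["k"])
    all_frames = np.concatenate([rec["frames"] for rec in records], axis=0)
    try:
        centroids = clustering.fit_centroids(
            all_frames,
            k=k,
            n_restarts=int(cl_cfg["n_restarts"]),
            rng_seed=run_config.stage_seed("cluster"),
        )
    except Exception as exc:  # noqa: BLE001
        _abort(manifest, out_dir, "cluster", exc)
    centroid_hash_before = _sha256(centroids.centroids)

    cap_sets: dict[str, clustering.CapSet] = {}
    subject_records = []
    import warnings as _warnings

    for cond in condition_labels:
        cond_frames = [rec for rec in records if rec["condition_label"] == cond]
        frames = np.concatenate([rec["frames"] for rec in cond_frames], axis=0)
        labels = clustering.assign_to_centroids(frames, centroids)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", clustering.EmptyClusterWarning)
            cap_sets[cond] = clustering.compute_caps(frames, labels, k, condition_label=cond)
        offset = 0
        for rec in cond_frames:
            n = rec["frames"].shape[0]
            subject_records.append(
                {
                    "subject_id": rec["subject_id"],
                    "condition_label": cond,
                    "frames": rec["frames"],
                    "labels": labels[offset : offset + n],
                }
            )
            offset += n
    centroid_hash_after = _sha256(centroids.centroids)
    manifest["stages"].append(
        {
            "stage": "cluster",
            "k": k,
            "centroid_hash_before": centroid_hash_before,
            "centroid_hash_after": centroid_hash_after,
            "occupancy": {
                cond: cap_sets[cond].occupancy.tolist() for cond in condition_labels
            },
        }
    )

    # --- compare --------------------------------------------------------
    ref_cond = condition_labels[0]
    similarity = {}
    for cond in condition_labels[1:]:
        tbl = clustering.match_and_compare(cap_sets[ref_cond], cap_sets[cond])
        similarity[cond] = [None if np.isnan(v) else round(float(v), 6)
                            for v in tbl["correlation"]]

    st_cfg = cfg["stats"]
    contrast_summary = None
    subjects = sorted({rec["subject_id"] for rec in subject_records})
    if len(condition_labels) == len(st_cfg["weights"]) and len(subjects) >= 3:
        try:
            maps, _counts = stats.subject_cap_maps(
                subject_records, k, subjects, condition_labels
            )
            per_cap = []
            for j in range(k):
                try:
                    res = stats.linear_consciousness_contrast(
                        maps[:, :, j, :], weights=st_cfg["weights"], q=float(st_cfg["q"])
                    )
                    per_cap.append(
                        {"cap_index": j, "n_significant": res.n_significant,
                         "n_subjects": res.n_subjects}
                    )
                except ValueError:
                    # fewer than 3 subjects with all condition cells for this CAP
                    per_cap.append(
                        {"cap_index": j, "n_significant": None, "n_subjects": None}
                    )
            contrast_summary = {"weights": list(st_cfg["weights"]),
                                "q": float(st_cfg["q"]), "per_cap": per_cap}
        except Exception as exc:  # noqa: BLE001
            _abort(manifest, out_dir, "stats", exc)
    manifest["stages"].append(
        {"stage": "compare", "reference_condition": ref_cond, "similarity": similarity,
         "contrast": contrast_summary}
    )

    manifest["qc_censored_fraction"] = qc_summary
    manifest["selected_fraction"] = select_summary
    manifest["conditions"] = condition_labels
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _abort(manifest: dict, out_dir: Path, stage: str, exc: Exception):
    manifest["failed_stage"] = stage
    manifest["error"] = str(exc)
    with open(out_dir / "manifest.partial.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    raise StageError(stage, exc)


def _per_condition_censoring(sessions, traces, condition_labels) -> dict:
    out = {}
    for cond in condition_labels:
        fracs = [
            tr.censored_fraction
            for sess, tr in zip(sessions, traces)
            if sess.condition_label == cond
        ]
        out[cond] = round(float(np.mean(fracs)), 6)
    return out


def _per_condition_selection(records, condition_labels) -> dict:
    out = {}
    for cond in condition_labels:
        recs = [r for r in records if r["condition_label"] == cond]
        n_ev = sum(r["n_events"] for r in recs)
        n_tot = sum(r["n_frames_total"] for r in recs)
        n_kept = sum(r["n_frames_kept"] for r in recs)
        out[cond] = {
            "of_total": round(n_ev / n_tot, 6) if n_tot else 0.0,
            "of_kept": round(n_ev / n_kept, 6) if n_kept else 0.0,
        }
    return out


def report(manifest: dict) -> str:
    """Human-readable run summary: occupancy, similarity, contrast tables."""
    import pandas as pd

    lines = [f"run: {manifest.get('run_id')}  (seed {manifest.get('rng_seed')})", ""]
    stages = {s["stage"]: s for s in manifest.get("stages", [])}
    if "cluster" in stages:
        occ = stages["cluster"]["occupancy"]
        rows = [
            {"condition": cond, "cap_index": j, "occupancy": n}
            for cond, counts in occ.items()
            for j, n in enumerate(counts)
        ]
        df = pd.DataFrame(rows)
        lines += ["CAP occupancy per condition:", df.to_string(index=False), ""]
        empties = df[df["occupancy"] == 0]
        if len(empties):
            lines += [f"warning: {len(empties)} empty CAP cell(s):",
                      empties.to_string(index=False), ""]
    else:
        lines.append("warning: cluster stage outputs missing")
    if "compare" in stages:
        sim = stages["compare"]["similarity"]
        ref = stages["compare"]["reference_condition"]
        if sim:
            df = pd.DataFrame(sim)
            df.index.name = "cap_index"
            lines += [f"spatial correlation with reference condition '{ref}':",
                      df.to_string(), ""]
        contrast = stages["compare"].get("contrast")
        if contrast:
            df = pd.DataFrame(contrast["per_cap"])
            lines += [
                f"linear consciousness contrast {contrast['weights']} "
                f"(FDR q={contrast['q']}):",
                df.to_string(index=False),
                "",
            ]
    else:
        lines.append("warning: compare stage outputs missing")
    return "\n".join(lines)
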