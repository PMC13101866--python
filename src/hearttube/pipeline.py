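"""End-to-end orchestration: generator → segmentation → assignment →
morphometry → profiles → statistics, driven by one declarative config.

A run is reproducible bit-identically from (config, seed): every heart gets
its own child seed derived from the base seed and its index, the report
carries the config hash, and no timestamps enter the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .image import LabelVolume
from .morphometry import measure_morphometry
from .profiles import estimate_normals, place_anchors, sample_line_profiles
from .regions import CenterlineMap, assign_compartment, normalize_volumes, run_group_test
from .segmentation import segment_heart, write_nuclei_csv
from .synthetic import COMPARTMENTS, SyntheticConfig, synthesize_heart

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("synthesize", "segment", "morphometry", "profiles", "compare")

_DEFAULTS = {
    "seed": 0,
    "outdir": "hearttube_run",
    "stages": list(KNOWN_STAGES),
    "save_images": True,
    "hearts": [{"id": "heart_0", "group": "control", "synthetic": {}}],
    "segmentation": {
        "sigmas": [1.2, 1.6, 2.0, 2.4],
        "threshold": None,
        "min_separation": 4.0,
    },
    "assignment": {"max_lumen_distance": 20.0},
    "morphometry": {"target_edge": 2.0, "smooth_window": 5},
    "profiles": {
        "regions": ["atrium", "AVC"],
        "n_lines": 8,
        "half_length": 3.0,
        "step": 0.25,
    },
    "comparisons": [],
}


class ConfigError(ValueError):
    """Carries the aggregated list of configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


@dataclasses.dataclass
class RunConfig:
    seed: int
    outdir: Path
    stages: list
    save_images: bool
    hearts: list
    segmentation: dict
    assignment: dict
    morphometry: dict
    profiles: dict
    comparisons: list
    raw: dict

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def validate_config(source) -> RunConfig:
    """Validate a YAML path / dict into a typed RunConfig with defaults filled.

    All problems are collected and reported together before any stage runs.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    problems: list[str] = []
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        problems.append(f"unknown top-level keys: {sorted(unknown)}")
    merged = {**_DEFAULTS, **{k: v for k, v in raw.items() if k in _DEFAULTS}}
    for nested in ("segmentation", "assignment", "morphometry", "profiles"):
        merged[nested] = {**_DEFAULTS[nested], **(merged[nested] or {})}
        bad = set(merged[nested]) - set(_DEFAULTS[nested])
        if bad:
            problems.append(f"unknown keys in {nested!r}: {sorted(bad)}")

    for stage in merged["stages"]:
        if stage not in KNOWN_STAGES:
            problems.append(
                f"unknown stage {stage!r}; valid stages: {list(KNOWN_STAGES)}"
            )
    if not isinstance(merged["seed"], int):
        problems.append(f"seed must be an integer, got {merged['seed']!r}")

    hearts = merged["hearts"]
    if not hearts:
        problems.append("at least one heart required")
    seen_ids = set()
    for i, h in enumerate(hearts):
        hid = h.get("id", f"heart_{i}")
        if hid in seen_ids:
            problems.append(f"duplicate heart id {hid!r}")
        seen_ids.add(hid)
        try:
            _heart_config(merged, h, seed=0)
        except Exception as exc:  # range errors from SyntheticConfig
            problems.append(f"heart {hid!r}: {exc}")

    for c in merged["comparisons"]:
        test = c.get("test", "mann_whitney")
        if test not in ("mann_whitney", "t_test", "kruskal_wallis"):
            problems.append(f"comparison has unsupported test {test!r}")
        if "groups" not in c or len(c["groups"]) < 2:
            problems.append("comparison needs a 'groups' list of ≥2 group names")

    for region in merged["profiles"]["regions"]:
        if region not in COMPARTMENTS:
            problems.append(
                f"unknown profile region {region!r}; valid: {list(COMPARTMENTS)}"
            )

    if problems:
        raise ConfigError(problems)
    return RunConfig(
        seed=merged["seed"],
        outdir=Path(merged["outdir"]),
        stages=list(merged["stages"]),
        save_images=bool(merged["save_images"]),
        hearts=hearts,
        segmentation=merged["segmentation"],
        assignment=merged["assignment"],
        morphometry=merged["morphometry"],
        profiles=merged["profiles"],
        comparisons=merged["comparisons"],
        raw=raw,
    )


def _heart_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0])


def _heart_config(merged: dict, heart: dict, seed: int) -> SyntheticConfig:
    overrides = dict(heart.get("synthetic", {}) or {})
    scale = overrides.pop("avc_volume_scale", None)
    cfg = SyntheticConfig(**overrides, seed=seed)
    if scale is not None:
        cfg = cfg.with_volume_scale(float(scale), "AVC")
    return cfg


def _process_heart(config: RunConfig, index: int, heart: dict) -> dict:
    hid = heart.get("id", f"heart_{index}")
    group = heart.get("group", "control")
    seed = _heart_seed(config.seed, index)
    logger.info("heart %s (group=%s): seed %d", hid, group, seed)
    entry: dict = {"id": hid, "group": group, "seed": seed}

    syn_cfg = _heart_config({}, heart, seed=seed)
    synth = synthesize_heart(syn_cfg)
    heart_dir = config.outdir / hid
    if config.save_images:
        synth.write(heart_dir)

    if "segment" in config.stages:
        seg = config.segmentation
        labels, records = segment_heart(
            synth.nuclear,
            sigmas=seg["sigmas"],
            threshold=seg["threshold"],
            min_separation=seg["min_separation"],
        )
        cmap = CenterlineMap(synth.truth.centerline, synth.truth.compartment_intervals)
        assign_compartment(
            records, synth.compartments, cmap,
            max_lumen_distance=config.assignment["max_lumen_distance"],
        )
        for r in records:
            r.group = group
        entry["nuclei"] = records
        if config.save_images:
            heart_dir.mkdir(parents=True, exist_ok=True)
            write_nuclei_csv(records, heart_dir / "nuclei.csv")

    if "morphometry" in config.stages:
        m = measure_morphometry(
            synth.compartments,
            target_edge=config.morphometry["target_edge"],
            smooth_window=config.morphometry["smooth_window"],
        )
        entry["morphometry"] = m.to_json_dict()
        if config.save_images:
            heart_dir.mkdir(parents=True, exist_ok=True)
            m.write(heart_dir / "morphometry.json")

    if "profiles" in config.stages:
        prof = config.profiles
        rng = np.random.default_rng(seed + 1)
        lumen = LabelVolume(
            (synth.compartments.data > 0).astype(np.int32), synth.compartments.spacing
        )
        summaries = {}
        for region in prof["regions"]:
            label = COMPARTMENTS.index(region) + 1
            anchors = place_anchors(
                synth.membrane_labels, label, prof["n_lines"], rng
            )
            normals, valid = estimate_normals(lumen, anchors)
            pset = sample_line_profiles(
                synth.membrane, anchors[valid], normals[valid],
                half_length=prof["half_length"], step=prof["step"],
                region=region, channel="membrane",
            )
            summaries[region] = {
                "n_lines": len(pset.lines),
                "maxima": pset.maxima.tolist(),
                "mean_max": float(pset.maxima.mean()) if pset.lines else None,
            }
            if config.save_images:
                heart_dir.mkdir(parents=True, exist_ok=True)
                pset.write_csv(heart_dir / f"profiles_{region}.csv")
        entry["profiles"] = summaries
    return entry


def _summarize_groups(heart_entries: list[dict], comparisons: list) -> tuple[dict, list]:
    """Per-group nucleus-volume summaries and requested group tests."""
    records = [
        r for e in heart_entries for r in e.get("nuclei", []) if "error" not in e
    ]
    groups = sorted({r.group for r in records})
    summaries = {}
    for g in groups:
        for comp in ("AVC",):
            vols = [r.volume for r in records if r.group == g and r.compartment == comp]
            summaries[g] = {
                "compartment": comp,
                "n": len(vols),
                "mean_volume_um3": float(np.mean(vols)) if vols else None,
            }
    results = []
    for comp_spec in comparisons:
        test = comp_spec.get("test", "mann_whitney")
        comp = comp_spec.get("compartment", "AVC")
        wanted = comp_spec.get("groups")
        reference = comp_spec.get("reference", wanted[0])
        values = {
            g: [r.volume for r in records if r.group == g and r.compartment == comp]
            for g in wanted
        }
        try:
            normalized = normalize_volumes(
                [r for r in records if r.compartment == comp],
                reference_group=reference, reference_compartment=comp,
            )
            comp_records = [r for r in records if r.compartment == comp]
            norm_means = {
                g: float(
                    np.mean([v for v, r in zip(normalized, comp_records) if r.group == g])
                )
                for g in wanted
            }
            result = run_group_test(values, test, normalization_reference=reference)
            results.append(
                {
                    "test": test,
                    "compartment": comp,
                    "groups": wanted,
                    "group_sizes": list(result.group_sizes),
                    "statistic": result.statistic,
                    "p_value": result.p_value,
                    "normalization_reference": reference,
                    "normalized_means": norm_means,
                }
            )
        except ValueError as exc:
            results.append({"test": test, "groups": wanted, "error": str(exc)})
    return summaries, results


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages for every heart and write the report.

    Failures in one heart are isolated: they are logged, recorded in that
    heart's entry, and do not abort the batch.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, heart in enumerate(config.hearts):
        try:
            entries.append(_process_heart(config, i, heart))
        except Exception as exc:
            logger.exception("heart %d failed", i)
            entries.append(
                {
                    "id": heart.get("id", f"heart_{i}"),
                    "group": heart.get("group", "control"),
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )

    group_summaries, comparison_results = _summarize_groups(
        entries, config.comparisons if "compare" in config.stages else []
    )
    import numpy as _np
    import scipy as _scipy

    report = {
        "provenance": {
            "config_hash": config.config_hash,
            "seed": config.seed,
            "versions": {
                "hearttube": __version__,
                "numpy": _np.__version__,
                "scipy": _scipy.__version__,
            },
        },
        "hearts": [
            {
                k: (
                    [dataclasses.asdict(r) for r in v]
                    if k == "nuclei"
                    else v
                )
                for k, v in e.items()
            }
            for e in entries
        ],
        "group_summaries": group_summaries,
        "comparisons": comparison_results,
    }
    report_path = config.outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
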