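"""End-to-end orchestration: simulate -> build-dict -> match -> qa-report.

The pipeline is configured from a YAML/JSON mapping (see
:class:`PipelineConfig`), is fully seeded, and writes a manifest recording
every output file with a checksum, the config hash, the seeds and the
package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

import mrfkit
from mrfkit.dictionary import (
    GridSpec,
    build_dictionary,
    compress,
    load_dictionary,
    save_dictionary,
)
from mrfkit.io import (
    default_affine,
    sha256_of,
    write_parameter_map,
    write_series,
    write_volume,
)
from mrfkit.matching import apply_t1_mask, match_image
from mrfkit.phantom import (
    AcquisitionNoise,
    default_phantom_spec,
    generate_b1_field,
    generate_phantom_truth,
    generate_test_retest_pair,
    phantom_roi_specs,
)
from mrfkit.qa import MeasurementTable, extract_roi_mean, qa_report, region_summary
from mrfkit.sequence import default_schedule, load_schedule_csv

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 7
    n_timepoints: int = 1500
    schedule_csv: str | None = None
    shape: tuple = (112, 112, 7)
    b1_amplitude: float = 0.05
    noise_sd: float = 0.0
    build_dictionary: bool = True
    dictionary_path: str | None = None
    b1_subset: tuple | None = (0.95, 1.0, 1.05)
    rank: int = 50
    t1_mask_threshold_ms: float = 400.0
    n_epg_states: int = 30
    # optional grid overrides (list of [lo, hi, step] segments)
    t1_segments: tuple | None = None
    t2_segments: tuple | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.out_dir:
            raise ValueError("out_dir is required")
        if not self.build_dictionary:
            if not self.dictionary_path:
                raise ValueError(
                    "dictionary_path is required when build_dictionary is false"
                )
            if not Path(self.dictionary_path).exists():
                raise ValueError(f"dictionary_path {self.dictionary_path} does not exist")
        if self.schedule_csv and not Path(self.schedule_csv).exists():
            raise ValueError(f"schedule_csv {self.schedule_csv} does not exist")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        self.shape = tuple(int(s) for s in self.shape)
        if self.b1_subset is not None:
            self.b1_subset = tuple(float(b) for b in self.b1_subset)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        if self.b1_subset is not None:
            d["b1_subset"] = list(self.b1_subset)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _record(manifest: dict, path: Path) -> None:
    manifest["outputs"][str(path)] = sha256_of(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all four stages; returns the manifest (also written to disk).

    On a stage failure, the manifest records the failed stage and error,
    previously written outputs are retained, and a ``manifest.partial.json``
    marker is written instead of the final manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": mrfkit.__version__,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seeds": {
            "base": config.seed,
            "b1": config.seed + 1,
            "noise_test": config.seed + 2,
            "noise_retest": config.seed + 3,
        },
        "stages": [],
        "outputs": {},
    }
    stage = "simulate"
    try:
        # -- stage 1: simulate -------------------------------------------
        t0 = time.time()
        logger.info("stage simulate: shape=%s noise_sd=%g", config.shape, config.noise_sd)
        if config.schedule_csv:
            params = load_schedule_csv(config.schedule_csv)
        else:
            params = default_schedule(config.n_timepoints)
        spec = default_phantom_spec(shape=config.shape)
        truth = generate_phantom_truth(spec)
        b1 = generate_b1_field(config.shape, config.b1_amplitude, seed=config.seed + 1)
        noise = AcquisitionNoise(sd=config.noise_sd)
        test, retest = generate_test_retest_pair(
            truth, b1, params, noise,
            seeds=(config.seed + 2, config.seed + 3),
            n_epg_states=config.n_epg_states,
        )
        affine = default_affine(spec.voxel_size_mm)
        for name, vol in (
            ("truth_t1", truth.t1_ms), ("truth_t2", truth.t2_ms),
            ("truth_m0", truth.m0), ("b1", b1),
        ):
            _record(manifest, write_volume(np.asarray(vol, dtype=np.float32),
                                           out / f"{name}.nii.gz", affine))
        _record(manifest, write_volume(truth.labels.astype(np.int16),
                                       out / "labels.nii.gz", affine))
        _record(manifest, write_series(test, out / "series_test.nii.gz", affine))
        _record(manifest, write_series(retest, out / "series_retest.nii.gz", affine))
        manifest["stages"].append({"name": stage, "seconds": time.time() - t0})

        # -- stage 2: dictionary -----------------------------------------
        stage = "build-dict"
        t0 = time.time()
        if config.build_dictionary:
            logger.info("stage build-dict: b1_subset=%s rank=%d", config.b1_subset, config.rank)
            grid_kwargs = {}
            if config.t1_segments is not None:
                grid_kwargs["t1_segments"] = tuple(map(tuple, config.t1_segments))
            if config.t2_segments is not None:
                grid_kwargs["t2_segments"] = tuple(map(tuple, config.t2_segments))
            grid = GridSpec(**grid_kwargs)
            dictionary = build_dictionary(
                grid, params, b1_subset=config.b1_subset,
                n_epg_states=config.n_epg_states,
            )
            comp = compress(
                dictionary,
                rank=min(config.rank, dictionary.n_entries, dictionary.n_timepoints),
            )
            dict_path = out / "dictionary.h5"
            save_dictionary(dictionary, dict_path, comp)
            _record(manifest, dict_path)
        else:
            dictionary, comp = load_dictionary(config.dictionary_path)
            if comp is None:
                comp = compress(
                    dictionary,
                    rank=min(config.rank, dictionary.n_entries, dictionary.n_timepoints),
                )
        manifest["stages"].append({"name": stage, "seconds": time.time() - t0})

        # -- stage 3: match ----------------------------------------------
        stage = "match"
        t0 = time.time()
        maps = {}
        for name, series in (("test", test), ("retest", retest)):
            logger.info("stage match: %s series %s", name, series.shape)
            pmap = match_image(series, b1, comp, voxel_size_mm=spec.voxel_size_mm)
            pmap = apply_t1_mask(pmap, config.t1_mask_threshold_ms)
            for p in write_parameter_map(pmap, out, affine, prefix=f"{name}_").values():
                _record(manifest, p)
            maps[name] = pmap
        manifest["stages"].append({"name": stage, "seconds": time.time() - t0})

        # -- stage 4: qa-report ------------------------------------------
        stage = "qa-report"
        t0 = time.time()
        rois = phantom_roi_specs(spec)
        records = []
        for repeat, pmap in maps.items():
            for unit, roi in rois:
                for metric in ("t1_ms", "t2_ms"):
                    try:
                        mean, _ = extract_roi_mean(pmap, roi, metric)
                    except ValueError:
                        continue  # fully masked vial (fat)
                    records.append(
                        dict(session_day=0, repeat=repeat, unit=unit,
                             metric=metric, value=mean)
                    )
        table = MeasurementTable.from_records(records)
        meas_path = out / "measurements.csv"
        table.to_csv(meas_path)
        _record(manifest, meas_path)

        reference = {}
        for unit, _roi in rois:
            mat_name = unit.rsplit(" #", 1)[0]
            mat = spec.materials.get(mat_name)
            if mat is not None:
                reference[unit] = {"t1_ms": mat.t1_ms, "t2_ms": mat.t2_ms}
        report = qa_report(table, reference=reference)
        report_csv = out / "qa_report.csv"
        report.to_csv(report_csv, index=False)
        _record(manifest, report_csv)
        report_json = out / "qa_report.json"
        report_json.write_text(json.dumps(report.to_dict(orient="records"), indent=2))
        _record(manifest, report_json)

        summary = region_summary(maps["test"], truth.labels)
        summary_csv = out / "region_summary.csv"
        summary.to_csv(summary_csv, index=False)
        _record(manifest, summary_csv)
        manifest["stages"].append({"name": stage, "seconds": time.time() - t0})
    except Exception as exc:  # record and re-raise with partial manifest
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.partial.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
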