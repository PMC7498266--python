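"""Pipeline orchestration: configuration, stage chaining, run manifest.

``run_pipeline`` executes the requested stages in dependency order on
synthetic data (simulate → analyze → report), writing CSV outputs plus a
JSON manifest with a config hash and per-stage output checksums so that
deterministic re-runs are verifiable byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import mapkdyn
from mapkdyn import extrusion as ext
from mapkdyn import io as mio
from mapkdyn import migration as mig
from mapkdyn import popstats, simulate, traces
from mapkdyn.errors import MapkdynError, ValidationError
from mapkdyn.params import (
    MigrationSimParams,
    PulseTrainParams,
    SustainedParams,
    WaveParams,
    ZStackSimParams,
)

STAGES = ("tracks", "traces", "migration", "extrusion", "edu", "shed")

#: config keys each stage requires
_REQUIRED_BLOCKS = {
    "tracks": ("simulate",),
    "traces": ("simulate", "peaks"),
    "migration": ("simulate", "migration"),
    "extrusion": ("extrusion",),
    "edu": ("edu",),
    "shed": ("shed",),
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (usually loaded from YAML)."""

    seed: int = 0
    outdir: str = "mapkdyn_out"
    stages: list = field(default_factory=lambda: list(STAGES))
    frame_interval_min: float = 5.0
    induction_time_min: float = 0.0
    simulate: dict = field(default_factory=dict)
    peaks: dict = field(default_factory=dict)
    migration: dict = field(default_factory=dict)
    extrusion: dict = field(default_factory=dict)
    edu: dict = field(default_factory=dict)
    shed: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        """Fail fast: every requested stage must have its config block."""
        for st in self.stages:
            if st not in STAGES:
                raise ValidationError(f"unknown stage: {st}")
            for block in _REQUIRED_BLOCKS[st]:
                if not getattr(self, block):
                    raise ValidationError(
                        f"stage '{st}' requested but config block '{block}' is empty"
                    )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        # outdir is excluded: the hash identifies the scientific run, not
        # where its files land
        payload = {k: v for k, v in self.as_dict().items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)
    failed_stage: str | None = None
    error: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _trace_params(block: dict, seed: int):
    kind = block.get("kind", "pulse")
    kwargs = {k: v for k, v in block.items() if k != "kind"}
    kwargs.setdefault("seed", seed)
    if kind == "pulse":
        return PulseTrainParams(**kwargs)
    if kind == "sustained":
        return SustainedParams(**kwargs)
    raise ValidationError(f"unknown trace kind: {kind}")


class _Runner:
    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest(cfg.config_hash, mapkdyn.__version__)
        self._table: pd.DataFrame | None = None

    def _record(self, stage: str, outputs: list[Path], rows: int,
                t0: float, extra: dict | None = None) -> None:
        entry = {
            "outputs": {p.name: _sha256(p) for p in outputs},
            "rows": rows,
            "wall_s": round(time.perf_counter() - t0, 3),
        }
        if extra:
            entry.update(extra)
        self.manifest.stages[stage] = entry

    def _write_csv(self, df: pd.DataFrame, name: str) -> Path:
        path = self.outdir / name
        with open(path, "w") as fh:
            fh.write(f"# config_hash: {self.cfg.config_hash}\n")
            df.to_csv(fh, index=False)
        return path

    # --- stages -----------------------------------------------------------

    def tracks(self) -> None:
        t0 = time.perf_counter()
        sim = self.cfg.simulate
        trace_p = _trace_params(dict(sim.get("trace", {})), self.cfg.seed)
        motion_kwargs = dict(sim.get("motion", {}))
        motion_kwargs.setdefault("seed", self.cfg.seed)
        motion_kwargs.setdefault("frame_interval_min", self.cfg.frame_interval_min)
        motion_p = MigrationSimParams(**motion_kwargs)
        wave = WaveParams(**sim["wave"]) if sim.get("wave") else None
        table, gt = simulate.simulate_track_population(trace_p, motion_p, wave)
        path = self.outdir / "tracks.csv"
        mio.write_track_table(table, path)
        gt.to_json(self.outdir / "tracks_ground_truth.json")
        self._table = table
        self._record("tracks", [path, self.outdir / "tracks_ground_truth.json"],
                     len(table), t0)

    def _load_table(self) -> pd.DataFrame:
        if self._table is None:
            path = self.outdir / "tracks.csv"
            if not path.exists():
                raise MapkdynError("traces/migration stages need the tracks stage")
            self._table = mio.read_track_table(path)
        return self._table

    def traces(self) -> None:
        t0 = time.perf_counter()
        table = self._load_table()
        pk_cfg = traces.PeakConfig(**{
            k: v for k, v in self.cfg.peaks.items()
            if k in ("smooth_window", "fit_halfwidth", "min_amplitude",
                     "min_slope", "fall_fraction")
        })
        n_frames = int(table["frame"].max()) + 1
        all_traces, rows = [], []
        for cid, grp in table.groupby("cell_id", sort=True):
            all_traces.append(traces.compute_activity_trace(grp, n_frames))
        kept, excluded = traces.clean_traces(
            all_traces, self.cfg.peaks.get("min_coverage", 2.0 / 3.0))
        for tr in kept:
            grp = table[table["cell_id"] == tr.cell_id]
            peaks = traces.count_peaks(tr, pk_cfg)
            call = traces.classify_dynamics(peaks, tr)
            loc = traces.compute_localization_trace(grp)
            rows.append({
                "cell_id": tr.cell_id,
                "population": grp["population"].iloc[0],
                "peak_count": peaks.count,
                "loc_fold": traces.localization_fold_change(loc),
                "mig_fold": traces.migration_fold_change(grp),
                "label": call.label,
                "duty_cycle": call.features["duty_cycle"],
            })
        metrics = pd.DataFrame(rows)
        summary = traces.summarize_population(kept)
        p1 = self._write_csv(metrics, "cell_metrics.csv")
        p2 = self._write_csv(summary, "population_summary.csv")
        excl = pd.DataFrame(excluded, columns=["cell_id", "reason"])
        p3 = self._write_csv(excl, "trace_exclusions.csv")
        self._record("traces", [p1, p2, p3], len(metrics), t0,
                     {"excluded": len(excluded)})

    def migration(self) -> None:
        t0 = time.perf_counter()
        table = self._load_table()
        blk = self.cfg.migration
        epochs = blk.get("epochs", {"before": [0.0, 120.0], "after": [120.0, 360.0]})
        samples = {}
        for label, (e0, e1) in epochs.items():
            samples[label] = mig.collect_angle_sample(
                table, (float(e0), float(e1)),
                condition=blk.get("condition", "synthetic"), epoch_label=label,
                interval_min=blk.get("interval_min", 20.0),
                half_width_um=blk.get("half_width_um", 100.0),
            )
        angle_rows = []
        for label, s in samples.items():
            for a in s.angles_deg:
                angle_rows.append({"condition": s.condition, "epoch": label,
                                   "angle_deg": a})
        p1 = self._write_csv(pd.DataFrame(angle_rows), "migration_angles.csv")
        labels = list(samples)
        results = []
        if len(labels) == 2:
            res = mig.subsampled_ks_test(
                samples[labels[0]], samples[labels[1]],
                n_iter=blk.get("n_iter", 1000), n_sub=blk.get("n_sub", 1000),
                seed=self.cfg.seed,
            )
            results.append({
                "pair": f"{labels[0]} vs {labels[1]}",
                "median_p": res.median_p,
                "stars": res.stars,
                "n_iterations": res.n_iterations,
                "subsample_size": res.subsample_size,
            })
        p2 = self._write_csv(pd.DataFrame(results), "migration_ks.csv")
        self._record("migration", [p1, p2], len(angle_rows), t0)

    def extrusion(self) -> None:
        t0 = time.perf_counter()
        blk = self.cfg.extrusion
        conditions = blk.get("conditions", {"parental": 0.0, "oncogenic": 6.0})
        n_rep = int(blk.get("n_replicates", 8))
        baseline_name = blk.get("baseline", "parental")
        rng = np.random.default_rng(self.cfg.seed)
        per_cond: dict[str, list[ext.ExtrusionResult]] = {}
        for cond, offset in conditions.items():
            results = []
            for rep in range(n_rep):
                params = ZStackSimParams(
                    extrusion_offset_um=float(offset),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    **{k: v for k, v in blk.get("stack", {}).items()},
                )
                stack, _ = simulate.simulate_zstack(params)
                prof_i = ext.z_intensity_histogram(
                    stack, 0, params.z_step_um, params.z_min_um, f"{cond}_{rep}")
                prof_a = ext.z_intensity_histogram(
                    stack, 1, params.z_step_um, params.z_min_um, f"{cond}_{rep}")
                dz = ext.delta_z(ext.fit_gaussian(prof_i), ext.fit_gaussian(prof_a))
                results.append(ext.ExtrusionResult(f"{cond}_{rep}", dz))
            per_cond[cond] = ext.flag_outliers(results)
        if baseline_name not in per_cond:
            raise ValidationError(f"baseline condition '{baseline_name}' not simulated")
        rows, summary = [], []
        for cond, results in per_cond.items():
            normed = ext.normalize_condition(results, per_cond[baseline_name])
            per_cond[cond] = normed
            for r in normed:
                rows.append({"condition": cond, "position": r.position_id,
                             "delta_z_um": r.delta_z_um,
                             "normalized_delta_z_um": r.normalized_delta_z_um,
                             "outlier": r.outlier})
        for cond, results in per_cond.items():
            vals = [r.normalized_delta_z_um for r in results if not r.outlier]
            entry = {"condition": cond, "mean_dz_um": float(np.mean(vals)),
                     "sd_dz_um": float(np.std(vals, ddof=1)), "n": len(vals)}
            if cond != baseline_name:
                t, p, stars = ext.compare_conditions(results, per_cond[baseline_name])
                entry.update({"t_vs_baseline": t, "p_vs_baseline": p, "stars": stars})
            summary.append(entry)
        p1 = self._write_csv(pd.DataFrame(rows), "extrusion_results.csv")
        p2 = self._write_csv(pd.DataFrame(summary), "extrusion_summary.csv")
        self._record("extrusion", [p1, p2], len(rows), t0)

    def edu(self) -> None:
        t0 = time.perf_counter()
        blk = self.cfg.edu
        table, _ = simulate.simulate_edu_table(
            n_positions=int(blk.get("n_positions", 16)),
            fractions=blk.get("fractions", {
                "neighbor": {"nodox": 0.1, "dox": 0.3},
                "parental": {"nodox": 0.1, "dox": 0.1},
            }),
            n_nuclei=blk.get("n_nuclei", 1000),
            seed=self.cfg.seed,
        )
        folds = popstats.edu_fold_table(table, blk.get("population", "neighbor"))
        p1 = self._write_csv(table, "edu_counts.csv")
        p2 = self._write_csv(folds, "edu_folds.csv")
        self._record("edu", [p1, p2], len(folds), t0)

    def shed(self) -> None:
        t0 = time.perf_counter()
        blk = self.cfg.shed
        table, _ = simulate.simulate_shed_table(
            n_proteins=int(blk.get("n_proteins", 200)),
            n_hits=int(blk.get("n_hits", 10)),
            effect_lnfc=float(blk.get("effect_lnfc", 1.0)),
            replicate_cv=float(blk.get("replicate_cv", 0.1)),
            seed=self.cfg.seed,
        )
        records = popstats.shed_records_from_abundance(table)
        filtered = popstats.filter_shed_proteins(
            records, p_max=float(blk.get("p_max", 0.05)),
            fc_min=float(blk.get("fc_min", 1.5)))
        p1 = self._write_csv(table, "shed_abundance.csv")
        p2 = self._write_csv(filtered, "shed_filtered.csv")
        self._record("shed", [p1, p2], len(filtered), t0)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages in dependency order.

    A stage failure stops downstream stages, leaves upstream outputs
    intact, and is recorded in the manifest (written regardless).
    """
    config.validate()
    runner = _Runner(config)
    order = [s for s in STAGES if s in config.stages]
    try:
        for stage in order:
            getattr(runner, stage)()
    except Exception as exc:
        runner.manifest.failed_stage = stage
        runner.manifest.error = f"{type(exc).__name__}: {exc}"
        runner.manifest.to_json(runner.outdir / "manifest.json")
        raise
    runner.manifest.to_json(runner.outdir / "manifest.json")
    return runner.manifest
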