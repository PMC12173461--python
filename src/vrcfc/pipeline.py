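"""End-to-end orchestration: simulate -> analyze -> stats -> report.

A single ``RunConfig`` holds every tunable and every seed; the manifest
written next to the outputs records the config hash, seeds and package
version so that a deterministic run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import write_session
from .placecells import detect_place_fields, bin_activity, place_cell_fraction
from .remapping import (
    across_session_correlation,
    compare_field_populations,
    split_half_correlations,
)
from .simulate.behavior import cohort_freezing_table, simulate_cohort
from .simulate.calcium import CalciumSimParams, simulate_two_sessions
from .stats import cohens_d_paired, fit_lme_freezing, ks_two_sample, paired_test

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _json_safe(obj):
    """Recursively map non-finite floats to None for strict JSON."""
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(obj) if np.isfinite(obj) else None
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


@dataclass
class RunConfig:
    """Configuration of one full synthetic run.

    ``n_bins * bin_width_cm`` must equal ``track_length_cm``; every
    source of randomness flows from ``seed`` (behavior), ``seed + 1``
    (imaging) and ``seed + 2`` (field detection bootstrap).
    """

    out_dir: str = "vrcfc_run"
    paradigm: int = 1
    n_mice: int = 12
    seed: int = 0
    epsilon: float = 0.0  # cm/s freezing tolerance
    min_epoch_s: float = 1.0
    n_bins: int = 40
    bin_width_cm: float = 5.0
    track_length_cm: float = 200.0
    speed_threshold: float = 1.0
    n_shuffles: int = 1000
    n_recall_days: int = 1
    effect: float = 8.0
    imaging: bool = True
    imaging_n_cells: int = 100
    remap_fraction: float = 0.3
    width_scale_session2: float = 0.8
    write_sessions: bool = False
    make_plots: bool = True

    def validate(self) -> None:
        if abs(self.n_bins * self.bin_width_cm - self.track_length_cm) > 1e-9:
            raise ValueError(
                f"n_bins ({self.n_bins}) x bin_width_cm ({self.bin_width_cm}) "
                f"must equal the track length ({self.track_length_cm} cm)"
            )
        if self.paradigm not in (1, 2, 3):
            raise ValueError(f"unknown paradigm {self.paradigm}")
        if self.n_mice < 2:
            raise ValueError("n_mice must be >= 2")

    def config_hash(self) -> str:
        # the hash fingerprints the analysis, not where it is written
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - stage attribution
                raise PipelineError(f"stage {name!r} failed: {err}") from err
        return wrapper
    return deco


@_stage("behavior")
def _behavior_stage(cfg: RunConfig, out: Path) -> pd.DataFrame:
    from .simulate.behavior import BehaviorSimCohortParams

    cohort = simulate_cohort(
        cfg.paradigm, cfg.n_mice, seed=cfg.seed,
        params=BehaviorSimCohortParams(
            effect=cfg.effect, n_recall_days=cfg.n_recall_days,
        ),
    )
    if cfg.write_sessions:
        ses_dir = out / "sessions"
        ses_dir.mkdir(exist_ok=True)
        for cs in cohort:
            name = f"m{cs.mouse:02d}_day{cs.day}_{cs.context_role}.csv"
            write_session(cs.session, ses_dir / name)
    table = cohort_freezing_table(cohort, epsilon=cfg.epsilon)
    table.to_csv(out / "freezing_table.csv", index=False)
    return table


@_stage("stats")
def _stats_stage(cfg: RunConfig, out: Path, table: pd.DataFrame) -> dict:
    results: dict = {}
    for metric in ("first_lap", "average"):
        sub = table[(table["day"] == "Recall1") & (table["metric"] == metric)]
        wide = sub.pivot(index="mouse_id", columns="vr_context",
                         values="freezing_pct").dropna()
        res = paired_test(wide["neutral"], wide["cfc"])
        results[metric] = {
            "neutral_mean": float(wide["neutral"].mean()),
            "cfc_mean": float(wide["cfc"].mean()),
            "delta": res.mean_diff,
            "t": res.t,
            "p": res.p,
            "ci": [res.ci_low, res.ci_high],
            "cohens_d": cohens_d_paired(wide["neutral"], wide["cfc"]),
            "n": res.n,
        }
    if cfg.n_recall_days >= 2:
        results["lme"] = {}
        for context in ("neutral", "cfc"):
            fit = fit_lme_freezing(table, context, metric="average")
            results["lme"][context] = fit.days.to_dict(orient="records")
    with open(out / "behavior_stats.json", "w") as fh:
        json.dump(_json_safe(results), fh, indent=2)
    return results


@_stage("placecells")
def _imaging_stage(cfg: RunConfig, out: Path) -> dict:
    params = CalciumSimParams(n_cells=cfg.imaging_n_cells,
                              n_bins=cfg.n_bins,
                              speed_threshold=cfg.speed_threshold)
    sim = simulate_two_sessions(
        params, cfg.remap_fraction, cfg.width_scale_session2,
        seed=cfg.seed + 1,
    )
    results: dict = {}
    fields = {}
    sams = {}
    for key, traces, laps in (
        ("a", sim.traces_a, sim.laps_a), ("b", sim.traces_b, sim.laps_b)
    ):
        sam = bin_activity(traces, laps, cfg.n_bins, cfg.speed_threshold)
        det = detect_place_fields(
            traces, laps, sam=sam, n_shuffles=cfg.n_shuffles,
            seed=cfg.seed + 2,
        )
        det.fields.to_csv(out / f"fields_{key}.csv", index=False)
        fields[key] = det
        sams[key] = sam
        results[f"place_cell_fraction_{key}"] = place_cell_fraction(det)
    within = split_half_correlations(sams["a"])
    across = across_session_correlation(
        sams["a"], sams["b"], sim.match, fields_a=fields["a"].fields
    )
    stability = pd.DataFrame(
        {"cell_id": sams["a"].cell_ids, "r_within": within}
    ).merge(
        across.rename(columns={"cell_id_a": "cell_id", "r": "r_across"}),
        on="cell_id", how="left",
    )
    stability.to_csv(out / "stability.csv", index=False)
    holders = np.isin(
        np.asarray(sams["a"].cell_ids),
        fields["a"].fields["cell_id"].unique(),
    )
    w = within[holders & np.isfinite(within)]
    x = across["r"].dropna().to_numpy()
    if w.size and x.size:
        ks_stat, ks_p = ks_two_sample(x, w)
        results["across_vs_within_ks"] = {"stat": ks_stat, "p": ks_p}
    comp = compare_field_populations(
        fields["a"].fields, fields["b"].fields,
        n_cells_a=fields["a"].n_cells, n_cells_b=fields["b"].n_cells,
    )
    results["population_comparison"] = comp.summary.to_dict(orient="records")
    results["narrowing"] = comp.narrowing
    results["fraction_increase"] = comp.fraction_increase
    with open(out / "remap_summary.json", "w") as fh:
        json.dump(_json_safe(results), fh, indent=2)
    return {"results": results, "fields": fields, "table": stability}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a run manifest.

    Returns the in-memory report bundle; all randomness derives from
    the named seeds, so re-running with the same config reproduces the
    deterministic outputs byte-for-byte.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}
    table = _behavior_stage(config, out)
    bundle["freezing_table"] = table
    bundle["behavior_stats"] = _stats_stage(config, out, table)
    if config.imaging:
        imaging = _imaging_stage(config, out)
        bundle["imaging"] = imaging["results"]
        if config.make_plots:
            from .plots import paired_freezing_plot, width_boxplot

            paired_freezing_plot(
                table, "Recall1", "average", out / "freezing_recall1.png"
            )
            width_boxplot(
                imaging["fields"]["a"].fields, imaging["fields"]["b"].fields,
                out / "field_widths.png",
            )
    manifest = {
        "package": "vrcfc",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seeds": {
            "behavior": config.seed,
            "imaging": config.seed + 1,
            "detection": config.seed + 2,
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle
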