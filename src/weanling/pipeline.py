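"""End-to-end orchestration: QC -> temporal model -> cessation -> mixing.

Each stage writes its outputs as CSV/JSON under the run directory and the
next stage consumes only those declared artifacts (per-bin posterior
means, never internal state), so a run is resumable and auditable.  All
randomness is derived from the single config seed, and every output file
carries the config hash in a leading ``#`` comment line, so reruns with an
identical config reproduce every table byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import changepoint, mixing, profile_io, tooth_time
from ._mcmc import derive_seed

__all__ = [
    "RunConfig",
    "PipelineError",
    "load_config",
    "run_pipeline",
    "summarize_sites",
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and individual id."""

    def __init__(self, stage: str, individual: str | None, cause: Exception):
        self.stage = stage
        self.individual = individual
        who = f" (individual {individual!r})" if individual else ""
        super().__init__(f"stage {stage!r}{who} failed: {cause}")
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    increments_csv: str
    out_dir: str
    seed: int = 1
    sources_csv: str | None = None
    source_preset: str | None = None
    schema: dict = field(default_factory=dict)
    growth: tooth_time.GrowthModel = field(default_factory=tooth_time.default_growth)
    qc: profile_io.QCCriteria = field(default_factory=profile_io.QCCriteria)
    grid: tooth_time.AgeGrid = field(default_factory=tooth_time.AgeGrid)
    threshold: float = 2.0
    run_mixing: bool = False
    milk_exclusive_until: float = 0.5
    temporal_kwargs: dict = field(default_factory=dict)
    changepoint_kwargs: dict = field(default_factory=dict)
    mixing_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")

    def validate_paths(self) -> None:
        if not Path(self.increments_csv).exists():
            raise FileNotFoundError(self.increments_csv)
        if self.sources_csv and not Path(self.sources_csv).exists():
            raise FileNotFoundError(self.sources_csv)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths under which outputs
        are written do not affect results and are excluded)."""

        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in sorted(obj.items())}
            return obj

        payload = enc(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode("utf8")).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "growth" in kwargs:
        kwargs["growth"] = tooth_time.GrowthModel(
            tuple(tuple(p) for p in kwargs["growth"])
        )
    if "qc" in kwargs:
        kwargs["qc"] = profile_io.QCCriteria(**kwargs["qc"])
    if "grid" in kwargs:
        kwargs["grid"] = tooth_time.AgeGrid(**kwargs["grid"])
    cfg = RunConfig(**kwargs)
    cfg.validate_paths()
    return cfg


def summarize_sites(cessation: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Per-site counts and fractions of cessation-age classifications.

    Expects the cessation table (individual_id, site, status, median,
    category columns).  Fractions are of the individuals with an estimated
    cessation age and are null when none was estimated at a site.
    """
    if len(cessation) == 0:
        raise ValueError("cessation table is empty")
    rows = []
    for site, grp in cessation.groupby("site", sort=True):
        est = grp[grp["status"] == "estimated"]
        n_est = len(est)
        counts = {
            c: int((est["category"] == c).sum())
            for c in ("above", "below", "straddling")
        }
        row = {
            "site": site,
            "n_individuals": len(grp),
            "n_estimated": n_est,
            "n_none": int((grp["status"] != "estimated").sum()),
            **{f"n_{c}": v for c, v in counts.items()},
            **{
                f"frac_{c}": (v / n_est if n_est else np.nan)
                for c, v in counts.items()
            },
            "min_median": est["median"].min() if n_est else np.nan,
            "max_median": est["median"].max() if n_est else np.nan,
            "threshold": threshold,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def _temporal_stage(profile, cfg, seed):
    """Fit both isotope series for one individual; return long table + draws."""
    aged = tooth_time.assign_increment_ages(profile, cfg.growth)
    W = tooth_time.build_overlap_matrix(
        aged[["age_start", "age_end"]].to_numpy(), cfg.grid
    )
    frames = {}
    for isotope in ("d15N", "d13C"):
        tp = tooth_time.fit_temporal_model(
            aged[isotope].to_numpy(),
            W,
            seed=derive_seed(seed, "temporal", isotope),
            isotope=isotope,
            grid=cfg.grid,
            **cfg.temporal_kwargs,
        )
        frames[isotope] = tp
    return frames


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the in-memory outputs and writes files.

    Outputs under ``cfg.out_dir``: qc_increments.csv, qc_individuals.csv,
    qc_summary.json, temporal.csv, cessation.csv, ranking.csv, diet.csv
    (when mixing is enabled), site_summary.csv and run_log.json.
    """
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"weanling run config={cfg.config_hash()} seed={cfg.seed}"
    log: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "threshold": cfg.threshold,
        "qc": cfg.qc.__dict__,
        "growth_control_points": list(cfg.growth.control_points),
        "grid": {
            "age_min": cfg.grid.age_min,
            "age_max": cfg.grid.age_max,
            "width": cfg.grid.width,
        },
        "stages": [],
        "individuals": {},
    }

    # --- QC -------------------------------------------------------------
    try:
        increments = profile_io.read_increments(cfg.increments_csv, cfg.schema)
        report = profile_io.qc_filter(increments, cfg.qc)
    except Exception as err:  # noqa: BLE001 - stage boundary
        raise PipelineError("qc", None, err) from err
    profile_io.write_table(report.increments, out / "qc_increments.csv", tag)
    profile_io.write_table(report.individuals, out / "qc_individuals.csv", tag)
    with open(out / "qc_summary.json", "w") as fh:
        json.dump({"config_hash": cfg.config_hash(), **report.summary()}, fh,
                  indent=2)
    log["stages"].append("qc")
    retained = report.retained_ids

    # --- Temporal model -------------------------------------------------
    temporal_frames = []
    profiles = {}
    for ind in retained:
        profile = increments[increments["individual_id"] == ind]
        # drop individual increments that failed QC inside a retained profile
        flags = report.increments
        ok_idx = flags.loc[
            (flags["individual_id"] == ind) & flags["qc_pass"], "increment_index"
        ]
        profile = profile[profile["increment_index"].isin(ok_idx)]
        try:
            frames = _temporal_stage(profile, cfg, derive_seed(cfg.seed, ind))
        except Exception as err:  # noqa: BLE001
            raise PipelineError("temporal", ind, err) from err
        profiles[ind] = frames
        site = profile["site"].iat[0]
        for tp in frames.values():
            df = tp.to_frame(ind)
            df.insert(1, "site", site)
            temporal_frames.append(df)
    temporal = pd.concat(temporal_frames, ignore_index=True)
    profile_io.write_table(temporal, out / "temporal.csv", tag)
    log["stages"].append("temporal")

    # --- Cessation change-point ----------------------------------------
    cess_rows, rank_frames = [], []
    estimates = {}
    for ind in retained:
        tp = profiles[ind]["d15N"]
        mids = tp.grid.mids[tp.observed]
        means = tp.mean[tp.observed]
        cp_kwargs = {"bin_width": tp.grid.width, **cfg.changepoint_kwargs}
        try:
            est, table = changepoint.estimate_cessation(
                mids, means, seed=derive_seed(cfg.seed, ind, "cess"), **cp_kwargs
            )
        except Exception as err:  # noqa: BLE001
            raise PipelineError("cessation", ind, err) from err
        estimates[ind] = est
        category = changepoint.classify_vs_threshold(est, cfg.threshold)
        site = increments.loc[
            increments["individual_id"] == ind, "site"
        ].iat[0]
        cess_rows.append(
            {
                "individual_id": ind,
                "site": site,
                "status": est.status,
                "median": est.median,
                "ci68_lo": est.ci68[0],
                "ci68_hi": est.ci68[1],
                "ci95_lo": est.ci95[0],
                "ci95_hi": est.ci95[1],
                "selected_spec": est.selected_spec.label
                if est.selected_spec
                else "",
                "prob_neg_slope1": est.prob_neg_slope1,
                "category": category,
            }
        )
        table = table.copy()
        table.insert(0, "individual_id", ind)
        rank_frames.append(table)
        log["individuals"][ind] = {
            "selected_spec": est.selected_spec.label if est.selected_spec else None,
            "status": est.status,
            "category": category,
        }
    cessation = pd.DataFrame(cess_rows)
    profile_io.write_table(cessation, out / "cessation.csv", tag)
    if rank_frames:
        profile_io.write_table(
            pd.concat(rank_frames, ignore_index=True), out / "ranking.csv", tag
        )
    log["stages"].append("cessation")

    # --- Dietary mixing (optional) --------------------------------------
    diet = None
    if cfg.run_mixing:
        if cfg.sources_csv:
            sources = mixing.read_sources(cfg.sources_csv)
        else:
            sources = mixing.default_source_table(
                cfg.source_preset or "roman_italy_demo"
            )
        diet_frames = []
        for ind in retained:
            est = estimates[ind]
            if est.status != "estimated":
                log["individuals"][ind]["mixing"] = "skipped (no cessation age)"
                continue
            frames = profiles[ind]
            obs = frames["d15N"].observed & frames["d13C"].observed
            grid = frames["d15N"].grid
            bins = np.column_stack([grid.starts[obs], grid.ends[obs]])
            consumer = pd.DataFrame(
                {
                    "bin_start": bins[:, 0],
                    "bin_end": bins[:, 1],
                    "d13C": frames["d13C"].mean[obs],
                    "d15N": frames["d15N"].mean[obs],
                }
            )
            constraints = mixing.MixingConstraints(
                cessation_age=est.median,
                milk_exclusive_until=cfg.milk_exclusive_until,
            )
            src = sources
            if not np.any(bins[:, 0] < est.median):
                src = sources[sources["name"] != constraints.milk_source]
            try:
                model = mixing.build_mixing_model(src, constraints, bins)
                fitres = mixing.fit_mixing(
                    model,
                    consumer,
                    seed=derive_seed(cfg.seed, ind, "mix"),
                    **cfg.mixing_kwargs,
                )
            except Exception as err:  # noqa: BLE001
                raise PipelineError("mixing", ind, err) from err
            diet_frames.append(fitres.summary(ind))
        if diet_frames:
            diet = pd.concat(diet_frames, ignore_index=True)
            profile_io.write_table(diet, out / "diet.csv", tag)
        log["stages"].append("mixing")

    # --- Site summary ---------------------------------------------------
    summary = summarize_sites(cessation, cfg.threshold)
    profile_io.write_table(summary, out / "site_summary.csv", tag)
    log["stages"].append("summary")
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)

    return {
        "qc": report,
        "temporal": temporal,
        "cessation": cessation,
        "diet": diet,
        "site_summary": summary,
        "log": log,
    }
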