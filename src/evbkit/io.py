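"""Trajectory tables, run configuration, manifests, and the full pipeline.

The interchange format is a plain tab-separated trajectory table, one file
per (temperature, replicate):

    # evbkit trajectory table; x: angstrom; U1, U2raw: kcal/mol; temperature: kelvin
    frame   lambda  temperature     x       U1      U2raw
    0       0.0     300.0           ...

U2raw is the raw product force-field energy; the gas-phase shift delta_alpha
is applied at analysis time, so the same tables can be re-analysed under any
(h12, delta_alpha).
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import EVBParameters
from .exceptions import InvalidInputError, TrajectoryParseError
from .free_energy import (
    BinSpec,
    extract_stationary_points,
    gap_profile,
    reweight_profile,
    zwanzig_accumulate,
)
from .simulate import (
    HarmonicDiabatModel,
    SamplingSpec,
    TrajectoryDataset,
    TrajectoryWindow,
    generate_dataset,
    subseed,
)
from .thermo import ArrheniusSeries, arrhenius_fit, replicate_statistics

logger = logging.getLogger("evbkit")

TRAJ_COLUMNS = ["frame", "lambda", "temperature", "x", "U1", "U2raw"]
_TRAJ_HEADER_COMMENT = (
    "# evbkit trajectory table; x: angstrom; U1, U2raw: kcal/mol; "
    "temperature: kelvin"
)
_FLOAT_FMT = "%.10g"


def _traj_filename(temperature: float, replicate: int) -> str:
    return f"traj_T{temperature:g}K_rep{replicate}.tsv"


def write_trajectory_tables(dataset: TrajectoryDataset, out_dir) -> list:
    """Write one tab-separated trajectory table per (temperature, replicate)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for temp in dataset.temperatures:
        for rep in dataset.replicates:
            windows = dataset.select(temperature=temp, replicate=rep)
            if not windows:
                continue
            frames = []
            for w in windows:
                frames.append(
                    pd.DataFrame(
                        {
                            "frame": np.arange(w.n_frames),
                            "lambda": w.lambda_m,
                            "temperature": w.temperature,
                            "x": w.x,
                            "U1": w.u1,
                            "U2raw": w.u2_raw,
                        }
                    )
                )
            table = pd.concat(frames, ignore_index=True)
            path = out_dir / _traj_filename(temp, rep)
            with open(path, "w") as fh:
                fh.write(_TRAJ_HEADER_COMMENT + "\n")
                table.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)
            paths.append(path)
    return paths


def read_trajectory_tables(paths) -> TrajectoryDataset:
    """Read and validate trajectory tables into a :class:`TrajectoryDataset`.

    Windows are grouped by (lambda, temperature, replicate); the replicate
    label is parsed from a ``rep<N>`` token in the filename, falling back to
    the file's position in ``paths``. Malformed rows (NaN energies,
    non-monotone frame indices) raise :class:`TrajectoryParseError` naming
    the file and line.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    windows = []
    for fi, path in enumerate(paths):
        path = Path(path)
        with open(path) as fh:
            lines = fh.readlines()
        n_comment = 0
        while n_comment < len(lines) and lines[n_comment].startswith("#"):
            n_comment += 1
        if n_comment >= len(lines):
            raise TrajectoryParseError(f"{path}: no header row found")
        header = lines[n_comment].rstrip("\n").split("\t")
        if header != TRAJ_COLUMNS:
            raise TrajectoryParseError(
                f"{path}, line {n_comment + 1}: header mismatch, expected "
                f"{TRAJ_COLUMNS}, got {header}"
            )
        df = pd.read_csv(path, sep="\t", comment="#")
        data_offset = n_comment + 2  # 1-based line of the first data row
        bad = np.flatnonzero(df[["x", "U1", "U2raw"]].isna().any(axis=1).to_numpy())
        if bad.size:
            raise TrajectoryParseError(
                f"{path}, line {bad[0] + data_offset}: non-finite energy value"
            )
        m = re.search(r"rep(\d+)", path.name)
        replicate = int(m.group(1)) if m else fi
        for (lam, temp), group in df.groupby(["lambda", "temperature"], sort=True):
            frame_idx = group["frame"].to_numpy()
            if np.any(np.diff(frame_idx) <= 0):
                row = int(group.index[np.argmin(np.diff(frame_idx))])
                raise TrajectoryParseError(
                    f"{path}, line {row + data_offset}: non-monotone frame index "
                    f"in window lambda={lam}"
                )
            windows.append(
                TrajectoryWindow(
                    lambda_m=float(lam),
                    temperature=float(temp),
                    x=group["x"].to_numpy(),
                    u1=group["U1"].to_numpy(),
                    u2_raw=group["U2raw"].to_numpy(),
                    replicate=replicate,
                )
            )
    return TrajectoryDataset(windows)


@dataclass
class RunConfig:
    """Resolved configuration of a full run; round-trips losslessly via YAML."""

    model: HarmonicDiabatModel = field(
        default_factory=lambda: HarmonicDiabatModel.symmetric()
    )
    sampling: SamplingSpec = field(default_factory=SamplingSpec)
    bins: BinSpec = field(default_factory=BinSpec)
    evb: Optional[EVBParameters] = None  # analysis parameters; default = model's
    t_ref: float = 300.0
    arrhenius_mode: str = "auto"
    perturbations: tuple = ()  # sequence of (dh12, ddelta_alpha) pairs
    log_level: str = "INFO"

    @property
    def analysis_parameters(self) -> EVBParameters:
        return self.evb if self.evb is not None else self.model.parameters

    def to_dict(self) -> dict:
        d = {
            "model": asdict(self.model),
            "sampling": {
                **asdict(self.sampling),
                "lambda_schedule": list(self.sampling.lambda_schedule),
                "temperatures": list(self.sampling.temperatures),
            },
            "bins": {
                "n_bins": self.bins.n_bins,
                "gap_range": list(self.bins.gap_range) if self.bins.gap_range else None,
                "min_frames": self.bins.min_frames,
            },
            "evb": asdict(self.evb) if self.evb is not None else None,
            "t_ref": self.t_ref,
            "arrhenius_mode": self.arrhenius_mode,
            "perturbations": [list(p) for p in self.perturbations],
            "log_level": self.log_level,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sampling = dict(d["sampling"])
        sampling["lambda_schedule"] = tuple(sampling["lambda_schedule"])
        sampling["temperatures"] = tuple(sampling["temperatures"])
        b = d["bins"]
        return cls(
            model=HarmonicDiabatModel(**d["model"]),
            sampling=SamplingSpec(**sampling),
            bins=BinSpec(
                n_bins=b["n_bins"],
                gap_range=tuple(b["gap_range"]) if b["gap_range"] else None,
                min_frames=b["min_frames"],
            ),
            evb=EVBParameters(**d["evb"]) if d.get("evb") else None,
            t_ref=d.get("t_ref", 300.0),
            arrhenius_mode=d.get("arrhenius_mode", "auto"),
            perturbations=tuple(tuple(p) for p in d.get("perturbations", [])),
            log_level=d.get("log_level", "INFO"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance of a run: tool version, timestamp, input hashes, sub-seeds."""

    version: str
    created: str
    seed: int
    input_hashes: dict
    subseeds: list

    @classmethod
    def for_run(cls, config: RunConfig, input_paths=()) -> "RunManifest":
        spec = config.sampling
        table = [
            {
                "temperature": temp,
                "replicate": ri,
                "lambda": lam,
                "spawn_key": [ti, ri, li],
            }
            for ti, temp in enumerate(spec.temperatures)
            for ri in range(spec.n_replicates)
            for li, lam in enumerate(spec.lambda_schedule)
        ]
        return cls(
            version=__version__,
            created=time.strftime("%Y-%m-%dT%H:%M:%S"),
            seed=spec.seed,
            input_hashes={str(p): _sha256(p) for p in input_paths},
            subseeds=table,
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def write_profile_table(profile, path) -> None:
    """Write a gap profile as tab-separated text with a units comment line."""
    df = profile.to_frame()
    with open(path, "w") as fh:
        fh.write(
            "# evbkit free-energy profile; coordinate: "
            f"{profile.coordinate}; energies: kcal/mol; T = {profile.temperature} K; "
            f"h12 = {profile.parameters.h12}, delta_alpha = "
            f"{profile.parameters.delta_alpha}; mode = {profile.mode}\n"
        )
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


@dataclass
class PipelineResult:
    """Everything a full pipeline run produced."""

    dataset: TrajectoryDataset
    summaries: "pd.DataFrame"
    replicate_stats: "pd.DataFrame"
    activation: Optional[object]
    perturbation_table: Optional["pd.DataFrame"]
    output_dir: Path


def run_pipeline(config: RunConfig, out_dir, seed: Optional[int] = None) -> PipelineResult:
    """simulate -> profile per (T, replicate) -> replicate stats -> Arrhenius.

    Writes trajectories, profiles, a summary table, replicate statistics, the
    Arrhenius report, the resolved config and a manifest under ``out_dir``.
    An optional perturbation sweep re-analyses the same trajectories under
    shifted (h12, delta_alpha) and repeats the Arrhenius fit for each shift.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config.sampling = config.sampling.with_(seed=seed)
    par = config.analysis_parameters
    spec = config.sampling

    t0 = time.perf_counter()
    logger.info("stage simulate: %d windows", len(spec.temperatures)
                * spec.n_replicates * len(spec.lambda_schedule))
    dataset = generate_dataset(config.model, spec, out_dir=out_dir / "trajectories")
    logger.info("stage simulate done in %.1fs", time.perf_counter() - t0)

    config.to_yaml(out_dir / "config.yaml")
    RunManifest.for_run(config).write(out_dir / "manifest.json")

    t0 = time.perf_counter()
    rows = []
    for temp in spec.temperatures:
        for rep in range(spec.n_replicates):
            windows = dataset.select(temperature=temp, replicate=rep)
            profile = gap_profile(windows, par, bins=config.bins)
            summary = extract_stationary_points(profile)
            write_profile_table(
                profile, out_dir / f"profile_T{temp:g}K_rep{rep}.tsv"
            )
            rows.append(
                {
                    "temperature": temp,
                    "replicate": rep,
                    "dg_act": summary.dg_act,
                    "dg_rxn": summary.dg_rxn,
                    "ts_c2_sq": summary.ts_weights.c2_sq
                    if summary.ts_weights
                    else np.nan,
                }
            )
    summaries = pd.DataFrame(rows)
    with open(out_dir / "summaries.tsv", "w") as fh:
        fh.write("# evbkit profile summaries; dg_act, dg_rxn: kcal/mol; "
                 "temperature: kelvin\n")
        summaries.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)
    logger.info("stage profile done in %.1fs", time.perf_counter() - t0)

    stats_rows = []
    for temp, group in summaries.groupby("temperature"):
        if len(group) >= 2:
            mean, sem = replicate_statistics(group["dg_act"].to_numpy())
        else:
            mean, sem = float(group["dg_act"].iloc[0]), 0.0
        stats_rows.append(
            {"temperature": temp, "dg_act_mean": mean, "dg_act_sem": sem,
             "n_replicates": len(group)}
        )
    replicate_stats = pd.DataFrame(stats_rows)
    with open(out_dir / "replicate_stats.tsv", "w") as fh:
        fh.write("# evbkit replicate statistics; energies kcal/mol\n")
        replicate_stats.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)

    activation = None
    if len(spec.temperatures) >= 3:
        series = ArrheniusSeries(
            replicate_stats["temperature"].to_numpy(),
            replicate_stats["dg_act_mean"].to_numpy(),
            sem=replicate_stats["dg_act_sem"].to_numpy(),
            n_replicates=spec.n_replicates,
        )
        activation = arrhenius_fit(series, mode=config.arrhenius_mode,
                                   t_ref=config.t_ref)
        report = {
            "mode": activation.mode,
            "dh": activation.dh,
            "ds": activation.ds,
            "tds_at_t_ref": activation.tds_at,
            "t_ref": activation.t_ref,
            "se_dh": activation.se_dh,
            "se_ds": activation.se_ds,
            "r_squared": activation.r_squared,
            "dg_table": stats_rows,
        }
        with open(out_dir / "arrhenius.json", "w") as fh:
            json.dump(report, fh, indent=2)
        logger.info(
            "Arrhenius (%s): dH = %.3f, T dS(%g K) = %.3f kcal/mol, R^2 = %.4f",
            activation.mode, activation.dh, activation.t_ref,
            activation.tds_at, activation.r_squared,
        )
    else:
        raise InvalidInputError(
            "Arrhenius stage needs at least 3 temperatures; "
            f"config has {len(spec.temperatures)}"
        )

    perturbation_table = None
    if config.perturbations:
        t0 = time.perf_counter()
        prows = []
        for dh12, ddalpha in config.perturbations:
            par_new = par.shifted(dh12, ddalpha)
            per_t = []
            for temp in spec.temperatures:
                vals = []
                for rep in range(spec.n_replicates):
                    windows = dataset.select(temperature=temp, replicate=rep)
                    _, s = reweight_profile(windows, par, par_new, bins=config.bins)
                    vals.append(s.dg_act)
                per_t.append(np.mean(vals))
            fit = arrhenius_fit(
                ArrheniusSeries(np.asarray(spec.temperatures, dtype=float),
                                np.asarray(per_t)),
                mode=config.arrhenius_mode, t_ref=config.t_ref,
            )
            prows.append(
                {"dh12": dh12, "ddelta_alpha": ddalpha,
                 "dg_act_tref": fit.dg(config.t_ref),
                 "dh": fit.dh, "tds": fit.tds_at, "r_squared": fit.r_squared}
            )
        perturbation_table = pd.DataFrame(prows)
        with open(out_dir / "perturbations.tsv", "w") as fh:
            fh.write("# evbkit parameter-perturbation sweep; energies kcal/mol\n")
            perturbation_table.to_csv(fh, sep="\t", index=False,
                                      float_format=_FLOAT_FMT)
        logger.info("stage reweight sweep done in %.1fs", time.perf_counter() - t0)

    return PipelineResult(
        dataset=dataset,
        summaries=summaries,
        replicate_stats=replicate_stats,
        activation=activation,
        perturbation_table=perturbation_table,
        output_dir=out_dir,
    )
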