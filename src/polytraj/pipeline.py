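"""End-to-end multi-temperature analysis driven by a YAML config.

Reads a topology + replicate trajectories per temperature, runs every
configured analysis stage (Rg distributions, chain extension, side-chain
lengths, solvation RDFs with the crossing temperature, hydrogen bonds) and
writes one TSV artifact per table schema, each with a provenance header.
Replicates are averaged at the level of derived statistics, never raw
coordinates.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chain_metrics import (
    RgSeries,
    chain_extension_stats,
    rg_distribution,
    rg_series,
    side_chain_lengths,
    side_chain_temperature_stats,
    temperature_average,
)
from .hydrogen_bonds import HBondCriteria, hbond_averages, intrapolymer_hbonds
from .solvation_rdf import (
    average_rdfs,
    crossing_temperature,
    peak_intensity_curve,
    rdf,
)
from .trajectory_io import Trajectory, assign_roles, read_pdb, read_xyz_multi, select

__all__ = ["RunConfig", "TemperatureInput", "SummaryReport", "PipelineError",
           "load_config", "run_pipeline"]

log = logging.getLogger("polytraj.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage, partial artifacts remain."""


@dataclass
class TemperatureInput:
    temperature: float
    topology: Path
    trajectories: list
    box: list | None = None


@dataclass
class RunConfig:
    temperatures: list  # list[TemperatureInput]
    role_map: Path
    output_dir: Path
    seed: int = 0
    tclp: float | None = None  # experimental cloud point (K), external constant
    dr: float = 0.1
    r_window: tuple = (2.0, 5.5)
    rg_bin_width: float = 0.1
    lmax_mode: str = "sum_of_bonds"
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    rdf_average: str = "g_first"  # or "peak_first"
    defaults_applied: list = field(default_factory=list)

    def validate(self) -> None:
        if not self.temperatures:
            raise ValueError("config needs at least one temperature")
        missing = []
        for t in self.temperatures:
            if not Path(t.topology).is_file():
                missing.append(str(t.topology))
            for p in t.trajectories:
                if not Path(p).is_file():
                    missing.append(str(p))
        if not Path(self.role_map).is_file():
            missing.append(str(self.role_map))
        if missing:
            raise ValueError(f"configured paths do not exist: {missing}")
        if self.rdf_average not in ("g_first", "peak_first"):
            raise ValueError(f"unknown rdf_average mode: {self.rdf_average!r}")


@dataclass
class SummaryReport:
    artifacts: dict  # stage name -> Path
    skips: list  # (stage name, reason)
    tcrp: float | None = None
    tclp: float | None = None


_DEFAULTS = {
    "seed": 0,
    "dr": 0.1,
    "r_window": (2.0, 5.5),
    "rg_bin_width": 0.1,
    "lmax_mode": "sum_of_bonds",
    "rdf_average": "g_first",
    "tclp": None,
}


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Relative data paths are resolved against the config file's directory.
    Defaults that were not explicitly set are recorded so the run log can
    audit them.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent
    temps = []
    for entry in raw.get("temperatures", []):
        temps.append(
            TemperatureInput(
                temperature=float(entry["temperature"]),
                topology=base / entry["topology"],
                trajectories=[base / p for p in entry["trajectories"]],
                box=entry.get("box"),
            )
        )
    defaults_applied = [k for k in _DEFAULTS if k not in raw]
    hb = raw.get("hbond", {})
    if not hb:
        defaults_applied.append("hbond")
    cfg = RunConfig(
        temperatures=temps,
        role_map=base / raw["role_map"],
        output_dir=base / raw.get("output_dir", "polytraj_out"),
        seed=int(raw.get("seed", _DEFAULTS["seed"])),
        tclp=raw.get("tclp", None),
        dr=float(raw.get("dr", _DEFAULTS["dr"])),
        r_window=tuple(raw.get("r_window", _DEFAULTS["r_window"])),
        rg_bin_width=float(raw.get("rg_bin_width", _DEFAULTS["rg_bin_width"])),
        lmax_mode=raw.get("lmax_mode", _DEFAULTS["lmax_mode"]),
        hbond=HBondCriteria(
            d_max=float(hb.get("d_max", 3.5)),
            angle_min=float(hb.get("angle_min", 150.0)),
        ),
        rdf_average=raw.get("rdf_average", _DEFAULTS["rdf_average"]),
        defaults_applied=sorted(defaults_applied),
    )
    cfg.validate()
    return cfg


def _load_role_map(path: Path) -> list:
    raw = yaml.safe_load(Path(path).read_text())
    return raw["roles"] if isinstance(raw, dict) else raw


def _load_replicates(entry: TemperatureInput, role_rules, role_meta) -> list:
    topo, first = read_pdb(entry.topology)
    topo = assign_roles(topo, role_rules)
    box = entry.box
    if box is None and isinstance(role_meta, dict):
        box = role_meta.get("box")
    if box is None and first.box is not None:
        box = first.box
    replicates = []
    for traj_path in entry.trajectories:
        frames = read_xyz_multi(traj_path, box=box)
        replicates.append(
            Trajectory(topology=topo, frames=frames, temperature=entry.temperature)
        )
    return replicates


def _config_hash(config: RunConfig) -> str:
    digest = hashlib.sha256(repr(config).encode()).hexdigest()
    return digest[:16]


def _write_tsv(path: Path, df: pd.DataFrame, config_hash: str) -> None:
    header = (
        f"# polytraj {__version__}\n"
        f"# config_hash={config_hash}\n"
    )
    path.write_text(header + df.to_csv(sep="\t", index=False, float_format="%.6g"))


def run_pipeline(config: RunConfig) -> SummaryReport:
    """Run every analysis stage and write the TSV report artifacts.

    Deterministic given inputs + seed.  Any stage failure raises
    :class:`PipelineError` naming the stage; artifacts written before the
    failure are kept.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artifacts: dict = {}
    skips: list = []
    stage = "load"
    try:
        log.info("polytraj %s config_hash=%s seed=%d", __version__, chash, config.seed)
        for name in config.defaults_applied:
            log.info("default applied: %s=%r", name, _DEFAULTS.get(name, "builtin"))
        role_meta = yaml.safe_load(Path(config.role_map).read_text())
        role_rules = _load_role_map(config.role_map)
        data = {
            entry.temperature: _load_replicates(entry, role_rules, role_meta)
            for entry in sorted(config.temperatures, key=lambda e: e.temperature)
        }

        stage = "rg"
        rows = []
        for temp, reps in data.items():
            series = np.concatenate([rg_series(r).values for r in reps])
            dist = rg_distribution(
                RgSeries(times=np.arange(len(series), dtype=float), values=series),
                bin_width=config.rg_bin_width,
            )
            rows.append(
                {
                    "temperature_K": temp,
                    "rg_principal_peak_A": dist.principal_peak,
                    "rg_sd_A": dist.sd,
                    "multimodal": dist.multimodal,
                }
            )
        artifacts["rg"] = out / "rg_peaks.tsv"
        _write_tsv(artifacts["rg"], pd.DataFrame(rows), chash)

        stage = "chain_extension"
        rows = []
        ratio_by_temp = []
        for temp, reps in data.items():
            stats = [chain_extension_stats(r, mode=config.lmax_mode) for r in reps]
            ratio = float(np.mean([s.ratio for s in stats]))
            sd = float(np.mean([s.sd for s in stats]))
            ideal = stats[0].ideal_ref
            rows.append(
                {
                    "temperature_K": temp,
                    "ratio": ratio,
                    "ideal_ref": ideal,
                    "sd": sd,
                    "cv": sd / ratio if ratio else float("nan"),
                    "state": "coil" if ratio > ideal else "globule",
                }
            )
            ratio_by_temp.append(ratio)
        artifacts["chain_extension"] = out / "chain_extension.tsv"
        _write_tsv(artifacts["chain_extension"], pd.DataFrame(rows), chash)

        stage = "chain_extension_temperature_average"
        tavg = temperature_average(ratio_by_temp)
        artifacts["chain_extension_tavg"] = out / "chain_extension_tavg.tsv"
        _write_tsv(
            artifacts["chain_extension_tavg"],
            pd.DataFrame(
                [{"mean_ratio": tavg.mean, "sd": tavg.sd, "cv": tavg.cv,
                  "n_temperatures": tavg.n_temperatures}]
            ),
            chash,
        )

        stage = "side_chain"
        rows = []
        chain_means = []
        for temp, reps in data.items():
            means = [side_chain_lengths(r).chain_mean for r in reps]
            chain_means.append(float(np.mean(means)))
            rows.append({"temperature_K": temp, "side_chain_length_A": chain_means[-1]})
        sc_stats = side_chain_temperature_stats(chain_means)
        rows.append(
            {"temperature_K": "average", "side_chain_length_A": sc_stats.mean}
        )
        artifacts["side_chain"] = out / "side_chain.tsv"
        _write_tsv(artifacts["side_chain"], pd.DataFrame(rows), chash)

        stage = "rdf"
        rdfs_by_temp = {}
        for temp, reps in data.items():
            per_rep = [
                rdf(
                    r,
                    select(r.topology, "terminal_carbon"),
                    select(r.topology, "water_oxygen"),
                    dr=config.dr,
                )
                for r in reps
            ]
            merged = average_rdfs(per_rep) if config.rdf_average == "g_first" else per_rep
            rdfs_by_temp[temp] = merged
            to_dump = merged if config.rdf_average == "g_first" else average_rdfs(per_rep)
            df = pd.DataFrame({"r_A": to_dump.r_centers, "g": to_dump.g})
            path = out / f"rdf_T{temp:g}.tsv"
            artifacts[f"rdf_T{temp:g}"] = path
            _write_tsv(path, df, chash)

        stage = "peak_curve"
        if config.rdf_average == "g_first":
            curve = peak_intensity_curve(rdfs_by_temp, r_window=config.r_window)
        else:
            # peak detection per replicate, then averaged per temperature
            from .solvation_rdf import first_peak

            temps, r_vals, i_vals = [], [], []
            for temp, per_rep in sorted(rdfs_by_temp.items()):
                found = [
                    first_peak(r, r_window=config.r_window) for r in per_rep
                ]
                found = [f for f in found if f is not None]
                temps.append(temp)
                r_vals.append(np.mean([f[0] for f in found]) if found else np.nan)
                i_vals.append(np.mean([f[1] for f in found]) if found else np.nan)
            from .solvation_rdf import PeakCurve

            curve = PeakCurve(
                temperatures=np.array(temps),
                first_peak_r=np.array(r_vals),
                first_peak_intensity=np.array(i_vals),
            )
        artifacts["peak_curve"] = out / "peak_curve.tsv"
        _write_tsv(
            artifacts["peak_curve"],
            pd.DataFrame(
                {
                    "temperature_K": curve.temperatures,
                    "r_peak_A": curve.first_peak_r,
                    "g_peak": curve.first_peak_intensity,
                }
            ),
            chash,
        )

        stage = "tcrp"
        tcrp_value = None
        if len(curve.temperatures) < 2:
            skips.append(("tcrp", "not determinable: needs >= 2 temperatures"))
            log.info("skip tcrp: single temperature")
        else:
            result = crossing_temperature(curve)
            tcrp_value = result.temperature
            row = {
                "tcrp_K": "none" if result.temperature is None else result.temperature,
                "bracket_lo_K": result.bracket[0] if result.bracket else "",
                "bracket_hi_K": result.bracket[1] if result.bracket else "",
                "tclp_K": "" if config.tclp is None else config.tclp,
                "delta_K": (
                    result.temperature - config.tclp
                    if result.temperature is not None and config.tclp is not None
                    else ""
                ),
                "method": result.method,
            }
            artifacts["tcrp"] = out / "tcrp.tsv"
            _write_tsv(artifacts["tcrp"], pd.DataFrame([row]), chash)

        stage = "hbonds"
        rows = []
        for temp, reps in data.items():
            stats = [hbond_averages(r, config.hbond) for r in reps]
            intra = float(np.mean([intrapolymer_hbonds(r, config.hbond) for r in reps]))
            rows.append(
                {
                    "temperature_K": temp,
                    "per_oxygen_mainchain": float(
                        np.mean([s.per_oxygen_mainchain for s in stats])
                    ),
                    "per_oxygen_sidechain": float(
                        np.mean([s.per_oxygen_sidechain for s in stats])
                    ),
                    "intrapolymer_mean": intra,
                }
            )
        artifacts["hbonds"] = out / "hbonds.tsv"
        _write_tsv(artifacts["hbonds"], pd.DataFrame(rows), chash)

        log.info("pipeline complete: %d artifacts, %d skips", len(artifacts), len(skips))
        return SummaryReport(
            artifacts=artifacts, skips=skips, tcrp=tcrp_value, tclp=config.tclp
        )
    except PipelineError:
        raise
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
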