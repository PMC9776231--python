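"""Config-driven analysis pipeline over one trajectory and/or energy table.

A :class:`PipelineConfig` (typically loaded from YAML) names the inputs,
the residue groups and region schemes, the interaction criteria, the
analysis windows, and which stages to run.  ``run_pipeline`` executes the
requested stages, writes one CSV per stage into the output directory, and
finishes with a JSON manifest recording inputs, parameters, seed and
package version — enough to re-run the pipeline exactly.  All randomness
(the population stage) flows from the single top-level seed, so identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import (
    InteractionCriteria,
    classify_region_contacts,
    electrostatic_occurrence_map,
    facing_fractions,
    hbond_occurrence_map,
    hydrophobic_occurrence_map,
)
from .gauges import GaugeSpec, default_gauge_spec, gauge_series, summarize_gauges
from .pdbio import read_pdb
from .populations import PopulationConfig, mc_populations, read_energy_table
from .secstruct import ss_percentages
from .structures import AnalysisWindow, RegionScheme, Trajectory
from .superpose import rmsd_series, rmsf

__all__ = ["PipelineConfig", "PipelineError", "load_config", "validate_config", "run_pipeline"]

ALL_STAGES = (
    "rmsd",
    "rmsf",
    "ss",
    "contacts",
    "electrostatics",
    "hbonds",
    "gauges",
    "populations",
)

#: Width of the head/tail analysis windows (ps): the first and last 5 ns.
DEFAULT_WINDOW_PS = 5000.0


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; mirrors the YAML config layout."""

    pdb: str | None = None
    energies: str | None = None
    out_dir: str = "results"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    frame_interval: float = 10.0
    group_a: tuple[str, int, int] | None = None
    group_b: tuple[str, int, int] | None = None
    regions_a: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    regions_b: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)
    gauge_spec: GaugeSpec | None = None
    window_initial: tuple[float, float] | None = None
    window_final: tuple[float, float] | None = None
    temperature: float = 298.0
    mc_steps: int = 1_000_000


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    kwargs: dict = {}
    for key in (
        "pdb",
        "energies",
        "out_dir",
        "seed",
        "frame_interval",
        "temperature",
        "mc_steps",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "stages" in raw:
        kwargs["stages"] = tuple(raw["stages"])
    for key in ("group_a", "group_b"):
        if key in raw and raw[key] is not None:
            c, a, b = raw[key]
            kwargs[key] = (str(c), int(a), int(b))
    for key in ("regions_a", "regions_b"):
        if key in raw and raw[key]:
            kwargs[key] = {
                str(k): (str(v[0]), int(v[1]), int(v[2])) for k, v in raw[key].items()
            }
    if "criteria" in raw and raw["criteria"]:
        kwargs["criteria"] = InteractionCriteria(**raw["criteria"])
    if "gauge_chain" in raw:
        kwargs["gauge_spec"] = default_gauge_spec(str(raw["gauge_chain"]))
    if "gauges" in raw and raw["gauges"]:
        g = raw["gauges"]
        kwargs["gauge_spec"] = GaugeSpec(
            distance_pairs=tuple(
                (str(name), (str(c1), int(r1)), (str(c2), int(r2)))
                for name, c1, r1, c2, r2 in g.get("distances", [])
            ),
            angle_triplets=tuple(
                (str(name), (str(c1), int(r1)), (str(c2), int(r2)), (str(c3), int(r3)))
                for name, c1, r1, c2, r2, c3, r3 in g.get("angles", [])
            ),
            atom_name=str(g.get("atom_name", "CA")),
        )
    for key, attr in (("window_initial", "window_initial"), ("window_final", "window_final")):
        if key in raw and raw[key] is not None:
            a, b = raw[key]
            kwargs[attr] = (float(a), float(b))
    return PipelineConfig(**kwargs)


def _default_windows(traj: Trajectory) -> tuple[AnalysisWindow, AnalysisWindow]:
    """First and last 5 ns of the trajectory (clipped to its span)."""
    t0, t1 = float(traj.times[0]), float(traj.times[-1])
    head_end = min(t0 + DEFAULT_WINDOW_PS, t1)
    tail_start = max(t1 - DEFAULT_WINDOW_PS, t0)
    return AnalysisWindow(t0, head_end), AnalysisWindow(tail_start, t1)


def _resolve_windows(config: PipelineConfig, traj: Trajectory) -> tuple[AnalysisWindow, AnalysisWindow]:
    head, tail = _default_windows(traj)
    if config.window_initial is not None:
        head = AnalysisWindow(*config.window_initial)
    if config.window_final is not None:
        tail = AnalysisWindow(*config.window_final)
    return head, tail


def validate_config(config: PipelineConfig) -> list[str]:
    """Check the config against run_pipeline's preconditions; return issues."""
    issues: list[str] = []
    structural = [s for s in config.stages if s != "populations"]
    for stage in config.stages:
        if stage not in ALL_STAGES:
            issues.append(f"stages: unknown stage {stage!r}")
    if structural and config.pdb is None:
        issues.append("pdb: structural stages requested but no PDB input given")
    if "populations" in config.stages and config.energies is None:
        issues.append("energies: populations stage requested but no energy table given")
    for key in ("pdb", "energies"):
        path = getattr(config, key)
        if path is not None and not Path(path).exists():
            issues.append(f"{key}: file {path} does not exist")
    try:
        _ = config.criteria  # construction already validates
    except ValueError as exc:
        issues.append(f"criteria: {exc}")
    if config.mc_steps < 1:
        issues.append("mc_steps: must be >= 1")
    if config.temperature <= 0:
        issues.append("temperature: must be positive")

    if config.pdb is not None and Path(config.pdb).exists():
        traj = read_pdb(config.pdb, frame_interval=config.frame_interval)
        frame = traj.frames[0]
        chain_spans = {
            c[0].chain_id: (c[0].index, c[-1].index) for c in frame.chains
        }
        for label, regions in (("regions_a", config.regions_a), ("regions_b", config.regions_b)):
            for name, (chain_id, first, last) in regions.items():
                if chain_id not in chain_spans:
                    issues.append(f"{label}.{name}: chain {chain_id!r} not in structure")
                else:
                    lo, hi = chain_spans[chain_id]
                    if first < lo or last > hi:
                        issues.append(
                            f"{label}.{name}: range {first}-{last} outside chain "
                            f"{chain_id} ({lo}-{hi})"
                        )
        for label, win in (("window_initial", config.window_initial), ("window_final", config.window_final)):
            if win is not None:
                a, b = win
                if not (0 <= a < b):
                    issues.append(f"{label}: requires 0 <= start < end")
                elif a > float(traj.times[-1]):
                    issues.append(
                        f"{label}: starts at {a} ps, beyond trajectory end "
                        f"{float(traj.times[-1])} ps"
                    )
    return issues


def _groups(config: PipelineConfig, traj: Trajectory) -> tuple[tuple[str, int, int], tuple[str, int, int]]:
    frame = traj.frames[0]
    if config.group_a is not None and config.group_b is not None:
        return config.group_a, config.group_b
    if len(frame.chains) < 2:
        raise PipelineError("contacts: need two chains or explicit group_a/group_b")
    a, b = frame.chains[0], frame.chains[1]
    return (
        (a[0].chain_id, a[0].index, a[-1].index),
        (b[0].chain_id, b[0].index, b[-1].index),
    )


def _region_schemes(config: PipelineConfig, traj: Trajectory) -> tuple[RegionScheme, RegionScheme]:
    if config.regions_a and config.regions_b:
        return RegionScheme(dict(config.regions_a)), RegionScheme(dict(config.regions_b))
    ga, gb = _groups(config, traj)
    return (
        RegionScheme({f"chain_{ga[0]}": ga}),
        RegionScheme({f"chain_{gb[0]}": gb}),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages; return the manifest (also written to disk).

    Each stage writes ``<stage>.csv`` under ``out_dir``.  A stage failure
    stops the run with :class:`PipelineError`; completed outputs are kept
    and the manifest marks the failed stage.
    """
    issues = validate_config(config)
    if issues:
        raise PipelineError("invalid config: " + "; ".join(issues))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    traj: Trajectory | None = None
    structural = [s for s in config.stages if s != "populations"]
    if structural:
        traj = read_pdb(config.pdb, frame_interval=config.frame_interval)

    manifest: dict = {
        "package_version": __version__,
        "inputs": {"pdb": config.pdb, "energies": config.energies},
        "seed": config.seed,
        "parameters": {
            "frame_interval_ps": config.frame_interval,
            "temperature_K": config.temperature,
            "mc_steps": config.mc_steps,
            "criteria": {
                k: (sorted(v) if isinstance(v, frozenset) else v)
                for k, v in dataclasses.asdict(config.criteria).items()
            },
        },
        "stages": {},
    }

    for stage in config.stages:
        out_path = out_dir / f"{stage}.csv"
        try:
            _run_stage(stage, config, traj, out_path)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {"status": "ok", "output": out_path.name}

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_stage(
    stage: str, config: PipelineConfig, traj: Trajectory | None, out_path: Path
) -> None:
    if stage == "populations":
        energies = read_energy_table(config.energies)
        est = mc_populations(
            energies,
            PopulationConfig(
                temperature=config.temperature, steps=config.mc_steps, seed=config.seed
            ),
        )
        est.to_frame(config.temperature).to_csv(out_path, index=False, float_format="%.6g")
        return

    assert traj is not None
    head, tail = _resolve_windows(config, traj)

    if stage == "rmsd":
        frames = []
        for chain in traj.frames[0].chains:
            cid = chain[0].chain_id
            series = rmsd_series(traj, 0, (cid, chain[0].index, chain[-1].index))
            frames.append(
                pd.DataFrame(
                    {"time_ps": series.times, "chain": cid, "rmsd_A": series.values}
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(out_path, index=False, float_format="%.4f")
    elif stage == "rmsf":
        frames = []
        for chain in traj.frames[0].chains:
            cid = chain[0].chain_id
            profile = rmsf(traj, (cid, chain[0].index, chain[-1].index))
            frames.append(
                pd.DataFrame(
                    {"chain": cid, "residue": profile.residue_indices, "rmsf_A": profile.values}
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(out_path, index=False, float_format="%.4f")
    elif stage == "ss":
        rows = []
        for label, window in (("initial", head), ("final", tail)):
            profile = ss_percentages(traj, window)
            for (chain_id, res), h, e in zip(
                profile.residue_keys, profile.helix_pct, profile.strand_pct
            ):
                rows.append(
                    {
                        "window": label,
                        "chain": chain_id,
                        "residue": res,
                        "helix_pct": h,
                        "strand_pct": e,
                    }
                )
        pd.DataFrame(rows).to_csv(out_path, index=False, float_format="%.4f")
    elif stage == "contacts":
        ga, gb = _groups(config, traj)
        occ = hydrophobic_occurrence_map(traj, ga, gb, config.criteria)
        facing = facing_fractions(traj, occ, config.criteria.facing_angle_cutoff)
        scheme_a, scheme_b = _region_schemes(config, traj)
        levels = classify_region_contacts(occ, facing, scheme_a, scheme_b, config.criteria)
        rows = [
            {
                "record": "pair",
                "a": f"{ka[0]}:{ka[1]}",
                "b": f"{kb[0]}:{kb[1]}",
                "occurrence_pct": pct,
                "facing_fraction": facing.get((ka, kb), float("nan")),
                "level": "",
            }
            for (ka, kb), pct in sorted(occ.entries.items())
        ]
        rows += [
            {
                "record": "region",
                "a": ra,
                "b": rb,
                "occurrence_pct": float("nan"),
                "facing_fraction": float("nan"),
                "level": level.value,
            }
            for (ra, rb), level in sorted(levels.items())
        ]
        pd.DataFrame(rows).to_csv(out_path, index=False, float_format="%.4f")
    elif stage in ("electrostatics", "hbonds"):
        ga, gb = _groups(config, traj)
        fn = electrostatic_occurrence_map if stage == "electrostatics" else hbond_occurrence_map
        occ = fn(traj, ga, gb, config.criteria)
        rows = [
            {"a": f"{ka[0]}:{ka[1]}", "b": f"{kb[0]}:{kb[1]}", "occurrence_pct": pct}
            for (ka, kb), pct in sorted(occ.entries.items())
        ]
        pd.DataFrame(rows, columns=["a", "b", "occurrence_pct"]).to_csv(
            out_path, index=False, float_format="%.4f"
        )
    elif stage == "gauges":
        spec = config.gauge_spec
        if spec is None:
            chain = traj.frames[0].chains[0]
            cid = chain[0].chain_id
            try:
                spec = default_gauge_spec(cid)
                gauge_series(Trajectory(frames=traj.frames[:1]), spec)
            except ValueError:
                # Structure lacks the named chamber residues: fall back to
                # generic end/middle/end descriptors of the first chain.
                first, mid, last = chain[0].index, chain[len(chain) // 2].index, chain[-1].index
                spec = GaugeSpec(
                    distance_pairs=(
                        (f"{cid}{first}-{cid}{last}", (cid, first), (cid, last)),
                        (f"{cid}{first}-{cid}{mid}", (cid, first), (cid, mid)),
                    ),
                    angle_triplets=(
                        (f"{cid}{first}-{cid}{mid}-{cid}{last}", (cid, first), (cid, mid), (cid, last)),
                    ),
                )
        series = gauge_series(traj, spec)
        series.to_frame().to_csv(out_path, index=False, float_format="%.4f")
    else:
        raise PipelineError(f"unknown stage {stage!r}")
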