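"""Umbrella workflows binding simulation and analysis end to end.

``run_trace_study`` emulates the 72-h live-imaging experiment: simulate a
fate-mixed cohort, classify every trace blind to its ground truth, and
summarize fate fractions and S/G2(/M) durations.  ``run_screen_study``
emulates the compound screen: simulate replicate plates, then run the full
QC / normalization / ranking chain.  Both are pure functions of
(config, seed) and write all intermediates plus the resolved config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from typing import ClassVar
from pathlib import Path

import yaml

from . import io as fio
from .screen import run_screen
from .synthetic import (
    FateMixture,
    KineticsParams,
    PlateSpec,
    PloidyPopulationSpec,
    cohort_truth,
    default_plate_layout,
    generate_plate,
    generate_trace_cohort,
)
from .traces import (
    DIVISION,
    BINUCLEATION,
    POLYPLOIDIZATION,
    FateClassifierConfig,
    align_traces,
    calls_to_frame,
    classify_fate,
    cohort_summary,
)

log = logging.getLogger(__name__)


def _from_mapping(cls, data: dict):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Top-level configuration; round-trips losslessly through YAML."""

    seed: int = 0
    n_cells: int = 570
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    mixture: FateMixture = field(default_factory=FateMixture)
    classifier: FateClassifierConfig = field(default_factory=FateClassifierConfig)
    plate: PlateSpec | None = None
    ploidy: PloidyPopulationSpec = field(default_factory=PloidyPopulationSpec)
    site_combine: str = "sum"
    log_level: str = "INFO"

    _NESTED: ClassVar[dict] = {
        "kinetics": KineticsParams,
        "mixture": FateMixture,
        "classifier": FateClassifierConfig,
        "ploidy": PloidyPopulationSpec,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, sub in cls._NESTED.items():
            if key in data and isinstance(data[key], dict):
                data[key] = _from_mapping(sub, data[key])
        if "plate" in data and isinstance(data["plate"], dict):
            plate = dict(data["plate"])
            layout = {
                k: plate.pop(k)
                for k in ("n_compounds", "n_controls", "effects")
                if k in plate
            }
            if layout:
                data["plate"] = default_plate_layout(**layout, **plate)
            else:
                data["plate"] = _from_mapping(PlateSpec, plate)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if out.get("plate") is not None:
            out["plate"]["compound_wells"] = {
                w: list(v) for w, v in out["plate"]["compound_wells"].items()
            }
            out["plate"]["control_wells"] = list(out["plate"]["control_wells"])
            out["plate"]["timepoints_h"] = list(out["plate"]["timepoints_h"])
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def run_trace_study(config: RunConfig | None = None, outdir=None) -> dict:
    """Simulate, blindly classify and summarize a live-imaging cohort.

    Classification sees only intensities and the daughter annotation; the
    summary reports classified fractions, per-fate durations, and — for
    verification — the generator's true fractions.
    """
    config = config or RunConfig()
    traces = generate_trace_cohort(
        config.n_cells, config.mixture, config.kinetics, seed=config.seed
    )
    calls = [classify_fate(tr, config.classifier) for tr in traces]
    summary = cohort_summary(calls)
    truth = cohort_truth(traces)
    summary["true_fractions"] = (
        truth["true_fate"].value_counts(normalize=True).to_dict()
    )
    summary["seed"] = config.seed

    profiles = {}
    for fate in (DIVISION, BINUCLEATION, POLYPLOIDIZATION):
        sel = [tr for tr, c in zip(traces, calls) if c.fate == fate]
        if sel:
            profiles[fate] = align_traces(sel, config.classifier)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fio.write_traces_csv(outdir / "traces.csv", traces)
        fio.write_csv(outdir / "truth.csv", truth)
        fio.write_csv(outdir / "fate_calls.csv", calls_to_frame(calls))
        for fate, prof in profiles.items():
            fio.write_csv(outdir / f"aligned_profile_{fate}.csv", prof)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        config.to_yaml(outdir / "config.yaml")
    return {"summary": summary, "calls": calls, "traces": traces, "profiles": profiles}


def run_screen_study(config: RunConfig | None = None, outdir=None) -> dict:
    """Simulate replicate screening plates and run the scoring chain."""
    config = config or RunConfig()
    spec = config.plate or default_plate_layout()
    sites, plate_map, truth = generate_plate(spec, seed=config.seed)
    res = run_screen(sites, plate_map, site_combine=config.site_combine)
    res["sites"] = sites
    res["plate_map"] = plate_map
    res["truth"] = truth

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fio.write_csv(outdir / "sites.csv", sites)
        fio.write_csv(outdir / "plate_map.csv", plate_map)
        fio.write_csv(outdir / "truth.csv", truth)
        fio.write_csv(outdir / "wells.csv", res["wells"])
        fio.write_csv(outdir / "result.csv", res["result"])
        fio.write_csv(outdir / "site_exclusions.csv", res["site_exclusions"])
        fio.write_csv(outdir / "treatment_exclusions.csv", res["treatment_exclusions"])
        fio.write_csv(outdir / "cv_table.csv", res["cv_table"])
        fio.write_csv(outdir / "ranked.csv", res["ranked"])
        with open(outdir / "summary.json", "w") as fh:
            json.dump(
                {
                    "seed": config.seed,
                    "selected_timepoint_h": res["selected_timepoint_h"],
                    "n_sites_excluded": len(res["site_exclusions"]),
                    "n_treatments_excluded": len(res["treatment_exclusions"]),
                    "top_compound": (
                        res["ranked"]["compound_id"].iloc[0] if len(res["ranked"]) else None
                    ),
                },
                fh,
                indent=2,
            )
        config.to_yaml(outdir / "config.yaml")
    return res
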