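"""End-to-end orchestration: simulate/read plates → spectra → decisions → summaries.

A run is driven by a RunConfig (YAML or JSON on disk).  Outputs are written
to the configured directory: plate CSV (when simulated), spectra JSON + CSV,
a per-strain decision table, composition/survival summaries (when strain
metadata is available), a structured log of per-stage events including every
dropped-data reason, and a manifest with the package version, seed and a
deterministic hash of config and results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .assay import (
    FLAG_OK,
    INPSpectrum,
    PlateAssay,
    TemperatureProtocol,
    compute_frozen_fraction,
    correct_background,
    estimate_spectrum,
    merge_dilutions,
    replicate_filter,
)
from .classify import (
    confirm_ina,
    infer_nature,
    onset_temperature,
    screen_assay,
    temperature_class,
)
from .io import (
    read_plates,
    read_strains_tsv,
    write_plates,
    write_spectra_csv,
    write_spectra_json,
    write_strains_tsv,
)
from .simulate import (
    Panel,
    PanelConfig,
    SpectrumComponent,
    SpectrumModel,
    generate_strain_panel,
)
from .strains import StrainRecord, composition_summary, survival_summary

__all__ = ["RunConfig", "RunResult", "run_pipeline", "model_to_dict", "model_from_dict"]


def model_to_dict(model: SpectrumModel) -> dict:
    def comp(c: SpectrumComponent) -> dict:
        return dataclasses.asdict(c)

    return {
        "components": [comp(c) for c in model.components],
        "background_per_droplet": (
            comp(model.background_per_droplet)
            if model.background_per_droplet is not None
            else None
        ),
    }


def model_from_dict(d: dict) -> SpectrumModel:
    bg = d.get("background_per_droplet")
    return SpectrumModel(
        components=tuple(SpectrumComponent(**c) for c in d["components"]),
        background_per_droplet=SpectrumComponent(**bg) if bg else None,
    )


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run.

    When ``plates_path`` is unset a synthetic panel is generated from
    ``panel``; otherwise plates (and optionally strain metadata) are read
    from disk.  Thresholds: ``ci_level`` for the Clopper–Pearson intervals,
    ``significance_threshold`` for the treatment contrasts, the screening
    setpoint/cutoff, and whether the screen subtracts the background first
    (off by default — the raw-fraction screen).
    """

    outdir: str = "results"
    seed: int = 0
    plates_path: str | None = None
    strains_path: str | None = None
    panel: PanelConfig = field(default_factory=PanelConfig)
    ci_level: float = 0.95
    significance_threshold: float = 0.05
    dunn_adjustment: str = "none"
    screen_temperature: float = -24.0
    screen_cutoff: float = 0.5
    screen_background_corrected: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if not 0.0 < self.significance_threshold < 1.0:
            raise ValueError("significance_threshold must lie in (0, 1)")
        if not 0.0 < self.screen_cutoff <= 1.0:
            raise ValueError("screen_cutoff must lie in (0, 1]")
        if self.dunn_adjustment not in ("none", "holm", "bh"):
            raise ValueError("dunn_adjustment must be none, holm or bh")
        for p in (self.plates_path, self.strains_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if "panel" in data and isinstance(data["panel"], dict):
            panel = dict(data["panel"])
            for key in ("airborne_class_counts", "aquatic_class_counts",
                        "isolation_medium_counts"):
                if key in panel:
                    panel[key] = tuple(tuple(x) for x in panel[key])
            if "airborne_taxonomy" in panel:
                panel["airborne_taxonomy"] = tuple(
                    tuple(x) for x in panel["airborne_taxonomy"]
                )
            for key in ("dilution_factors", "media", "amplitude_range",
                        "slope_range"):
                if key in panel:
                    panel[key] = tuple(panel[key])
            data["panel"] = PanelConfig(**panel)
        return cls(**data)

    def to_canonical_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, default=str)


@dataclass(frozen=True)
class RunResult:
    outdir: Path
    manifest: dict
    spectra: tuple[INPSpectrum, ...]
    decisions: pd.DataFrame


def _match_control(
    controls: dict[tuple[str, str], PlateAssay], sample_id: str, replicate_id: str
) -> PlateAssay | None:
    for key in (
        (sample_id, replicate_id),
        (sample_id, "*"),
        ("*", replicate_id),
        ("*", "*"),
    ):
        if key in controls:
            return controls[key]
    return None


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute a full run; deterministic given config + seed."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, subject: str, message: str) -> None:
        log_lines.append(json.dumps(
            {"stage": stage, "subject": subject, "message": message}
        ))

    # ------------------------------------------------------------------ input
    records: list[StrainRecord] | None = None
    if config.plates_path is None:
        panel = generate_strain_panel(config.panel, config.seed)
        assays = list(panel.plates)
        records = list(panel.records)
        write_plates(assays, outdir / "plates.csv")
        write_strains_tsv(records, outdir / "strains.tsv")
        (outdir / "truth.json").write_text(json.dumps(
            {t.strain_id: model_to_dict(t.model) for t in panel.truth}, indent=1
        ))
        log("input", "panel", f"simulated {len(assays)} plates, "
            f"{len(records)} strains (seed {config.seed})")
    else:
        assays, errors = read_plates(config.plates_path)
        if errors:
            report = outdir / "input_errors.csv"
            pd.DataFrame([{"line": e.line, "message": e.message} for e in errors]
                         ).to_csv(report, index=False)
            for e in errors:
                log("input", f"line {e.line}", e.message)
        if not assays:
            raise ValueError(
                f"no valid plate rows in {config.plates_path}; see input_errors.csv"
            )
        if config.strains_path is not None:
            records = read_strains_tsv(config.strains_path)

    controls: dict[tuple[str, str], PlateAssay] = {}
    for a in assays:
        if a.treatment == "control":
            controls[(a.sample_id, a.replicate_id)] = a

    # ------------------------------------------------------------- screening
    is_screen = lambda a: a.replicate_id.startswith("screen")
    screen_assays = [a for a in assays
                     if a.treatment == "untreated" and is_screen(a)]
    if not screen_assays:
        screen_assays = [a for a in assays if a.treatment == "untreated"]
    screens: dict[str, list[bool]] = {}
    for a in screen_assays:
        if float(config.screen_temperature) not in a.protocol.setpoints:
            log("screen", a.sample_id,
                f"no {config.screen_temperature:g} °C setpoint; skipped")
            continue
        if config.screen_background_corrected:
            ctrl = _match_control(controls, a.sample_id, a.replicate_id)
            idx = a.protocol.setpoints.index(float(config.screen_temperature))
            ff = a.frozen_counts[idx] / a.n_wells
            if ctrl is not None:
                ff -= compute_frozen_fraction(ctrl).fractions[idx]
            flag = ff >= config.screen_cutoff
        else:
            flag = screen_assay(a, config.screen_temperature, config.screen_cutoff)
        screens.setdefault(a.sample_id, []).append(flag)

    # --------------------------------------------------------------- spectra
    profile_assays = [a for a in assays
                      if a.treatment != "control" and not is_screen(a)]
    by_arm: dict[tuple[str, str, str], list[PlateAssay]] = {}
    for a in profile_assays:
        by_arm.setdefault((a.sample_id, a.treatment, a.replicate_id), []).append(a)

    spectra: list[INPSpectrum] = []
    arm_spectra: dict[tuple[str, str, str], INPSpectrum] = {}
    for (sample_id, treatment, replicate_id), group in sorted(by_arm.items()):
        per_dilution = []
        for a in sorted(group, key=lambda a: a.droplet.dilution_factor):
            ctrl = _match_control(controls, sample_id, replicate_id)
            per_dilution.append(estimate_spectrum(a, ctrl, config.ci_level))
        merged = merge_dilutions(per_dilution)
        spectra.append(merged)
        arm_spectra[(sample_id, treatment, replicate_id)] = merged
        removed = [t for t, fl in zip(merged.setpoints, merged.flags)
                   if fl == "negative_removed"]
        if removed:
            log("spectrum", f"{sample_id}/{treatment}/{replicate_id}",
                f"negative corrected fractions removed at {removed} °C")
    write_spectra_json(spectra, outdir / "spectra.json")
    write_spectra_csv(spectra, outdir / "spectra.csv")

    # ------------------------------------------------------------- decisions
    strain_ids = sorted({a.sample_id for a in assays if a.treatment != "control"})
    rows = []
    for sid in strain_ids:
        flags = screens.get(sid, [])
        screened = any(flags) if flags else False
        confirmed = confirm_ina(flags) if len(flags) >= 2 else False
        if len(flags) < 2:
            log("confirm", sid, f"only {len(flags)} screen(s); not confirmable")

        untreated_reps = [s for (s_id, tr, _), s in sorted(arm_spectra.items())
                          if s_id == sid and tr == "untreated"]
        retained = None
        onset = None
        tclass = None
        if len(untreated_reps) == 3:
            decision = replicate_filter(untreated_reps)
            retained = decision.retained
            if not decision.retained:
                log("replicate_filter", sid, decision.reason)
            else:
                onset = onset_temperature(untreated_reps)
                tclass = temperature_class(onset) if onset is not None else None
        elif untreated_reps:
            log("replicate_filter", sid,
                f"{len(untreated_reps)} replicate(s); three-replicate QC skipped")

        def arm_mean(treatment: str) -> INPSpectrum | None:
            reps = [s for (s_id, tr, _), s in sorted(arm_spectra.items())
                    if s_id == sid and tr == treatment]
            return merge_dilutions(reps) if reps else None

        verdict = None
        if untreated_reps:
            heated = arm_mean("heated")
            filt = arm_mean("filtrate")
            if heated is not None or filt is not None:
                verdict = infer_nature(
                    merge_dilutions(untreated_reps), heated, filt,
                    stats_threshold=config.significance_threshold,
                )
                for note in verdict.notes:
                    log("nature", sid, note)

        kw = verdict.evidence.get("kruskal_wallis") if verdict else None
        rows.append(
            {
                "strain_id": sid,
                "n_screens": len(flags),
                "screened_positive": screened,
                "confirmed": confirmed,
                "replicates_retained": retained,
                "onset_temperature_c": onset,
                "temperature_class": tclass,
                "protein_axis": verdict.protein_axis if verdict else None,
                "localization_axis": verdict.localization_axis if verdict else None,
                "kw_statistic": kw.statistic if kw else None,
                "kw_p_value": kw.p_value if kw else None,
            }
        )
    decisions = pd.DataFrame(rows)
    decisions.to_csv(outdir / "decisions.csv", index=False)

    # ------------------------------------------------------------- summaries
    if records:
        composition_summary(records, "class").to_csv(
            outdir / "composition_by_class.csv", index=False)
        composition_summary(records, "ina_status").to_csv(
            outdir / "composition_by_ina_status.csv", index=False)
        survival_summary(records, "freezing").to_csv(
            outdir / "survival_freezing.csv", index=False)
        try:
            survival_summary(records, "desiccation").to_csv(
                outdir / "survival_desiccation.csv", index=False)
        except ValueError as exc:
            log("summary", "desiccation", str(exc))

    # --------------------------------------------------------------- outputs
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    results_hash = hashlib.sha256(
        (outdir / "spectra.json").read_bytes()
        + (outdir / "decisions.csv").read_bytes()
    ).hexdigest()
    manifest = {
        "package": "dropfreeze",
        "version": _pkg_version,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            config.to_canonical_json().encode()).hexdigest(),
        "results_hash": results_hash,
        "n_plates": len(assays),
        "n_strains": len(strain_ids),
        "n_spectra": len(spectra),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return RunResult(outdir, manifest, tuple(spectra), decisions)
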