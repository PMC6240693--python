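"""Strain-level decisions from INP spectra.

Covers the four judgement calls of the assay workflow: the screening rule
(at least half the wells frozen at -24 °C), confirmation by repeated
screens, onset temperature and its temperature class, and inference of the
INA compound's nature from the heat / filtration treatment contrasts via
Kruskal–Wallis + Dunn tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assay import (
    FLAG_BELOW_DETECTION,
    FLAG_NEGATIVE_REMOVED,
    FLAG_OK,
    FLAG_SATURATED,
    INPSpectrum,
    PlateAssay,
)
from .stats import PairwiseResult, TestResult, dunn_posthoc, kruskal_wallis

__all__ = [
    "TEMPERATURE_CLASSES",
    "InaDecision",
    "NatureVerdict",
    "screen_ina",
    "screen_assay",
    "confirm_ina",
    "onset_temperature",
    "temperature_class",
    "infer_nature",
]

# class edges in °C; warm boundary inclusive at -6, colder boundaries
# assigned to the colder side (mid is -6 > T >= -12, and so on)
TEMPERATURE_CLASSES = (
    ("warm", -6.0),
    ("mid", -12.0),
    ("cool", -18.0),
    ("cold", -24.0),
)

SCREEN_TEMPERATURE = -24.0
SCREEN_CUTOFF = 0.5


@dataclass(frozen=True)
class InaDecision:
    """Screening/confirmation outcome for one strain."""

    screened_positive: bool
    confirmed: bool
    onset_temperature: float | None
    temperature_class: str | None

    def __post_init__(self) -> None:
        if self.confirmed and not self.screened_positive:
            raise ValueError("confirmed implies screened_positive")
        if (self.temperature_class is None) != (self.onset_temperature is None):
            raise ValueError(
                "temperature_class must be set exactly when an onset exists"
            )


@dataclass(frozen=True)
class NatureVerdict:
    """Inferred nature of the INA compound from treatment contrasts."""

    protein_axis: str  # proteinaceous | non_proteinaceous | indeterminate
    localization_axis: str  # cell_associated | soluble | indeterminate
    evidence: dict
    notes: tuple[str, ...] = ()


def screen_ina(
    frozen_count_at_minus24: int,
    n_wells: int,
    cutoff: float = SCREEN_CUTOFF,
) -> bool:
    """Screening rule: INA iff the frozen fraction at -24 °C reaches the
    cutoff (default 0.5, boundary inclusive: 8 of 16 is positive)."""
    if not 0 <= frozen_count_at_minus24 <= n_wells:
        raise ValueError("frozen count outside [0, n_wells]")
    return frozen_count_at_minus24 / n_wells >= cutoff


def screen_assay(
    assay: PlateAssay,
    temperature: float = SCREEN_TEMPERATURE,
    cutoff: float = SCREEN_CUTOFF,
) -> bool:
    """Apply the screen to a plate, reading the count at the screening
    setpoint (raw frozen fraction, no background correction by default —
    use estimate_spectrum + a corrected curve if a corrected screen is
    wanted)."""
    try:
        idx = assay.protocol.setpoints.index(float(temperature))
    except ValueError:
        raise ValueError(
            f"screening setpoint {temperature:g} °C absent from the protocol"
        ) from None
    return screen_ina(assay.frozen_counts[idx], assay.n_wells, cutoff)


def confirm_ina(screens) -> bool:
    """Confirmation by repetition: every one of >= 2 independent screens
    must be positive."""
    flags = list(screens)
    if len(flags) < 2:
        raise ValueError("confirmation needs at least two independent screens")
    return all(bool(f) for f in flags)


def onset_temperature(
    replicate_spectra,
    require_all: bool = True,
) -> float | None:
    """Warmest setpoint with usable activity in the replicates.

    With ``require_all`` (default, matching the three-replicate QC spirit)
    every replicate must be flagged ok with a positive estimate at the
    setpoint; otherwise one replicate suffices.  Returns None when no
    setpoint qualifies.
    """
    spectra = list(replicate_spectra)
    if not spectra:
        raise ValueError("need at least one replicate spectrum")
    setpoints = spectra[0].protocol.setpoints
    for s in spectra[1:]:
        if s.protocol.setpoints != setpoints:
            raise ValueError("replicate spectra are on different protocols")
    for i, t in enumerate(setpoints):  # warm to cold
        active = [
            s.flags[i] == FLAG_OK and s.values[i] > 0 for s in spectra
        ]
        if (all(active) if require_all else any(active)):
            return t
    return None


def temperature_class(onset: float) -> str | None:
    """Bin an onset temperature into the assay's activity classes.

    warm: onset >= -6; mid: -6 > onset >= -12; cool: -12 > onset >= -18;
    cold: -18 > onset >= -24; below -24 °C is outside the assay range
    (None).  Requires onset <= -2 °C (the warmest assayed setpoint).
    """
    if onset > -2.0:
        raise ValueError("onset must be <= -2 °C (the assay's warm end)")
    for label, cold_edge in TEMPERATURE_CLASSES:
        if onset >= cold_edge:
            return label
    return None


def _contrast_values(
    spectrum: INPSpectrum, keep: np.ndarray, per_droplet_scale: float
) -> np.ndarray:
    """Per-setpoint activity on a common per-droplet scale.

    ok and saturated entries contribute their estimate (the saturated value
    is the continuity-corrected lower bound), below_detection contributes 0;
    setpoints dropped by ``keep`` (negative_removed anywhere) are excluded.
    """
    vals = []
    for use, v, fl in zip(keep, spectrum.values, spectrum.flags):
        if not use:
            continue
        if fl == FLAG_BELOW_DETECTION:
            vals.append(0.0)
        else:
            vals.append(v * per_droplet_scale)
    return np.asarray(vals)


def infer_nature(
    untreated: INPSpectrum,
    heated: INPSpectrum | None,
    filtrate: INPSpectrum | None,
    stats_threshold: float = 0.05,
    setpoint_window: tuple[float, float] | None = None,
) -> NatureVerdict:
    """Infer the INA compound's nature from treatment contrasts.

    All supplied arms are first brought onto a common per-droplet scale
    (per-cell spectra are multiplied by their plate's cell load), restricted
    to ``setpoint_window`` (cold_edge, warm_edge) if given — this is how
    temperature-resolved verdicts for strains whose nature changes along the
    spectrum are obtained.  A Kruskal–Wallis test across the available arms
    gates Dunn pairwise contrasts against the untreated arm:

    * protein axis: proteinaceous iff untreated-vs-heated is significant at
      ``stats_threshold`` with the heated arm lower; otherwise
      non_proteinaceous; indeterminate when the heated arm is missing.
    * localization axis: cell_associated iff untreated-vs-filtrate is
      significant with the filtrate lower; soluble when the filtrate retains
      activity not significantly below untreated; indeterminate when the
      filtrate arm is missing.
    """
    arms: list[tuple[str, INPSpectrum]] = [("untreated", untreated)]
    notes: list[str] = []
    if heated is not None:
        arms.append(("heated", heated))
    else:
        notes.append("heated arm missing: protein axis indeterminate")
    if filtrate is not None:
        arms.append(("filtrate", filtrate))
    else:
        notes.append("filtrate arm missing: localization axis indeterminate")

    setpoints = untreated.protocol.setpoints
    for _, s in arms[1:]:
        if s.protocol.setpoints != setpoints:
            raise ValueError("treatment arms are on different protocols")

    keep = np.ones(len(setpoints), dtype=bool)
    if setpoint_window is not None:
        cold, warm = min(setpoint_window), max(setpoint_window)
        keep &= np.array([cold <= t <= warm for t in setpoints])
    for _, s in arms:
        keep &= np.array([fl != FLAG_NEGATIVE_REMOVED for fl in s.flags])

    def scale(s: INPSpectrum) -> float:
        # per-droplet values are -ln(1-FF)/V, so per-cell values (over c*V)
        # are brought onto that scale by multiplying with c
        return s.droplet.cells_per_ul if s.unit == "per_cell" else 1.0

    groups = {name: _contrast_values(s, keep, scale(s)) for name, s in arms}
    evidence: dict = {}
    protein_axis = "indeterminate"
    localization_axis = "indeterminate"

    usable = all(g.size >= 2 for g in groups.values()) and len(groups) >= 2
    if usable:
        names = list(groups)
        kw = kruskal_wallis([groups[n] for n in names])
        evidence["kruskal_wallis"] = kw
        pairwise = dunn_posthoc([groups[n] for n in names])
        by_pair = {
            (names[p.group_a], names[p.group_b]): p for p in pairwise
        }
        evidence["dunn"] = by_pair

        def contrast(arm: str) -> tuple[bool, bool]:
            p = by_pair.get(("untreated", arm)) or by_pair.get((arm, "untreated"))
            assert p is not None
            # z sign: positive means first-listed group ranks higher
            first_is_untreated = names[p.group_a] == "untreated"
            arm_lower = p.statistic > 0 if first_is_untreated else p.statistic < 0
            significant = kw.p_value < stats_threshold and p.p_value < stats_threshold
            return significant, arm_lower

        if heated is not None:
            sig, lower = contrast("heated")
            protein_axis = "proteinaceous" if sig and lower else "non_proteinaceous"
        if filtrate is not None:
            sig, lower = contrast("filtrate")
            localization_axis = "cell_associated" if sig and lower else "soluble"
    else:
        notes.append("too few comparable setpoints for the rank tests")

    return NatureVerdict(protein_axis, localization_axis, evidence, tuple(notes))
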