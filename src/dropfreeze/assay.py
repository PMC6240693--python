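"""Droplet-freezing assay data model and the INP-spectrum estimation chain.

The pipeline runs: frozen-well counts → frozen fraction → background
correction against a buffer control → cumulative ice-nucleating-particle
(INP) concentration per cell via the Vali relation

    N(T) = -ln(1 - [FF_sample(T) - FF_control(T)]) / (c * V)

with c the cell concentration (cells/µL) and V the droplet volume (µL).
Cell-free plates (buffer controls, filtrates) are normalised per droplet
(divide by V only).  Per-setpoint flags track the estimate's status:

* ``ok``               — usable estimate at or above the plate's lower
                         detection limit (one frozen well out of n);
* ``below_detection``  — no freezing above background, or an estimate
                         smaller than a single frozen well can resolve;
* ``saturated``        — all wells frozen; the reported value is a lower
                         bound computed with FF = (n - 0.5)/n;
* ``negative_removed`` — background exceeded the sample; the setpoint is
                         excluded from all downstream computation.

Temperatures are degrees Celsius, negative, with "warmer" meaning
numerically greater; spectra live on the protocol's setpoint grid with no
interpolation.  Frozen counts are cumulative (a frozen well stays frozen);
non-cumulative inputs are rejected rather than repaired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import beta

__all__ = [
    "TREATMENTS",
    "FLAG_OK",
    "FLAG_BELOW_DETECTION",
    "FLAG_SATURATED",
    "FLAG_NEGATIVE_REMOVED",
    "TemperatureProtocol",
    "DropletSpec",
    "PlateAssay",
    "FrozenFractionCurve",
    "CorrectedCurve",
    "INPSpectrum",
    "ReplicateDecision",
    "compute_frozen_fraction",
    "correct_background",
    "inp_per_cell",
    "detection_limits",
    "binomial_ci",
    "estimate_spectrum",
    "merge_dilutions",
    "replicate_filter",
]

TREATMENTS = (
    "untreated",
    "heated",
    "filtrate",
    "heated_filtrate",
    "axenic",
    "control",
)

FLAG_OK = "ok"
FLAG_BELOW_DETECTION = "below_detection"
FLAG_SATURATED = "saturated"
FLAG_NEGATIVE_REMOVED = "negative_removed"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemperatureProtocol:
    """Ordered sub-zero temperature setpoints with a hold time per step.

    Setpoints must be strictly decreasing, all below 0 °C, with consecutive
    gaps inside ``[min_step, max_step]`` (default 1–2 °C, configurable for
    non-standard ramps).
    """

    setpoints: tuple[float, ...]
    hold_minutes: float = 30.0
    min_step: float = 1.0
    max_step: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "setpoints", tuple(float(t) for t in self.setpoints))
        if not self.setpoints:
            raise ValueError("protocol needs at least one setpoint")
        if self.hold_minutes <= 0:
            raise ValueError("hold_minutes must be positive")
        if any(t >= 0 for t in self.setpoints):
            raise ValueError("all setpoints must be below 0 °C")
        for warm, cold in zip(self.setpoints, self.setpoints[1:]):
            gap = warm - cold
            if gap <= 0:
                raise ValueError("setpoints must be strictly decreasing")
            if not (self.min_step - 1e-9 <= gap <= self.max_step + 1e-9):
                raise ValueError(
                    f"setpoint gap {gap:g} °C outside [{self.min_step:g}, "
                    f"{self.max_step:g}] between {warm:g} and {cold:g}"
                )

    def __len__(self) -> int:
        return len(self.setpoints)

    @classmethod
    def default(cls) -> "TemperatureProtocol":
        """Screening ramp: -2 to -28 °C in 2 °C steps, 30 min holds."""
        return cls(tuple(float(t) for t in range(-2, -30, -2)))


@dataclass(frozen=True)
class DropletSpec:
    """Physical description of the droplets on one plate.

    ``cells_per_ul`` may be 0 only for cell-free plates (buffer controls and
    filtrates), which are analysed per droplet.  ``source_cells_per_ul``
    optionally records the concentration of the suspension a filtrate was
    prepared from; the simulator uses it to scale exuded (soluble) activity,
    the estimator never does.
    """

    volume_ul: float = 20.0
    cells_per_ul: float = 0.0
    dilution_factor: float = 1.0
    source_cells_per_ul: float | None = None

    def __post_init__(self) -> None:
        if self.volume_ul <= 0:
            raise ValueError("volume_ul must be positive")
        if self.cells_per_ul < 0:
            raise ValueError("cells_per_ul must be non-negative")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")

    @property
    def cells_per_droplet(self) -> float:
        return self.cells_per_ul * self.volume_ul

    @property
    def normalisation(self) -> float:
        """Denominator of the Vali relation: c*V, or V for cell-free plates."""
        return self.cells_per_droplet if self.cells_per_ul > 0 else self.volume_ul

    @property
    def unit(self) -> str:
        return "per_cell" if self.cells_per_ul > 0 else "per_droplet"


@dataclass(frozen=True)
class PlateAssay:
    """Cumulative frozen-well counts for one sample×treatment×replicate×dilution."""

    sample_id: str
    treatment: str
    replicate_id: str
    droplet: DropletSpec
    protocol: TemperatureProtocol
    frozen_counts: tuple[int, ...]
    n_wells: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        counts = tuple(int(k) for k in self.frozen_counts)
        object.__setattr__(self, "frozen_counts", counts)
        if len(counts) != len(self.protocol):
            raise ValueError(
                f"{len(counts)} frozen counts for {len(self.protocol)} setpoints"
            )
        prev = 0
        for t, k in zip(self.protocol.setpoints, counts):
            if not 0 <= k <= self.n_wells:
                raise ValueError(
                    f"frozen count {k} at {t:g} °C outside [0, {self.n_wells}]"
                )
            if k < prev:
                raise ValueError(
                    f"frozen counts decrease at {t:g} °C ({prev} -> {k}); "
                    "counts must be cumulative"
                )
            prev = k


@dataclass(frozen=True)
class FrozenFractionCurve:
    """Fraction of wells frozen at each setpoint (non-decreasing with cooling)."""

    protocol: TemperatureProtocol
    fractions: tuple[float, ...]
    n_wells: int
    role: Literal["sample", "control"] = "sample"

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "fractions", fr)
        if len(fr) != len(self.protocol):
            raise ValueError("fraction/setpoint length mismatch")
        if any(not 0.0 <= f <= 1.0 for f in fr):
            raise ValueError("frozen fractions must lie in [0, 1]")
        if any(b < a - 1e-12 for a, b in zip(fr, fr[1:])):
            raise ValueError("frozen fractions must be non-decreasing with cooling")

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(int(round(f * self.n_wells)) for f in self.fractions)


@dataclass(frozen=True)
class CorrectedCurve:
    """Background-corrected frozen fractions with per-setpoint exclusion flags."""

    protocol: TemperatureProtocol
    values: tuple[float, ...]
    excluded: tuple[bool, ...]  # True where sample - control < 0


@dataclass(frozen=True)
class INPSpectrum:
    """Cumulative INP spectrum for one assay, on the protocol's setpoint grid.

    ``values`` hold the estimate (NaN where the setpoint was removed),
    ``ci_low``/``ci_high`` the propagated 95 % (by default) binomial bounds,
    and ``flags`` the per-setpoint status.  ``unit`` is ``per_cell`` or
    ``per_droplet`` depending on whether the plate contained cells.
    """

    protocol: TemperatureProtocol
    values: tuple[float, ...]
    ci_low: tuple[float, ...]
    ci_high: tuple[float, ...]
    flags: tuple[str, ...]
    unit: str
    n_wells: int
    droplet: DropletSpec
    sample_id: str = ""
    treatment: str = "untreated"
    replicate_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.protocol)
        for name in ("values", "ci_low", "ci_high", "flags"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match the protocol")
        for v, lo, hi, fl in zip(self.values, self.ci_low, self.ci_high, self.flags):
            if fl == FLAG_NEGATIVE_REMOVED:
                continue
            if fl == FLAG_OK and v < 0:
                raise ValueError("ok estimates must be non-negative")
            if not (lo - 1e-12 <= v <= hi + 1e-12):
                raise ValueError("estimate must lie inside its confidence bounds")

    @property
    def setpoints(self) -> tuple[float, ...]:
        return self.protocol.setpoints

    def ok_mask(self) -> np.ndarray:
        return np.array([fl == FLAG_OK for fl in self.flags])

    def lower_detection_limit(self) -> float:
        return detection_limits(self.n_wells, self.droplet)[0]


@dataclass(frozen=True)
class ReplicateDecision:
    """Keep/drop outcome of the three-replicate quality filter."""

    retained: bool
    reason: str
    spectra: tuple[INPSpectrum, ...]


# ---------------------------------------------------------------------------
# estimation chain
# ---------------------------------------------------------------------------


def compute_frozen_fraction(assay: PlateAssay) -> FrozenFractionCurve:
    """Frozen fraction per setpoint: frozen wells over total wells.

    Monotonicity is inherited from the cumulative counts (PlateAssay rejects
    decreasing counts, naming the offending setpoint).
    """
    fractions = tuple(k / assay.n_wells for k in assay.frozen_counts)
    role = "control" if assay.treatment == "control" else "sample"
    return FrozenFractionCurve(assay.protocol, fractions, assay.n_wells, role)


def correct_background(
    sample: FrozenFractionCurve, control: FrozenFractionCurve
) -> CorrectedCurve:
    """Subtract the buffer control's frozen fraction from the sample's.

    Setpoints where the control exceeds the sample yield negative corrected
    fractions; these are flagged for removal (not clipped to zero) and carry
    no estimate downstream.
    """
    if sample.protocol.setpoints != control.protocol.setpoints:
        raise ValueError(
            "sample and control curves are on different temperature protocols"
        )
    values = tuple(s - c for s, c in zip(sample.fractions, control.fractions))
    excluded = tuple(v < 0 for v in values)
    return CorrectedCurve(sample.protocol, values, excluded)


def inp_per_cell(ff_corrected: float, droplet: DropletSpec) -> float:
    """Vali relation: cumulative INP per cell from a corrected frozen fraction.

    ``-ln(1 - ff) / (c * V)``; strictly increasing in ``ff_corrected`` and
    inversely proportional to both c and V.  ``ff_corrected`` must be in
    [0, 1): a fully frozen plate carries no finite estimate (see
    ``estimate_spectrum`` for the saturation bound).  Requires a plate with
    cells; cell-free plates use per-droplet normalisation instead.
    """
    if not 0.0 <= ff_corrected < 1.0:
        raise ValueError(
            f"ff_corrected must lie in [0, 1); got {ff_corrected!r}"
            + (" (saturated plate)" if ff_corrected == 1.0 else "")
        )
    if droplet.cells_per_ul <= 0:
        raise ValueError(
            "cells_per_ul is 0: per-cell normalisation unavailable, "
            "use per-droplet mode"
        )
    return -math.log1p(-ff_corrected) / droplet.cells_per_droplet


def _inp_per_norm(ff: float, normalisation: float) -> float:
    return -math.log1p(-ff) / normalisation


def detection_limits(n_wells: int, droplet: DropletSpec) -> tuple[float, float]:
    """Smallest and largest INP concentrations a plate of n wells resolves.

    Lower limit: one frozen well, ``-ln(1 - 1/n) / (cV)``.  Upper limit: the
    near-saturation bound with FF = (n - 0.5)/n, the same continuity-corrected
    fraction used for saturated setpoints.
    """
    if n_wells < 2:
        raise ValueError("n_wells must be >= 2 for detection limits")
    norm = droplet.normalisation
    if norm <= 0:
        raise ValueError("droplet normalisation (cV or V) must be positive")
    lower = _inp_per_norm(1.0 / n_wells, norm)
    upper = _inp_per_norm((n_wells - 0.5) / n_wells, norm)
    return lower, upper


def binomial_ci(k_frozen: int, n_wells: int, level: float = 0.95) -> tuple[float, float]:
    """Two-sided Clopper–Pearson interval for a frozen-well proportion."""
    if not 0 <= k_frozen <= n_wells:
        raise ValueError("k_frozen must lie in [0, n_wells]")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if k_frozen == 0 else float(beta.ppf(alpha / 2, k_frozen, n_wells - k_frozen + 1))
    high = 1.0 if k_frozen == n_wells else float(
        beta.ppf(1 - alpha / 2, k_frozen + 1, n_wells - k_frozen)
    )
    return low, high


def estimate_spectrum(
    sample: PlateAssay,
    control: PlateAssay | None = None,
    ci_level: float = 0.95,
) -> INPSpectrum:
    """Full chain from one plate (plus optional buffer control) to a spectrum.

    Per setpoint: correct the sample frozen fraction by the control's, apply
    the Vali relation, propagate the Clopper–Pearson interval on the sample
    proportion through the same monotone map (after background shift, clipped
    at 0), and assign a status flag.  A fully frozen sample plate (k = n) is
    saturated regardless of the control: the reported value is the
    continuity-corrected lower bound FF = (n - 0.5)/n minus the background,
    with an unbounded upper confidence limit.
    """
    ff_sample = compute_frozen_fraction(sample)
    if control is not None:
        if control.treatment != "control":
            raise ValueError("background plate must carry treatment 'control'")
        corrected = correct_background(ff_sample, compute_frozen_fraction(control))
    else:
        corrected = CorrectedCurve(
            sample.protocol, ff_sample.fractions, (False,) * len(sample.protocol)
        )

    norm = sample.droplet.normalisation
    lower_limit = detection_limits(sample.n_wells, sample.droplet)[0]
    sat_ff = (sample.n_wells - 0.5) / sample.n_wells

    values, lows, highs, flags = [], [], [], []
    for k, ff_corr, excl in zip(
        sample.frozen_counts, corrected.values, corrected.excluded
    ):
        if excl:
            values.append(math.nan)
            lows.append(math.nan)
            highs.append(math.nan)
            flags.append(FLAG_NEGATIVE_REMOVED)
            continue
        ctrl_ff = (k / sample.n_wells) - ff_corr  # background at this setpoint
        ci_lo_ff, ci_hi_ff = binomial_ci(k, sample.n_wells, ci_level)
        lo_ff = max(ci_lo_ff - ctrl_ff, 0.0)
        lo = _inp_per_norm(lo_ff, norm)
        if k == sample.n_wells:
            # all wells frozen: the plate cannot resolve activity above its
            # upper detection limit, whatever the control shows
            value = _inp_per_norm(max(sat_ff - ctrl_ff, 0.0), norm)
            flag = FLAG_SATURATED
            hi = math.inf
        else:
            hi_ff = max(ci_hi_ff - ctrl_ff, 0.0)  # < 1 since k < n
            hi = _inp_per_norm(hi_ff, norm)
            value = _inp_per_norm(ff_corr, norm)
            flag = FLAG_OK if value >= lower_limit else FLAG_BELOW_DETECTION
        values.append(value)
        lows.append(min(lo, value))
        highs.append(max(hi, value))
        flags.append(flag)

    return INPSpectrum(
        protocol=sample.protocol,
        values=tuple(values),
        ci_low=tuple(lows),
        ci_high=tuple(highs),
        flags=tuple(flags),
        unit=sample.droplet.unit,
        n_wells=sample.n_wells,
        droplet=sample.droplet,
        sample_id=sample.sample_id,
        treatment=sample.treatment,
        replicate_id=sample.replicate_id,
    )


def merge_dilutions(spectra: Sequence[INPSpectrum]) -> INPSpectrum:
    """Combine a dilution series into one spectrum.

    Per setpoint only dilutions flagged ``ok`` contribute; the combined
    estimate (and each confidence bound) is their unweighted arithmetic mean.
    Where no dilution is usable the flags propagate: any saturated dilution
    dominates (the largest saturation bound is kept as a lower-bound value),
    otherwise below_detection, otherwise negative_removed.  The result is
    order-invariant in the input.
    """
    if not spectra:
        raise ValueError("merge_dilutions needs at least one spectrum")
    first = spectra[0]
    for s in spectra[1:]:
        if s.protocol.setpoints != first.protocol.setpoints:
            raise ValueError("dilution spectra are on different protocols")
        if s.unit != first.unit:
            raise ValueError("cannot merge per-cell with per-droplet spectra")
    if len(spectra) == 1:
        return first

    values, lows, highs, flags = [], [], [], []
    for i in range(len(first.protocol)):
        entries = [(s.values[i], s.ci_low[i], s.ci_high[i], s.flags[i]) for s in spectra]
        ok = [(v, lo, hi) for v, lo, hi, fl in entries if fl == FLAG_OK]
        if ok:
            values.append(float(np.mean([v for v, _, _ in ok])))
            lows.append(float(np.mean([lo for _, lo, _ in ok])))
            highs.append(float(np.mean([hi for _, _, hi in ok])))
            flags.append(FLAG_OK)
            continue
        sat = [(v, lo, hi) for v, lo, hi, fl in entries if fl == FLAG_SATURATED]
        if sat:
            v, lo, hi = max(sat, key=lambda e: e[0])
            values.append(v)
            lows.append(lo)
            highs.append(hi)
            flags.append(FLAG_SATURATED)
        elif any(fl == FLAG_BELOW_DETECTION for *_, fl in entries):
            bd = [(v, lo, hi) for v, lo, hi, fl in entries if fl == FLAG_BELOW_DETECTION]
            values.append(float(np.mean([v for v, _, _ in bd])))
            lows.append(float(np.mean([lo for _, lo, _ in bd])))
            highs.append(float(np.mean([hi for _, _, hi in bd])))
            flags.append(FLAG_BELOW_DETECTION)
        else:
            values.append(math.nan)
            lows.append(math.nan)
            highs.append(math.nan)
            flags.append(FLAG_NEGATIVE_REMOVED)

    # the merged spectrum keeps the least-diluted plate's droplet for metadata
    base = min(spectra, key=lambda s: s.droplet.dilution_factor)
    return INPSpectrum(
        protocol=first.protocol,
        values=tuple(values),
        ci_low=tuple(lows),
        ci_high=tuple(highs),
        flags=tuple(flags),
        unit=first.unit,
        n_wells=base.n_wells,
        droplet=base.droplet,
        sample_id=base.sample_id,
        treatment=base.treatment,
        replicate_id=base.replicate_id,
    )


def replicate_filter(spectra: Sequence[INPSpectrum]) -> ReplicateDecision:
    """Three-replicate quality rule: keep a strain only if every biological
    replicate shows activity above the plate's lower detection limit at one
    or more setpoints (flag ``ok``)."""
    if len(spectra) != 3:
        raise ValueError(
            f"replicate_filter expects exactly 3 biological replicates "
            f"(the assay design), got {len(spectra)}"
        )
    for idx, spec in enumerate(spectra):
        limit = spec.lower_detection_limit()
        active = any(
            fl == FLAG_OK and v >= limit for v, fl in zip(spec.values, spec.flags)
        )
        if not active:
            return ReplicateDecision(
                False,
                f"replicate {spec.replicate_id or idx} has no setpoint above "
                "the detection limit",
                tuple(spectra),
            )
    return ReplicateDecision(True, "all three replicates above detection", tuple(spectra))
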