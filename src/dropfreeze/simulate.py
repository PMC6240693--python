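"""Synthetic droplet-freezing data with known ground truth.

The generator emulates the study design the analysis modules expect: plates
of 16–32 wells of 20–30 µL cooled from -2 to -28 °C in 1–2 °C steps, a PBS
background control on every plate batch, treatment arms (heated, filtrate,
heated+filtrate, axenic) and a two-habitat strain panel (airborne vs
aquatic) with configurable INA prevalence, onset-temperature class mix,
taxonomy composition and survival outcomes.

Freezing follows the singular (time-independent) approximation that also
underlies the Vali relation: a well freezes at the warmest setpoint T where
its uniform draw u falls below 1 - exp(-rate(T)), with

    rate(T) = K(T) * c * V + K_bg(T)

K(T) the per-cell cumulative INP spectrum (a sum of log-linear components
A * exp(gamma * (onset - T)) for T <= onset) and K_bg a small per-droplet
background representing buffer/impurity freezing.  Hold-time kinetics and
droplet-volume variability are deliberately not modelled.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .assay import DropletSpec, PlateAssay, TemperatureProtocol

__all__ = [
    "SpectrumComponent",
    "SpectrumModel",
    "PanelConfig",
    "StrainTruth",
    "Panel",
    "default_background",
    "simulate_plate",
    "simulate_treatment_batch",
    "apply_treatment",
    "generate_strain_panel",
    "substream_seed",
]

PROTEIN_CLASSES = ("proteinaceous", "non_proteinaceous")
LOCALIZATIONS = ("particulate", "soluble")


@dataclass(frozen=True)
class SpectrumComponent:
    """One log-linear component of a cumulative per-cell INP spectrum.

    ``K(T) = amplitude_a * exp(slope_gamma * (onset_t - T))`` for
    ``T <= onset_t``, else 0; non-decreasing as T decreases.  ``epibiont``
    marks activity contributed by phycosphere bacteria rather than the alga,
    which the axenic (antibiotic) treatment attenuates.
    """

    protein_class: str
    localization: str
    onset_t: float
    amplitude_a: float
    slope_gamma: float
    epibiont: bool = False

    def __post_init__(self) -> None:
        if self.protein_class not in PROTEIN_CLASSES:
            raise ValueError(f"unknown protein_class {self.protein_class!r}")
        if self.localization not in LOCALIZATIONS:
            raise ValueError(f"unknown localization {self.localization!r}")
        if self.amplitude_a < 0:
            raise ValueError("amplitude_a must be non-negative")
        if self.slope_gamma < 0:
            raise ValueError("slope_gamma must be non-negative")

    def cumulative(self, temps) -> np.ndarray:
        """K(T) on an array of temperatures (°C)."""
        t = np.asarray(temps, dtype=float)
        active = t <= self.onset_t
        return np.where(
            active, self.amplitude_a * np.exp(self.slope_gamma * (self.onset_t - t)), 0.0
        )


def default_background() -> SpectrumComponent:
    """Per-droplet buffer/impurity background.

    Tuned so a 16-well PBS control rarely shows any frozen well above
    -24 °C (expected frozen wells at -24 °C ≈ 16 * 5e-3 ≈ 0.08).
    """
    return SpectrumComponent(
        protein_class="non_proteinaceous",
        localization="soluble",
        onset_t=-20.0,
        amplitude_a=1e-3,
        slope_gamma=0.4,
    )


@dataclass(frozen=True)
class SpectrumModel:
    """Ground-truth spectrum: per-cell components plus a per-droplet background."""

    components: tuple[SpectrumComponent, ...] = ()
    background_per_droplet: SpectrumComponent | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))

    def per_cell(self, temps) -> np.ndarray:
        """Total per-cell cumulative spectrum K(T) (cell^-1)."""
        t = np.asarray(temps, dtype=float)
        total = np.zeros_like(t)
        for comp in self.components:
            total += comp.cumulative(t)
        return total

    def background(self, temps) -> np.ndarray:
        t = np.asarray(temps, dtype=float)
        if self.background_per_droplet is None:
            return np.zeros_like(t)
        return self.background_per_droplet.cumulative(t)

    def droplet_rate(self, temps, droplet: DropletSpec) -> np.ndarray:
        """Expected INP per droplet at each setpoint.

        Per-cell components scale with the droplet's cell load; for
        cell-free droplets (filtrates) the source suspension's concentration
        scales the exuded soluble activity instead.
        """
        c_eff = droplet.cells_per_ul
        if c_eff <= 0 and droplet.source_cells_per_ul is not None:
            c_eff = droplet.source_cells_per_ul
        return self.per_cell(temps) * c_eff * droplet.volume_ul + self.background(temps)


def substream_seed(master_seed: int, *keys) -> int:
    """Deterministic per-plate seed derived from a master seed and labels."""
    digest = hashlib.sha256(
        ("/".join([str(master_seed), *map(str, keys)])).encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def simulate_plate(
    model: SpectrumModel,
    droplet: DropletSpec,
    protocol: TemperatureProtocol,
    n_wells: int,
    seed: int | np.random.Generator,
    sample_id: str = "sim",
    treatment: str = "untreated",
    replicate_id: str = "r1",
) -> PlateAssay:
    """Simulate one plate under the singular freezing approximation.

    Each well draws u ~ U(0, 1) once and freezes at the warmest setpoint
    where 1 - exp(-rate(T)) >= u; cumulative counts follow.  The same seed
    always yields the identical plate.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    temps = np.asarray(protocol.setpoints)
    p_frozen = 1.0 - np.exp(-model.droplet_rate(temps, droplet))
    u = rng.uniform(size=n_wells)
    counts = (u[None, :] <= p_frozen[:, None]).sum(axis=1)
    return PlateAssay(
        sample_id=sample_id,
        treatment=treatment,
        replicate_id=replicate_id,
        droplet=droplet,
        protocol=protocol,
        frozen_counts=tuple(int(k) for k in counts),
        n_wells=n_wells,
    )


def apply_treatment(
    model: SpectrumModel,
    treatment: str,
    axenic_attenuation: float = 0.05,
) -> SpectrumModel:
    """Transform a ground-truth model according to a laboratory treatment.

    * ``heated``          — 100 °C denatures proteins: proteinaceous
                            components are removed.
    * ``filtrate``        — 0.22 µm filtration removes cells and fragments:
                            only soluble components remain (per-droplet
                            analysis semantics; the simulator scales exudates
                            by the source concentration).
    * ``heated_filtrate`` — composition of both.
    * ``axenic``          — antibiotic treatment attenuates components marked
                            as epibiont by ``axenic_attenuation``.

    The per-droplet buffer background is untouched (it is soluble and
    non-proteinaceous by nature).  ``heated`` and ``filtrate`` are idempotent.
    """
    if treatment == "heated":
        keep = tuple(
            c for c in model.components if c.protein_class != "proteinaceous"
        )
        return replace(model, components=keep)
    if treatment == "filtrate":
        keep = tuple(c for c in model.components if c.localization == "soluble")
        return replace(model, components=keep)
    if treatment == "heated_filtrate":
        return apply_treatment(apply_treatment(model, "heated"), "filtrate")
    if treatment == "axenic":
        comps = tuple(
            replace(c, amplitude_a=c.amplitude_a * axenic_attenuation)
            if c.epibiont
            else c
            for c in model.components
        )
        return replace(model, components=comps)
    raise ValueError(f"unknown treatment {treatment!r}")


def simulate_treatment_batch(
    model: SpectrumModel,
    droplet: DropletSpec,
    protocol: TemperatureProtocol,
    n_wells: int,
    seed: int,
    treatments: Sequence[str] = ("untreated", "heated", "filtrate"),
    sample_id: str = "sim",
    replicate_id: str = "r1",
) -> dict[str, PlateAssay]:
    """Simulate one batch: treatment arms plus the PBS control plate.

    Filtrate-type arms get a cell-free droplet whose ``source_cells_per_ul``
    records the untreated suspension's concentration so exuded soluble
    activity scales correctly; all other arms share ``droplet``.  Each arm
    draws from its own deterministic substream of ``seed``.
    """
    plates: dict[str, PlateAssay] = {}
    for treatment in treatments:
        arm_model = model if treatment == "untreated" else apply_treatment(model, treatment)
        if treatment in ("filtrate", "heated_filtrate"):
            arm_droplet = DropletSpec(
                volume_ul=droplet.volume_ul,
                cells_per_ul=0.0,
                dilution_factor=droplet.dilution_factor,
                source_cells_per_ul=droplet.cells_per_ul,
            )
        else:
            arm_droplet = droplet
        plates[treatment] = simulate_plate(
            arm_model, arm_droplet, protocol, n_wells,
            substream_seed(seed, sample_id, replicate_id, treatment),
            sample_id=sample_id, treatment=treatment, replicate_id=replicate_id,
        )
    plates["control"] = simulate_plate(
        SpectrumModel(background_per_droplet=model.background_per_droplet),
        DropletSpec(volume_ul=droplet.volume_ul),
        protocol, n_wells,
        substream_seed(seed, sample_id, replicate_id, "control"),
        sample_id=sample_id, treatment="control", replicate_id=replicate_id,
    )
    return plates


# ---------------------------------------------------------------------------
# strain-panel generation
# ---------------------------------------------------------------------------

# onset-temperature class windows (°C), warm edge inclusive
CLASS_WINDOWS = {
    "warm": (-6.0, -4.0),
    "mid": (-12.0, -7.0),
    "cool": (-18.0, -13.0),
    "cold": (-24.0, -19.0),
}


@dataclass(frozen=True)
class PanelConfig:
    """Study-design parameters for the synthetic strain panel.

    Defaults mirror the study conditions: 81 airborne strains of which 14
    are confirmed INA (66 screen positive initially), 32 aquatic strains of
    which 16 are INA; airborne INA onsets biased warm (6 warm / 5 mid /
    3 cool) and aquatic biased cold (2 mid / 12 cool / 2 cold); 10 of 32
    aquatic strains survive freezing while all 38 tested airborne strains
    do; 11 aquatic strains desiccation-tested, none surviving.  Screens use
    16 wells, freezing profiles 32 wells × 3 biological replicates × a
    10-fold dilution series.
    """

    n_airborne: int = 81
    n_aquatic: int = 32
    n_ina_airborne: int = 14
    n_ina_aquatic: int = 16
    n_screen_positive_airborne: int = 66
    airborne_class_counts: tuple[tuple[str, int], ...] = (
        ("warm", 6),
        ("mid", 5),
        ("cool", 3),
    )
    aquatic_class_counts: tuple[tuple[str, int], ...] = (
        ("mid", 2),
        ("cool", 12),
        ("cold", 2),
    )
    airborne_taxonomy: tuple[tuple[str, str, int], ...] = (
        ("Chlorophyta", "Trebouxiophyceae", 40),
        ("Chlorophyta", "Chlorophyceae", 6),
        ("Stramenopiles", "Xanthophyceae", 11),
        ("unknown", "unknown", 24),
    )
    n_freeze_tested_airborne: int = 38
    n_freeze_survivors_airborne: int = 38
    n_freeze_survivors_aquatic: int = 10
    n_desiccation_tested_aquatic: int = 11
    n_desiccation_survivors_aquatic: int = 0
    generalist_fraction: float = 0.5
    media: tuple[str, ...] = ("ARW", "MWC", "f2_25", "f2_100")
    isolation_medium_counts: tuple[tuple[str, int], ...] = (
        ("MWC", 52),
        ("f2_25", 20),
        ("ARW", 9),
    )
    screen_wells: int = 16
    profile_wells: int = 32
    n_replicates: int = 3
    dilution_factors: tuple[float, ...] = (1.0, 10.0, 100.0)
    stock_cells_per_ul: float = 100.0
    droplet_volume_ul: float = 20.0
    amplitude_range: tuple[float, float] = (1e-4, 1e-2)
    slope_range: tuple[float, float] = (0.4, 0.8)
    proteinaceous_fraction: float = 0.85
    particulate_fraction: float = 0.85

    def validate(self) -> None:
        if self.n_ina_airborne > self.n_airborne or self.n_ina_aquatic > self.n_aquatic:
            raise ValueError("INA prevalence exceeds group size")
        if not self.n_ina_airborne <= self.n_screen_positive_airborne <= self.n_airborne:
            raise ValueError(
                "initial screen positives must lie between confirmed INA "
                "count and group size"
            )
        if sum(n for _, n in self.airborne_class_counts) != self.n_ina_airborne:
            raise ValueError("airborne class mix must sum to n_ina_airborne")
        if sum(n for _, n in self.aquatic_class_counts) != self.n_ina_aquatic:
            raise ValueError("aquatic class mix must sum to n_ina_aquatic")
        if sum(n for _, _, n in self.airborne_taxonomy) != self.n_airborne:
            raise ValueError("airborne taxonomy counts must sum to n_airborne")
        if sum(n for _, n in self.isolation_medium_counts) != self.n_airborne:
            raise ValueError("isolation medium counts must sum to n_airborne")
        if self.n_freeze_survivors_aquatic > self.n_aquatic:
            raise ValueError("aquatic freeze survivors exceed group size")
        if not 0.0 <= self.generalist_fraction <= 1.0:
            raise ValueError("generalist_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class StrainTruth:
    """Generating model and latent labels for one synthetic strain."""

    strain_id: str
    source: str
    model: SpectrumModel
    ina: bool
    screen_only: bool
    temperature_class: str | None


@dataclass(frozen=True)
class Panel:
    """A synthetic strain panel: metadata records, plates, and ground truth."""

    records: tuple  # tuple[StrainRecord, ...]; typed loosely to avoid a cycle
    plates: tuple[PlateAssay, ...]
    truth: tuple[StrainTruth, ...]


def _draw_component(
    rng: np.random.Generator, cls: str, config: PanelConfig
) -> SpectrumComponent:
    lo_t, hi_t = CLASS_WINDOWS[cls]
    onset = float(rng.uniform(lo_t, hi_t))
    log_a = rng.uniform(*np.log(config.amplitude_range))
    protein = (
        "proteinaceous"
        if rng.uniform() < config.proteinaceous_fraction
        else "non_proteinaceous"
    )
    local = (
        "particulate"
        if rng.uniform() < config.particulate_fraction
        else "soluble"
    )
    return SpectrumComponent(
        protein_class=protein,
        localization=local,
        onset_t=onset,
        amplitude_a=float(np.exp(log_a)),
        slope_gamma=float(rng.uniform(*config.slope_range)),
    )


def generate_strain_panel(config: PanelConfig, seed: int) -> Panel:
    """Build a reproducible synthetic panel under the configured design.

    Every strain receives two 16-well screening plates (plus matched PBS
    controls); confirmed-INA strains additionally receive 3 biological
    replicates × a 10-fold dilution series of 32-well profile plates with
    per-replicate controls.  Identical seed and config give byte-identical
    output.
    """
    from .strains import StrainRecord  # local import: strains depends on assay only

    config.validate()
    rng = np.random.default_rng(substream_seed(seed, "panel"))
    protocol = TemperatureProtocol.default()
    background = default_background()

    records: list[StrainRecord] = []
    plates: list[PlateAssay] = []
    truths: list[StrainTruth] = []

    groups = (
        ("airborne", config.n_airborne, config.n_ina_airborne,
         config.airborne_class_counts),
        ("aquatic", config.n_aquatic, config.n_ina_aquatic,
         config.aquatic_class_counts),
    )
    # airborne taxonomy / medium assignment orders are shuffled once
    air_taxa = [
        (phylum, cls)
        for phylum, cls, n in config.airborne_taxonomy
        for _ in range(n)
    ]
    rng.shuffle(air_taxa)
    air_media = [m for m, n in config.isolation_medium_counts for _ in range(n)]
    rng.shuffle(air_media)

    for source, n_total, n_ina, class_counts in groups:
        classes = [cls for cls, n in class_counts for _ in range(n)]
        ina_idx = set(rng.choice(n_total, size=n_ina, replace=False).tolist())
        if source == "airborne":
            pool = [i for i in range(n_total) if i not in ina_idx]
            extra = config.n_screen_positive_airborne - n_ina
            screen_only_idx = set(
                rng.choice(pool, size=extra, replace=False).tolist()
            ) if extra else set()
            freeze_tested = set(
                rng.choice(n_total, size=config.n_freeze_tested_airborne,
                           replace=False).tolist()
            )
            desiccation_tested: set[int] = set()
            n_freeze_surv = config.n_freeze_survivors_airborne
        else:
            screen_only_idx = set()
            freeze_tested = set(range(n_total))
            desiccation_tested = set(
                rng.choice(n_total, size=config.n_desiccation_tested_aquatic,
                           replace=False).tolist()
            )
            n_freeze_surv = config.n_freeze_survivors_aquatic
        freeze_surv_idx = set(
            rng.choice(sorted(freeze_tested), size=n_freeze_surv,
                       replace=False).tolist()
        )
        desic_surv_idx = set(
            rng.choice(sorted(desiccation_tested),
                       size=config.n_desiccation_survivors_aquatic,
                       replace=False).tolist()
        ) if desiccation_tested else set()

        class_iter = iter(classes)
        for i in range(n_total):
            strain_id = f"{source[:3].upper()}-{i + 1:03d}"
            is_ina = i in ina_idx
            cls = next(class_iter) if is_ina else None
            comps = (_draw_component(rng, cls, config),) if is_ina else ()
            model = SpectrumModel(components=comps, background_per_droplet=background)
            truths.append(
                StrainTruth(strain_id, source, model, is_ina,
                            i in screen_only_idx, cls)
            )

            droplet = DropletSpec(
                volume_ul=config.droplet_volume_ul,
                cells_per_ul=config.stock_cells_per_ul,
            )
            for screen_no in (1, 2):
                s_seed = substream_seed(seed, strain_id, "screen", screen_no)
                plates.append(
                    simulate_plate(model, droplet, protocol, config.screen_wells,
                                   s_seed, sample_id=strain_id,
                                   treatment="untreated",
                                   replicate_id=f"screen{screen_no}")
                )
                plates.append(
                    simulate_plate(
                        SpectrumModel(background_per_droplet=background),
                        DropletSpec(volume_ul=config.droplet_volume_ul),
                        protocol, config.screen_wells,
                        substream_seed(seed, strain_id, "screen-ctrl", screen_no),
                        sample_id=strain_id, treatment="control",
                        replicate_id=f"screen{screen_no}",
                    )
                )
            if is_ina:
                for rep in range(1, config.n_replicates + 1):
                    rep_id = f"rep{rep}"
                    for dil in config.dilution_factors:
                        d = DropletSpec(
                            volume_ul=config.droplet_volume_ul,
                            cells_per_ul=config.stock_cells_per_ul / dil,
                            dilution_factor=dil,
                        )
                        plates.append(
                            simulate_plate(
                                model, d, protocol, config.profile_wells,
                                substream_seed(seed, strain_id, rep_id, dil),
                                sample_id=strain_id, treatment="untreated",
                                replicate_id=rep_id,
                            )
                        )
                    plates.append(
                        simulate_plate(
                            SpectrumModel(background_per_droplet=background),
                            DropletSpec(volume_ul=config.droplet_volume_ul),
                            protocol, config.profile_wells,
                            substream_seed(seed, strain_id, rep_id, "ctrl"),
                            sample_id=strain_id, treatment="control",
                            replicate_id=rep_id,
                        )
                    )

            if source == "airborne":
                phylum, tax_class = air_taxa[i]
                iso_medium = air_media[i]
                candidate_media = ("ARW", "MWC", "f2_25")
            else:
                phylum, tax_class = "aquatic_collection", "mixed"
                iso_medium = "MWC" if rng.uniform() < 0.5 else "f2_25"
                candidate_media = ("MWC", "f2_25", "f2_100")
            growth = {m: False for m in config.media}
            growth[iso_medium] = True
            if rng.uniform() < config.generalist_fraction:
                others = [m for m in candidate_media if m != iso_medium]
                n_extra = int(rng.integers(1, len(others) + 1))
                for m in rng.choice(others, size=n_extra, replace=False):
                    growth[str(m)] = True

            if i in freeze_tested:
                freeze = "survived" if i in freeze_surv_idx else "killed"
            else:
                freeze = "untested"
            if i in desiccation_tested:
                desic = "survived" if i in desic_surv_idx else "killed"
            else:
                desic = "untested"
            if is_ina:
                ina_status = "confirmed"
            elif i in screen_only_idx:
                ina_status = "screened_only"
            else:
                ina_status = "negative"

            records.append(
                StrainRecord(
                    strain_id=strain_id,
                    source=source,
                    taxon={"phylum": phylum, "class": tax_class,
                           "genus": None, "species": None},
                    isolation_medium=iso_medium,
                    growth_by_medium=growth,
                    freeze_survival=freeze,
                    desiccation=desic,
                    ina_status=ina_status,
                )
            )

    return Panel(tuple(records), tuple(plates), tuple(truths))
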