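"""Delimited-text readers and writers for plates, spectra and strain tables.

Plate files are comma-separated UTF-8 with a mandatory header, one row per
(sample, treatment, replicate, dilution, setpoint); temperatures are signed
decimals in °C.  A strict validator precedes any computation: malformed rows
are collected with their line numbers instead of aborting the read, and the
caller decides whether to proceed.  Control rows may use sample_id ``*`` for
a plate-batch-shared background.  Spectra are written as JSON records plus a
flat CSV twin; strain metadata travels as TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .assay import (
    DropletSpec,
    INPSpectrum,
    PlateAssay,
    TemperatureProtocol,
)
from .strains import MEDIA, StrainRecord

__all__ = [
    "PLATE_COLUMNS",
    "RowError",
    "read_plates",
    "write_plates",
    "spectra_to_records",
    "write_spectra_json",
    "write_spectra_csv",
    "read_spectra_json",
    "write_strains_tsv",
    "read_strains_tsv",
]

PLATE_COLUMNS = (
    "sample_id",
    "treatment",
    "replicate_id",
    "dilution_factor",
    "cells_per_ul",
    "droplet_ul",
    "temperature_c",
    "frozen_count",
    "n_wells",
)


@dataclass(frozen=True)
class RowError:
    """One malformed input row, traceable by line number."""

    line: int
    message: str


def write_plates(assays: Sequence[PlateAssay], path: str | Path) -> None:
    rows = []
    for a in assays:
        for t, k in zip(a.protocol.setpoints, a.frozen_counts):
            rows.append(
                {
                    "sample_id": a.sample_id,
                    "treatment": a.treatment,
                    "replicate_id": a.replicate_id,
                    "dilution_factor": a.droplet.dilution_factor,
                    "cells_per_ul": a.droplet.cells_per_ul,
                    "droplet_ul": a.droplet.volume_ul,
                    "temperature_c": t,
                    "frozen_count": k,
                    "n_wells": a.n_wells,
                }
            )
    pd.DataFrame(rows, columns=list(PLATE_COLUMNS)).to_csv(path, index=False)


def read_plates(
    path: str | Path,
    protocol_kwargs: dict | None = None,
) -> tuple[list[PlateAssay], list[RowError]]:
    """Parse a plate CSV into PlateAssay objects.

    Rows are grouped by (sample_id, treatment, replicate_id, dilution);
    setpoints are ordered warm-to-cold within each group.  Violations of the
    assay invariants (counts above n_wells, non-cumulative counts, bad
    temperatures) become RowError entries pointing at the offending line.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate file is missing columns: {missing}")
    errors: list[RowError] = []
    parsed = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            parsed.append(
                {
                    "line": line,
                    "sample_id": row["sample_id"],
                    "treatment": row["treatment"],
                    "replicate_id": row["replicate_id"],
                    "dilution_factor": float(row["dilution_factor"]),
                    "cells_per_ul": float(row["cells_per_ul"]),
                    "droplet_ul": float(row["droplet_ul"]),
                    "temperature_c": float(row["temperature_c"]),
                    "frozen_count": int(row["frozen_count"]),
                    "n_wells": int(row["n_wells"]),
                }
            )
        except (TypeError, ValueError) as exc:
            errors.append(RowError(line, f"unparseable row: {exc}"))

    assays: list[PlateAssay] = []
    groups: dict[tuple, list[dict]] = {}
    for rec in parsed:
        key = (
            rec["sample_id"],
            rec["treatment"],
            rec["replicate_id"],
            rec["dilution_factor"],
        )
        groups.setdefault(key, []).append(rec)
    for (sample_id, treatment, replicate_id, dilution), recs in groups.items():
        recs.sort(key=lambda r: -r["temperature_c"])
        first = recs[0]
        try:
            protocol = TemperatureProtocol(
                tuple(r["temperature_c"] for r in recs),
                **(protocol_kwargs or {}),
            )
            droplet = DropletSpec(
                volume_ul=first["droplet_ul"],
                cells_per_ul=first["cells_per_ul"],
                dilution_factor=dilution,
            )
            assays.append(
                PlateAssay(
                    sample_id=sample_id,
                    treatment=treatment,
                    replicate_id=replicate_id,
                    droplet=droplet,
                    protocol=protocol,
                    frozen_counts=tuple(r["frozen_count"] for r in recs),
                    n_wells=first["n_wells"],
                )
            )
        except ValueError as exc:
            errors.append(RowError(first["line"], str(exc)))
    return assays, errors


def spectra_to_records(spectra: Iterable[INPSpectrum]) -> list[dict]:
    records = []
    for s in spectra:
        records.append(
            {
                "sample_id": s.sample_id,
                "treatment": s.treatment,
                "replicate_id": s.replicate_id,
                "unit": s.unit,
                "n_wells": s.n_wells,
                "dilution_factor": s.droplet.dilution_factor,
                "cells_per_ul": s.droplet.cells_per_ul,
                "droplet_ul": s.droplet.volume_ul,
                "setpoints": [
                    {
                        "temperature_c": t,
                        # NaN (removed setpoints) -> null; the saturated
                        # upper bound is unbounded and stored as "inf"
                        "estimate": None if v != v else v,
                        "ci_low": None if lo != lo else lo,
                        "ci_high": (
                            None if hi != hi else ("inf" if hi == float("inf") else hi)
                        ),
                        "flag": fl,
                    }
                    for t, v, lo, hi, fl in zip(
                        s.setpoints, s.values, s.ci_low, s.ci_high, s.flags
                    )
                ],
            }
        )
    return records


def write_spectra_json(spectra: Iterable[INPSpectrum], path: str | Path) -> None:
    Path(path).write_text(json.dumps(spectra_to_records(spectra), indent=1))


def write_spectra_csv(spectra: Iterable[INPSpectrum], path: str | Path) -> None:
    rows = []
    for rec in spectra_to_records(spectra):
        for sp in rec["setpoints"]:
            rows.append(
                {
                    "sample_id": rec["sample_id"],
                    "treatment": rec["treatment"],
                    "replicate_id": rec["replicate_id"],
                    "unit": rec["unit"],
                    "temperature_c": sp["temperature_c"],
                    "estimate": sp["estimate"],
                    "ci_low": sp["ci_low"],
                    "ci_high": sp["ci_high"],
                    "flag": sp["flag"],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_spectra_json(path: str | Path) -> list[INPSpectrum]:
    """Parse spectra written by write_spectra_json back into objects."""
    nan = float("nan")
    out = []
    for rec in json.loads(Path(path).read_text()):
        sps = rec["setpoints"]
        protocol = TemperatureProtocol(tuple(sp["temperature_c"] for sp in sps))
        droplet = DropletSpec(
            volume_ul=rec["droplet_ul"],
            cells_per_ul=rec["cells_per_ul"],
            dilution_factor=rec["dilution_factor"],
        )
        out.append(
            INPSpectrum(
                protocol=protocol,
                values=tuple(nan if sp["estimate"] is None else sp["estimate"] for sp in sps),
                ci_low=tuple(nan if sp["ci_low"] is None else sp["ci_low"] for sp in sps),
                ci_high=tuple(
                    nan if sp["ci_high"] is None
                    else float("inf") if sp["ci_high"] == "inf"
                    else sp["ci_high"]
                    for sp in sps
                ),
                flags=tuple(sp["flag"] for sp in sps),
                unit=rec["unit"],
                n_wells=rec["n_wells"],
                droplet=droplet,
                sample_id=rec["sample_id"],
                treatment=rec["treatment"],
                replicate_id=rec["replicate_id"],
            )
        )
    return out


def write_strains_tsv(records: Sequence[StrainRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "strain_id": r.strain_id,
            "source": r.source,
            "phylum": r.taxon.get("phylum") or "",
            "class": r.taxon.get("class") or "",
            "genus": r.taxon.get("genus") or "",
            "species": r.taxon.get("species") or "",
            "isolation_medium": r.isolation_medium,
            "freeze_survival": r.freeze_survival,
            "desiccation": r.desiccation,
            "ina_status": r.ina_status,
        }
        for m in MEDIA:
            row[f"growth_{m}"] = int(bool(r.growth_by_medium.get(m, False)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_strains_tsv(path: str | Path) -> list[StrainRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        records.append(
            StrainRecord(
                strain_id=row["strain_id"],
                source=row["source"],
                taxon={
                    k: (row[k] or None)
                    for k in ("phylum", "class", "genus", "species")
                },
                isolation_medium=row["isolation_medium"],
                growth_by_medium={
                    m: bool(int(row[f"growth_{m}"])) for m in MEDIA
                },
                freeze_survival=row["freeze_survival"],
                desiccation=row["desiccation"],
                ina_status=row["ina_status"],
            )
        )
    return records
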