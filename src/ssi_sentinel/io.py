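"""CSV readers/writers for cohort tables and YAML config round-trips.

Table layout (UTF-8, header row mandatory, ISO-8601 dates):

* ``surgeries.csv``    surgery_id,patient_id,surgery_date,specialty,department + covariate columns
* ``admissions.csv``   patient_id,admit_date,discharge_date,department,died_in_hospital
* ``reoperations.csv`` patient_id,procedure_date,specialty
* ``radiology.csv``    patient_id,order_date,modality
* ``antibiotics.csv``  patient_id,administration_date,atc_code
* ``microbiology.csv`` patient_id,sample_date,body_site[,relevant_site]
* ``reference.csv``    surgery_id,deep_ssi,annotator_id
* ``deaths.csv``       patient_id,death_date  (optional; joined into admission episodes)

An empty ``discharge_date`` denotes an open stay. When ``relevant_site``
is absent it is derived from ``body_site`` via a relevant-site lookup
(default: abdominal/pelvic/wound/drain/blood).
"""
from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
import yaml
from pydantic import ValidationError

from .model import (
    DEFAULT_RELEVANT_SITES,
    AdmissionEpisode,
    AntibioticAdministration,
    CohortData,
    Covariates,
    EventStreams,
    MicrobiologyCulture,
    RadiologyOrder,
    ReferenceAnnotation,
    ReoperationRecord,
    SurgeryRecord,
    SurveillanceWindowConfig,
)

__all__ = [
    "CohortReadError",
    "read_cohort",
    "write_cohort",
    "load_window_config",
    "save_window_config",
    "TABLE_FILES",
]

TABLE_FILES = {
    "surgeries": "surgeries.csv",
    "admissions": "admissions.csv",
    "reoperations": "reoperations.csv",
    "radiology": "radiology.csv",
    "antibiotics": "antibiotics.csv",
    "microbiology": "microbiology.csv",
    "reference": "reference.csv",
    "deaths": "deaths.csv",
}

_COVARIATE_FIELDS = list(Covariates.model_fields)

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


class CohortReadError(ValueError):
    """Raised for missing files or malformed rows, naming file/line/field."""


def _parse_bool(raw: str, *, file: str, line: int, field: str) -> bool:
    try:
        return _BOOL[raw.strip().lower()]
    except KeyError:
        raise CohortReadError(
            f"{file}, line {line}, field {field!r}: cannot parse boolean from {raw!r}"
        ) from None


def _parse_date(raw: str, *, file: str, line: int, field: str) -> dt.date:
    try:
        return dt.date.fromisoformat(raw.strip())
    except ValueError:
        raise CohortReadError(
            f"{file}, line {line}, field {field!r}: cannot parse ISO date from {raw!r}"
        ) from None


def _read_table(path: Path, required: Iterable[str]) -> pd.DataFrame:
    if not path.exists():
        raise CohortReadError(f"missing input file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(required) - set(df.columns)
    if missing:
        raise CohortReadError(f"{path.name}: missing columns {sorted(missing)}")
    return df


def _row_model(cls, payload: dict, *, file: str, line: int):
    try:
        return cls(**payload)
    except ValidationError as exc:
        first = exc.errors()[0]
        field = ".".join(str(p) for p in first["loc"]) or "<row>"
        raise CohortReadError(
            f"{file}, line {line}, field {field!r}: {first['msg']}"
        ) from None


def _surgery_from_row(row: pd.Series, *, file: str, line: int) -> SurgeryRecord:
    cov: dict = {}
    for name in _COVARIATE_FIELDS:
        raw = str(row.get(name, "")).strip()
        if not raw:
            continue
        ann = Covariates.model_fields[name].annotation
        if ann == Optional[bool]:
            cov[name] = _parse_bool(raw, file=file, line=line, field=name)
        else:
            cov[name] = raw  # pydantic coerces numerics, errors surfaced below
    payload = {
        "surgery_id": row["surgery_id"],
        "patient_id": row["patient_id"],
        "surgery_date": _parse_date(row["surgery_date"], file=file, line=line, field="surgery_date"),
        "specialty": row["specialty"],
        "department": row["department"],
        "covariates": cov,
    }
    return _row_model(SurgeryRecord, payload, file=file, line=line)


def read_cohort(
    source: Union[str, Path, Mapping[str, Union[str, Path]]],
    *,
    relevant_sites: Iterable[str] = DEFAULT_RELEVANT_SITES,
) -> CohortData:
    """Read and validate a cohort from CSV tables.

    ``source`` is either a directory containing the standard file names or
    a mapping table-name -> path. ``surgeries`` is mandatory; every other
    table is optional and defaults to empty. Line numbers in error
    messages are 1-based file lines (header = line 1).
    """
    if isinstance(source, (str, Path)):
        base = Path(source)
        paths = {k: base / v for k, v in TABLE_FILES.items()}
        optional_missing_ok = True
    else:
        paths = {k: Path(v) for k, v in source.items()}
        optional_missing_ok = False
    if "surgeries" not in paths:
        raise CohortReadError("no surgeries table given")

    def table(name: str, required_cols: list[str]) -> pd.DataFrame | None:
        path = paths.get(name)
        if path is None or (optional_missing_ok and not path.exists() and name != "surgeries"):
            return None
        return _read_table(path, required_cols)

    sdf = _read_table(paths["surgeries"], ["surgery_id", "patient_id", "surgery_date", "specialty", "department"])
    fname = paths["surgeries"].name
    surgeries = [
        _surgery_from_row(row, file=fname, line=i + 2) for i, row in sdf.iterrows()
    ]

    events = EventStreams()
    adf = table("admissions", ["patient_id", "admit_date", "discharge_date", "department", "died_in_hospital"])
    if adf is not None:
        fname = paths["admissions"].name
        for i, row in adf.iterrows():
            line = i + 2
            discharge = row["discharge_date"].strip()
            events.admissions.append(
                _row_model(
                    AdmissionEpisode,
                    {
                        "patient_id": row["patient_id"],
                        "admit_date": _parse_date(row["admit_date"], file=fname, line=line, field="admit_date"),
                        "discharge_date": _parse_date(discharge, file=fname, line=line, field="discharge_date")
                        if discharge
                        else None,
                        "department": row["department"],
                        "died_in_hospital": _parse_bool(
                            row["died_in_hospital"], file=fname, line=line, field="died_in_hospital"
                        ),
                    },
                    file=fname,
                    line=line,
                )
            )
    rdf = table("reoperations", ["patient_id", "procedure_date", "specialty"])
    if rdf is not None:
        fname = paths["reoperations"].name
        for i, row in rdf.iterrows():
            events.reoperations.append(
                _row_model(
                    ReoperationRecord,
                    {
                        "patient_id": row["patient_id"],
                        "procedure_date": _parse_date(
                            row["procedure_date"], file=fname, line=i + 2, field="procedure_date"
                        ),
                        "specialty": row["specialty"],
                    },
                    file=fname,
                    line=i + 2,
                )
            )
    xdf = table("radiology", ["patient_id", "order_date", "modality"])
    if xdf is not None:
        fname = paths["radiology"].name
        for i, row in xdf.iterrows():
            events.radiology.append(
                _row_model(
                    RadiologyOrder,
                    {
                        "patient_id": row["patient_id"],
                        "order_date": _parse_date(row["order_date"], file=fname, line=i + 2, field="order_date"),
                        "modality": row["modality"],
                    },
                    file=fname,
                    line=i + 2,
                )
            )
    bdf = table("antibiotics", ["patient_id", "administration_date", "atc_code"])
    if bdf is not None:
        fname = paths["antibiotics"].name
        for i, row in bdf.iterrows():
            events.antibiotics.append(
                _row_model(
                    AntibioticAdministration,
                    {
                        "patient_id": row["patient_id"],
                        "administration_date": _parse_date(
                            row["administration_date"], file=fname, line=i + 2, field="administration_date"
                        ),
                        "atc_code": row["atc_code"],
                    },
                    file=fname,
                    line=i + 2,
                )
            )
    mdf = table("microbiology", ["patient_id", "sample_date", "body_site"])
    if mdf is not None:
        fname = paths["microbiology"].name
        relevant = {s.lower() for s in relevant_sites}
        has_flag = "relevant_site" in mdf.columns
        for i, row in mdf.iterrows():
            line = i + 2
            if has_flag and str(row["relevant_site"]).strip():
                flag = _parse_bool(row["relevant_site"], file=fname, line=line, field="relevant_site")
            else:
                flag = row["body_site"].strip().lower() in relevant
            events.microbiology.append(
                _row_model(
                    MicrobiologyCulture,
                    {
                        "patient_id": row["patient_id"],
                        "sample_date": _parse_date(row["sample_date"], file=fname, line=line, field="sample_date"),
                        "body_site": row["body_site"],
                        "relevant_site": flag,
                    },
                    file=fname,
                    line=line,
                )
            )

    # optional standalone deaths table: flag the episode whose interval
    # contains the death date and stamp the death date as discharge
    ddf = table("deaths", ["patient_id", "death_date"])
    if ddf is not None:
        fname = paths["deaths"].name
        for i, row in ddf.iterrows():
            death = _parse_date(row["death_date"], file=fname, line=i + 2, field="death_date")
            pid = row["patient_id"]
            for ep in events.admissions:
                if ep.patient_id != pid or ep.admit_date > death:
                    continue
                if ep.discharge_date is None or ep.discharge_date >= death:
                    ep.died_in_hospital = True
                    ep.discharge_date = death
                    break

    refdf = table("reference", ["surgery_id", "deep_ssi"])
    reference: list[ReferenceAnnotation] = []
    if refdf is not None:
        fname = paths["reference"].name
        for i, row in refdf.iterrows():
            line = i + 2
            reference.append(
                _row_model(
                    ReferenceAnnotation,
                    {
                        "surgery_id": row["surgery_id"],
                        "deep_ssi": _parse_bool(row["deep_ssi"], file=fname, line=line, field="deep_ssi"),
                        "annotator_id": row.get("annotator_id", "") or "icp-1",
                    },
                    file=fname,
                    line=line,
                )
            )
    return CohortData(surgeries=surgeries, events=events, reference=reference)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, dt.date):
        return value.isoformat()
    return str(value)


def write_cohort(cohort: CohortData, directory: Union[str, Path]) -> dict[str, Path]:
    """Write all cohort tables to ``directory``; returns table -> path.

    ``read_cohort(write_cohort(c)) == c`` field-for-field for valid data.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    rows = []
    for s in cohort.surgeries:
        row = {
            "surgery_id": s.surgery_id,
            "patient_id": s.patient_id,
            "surgery_date": _fmt(s.surgery_date),
            "specialty": s.specialty,
            "department": s.department,
        }
        cov = s.covariates.model_dump()
        row.update({k: _fmt(v) for k, v in cov.items()})
        rows.append(row)
    cols = ["surgery_id", "patient_id", "surgery_date", "specialty", "department"] + _COVARIATE_FIELDS
    out["surgeries"] = directory / TABLE_FILES["surgeries"]
    pd.DataFrame(rows, columns=cols).to_csv(out["surgeries"], index=False)

    def dump(name: str, records: list, cols: list[str]) -> None:
        out[name] = directory / TABLE_FILES[name]
        data = [{c: _fmt(getattr(r, c)) for c in cols} for r in records]
        pd.DataFrame(data, columns=cols).to_csv(out[name], index=False)

    dump("admissions", cohort.events.admissions,
         ["patient_id", "admit_date", "discharge_date", "department", "died_in_hospital"])
    dump("reoperations", cohort.events.reoperations, ["patient_id", "procedure_date", "specialty"])
    dump("radiology", cohort.events.radiology, ["patient_id", "order_date", "modality"])
    dump("antibiotics", cohort.events.antibiotics, ["patient_id", "administration_date", "atc_code"])
    dump("microbiology", cohort.events.microbiology,
         ["patient_id", "sample_date", "body_site", "relevant_site"])
    dump("reference", cohort.reference, ["surgery_id", "deep_ssi", "annotator_id"])
    return out


def load_window_config(path: Union[str, Path]) -> SurveillanceWindowConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return SurveillanceWindowConfig(**payload)


def save_window_config(cfg: SurveillanceWindowConfig, path: Union[str, Path]) -> None:
    payload = cfg.model_dump()
    payload["radiology_modalities"] = sorted(payload["radiology_modalities"])
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
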