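"""Readers and writers for the package's plain-text dialects.

Spectrum sweeps travel as UTF-8 CSV with '.' decimal separator and header
``frequency_hz,resistance_ohm,reactance_ohm`` plus embedded metadata
columns ``subject_id,state`` (state 0–3).  Cohorts are CSV in the column
order of :data:`esospec.cohort.COHORT_COLUMNS`; sensor geometry is a small
JSON or YAML mapping with keys ``surface_m2`` and ``separation_m``; fit
results and study statistics are JSON.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort
from .dispersion import FittedDispersionModel, RelaxationSummary
from .spectra import ImpedanceSpectrum, MeasurementState, SensorGeometry

SPECTRUM_COLUMNS = ("frequency_hz", "resistance_ohm", "reactance_ohm")
META_COLUMNS = ("subject_id", "state")


class SpectrumParseError(ValueError):
    """Malformed spectrum CSV; the message carries the offending line number."""


def write_spectrum_csv(spectrum: ImpedanceSpectrum, path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(SPECTRUM_COLUMNS) + list(META_COLUMNS))
        for f, r, x in zip(spectrum.frequencies, spectrum.resistance, spectrum.reactance):
            writer.writerow(
                [repr(float(f)), repr(float(r)), repr(float(x)),
                 spectrum.subject_id, int(spectrum.state)]
            )


def read_spectrum_csv(path) -> ImpedanceSpectrum:
    """Parse and validate a spectrum CSV; errors name the offending line."""
    path = Path(path)
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SpectrumParseError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        missing = [c for c in SPECTRUM_COLUMNS if c not in header]
        if missing:
            raise SpectrumParseError(f"{path}: missing column(s) {missing}")
        idx = {c: header.index(c) for c in header}

        freqs: list[float] = []
        res: list[float] = []
        rea: list[float] = []
        subject_id = ""
        state = 0
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < len(SPECTRUM_COLUMNS):
                raise SpectrumParseError(f"{path}: line {lineno}: too few fields")
            try:
                f = _parse_number(row[idx["frequency_hz"]])
                r = _parse_number(row[idx["resistance_ohm"]])
                x = _parse_number(row[idx["reactance_ohm"]])
            except ValueError as exc:
                raise SpectrumParseError(f"{path}: line {lineno}: {exc}") from None
            if freqs and f <= freqs[-1]:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: frequencies must be strictly increasing"
                )
            freqs.append(f)
            res.append(r)
            rea.append(x)
            if "subject_id" in idx and len(row) > idx["subject_id"]:
                subject_id = row[idx["subject_id"]]
            if "state" in idx and len(row) > idx["state"]:
                try:
                    state = int(row[idx["state"]])
                except ValueError:
                    raise SpectrumParseError(
                        f"{path}: line {lineno}: non-integer state"
                    ) from None
    try:
        return ImpedanceSpectrum(
            frequencies=np.array(freqs),
            resistance=np.array(res),
            reactance=np.array(rea),
            subject_id=subject_id,
            state=MeasurementState(state),
        )
    except ValueError as exc:
        raise SpectrumParseError(f"{path}: {exc}") from None


def _parse_number(cell: str) -> float:
    cell = cell.strip()
    if "," in cell:
        raise ValueError(
            f"comma in numeric cell {cell!r}: dialect requires '.' decimal separator"
        )
    return float(cell)


def write_cohort_csv(cohort: Cohort, path) -> None:
    cohort.to_dataframe().to_csv(path, index=False)


def read_cohort_csv(path) -> Cohort:
    df = pd.read_csv(path, dtype={"subject_id": str, "sex": str})
    return Cohort.from_dataframe(df)


def read_geometry(path) -> SensorGeometry:
    """Load sensor geometry from JSON or YAML (keys surface_m2, separation_m)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict) or not {"surface_m2", "separation_m"} <= set(data):
        raise ValueError(f"{path}: expected keys surface_m2 and separation_m")
    return SensorGeometry(
        surface=float(data["surface_m2"]), separation=float(data["separation_m"])
    )


def write_geometry(geometry: SensorGeometry, path) -> None:
    Path(path).write_text(
        json.dumps(
            {"surface_m2": geometry.surface, "separation_m": geometry.separation},
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )


def fit_record(
    spectrum: ImpedanceSpectrum,
    fit: FittedDispersionModel,
    summary: RelaxationSummary | None,
) -> dict:
    """One JSON-ready record per (subject, state) fit."""
    rec = {
        "subject_id": spectrum.subject_id,
        "state": int(spectrum.state),
        "n_terms": fit.params.n_terms,
        "log_eps_inf": fit.params.log_eps_inf,
        "terms": [asdict(t) for t in fit.params.terms],
        "sse": fit.residual_sse,
        "converged": fit.converged,
    }
    if summary is not None:
        rec.update({
            "f_alpha_hz": summary.f_alpha,
            "f_beta_hz": summary.f_beta,
            "eps_alpha": summary.eps_alpha,
            "eps_beta": summary.eps_beta,
            "sigma_alpha_s_m": summary.sigma_alpha,
            "sigma_beta_s_m": summary.sigma_beta,
            "loss_alpha": summary.loss_alpha,
        })
    return rec


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
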