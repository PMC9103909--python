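"""Reading and writing spectra tables, reports and configurations.

One CSV dialect is used for spectra: samples as rows, a header row of
``sample_id, concentration`` followed by the wavenumber axis, UTF-8, point
decimal.  Intensities and wavenumbers are serialised with Python's
shortest round-trip ``repr``, so ``read_spectra(write_spectra(S))``
reproduces ``S`` bit-exactly.  An empty concentration field marks an
unknown sample (read back as ``nan``).

Reports are written as CSV (stable column order, machine-readable) or a
human-readable text table.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .evaluation import ModelReport, RecoveryReport
from .spectra import SpectraParseError, SpectraSet
from .synthetic import GeneratorConfig

__all__ = [
    "read_spectra",
    "write_spectra",
    "write_report",
    "write_recovery_report",
    "load_generator_config",
    "save_generator_config",
]

_REPORT_COLUMNS = (
    "method",
    "n_components",
    "n_selected",
    "selected_wavelengths",
    "R_C",
    "RMSEC",
    "R_P",
    "RMSEP",
    "RPD",
)


def write_spectra(spectra: SpectraSet, path: str | Path) -> None:
    """Serialise a SpectraSet in the package's CSV dialect."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        header = ["sample_id", "concentration"] + [
            repr(float(w)) for w in spectra.wavenumbers
        ]
        fh.write(",".join(header) + "\n")
        for sid, conc, row in zip(spectra.sample_ids, spectra.y, spectra.intensities):
            cell = "" if np.isnan(conc) else repr(float(conc))
            fh.write(",".join([sid, cell] + [repr(float(v)) for v in row]) + "\n")


def read_spectra(path: str | Path) -> SpectraSet:
    """Parse a spectra CSV; errors name the offending line.

    Validates a strictly increasing, duplicate-free wavenumber header,
    rectangular rows and numeric intensities.  Missing concentrations are
    read as ``nan``.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SpectraParseError(f"{path}: empty file") from None
        if len(header) < 3 or header[0] != "sample_id" or header[1] != "concentration":
            raise SpectraParseError(
                f"{path}: line 1: header must start with 'sample_id,concentration' "
                "followed by at least one wavenumber"
            )
        try:
            wavenumbers = np.array([float(w) for w in header[2:]])
        except ValueError as exc:
            raise SpectraParseError(f"{path}: line 1: non-numeric wavenumber: {exc}") from None
        if np.unique(wavenumbers).size != wavenumbers.size:
            raise SpectraParseError(f"{path}: line 1: duplicated wavenumber column")
        if np.any(np.diff(wavenumbers) <= 0):
            raise SpectraParseError(f"{path}: line 1: wavenumber header not increasing")

        ids: list[str] = []
        concs: list[float] = []
        rows: list[list[float]] = []
        for lineno, record in enumerate(reader, start=2):
            if not record:
                continue
            if len(record) != len(header):
                raise SpectraParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(record)} (ragged row)"
                )
            ids.append(record[0])
            concs.append(float("nan") if record[1] == "" else _num(record[1], path, lineno))
            rows.append([_num(v, path, lineno) for v in record[2:]])
    if not rows:
        raise SpectraParseError(f"{path}: no sample rows")
    return SpectraSet(wavenumbers, np.array(rows), np.array(concs), ids)


def _num(token: str, path: Path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise SpectraParseError(
            f"{path}: line {lineno}: non-numeric value {token!r}"
        ) from None


def _format_wavelengths(values: np.ndarray) -> str:
    return "; ".join(f"{v:.0f}" for v in np.asarray(values, dtype=float))


def write_report(
    reports: Sequence[ModelReport], path: str | Path, format: str = "csv"
) -> None:
    """Write the model-comparison table (one row per method).

    Columns, in fixed order: method, components, number of selected
    variables, cluster-representative wavelengths, R_C, RMSEC, R_P, RMSEP,
    RPD.  ``format`` is ``csv`` or ``txt`` (aligned text table).
    """
    if not reports:
        raise SpectraParseError("cannot write an empty report")
    rows = [
        (
            r.method,
            str(r.n_components),
            str(r.n_selected),
            _format_wavelengths(r.selected_wavelengths),
            f"{r.r_c:.4f}",
            f"{r.rmsec:.4f}",
            f"{r.r_p:.4f}",
            f"{r.rmsep:.4f}",
            f"{r.rpd:.4f}" if np.isfinite(r.rpd) else "inf",
        )
        for r in reports
    ]
    path = Path(path)
    if format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_REPORT_COLUMNS)
            writer.writerows(rows)
    elif format == "txt":
        table = [_REPORT_COLUMNS, *rows]
        widths = [max(len(row[i]) for row in table) for i in range(len(_REPORT_COLUMNS))]
        with path.open("w", encoding="utf-8") as fh:
            for row in table:
                fh.write("  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip() + "\n")
    else:
        raise SpectraParseError(f"unknown report format {format!r} (use 'csv' or 'txt')")


def write_recovery_report(reports: Sequence[RecoveryReport], path: str | Path) -> None:
    """CSV of per-level spike-recovery statistics."""
    if not reports:
        raise SpectraParseError("cannot write an empty recovery report")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["level_mg_L", "mean", "sd", "recovery_min_pct", "recovery_max_pct",
             "rsd_pct", "max_abs_relative_error_pct"]
        )
        for r in reports:
            lo, hi = r.recovery_range if r.recovery_range is not None else ("", "")
            max_rel = (
                f"{np.nanmax(np.abs(r.relative_errors)):.3f}"
                if np.any(np.isfinite(r.relative_errors))
                else ""
            )
            writer.writerow(
                [
                    f"{r.level:g}", f"{r.mean:.4f}", f"{r.sd:.4f}",
                    f"{lo:.2f}" if lo != "" else "",
                    f"{hi:.2f}" if hi != "" else "",
                    f"{r.rsd:.3f}", max_rel,
                ]
            )


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Read a generator configuration from a YAML file."""
    with Path(path).open("r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    return GeneratorConfig.from_dict(payload)


def save_generator_config(config: GeneratorConfig, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
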