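"""CSV / JSON / YAML input and output.

The measurement CSV dialect is fixed: comma-separated, UTF-8, a header
row ``cluster_id,value``, '.' as decimal mark, one observation per row.
Cluster order is irrelevant.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .anova import AnovaSummary, IccEstimates, MeasurementTable
from .exceptions import IccError
from .simulate import SimConfig

__all__ = [
    "read_measurements_csv",
    "write_measurements_csv",
    "report_dict",
    "write_report_json",
    "load_study_config",
    "write_study_csv",
]

HEADER = ("cluster_id", "value")


class CsvFormatError(IccError):
    """Malformed measurement CSV; the message carries the line number."""


def read_measurements_csv(path: str | Path) -> MeasurementTable:
    """Read a long-format measurement table from CSV.

    Raises
    ------
    CsvFormatError
        on a missing/incorrect header, wrong field count or a value that
        does not parse as a number, naming the offending line.
    """
    ids: list[str] = []
    vals: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CsvFormatError(f"{path}: line 1: empty file, expected header "
                                 f"{','.join(HEADER)}") from None
        if [h.strip().lower() for h in header] != list(HEADER):
            raise CsvFormatError(
                f"{path}: line 1: expected header {','.join(HEADER)}, "
                f"got {','.join(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise CsvFormatError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(row)}"
                )
            try:
                vals.append(float(row[1]))
            except ValueError:
                raise CsvFormatError(
                    f"{path}: line {lineno}: value {row[1]!r} is not a number"
                ) from None
            ids.append(row[0])
    if not ids:
        raise CsvFormatError(f"{path}: no data rows")
    return MeasurementTable(np.array(ids), np.array(vals))


def write_measurements_csv(data: MeasurementTable, path: str | Path) -> None:
    """Write a measurement table in the dialect ``read_measurements_csv`` reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(HEADER)
        for cid, val in zip(data.cluster_ids, data.values):
            writer.writerow([cid, repr(float(val))])


def report_dict(s: AnovaSummary, est: IccEstimates) -> dict:
    """Machine-readable estimation report for one dataset."""
    return {
        "n": s.n,
        "k": s.k,
        "SSB": s.SSB,
        "SSE": s.SSE,
        "BMS": s.BMS,
        "EMS": s.EMS,
        "rho_hat": est.rho_hat,
        "F_hat": est.F_hat,
        "var_F_hat": est.var_F_hat,
        "rho_tilde": est.rho_tilde,
        "rho_bc": est.rho_bc,
        "rho_bc_raw": est.rho_bc_raw,
        "branch_used": est.branch_used,
    }


def write_report_json(report: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")


def load_study_config(path: str | Path) -> list[SimConfig]:
    """Build a study grid from a YAML file listing the grid axes.

    Recognised keys (all optional, defaults in parentheses):
    ``dists`` ([gamma, normal]), ``n_clusters`` ([10, 30, 50]),
    ``rhos`` ([0.1 .. 0.9]), ``cluster_size`` (10), ``reps`` (5000),
    ``total_variance`` (1000), ``mu`` (10), ``gamma_shape`` (1.67).
    """
    from .study import default_grid

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise IccError(f"{path}: study config must be a mapping")
    known = {
        "dists", "n_clusters", "rhos", "cluster_size", "reps",
        "total_variance", "mu", "gamma_shape",
    }
    unknown = set(raw) - known
    if unknown:
        raise IccError(
            f"{path}: unknown config fields: {', '.join(sorted(unknown))}; "
            f"recognised fields: {', '.join(sorted(known))}"
        )
    try:
        return default_grid(
            dists=tuple(raw.get("dists", ("gamma", "normal"))),
            n_clusters=tuple(raw.get("n_clusters", (10, 30, 50))),
            rhos=tuple(raw.get("rhos", (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9))),
            cluster_size=int(raw.get("cluster_size", 10)),
            reps=int(raw.get("reps", 5000)),
            total_variance=float(raw.get("total_variance", 1000.0)),
            mu=float(raw.get("mu", 10.0)),
            gamma_shape=float(raw.get("gamma_shape", 1.67)),
        )
    except (TypeError, ValueError) as exc:
        raise IccError(f"{path}: invalid study config: {exc}") from exc


def write_study_csv(results: Sequence, path: str | Path) -> None:
    """Write study results as tidy CSV, one row per cell."""
    from .study import results_to_dataframe

    results_to_dataframe(results).to_csv(path, index=False)
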