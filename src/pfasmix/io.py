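"""Plate-format CSV input/output and embryoid-body size quality control.

One CSV dialect only: comma separator, dot decimal, UTF-8, mandatory header.
Two schemas are documented:

single-compound plates
    ``experiment_id, treatment_id, compound, concentration_uM, eb_id,
    luminescence_rlu``

mixture plates
    the single-compound columns plus ``mixture_id, enrichment_factor``

QC tables carry ``experiment_id, mean_eb_diameter_um``.  Experiments whose
mean embryoid-body diameter is below the 500 µm threshold are discarded
wholesale; the comparison is strict (exactly 500 µm passes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "PlateSchemaError",
    "PlateParseError",
    "MissingQCError",
    "PLATE_COLUMNS_SINGLE",
    "PLATE_COLUMNS_MIXTURE",
    "QC_COLUMNS",
    "QC_DIAMETER_THRESHOLD_UM",
    "read_plate_csv",
    "write_plate_csv",
    "read_qc_csv",
    "QCReport",
    "qc_filter_experiments",
]


class PlateSchemaError(ValueError):
    """The CSV header does not match the documented plate schema."""


class PlateParseError(ValueError):
    """A row failed to parse; the message names the offending line(s)."""


class MissingQCError(ValueError):
    """An experiment has luminescence records but no QC entry."""


PLATE_COLUMNS_SINGLE = (
    "experiment_id", "treatment_id", "compound",
    "concentration_uM", "eb_id", "luminescence_rlu",
)
PLATE_COLUMNS_MIXTURE = PLATE_COLUMNS_SINGLE + ("mixture_id", "enrichment_factor")
QC_COLUMNS = ("experiment_id", "mean_eb_diameter_um")

#: minimum acceptable mean embryoid-body diameter (µm)
QC_DIAMETER_THRESHOLD_UM = 500.0

_NUMERIC = {"concentration_uM": float, "eb_id": int,
            "luminescence_rlu": float, "enrichment_factor": float}


def _schema(schema_mode: str):
    if schema_mode == "single_compound":
        return PLATE_COLUMNS_SINGLE
    if schema_mode == "mixture":
        return PLATE_COLUMNS_MIXTURE
    raise ValueError(f"unknown schema_mode {schema_mode!r}")


def read_plate_csv(path, schema_mode: str = "single_compound") -> pd.DataFrame:
    """Read a plate CSV into a validated record table.

    Raises :class:`PlateSchemaError` when a required column is missing and
    :class:`PlateParseError` naming the 1-based CSV line numbers of any
    malformed (non-numeric / non-positive luminescence) rows.
    """
    columns = _schema(schema_mode)
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise PlateSchemaError(f"{path.name}: missing column(s) {missing}")
    df = df[list(columns)]

    bad: list[tuple[int, str]] = []
    out = df.copy()
    for col, typ in _NUMERIC.items():
        if col not in out.columns:
            continue
        converted = pd.to_numeric(out[col], errors="coerce")
        for idx in out.index[converted.isna()]:
            bad.append((idx + 2, f"non-numeric {col}: {out.at[idx, col]!r}"))
        out[col] = converted
    for idx in out.index[(out["luminescence_rlu"] <= 0).fillna(False)]:
        bad.append((idx + 2, "luminescence must be positive"))
    if bad:
        detail = "; ".join(f"line {line}: {msg}" for line, msg in sorted(bad))
        raise PlateParseError(f"{path.name}: {detail}")
    if _NUMERIC["eb_id"] is int:
        out["eb_id"] = out["eb_id"].astype(int)

    dup = out.duplicated(subset=["experiment_id", "treatment_id", "eb_id"])
    if dup.any():
        lines = [str(i + 2) for i in out.index[dup]]
        raise PlateParseError(
            f"{path.name}: duplicate (experiment_id, treatment_id, eb_id) at line(s) {', '.join(lines)}"
        )
    return out


def write_plate_csv(records: pd.DataFrame, path, schema_mode: str = "single_compound") -> None:
    """Write records in the documented column order (lossless round trip)."""
    columns = _schema(schema_mode)
    missing = [c for c in columns if c not in records.columns]
    if missing:
        raise PlateSchemaError(f"records missing column(s) {missing}")
    records[list(columns)].to_csv(path, index=False)


def read_qc_csv(path) -> pd.DataFrame:
    """Read an EB-size QC table (experiment_id, mean_eb_diameter_um)."""
    df = pd.read_csv(path)
    missing = [c for c in QC_COLUMNS if c not in df.columns]
    if missing:
        raise PlateSchemaError(f"{Path(path).name}: missing column(s) {missing}")
    return df[list(QC_COLUMNS)]


@dataclass(frozen=True)
class QCReport:
    """Outcome of the EB-size filter."""

    threshold_um: float
    kept: tuple
    discarded: tuple
    diameters: dict = field(default_factory=dict)

    def __str__(self) -> str:  # human-readable discard report
        lines = [f"EB-size QC (threshold {self.threshold_um:g} um):"]
        for exp in self.discarded:
            lines.append(f"  discarded {exp} (mean diameter {self.diameters[exp]:g} um)")
        if not self.discarded:
            lines.append("  no experiments discarded")
        return "\n".join(lines)


def qc_filter_experiments(records: pd.DataFrame, qc: pd.DataFrame,
                          threshold: float = QC_DIAMETER_THRESHOLD_UM):
    """Drop whole experiments whose mean EB diameter is below ``threshold``.

    The comparison is strict: a mean diameter exactly at the threshold
    passes.  Surviving records are returned unaltered alongside a
    :class:`QCReport`.  Every experiment present in ``records`` must have a
    QC entry; otherwise :class:`MissingQCError` is raised (no silent pass).
    """
    diameters = dict(zip(qc["experiment_id"], qc["mean_eb_diameter_um"].astype(float)))
    experiments = list(dict.fromkeys(records["experiment_id"]))
    missing = [e for e in experiments if e not in diameters]
    if missing:
        raise MissingQCError(f"experiments without QC entry: {missing}")
    discarded = tuple(e for e in experiments if diameters[e] < threshold)
    kept = tuple(e for e in experiments if diameters[e] >= threshold)
    filtered = records[records["experiment_id"].isin(kept)].copy()
    report = QCReport(threshold_um=float(threshold), kept=kept, discarded=discarded,
                      diameters={e: diameters[e] for e in experiments})
    return filtered, report
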