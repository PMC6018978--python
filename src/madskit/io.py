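"""Tabular I/O for titration/saturation series and fit reports.

All formats are plain TSV.  Comment lines starting with ``#`` are ignored
on read and used on write to stamp provenance (seed, config hash) without
touching the data columns.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .binding import (
    CooperativeFit,
    SaturationFit,
    SaturationSeries,
    TitrationSeries,
)
from .exceptions import ValidationError

TITRATION_COLUMNS = ["lane", "applied_protein", "frac_free", "frac_one_dimer", "frac_two_dimers"]
SATURATION_COLUMNS = ["lane", "free_probe", "bound"]


def _read_tsv(path, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def read_titration(path) -> TitrationSeries:
    df = _read_tsv(path, TITRATION_COLUMNS[1:])
    return TitrationSeries.from_arrays(
        df["applied_protein"].to_numpy(),
        df[["frac_free", "frac_one_dimer", "frac_two_dimers"]].to_numpy(),
        label=str(Path(path).stem),
    )


def write_titration(series: TitrationSeries, path, header_lines: Iterable[str] = ()) -> None:
    df = pd.DataFrame(
        {
            "lane": range(1, len(series.points) + 1),
            "applied_protein": series.applied_protein,
            "frac_free": series.fractions[:, 0],
            "frac_one_dimer": series.fractions[:, 1],
            "frac_two_dimers": series.fractions[:, 2],
        }
    )
    _write_with_header(df, path, header_lines)


def read_saturation(path) -> SaturationSeries:
    df = _read_tsv(path, SATURATION_COLUMNS[1:])
    return SaturationSeries.from_arrays(
        df["free_probe"].to_numpy(), df["bound"].to_numpy(), label=str(Path(path).stem)
    )


def write_saturation(series: SaturationSeries, path, header_lines: Iterable[str] = ()) -> None:
    df = pd.DataFrame(
        {
            "lane": range(1, len(series.points) + 1),
            "free_probe": series.free_probe,
            "bound": series.bound,
        }
    )
    _write_with_header(df, path, header_lines)


def _write_with_header(df: pd.DataFrame, path, header_lines: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_fit(fit: CooperativeFit | SaturationFit, path, header_lines: Iterable[str] = ()) -> None:
    """Write a fit as TSV key-value pairs plus a JSON diagnostics blob."""
    record = dataclasses.asdict(fit)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("key\tvalue\n")
        for key, value in record.items():
            fh.write(f"{key}\t{value}\n")
        fh.write(f"# diagnostics {json.dumps(record, default=float, sort_keys=True)}\n")
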