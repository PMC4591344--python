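"""Reading, validating and writing survey record tables.

The interchange format is a UTF-8 CSV with one row per
(field, year, species): columns ``field_id``, ``year``, ``action``,
``species_id``, ``abundance_class``.  The action column is the crop grown
in the season covered by that year's survey; observed classes are the
four-class Barralis-derived scale.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .core import FieldSeries, SurveyDataset

__all__ = [
    "RECORD_COLUMNS",
    "read_records",
    "write_records",
    "records_to_series",
    "dataset_to_records",
]

RECORD_COLUMNS = ("field_id", "year", "action", "species_id", "abundance_class")


class RecordsError(ValueError):
    """Malformed records file; message names the offending rows."""


def _fail(problems: List[str], path) -> None:
    if problems:
        head = "; ".join(problems[:5])
        more = f" (+{len(problems) - 5} more)" if len(problems) > 5 else ""
        raise RecordsError(f"{path}: {head}{more}")


def read_records(path: str | Path) -> pd.DataFrame:
    """Read and validate a records CSV.

    Rows failing validation are reported with their file line number
    (header = line 1).  The (field_id, year, species_id) triple must be
    unique.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise RecordsError(f"{path}: missing column(s) {missing}")
    df = df[list(RECORD_COLUMNS)]
    problems: List[str] = []

    def _int_col(name: str) -> pd.Series:
        s = pd.to_numeric(df[name], errors="coerce")
        bad = s.isna() | (s != s.round())
        for i in df.index[bad]:
            problems.append(f"line {i + 2}: non-integer {name} {df.at[i, name]!r}")
        return s

    years = _int_col("year")
    classes = _int_col("abundance_class")
    ok = ~classes.isna()
    out_of_range = ok & ~classes.isin([1, 2, 3, 4])
    for i in df.index[out_of_range]:
        problems.append(
            f"line {i + 2}: abundance_class {df.at[i, 'abundance_class']} "
            "outside the observed range 1..4"
        )
    for name in ("field_id", "action", "species_id"):
        for i in df.index[df[name].str.strip() == ""]:
            problems.append(f"line {i + 2}: empty {name}")
    _fail(problems, path)
    df["year"] = years.astype(np.int64)
    df["abundance_class"] = classes.astype(np.int64)
    dup = df.duplicated(subset=["field_id", "year", "species_id"], keep=False)
    if dup.any():
        first = df.index[dup][0]
        raise RecordsError(
            f"{path}: duplicate (field_id, year, species_id) starting at line {first + 2}"
        )
    return df.reset_index(drop=True)


def write_records(table: pd.DataFrame, path: str | Path) -> None:
    table = table[list(RECORD_COLUMNS)]
    table.to_csv(path, index=False)


def records_to_series(
    table: pd.DataFrame,
    species_id: str,
    impute_absence: bool = True,
) -> SurveyDataset:
    """Build a species' independent time series from a records table.

    Survey coverage (which field-years were visited, and under which crop)
    is taken from the whole table; in an exhaustively surveyed field-year
    with no record of the species the species is scored class 1 when
    ``impute_absence`` is on, and the field-year is skipped otherwise.
    Within each field, runs of consecutive years are split at gaps; a run
    of ``L`` surveyed years yields ``L - 1`` observations (the first year
    contributes its action only), and runs of a single year are dropped.
    """
    surveyed = (
        table.groupby(["field_id", "year"], as_index=False)
        .agg(action=("action", "first"))
        .sort_values(["field_id", "year"])
    )
    sp = table[table["species_id"] == species_id]
    cls_map = {(f, y): c for f, y, c in zip(sp["field_id"], sp["year"], sp["abundance_class"])}
    series = []
    for fid, grp in surveyed.groupby("field_id", sort=True):
        years = grp["year"].to_numpy()
        acts = grp["action"].to_numpy()
        keep = np.ones(len(years), dtype=bool)
        if not impute_absence:
            keep = np.array([(fid, y) in cls_map for y in years])
        # split into runs of consecutive surveyed years
        run_start = 0
        breaks = list(np.nonzero(np.diff(years[keep]) != 1)[0] + 1) + [int(keep.sum())]
        yk, ak = years[keep], acts[keep]
        n_run = 0
        for b in breaks:
            run_y = yk[run_start:b]
            run_a = ak[run_start:b]
            run_start = b
            if len(run_y) < 2:
                continue
            obs = tuple(int(cls_map.get((fid, y), 1)) for y in run_y[1:])
            n_run += 1
            suffix = f"_{n_run}" if n_run > 1 else ""
            series.append(
                FieldSeries(
                    field_id=f"{fid}{suffix}",
                    actions=tuple(run_a[:-1]),
                    observations=obs,
                )
            )
    if not series:
        raise RecordsError(
            f"no usable series (>= 2 consecutive surveyed years) for species {species_id!r}"
        )
    return SurveyDataset(species_id=species_id, series=series)


def dataset_to_records(
    dataset: SurveyDataset,
    start_year: int = 2001,
) -> pd.DataFrame:
    """Serialise a dataset in the records format.

    A series with T observations becomes T + 1 year-rows: the first year
    carries the first action and a placeholder class 1 (its observation is
    not part of the model and is discarded on reading); the final year
    repeats the last action, which the reader likewise ignores.
    """
    rows = []
    for s in dataset.series:
        acts = list(s.actions) + [s.actions[-1]]
        classes = [1] + list(s.observations)
        for t, (a, c) in enumerate(zip(acts, classes)):
            rows.append(
                {
                    "field_id": s.field_id,
                    "year": start_year + t,
                    "action": a,
                    "species_id": dataset.species_id,
                    "abundance_class": c,
                }
            )
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
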