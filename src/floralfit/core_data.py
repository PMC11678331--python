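"""Domain types for the floral-induction expression experiment.

The experimental design is a qRT-PCR time course of five narrow-leafed
lupin genes — four FT-like florigen genes (*FTc1*, *FTa1*, *FTc2*, *FTa2*)
and the floral integrator *AGL8* — measured in one plant line under one
photoperiod, stratified into four condition blocks: vernalized vs
non-vernalized crossed with a morning vs evening sampling time.  Each
series carries a mean and a standard deviation (3 biological replicates)
per sampling term.

*AGL8* is always the regression target; the four FT-like genes are the
predictor universe.  Datasets are exchanged as long-form CSV with one row
per (condition, gene, sampling term).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "FT_GENES",
    "TARGET_GENE",
    "ALL_GENES",
    "PHOTOPERIODS",
    "VERNALIZATIONS",
    "DAYTIMES",
    "BLOCKS",
    "CSV_COLUMNS",
    "ConditionKey",
    "ExpressionSeries",
    "ExperimentDataset",
    "DatasetFormatError",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
]

FT_GENES: tuple[str, ...] = ("FTc1", "FTa1", "FTc2", "FTa2")
TARGET_GENE: str = "AGL8"
ALL_GENES: tuple[str, ...] = FT_GENES + (TARGET_GENE,)

PHOTOPERIODS: tuple[str, ...] = ("SD_8h", "LD_16h")
VERNALIZATIONS: tuple[str, ...] = ("V", "N")
DAYTIMES: tuple[str, ...] = ("morning", "evening")

#: Canonical order of the four (vernalization, daytime) condition blocks.
BLOCKS: tuple[tuple[str, str], ...] = (
    ("V", "morning"),
    ("V", "evening"),
    ("N", "morning"),
    ("N", "evening"),
)

#: Clock times of the two daily collections, per photoperiod (display only).
CLOCK_TIMES: dict[str, dict[str, str]] = {
    "SD_8h": {"morning": "9 A.M.", "evening": "3 P.M."},
    "LD_16h": {"morning": "7 A.M.", "evening": "6 P.M."},
}

CSV_COLUMNS: tuple[str, ...] = (
    "line",
    "photoperiod",
    "vernalization",
    "daytime",
    "term",
    "time_days",
    "gene",
    "mean",
    "sd",
)

#: Decimal precision used when writing CSV; round-tripping is exact to this.
CSV_FLOAT_FORMAT = "%.12g"


class DatasetFormatError(ValueError):
    """The on-disk file does not follow the long-form CSV dialect."""


class DatasetValidationError(ValueError):
    """The data violate a structural invariant of the experimental design."""


@dataclasses.dataclass(frozen=True)
class ConditionKey:
    """One experimental condition: line x photoperiod x block."""

    line: str
    photoperiod: str
    vernalization: str
    daytime: str

    def __post_init__(self) -> None:
        if self.photoperiod not in PHOTOPERIODS:
            raise DatasetValidationError(
                f"unknown photoperiod {self.photoperiod!r}; expected one of {PHOTOPERIODS}"
            )
        if self.vernalization not in VERNALIZATIONS:
            raise DatasetValidationError(
                f"unknown vernalization {self.vernalization!r}; expected one of {VERNALIZATIONS}"
            )
        if self.daytime not in DAYTIMES:
            raise DatasetValidationError(
                f"unknown daytime {self.daytime!r}; expected one of {DAYTIMES}"
            )

    @property
    def block(self) -> tuple[str, str]:
        """The (vernalization, daytime) stratum this condition belongs to."""
        return (self.vernalization, self.daytime)

    @property
    def clock_time(self) -> str:
        """Human-readable collection time (e.g. '9 A.M.')."""
        return CLOCK_TIMES[self.photoperiod][self.daytime]


@dataclasses.dataclass
class ExpressionSeries:
    """One gene's time course (mean +- s.d. per sampling term) in one condition.

    ``time_days`` is real-valued days since the first sampling term of the
    block; the term labels (T1..T4) are retained as metadata.
    """

    condition: ConditionKey
    gene: str
    terms: tuple[str, ...]
    time_days: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.time_days = np.asarray(self.time_days, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.terms = tuple(str(t) for t in self.terms)
        n = self.time_days.size
        if not (len(self.terms) == n == self.mean.size == self.sd.size):
            raise DatasetValidationError(
                f"series {self.gene}/{self.condition.block}: field lengths differ"
            )
        if n < 2:
            raise DatasetValidationError(
                f"series {self.gene}/{self.condition.block}: needs >=2 sampling terms, got {n}"
            )
        if np.any(np.diff(self.time_days) <= 0):
            raise DatasetValidationError(
                f"series {self.gene}/{self.condition.block}: time_days must be strictly increasing"
            )
        if np.any(self.sd < 0):
            raise DatasetValidationError(
                f"series {self.gene}/{self.condition.block}: negative s.d."
            )

    @property
    def n_points(self) -> int:
        return self.time_days.size


@dataclasses.dataclass
class ExperimentDataset:
    """All series for one (line, photoperiod): the unit of model fitting.

    ``series`` maps (block, gene) -> :class:`ExpressionSeries` where block is
    a (vernalization, daytime) pair.  A complete dataset has all 5 genes in
    all 4 blocks, on an identical time grid within each block.
    """

    line: str
    photoperiod: str
    series: dict[tuple[tuple[str, str], str], ExpressionSeries]

    def get(self, block: tuple[str, str], gene: str) -> ExpressionSeries:
        return self.series[(block, gene)]

    def block_times(self, block: tuple[str, str]) -> np.ndarray:
        """The common time grid of a block (taken from the AGL8 series)."""
        return self.get(block, TARGET_GENE).time_days

    def validate(self, genes: Iterable[str] = ALL_GENES) -> None:
        """Check completeness and the shared-grid invariant; raise otherwise."""
        genes = tuple(genes)
        for block in BLOCKS:
            present = [g for g in genes if (block, g) in self.series]
            missing = [g for g in genes if g not in present]
            if missing:
                raise DatasetValidationError(
                    f"block {block}: missing series for genes {missing}"
                )
            ref = self.series[(block, present[0])]
            for g in present[1:]:
                s = self.series[(block, g)]
                if s.time_days.size != ref.time_days.size or np.any(
                    s.time_days != ref.time_days
                ):
                    raise DatasetValidationError(
                        f"block {block}: time grid of {g} differs from {present[0]}"
                    )

    def to_frame(self) -> pd.DataFrame:
        """Long-form table, deterministically ordered by (block, gene, time)."""
        rows = []
        for block in BLOCKS:
            for gene in ALL_GENES:
                s = self.series.get((block, gene))
                if s is None:
                    continue
                for i in range(s.n_points):
                    rows.append(
                        (
                            self.line,
                            self.photoperiod,
                            block[0],
                            block[1],
                            s.terms[i],
                            s.time_days[i],
                            gene,
                            s.mean[i],
                            s.sd[i],
                        )
                    )
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def _series_from_rows(line: str, photoperiod: str, g: pd.DataFrame) -> ExpressionSeries:
    g = g.sort_values("time_days")
    cond = ConditionKey(
        line=line,
        photoperiod=photoperiod,
        vernalization=str(g["vernalization"].iloc[0]),
        daytime=str(g["daytime"].iloc[0]),
    )
    return ExpressionSeries(
        condition=cond,
        gene=str(g["gene"].iloc[0]),
        terms=tuple(g["term"].astype(str)),
        time_days=g["time_days"].to_numpy(dtype=float),
        mean=g["mean"].to_numpy(dtype=float),
        sd=g["sd"].to_numpy(dtype=float),
    )


def dataset_from_frame(df: pd.DataFrame, line: str, photoperiod: str) -> ExperimentDataset:
    """Build a validated dataset from a long-form table."""
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing required columns: {missing}")
    sel = df[(df["line"].astype(str) == line) & (df["photoperiod"].astype(str) == photoperiod)]
    if sel.empty:
        raise DatasetValidationError(
            f"no rows for line={line!r}, photoperiod={photoperiod!r}"
        )
    series: dict[tuple[tuple[str, str], str], ExpressionSeries] = {}
    for (vern, day, gene), g in sel.groupby(
        ["vernalization", "daytime", "gene"], sort=False
    ):
        s = _series_from_rows(line, photoperiod, g)
        series[((str(vern), str(day)), str(gene))] = s
    ds = ExperimentDataset(line=line, photoperiod=photoperiod, series=series)
    ds.validate()
    return ds


def read_dataset(path: str | Path, line: str, photoperiod: str) -> ExperimentDataset:
    """Read the long-form CSV at ``path``, keeping rows for one (line, photoperiod).

    The CSV must carry the header
    ``line,photoperiod,vernalization,daytime,term,time_days,gene,mean,sd``.
    Lines beginning with ``#`` are treated as comments.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DatasetFormatError(f"cannot parse {path}: {exc}") from exc
    return dataset_from_frame(df, line, photoperiod)


def write_dataset(ds: ExperimentDataset, path: str | Path) -> None:
    """Write a dataset as long-form CSV with a deterministic row order.

    Two writes of the same dataset produce byte-identical files; numeric
    content round-trips exactly at 12 significant digits.
    """
    df = ds.to_frame()
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)
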