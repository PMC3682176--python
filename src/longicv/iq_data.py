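"""Behavioural IQ table: loading, validation and summary statistics.

The cohort behavioural record consists of verbal IQ (VIQ) and performance
IQ (PIQ) measured at two time points a few years apart, on the usual
age-standardised scale (population mean 100, SD 15).  The change scores
``d_viq = viq_t2 - viq_t1`` and ``d_piq = piq_t2 - piq_t1`` are the
quantities the imaging analysis tries to predict.

Change columns are always *derived* from the two time points.  If an input
file also carries printed change columns they are cross-checked against the
recomputed values and any mismatch is rejected — a transcription error in
either column would silently corrupt every downstream regression.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IQRecord",
    "IQTable",
    "MeasureSummary",
    "BehaviouralSummary",
    "IQValidationError",
    "load_iq_table",
    "write_iq_table",
    "load_reference_table",
    "summarise",
]

SCORE_COLUMNS = ("viq_t1", "piq_t1", "viq_t2", "piq_t2")
CHANGE_COLUMNS = ("d_viq", "d_piq")
MEASURES = ("viq", "piq")


class IQValidationError(ValueError):
    """Raised when a behavioural table violates its contract."""


@dataclass(frozen=True)
class IQRecord:
    """One subject's scores at both time points plus derived changes."""

    subject_id: int
    viq_t1: float
    piq_t1: float
    viq_t2: float
    piq_t2: float

    @property
    def d_viq(self) -> float:
        return self.viq_t2 - self.viq_t1

    @property
    def d_piq(self) -> float:
        return self.piq_t2 - self.piq_t1

    def score(self, measure: str, time: int) -> float:
        return getattr(self, f"{measure}_t{time}")

    def change(self, measure: str) -> float:
        return getattr(self, f"d_{measure}")

    def __post_init__(self) -> None:
        for col in SCORE_COLUMNS:
            v = getattr(self, col)
            if not np.isfinite(v) or v <= 0:
                raise IQValidationError(
                    f"subject {self.subject_id}: {col}={v!r} must be finite and > 0"
                )


@dataclass(frozen=True)
class IQTable:
    """Ordered collection of :class:`IQRecord` with unique subject ids."""

    records: tuple[IQRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.records:
            raise IQValidationError("IQ table is empty")
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IQValidationError(f"duplicate subject_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def subject_ids(self) -> list[int]:
        return [r.subject_id for r in self.records]

    def changes(self, measure: str) -> np.ndarray:
        """Change scores (t2 - t1) for ``measure`` in table order."""
        return np.array([r.change(measure) for r in self.records], dtype=float)

    def scores(self, measure: str, time: int) -> np.ndarray:
        return np.array([r.score(measure, time) for r in self.records], dtype=float)

    def subset(self, subject_ids: Iterable[int]) -> "IQTable":
        """Sub-table restricted to ``subject_ids``, preserving table order."""
        keep = set(subject_ids)
        missing = keep - set(self.subject_ids)
        if missing:
            raise IQValidationError(f"unknown subject_id(s): {sorted(missing)}")
        return IQTable(tuple(r for r in self.records if r.subject_id in keep))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": r.subject_id,
                **{c: getattr(r, c) for c in SCORE_COLUMNS},
                "d_viq": r.d_viq,
                "d_piq": r.d_piq,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IQTable":
        records = tuple(
            IQRecord(
                subject_id=int(row.subject_id),
                **{c: float(getattr(row, c)) for c in SCORE_COLUMNS},
            )
            for row in df.itertuples(index=False)
        )
        return cls(records)


@dataclass(frozen=True)
class MeasureSummary:
    """Summary statistics for one IQ measure (VIQ or PIQ)."""

    mean_t1: float
    mean_t2: float
    sd_t1: float
    sd_t2: float
    mean_change: float
    sd_change: float
    min_change: float
    max_change: float
    test_retest_r: float  # NaN when a column has zero variance
    shapiro_p_t1: float
    shapiro_p_t2: float
    shift_fraction: float


@dataclass(frozen=True)
class BehaviouralSummary:
    viq: MeasureSummary
    piq: MeasureSummary
    n: int
    shift_threshold: float

    def measure(self, name: str) -> MeasureSummary:
        return getattr(self, name)


def load_iq_table(source: Union[str, Path, io.IOBase]) -> IQTable:
    """Read a behavioural CSV into an :class:`IQTable`.

    The file must have a header naming ``subject_id`` and the four score
    columns; optional ``d_viq``/``d_piq`` columns are verified against the
    recomputed differences and rejected on mismatch.
    """
    try:
        df = pd.read_csv(source)
    except pd.errors.EmptyDataError as exc:
        raise IQValidationError("empty behavioural table stream") from exc
    missing = [c for c in ("subject_id", *SCORE_COLUMNS) if c not in df.columns]
    if missing:
        raise IQValidationError(f"missing column(s): {missing}")
    if df.empty:
        raise IQValidationError("behavioural table has no rows")

    for col in ("subject_id", *SCORE_COLUMNS):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            raise IQValidationError(
                f"non-numeric value in column {col!r}, row {int(bad[0]) + 2} of the file"
            )
        df[col] = numeric

    table = IQTable.from_frame(df)

    # printed change columns, if any, must agree with the recomputed ones
    for col, measure in zip(CHANGE_COLUMNS, MEASURES):
        if col in df.columns:
            printed = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            derived = table.changes(measure)
            off = np.flatnonzero(printed != derived)
            if len(off):
                i = int(off[0])
                raise IQValidationError(
                    f"column {col!r} row {i + 2}: printed change {printed[i]} "
                    f"!= recomputed {derived[i]}"
                )
    return table


def write_iq_table(table: IQTable, dest: Union[str, Path, io.IOBase]) -> None:
    """Write a behavioural table as CSV (scores plus derived changes)."""
    table.to_frame().to_csv(dest, index=False)


def load_reference_table() -> IQTable:
    """The packaged 33-subject reference behavioural table."""
    ref = resources.files("longicv").joinpath("data/table1_behavioural.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return load_iq_table(fh)


def _measure_summary(
    t1: np.ndarray, t2: np.ndarray, shift_threshold: float
) -> MeasureSummary:
    change = t2 - t1
    if np.std(t1) == 0 or np.std(t2) == 0:
        r = float("nan")  # correlation undefined, not silently 0
    else:
        r = float(stats.pearsonr(t1, t2)[0])

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return float("nan")
        return float(stats.shapiro(x).pvalue)

    return MeasureSummary(
        mean_t1=float(np.mean(t1)),
        mean_t2=float(np.mean(t2)),
        sd_t1=float(np.std(t1, ddof=1)),
        sd_t2=float(np.std(t2, ddof=1)),
        mean_change=float(np.mean(change)),
        sd_change=float(np.std(change, ddof=1)),
        min_change=float(np.min(change)),
        max_change=float(np.max(change)),
        test_retest_r=r,
        shapiro_p_t1=_shapiro_p(t1),
        shapiro_p_t2=_shapiro_p(t2),
        shift_fraction=float(np.mean(np.abs(change) >= shift_threshold)),
    )


def summarise(table: IQTable, shift_threshold: float = 15.0) -> BehaviouralSummary:
    """Summary statistics per measure.

    Standard deviations use the n-1 denominator; ``test_retest_r`` is the
    Pearson correlation of the two time points; ``shift_fraction`` is the
    proportion of subjects whose absolute change reaches ``shift_threshold``
    IQ points (one population SD by default).
    """
    if len(table) < 3:
        raise IQValidationError(
            "summary statistics need at least 3 records "
            f"(got {len(table)}): correlation and normality tests are undefined"
        )
    summaries = {
        m: _measure_summary(table.scores(m, 1), table.scores(m, 2), shift_threshold)
        for m in MEASURES
    }
    return BehaviouralSummary(
        viq=summaries["viq"],
        piq=summaries["piq"],
        n=len(table),
        shift_threshold=shift_threshold,
    )


def format_summary(summary: BehaviouralSummary) -> str:
    """Human-readable behavioural summary (1 dp for means/SDs, 2 dp for r)."""
    lines = [f"n = {summary.n}"]
    for m in MEASURES:
        s = summary.measure(m)
        lines += [
            f"{m.upper()}: t1 {s.mean_t1:.1f} ({s.sd_t1:.1f}), "
            f"t2 {s.mean_t2:.1f} ({s.sd_t2:.1f})",
            f"  change {s.mean_change:.1f} ({s.sd_change:.1f}), "
            f"range {s.min_change:+.0f}..{s.max_change:+.0f}",
            f"  test-retest r = {s.test_retest_r:.2f}",
            f"  Shapiro-Wilk p: t1 {s.shapiro_p_t1:.3f}, t2 {s.shapiro_p_t2:.3f}",
            f"  shift >= {summary.shift_threshold:g} points: "
            f"{round(100 * s.shift_fraction):d}%",
        ]
    return "\n".join(lines)
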