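"""Trial-level data model for response-deadline (urgency) conflict tasks.

A trial log is a flat table with one row per trial: who, which task, the
design factors (gap duration, fixation duration, congruency, stimulus),
and the behavioral outcome (response side, reaction time). The derived
quantity of interest is the raw processing time

    rPT = RT - gap duration  (integer milliseconds),

the time the target was actually visible before the response. rPT, response
correctness and deadline compliance are always recomputed from the stored
fields, never trusted from a file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

EXPERIMENTS = ("spatial_stroop", "numerical_stroop", "simon")
CONGRUENCIES = ("congruent", "incongruent")
SIDES = ("left", "right")
RESPONSES = ("left", "right", "none")

DEFAULT_DEADLINE_MS = 1000

#: Exact on-disk column set of the trial-log CSV (header order).
CSV_COLUMNS = [
    "participant_id",
    "experiment",
    "session",
    "block",
    "trial_index",
    "is_practice",
    "fixation_ms",
    "gap_ms",
    "congruency",
    "stim_desc",
    "correct_side",
    "response_side",
    "rt_ms",
]

_INT_COLUMNS = ["session", "block", "trial_index", "fixation_ms", "gap_ms"]


class SchemaError(ValueError):
    """A trial log is missing a required column or has an invalid value."""


@dataclass
class FilterReport:
    """Bookkeeping of the exclusion filter, one count per removal rule."""

    n_input: int = 0
    n_practice_removed: int = 0
    n_no_response: int = 0
    n_rpt_out_of_range: int = 0
    n_retained: int = 0

    def __post_init__(self) -> None:
        total = (
            self.n_practice_removed
            + self.n_no_response
            + self.n_rpt_out_of_range
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError(
                f"filter counts do not add up: {total} != n_input={self.n_input}"
            )


@dataclass
class TrialTable:
    """An ordered collection of trials plus provenance metadata.

    ``data`` holds one row per trial with the columns of :data:`CSV_COLUMNS`
    plus the derived columns ``rpt_ms``, ``on_time`` and ``correct``.
    """

    data: pd.DataFrame
    experiment: str | None = None
    deadline_ms: int = DEFAULT_DEADLINE_MS
    source: str | None = None

    def __post_init__(self) -> None:
        self.data = derive_columns(self.data, deadline_ms=self.deadline_ms)
        if self.experiment is None and len(self.data):
            exps = self.data["experiment"].unique()
            if len(exps) == 1:
                self.experiment = exps[0]

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_participants(self) -> int:
        return self.data["participant_id"].nunique()


def compute_rpt(rt_ms, gap_ms):
    """Raw processing time: ``rt_ms - gap_ms`` (exact integer arithmetic).

    Works elementwise on scalars or arrays; NA-valued RTs propagate.
    """
    return rt_ms - gap_ms


def derive_columns(df: pd.DataFrame, deadline_ms: int = DEFAULT_DEADLINE_MS) -> pd.DataFrame:
    """Recompute ``rpt_ms``, ``on_time`` and ``correct`` from the raw fields.

    Stored values of the derived columns are discarded: rPT is always
    ``rt_ms - gap_ms``, ``correct`` is always the side match, and ``on_time``
    compares the RT against the deadline. Trials with no response get
    ``correct = False`` and ``on_time = False``.
    """
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table is missing required column(s): {missing}")
    df = df.copy()
    df["rt_ms"] = df["rt_ms"].astype("Int64")
    for c in _INT_COLUMNS:
        df[c] = df[c].astype("int64")
    df["is_practice"] = df["is_practice"].astype(bool)
    df["rpt_ms"] = compute_rpt(df["rt_ms"], df["gap_ms"]).astype("Int64")
    responded = df["response_side"].isin(SIDES)
    df["correct"] = responded & (df["response_side"] == df["correct_side"])
    df["on_time"] = responded & (df["rt_ms"].fillna(deadline_ms + 1) <= deadline_ms)
    return df


def _parse_bool(series: pd.Series, column: str) -> pd.Series:
    s = series.astype(str).str.strip().str.lower()
    bad = ~s.isin(["true", "false"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +2: header + 1-based
        raise SchemaError(
            f"column {column!r}: expected true/false, got {series[bad].iloc[0]!r} "
            f"at file row {row}"
        )
    return s == "true"


def read_trial_table(
    path: str | Path | io.IOBase,
    deadline_ms: int = DEFAULT_DEADLINE_MS,
    delimiter: str = ",",
) -> TrialTable:
    """Read a trial-log CSV into a :class:`TrialTable`.

    The file must carry a header with all columns of :data:`CSV_COLUMNS`.
    ``rpt_ms`` is recomputed from ``rt_ms`` and ``gap_ms`` regardless of any
    stored value; row order is preserved. Empty ``rt_ms``/``response_side``
    fields denote an unsimulated design row (RT missing, response "none").

    Raises
    ------
    SchemaError
        If a required column is absent or a numeric field fails to parse
        (the error names the column and the 1-based file row).
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial log is missing required column(s): {missing}")
    out = pd.DataFrame(index=df.index)
    for c in ["participant_id", "experiment", "congruency", "stim_desc",
              "correct_side", "response_side"]:
        out[c] = df[c].str.strip()
    out.loc[out["response_side"] == "", "response_side"] = "none"
    for c in _INT_COLUMNS + ["rt_ms"]:
        raw = df[c].str.strip()
        empty = raw == ""
        if empty.any() and c != "rt_ms":
            row = int(np.flatnonzero(empty.to_numpy())[0]) + 2
            raise SchemaError(f"column {c!r}: empty value at file row {row}")
        numeric = pd.to_numeric(raw.where(~empty), errors="coerce")
        bad = numeric.isna() & ~empty
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise SchemaError(
                f"column {c!r}: non-numeric value {raw[bad].iloc[0]!r} "
                f"at file row {row}"
            )
        # sub-ms timestamps are rounded half-up at ingest
        out[c] = np.floor(numeric + 0.5).astype("Int64")
    out["is_practice"] = _parse_bool(df["is_practice"], "is_practice")
    out = out[CSV_COLUMNS]
    source = str(path) if isinstance(path, (str, Path)) else None
    return TrialTable(out, deadline_ms=deadline_ms, source=source)


def write_trial_table(table: TrialTable, path: str | Path | io.IOBase) -> None:
    """Write the trial log as UTF-8 CSV with the documented header.

    Only the raw fields are written (derived columns are recomputed on
    read); enum spellings and booleans (``true``/``false``) round-trip
    losslessly. An empty table is refused.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty trial table")
    df = table.data[CSV_COLUMNS].copy()
    df["is_practice"] = np.where(df["is_practice"], "true", "false")
    df["rt_ms"] = df["rt_ms"].astype(object).where(df["rt_ms"].notna(), "")
    df.to_csv(path, index=False)


def apply_exclusions(
    table: TrialTable,
    rpt_lo: int = -200,
    rpt_hi: int = 1000,
    drop_late: bool = False,
) -> tuple[TrialTable, FilterReport]:
    """Apply the standard trial exclusions, in order, and count each.

    Removal order: (1) practice trials; (2) trials with no response;
    (3) trials with rPT outside the inclusive window ``[rpt_lo, rpt_hi]``.
    Each trial is counted against the first rule that removes it. Retained
    trials keep their original order. ``drop_late`` additionally removes
    responses after the deadline (off by default: the analysis window is
    defined by rPT, not deadline compliance). Idempotent.
    """
    if rpt_lo >= rpt_hi:
        raise ValueError(f"rpt_lo must be < rpt_hi, got [{rpt_lo}, {rpt_hi}]")
    df = table.data
    n_input = len(df)
    practice = df["is_practice"].to_numpy(bool)
    no_resp = (~df["response_side"].isin(SIDES)).to_numpy() & ~practice
    if drop_late:
        no_resp |= (~df["on_time"].to_numpy(bool)) & ~practice
    rpt = df["rpt_ms"].to_numpy("float64", na_value=np.nan)
    out_of_range = (~((rpt >= rpt_lo) & (rpt <= rpt_hi))) & ~practice & ~no_resp
    keep = ~(practice | no_resp | out_of_range)
    report = FilterReport(
        n_input=n_input,
        n_practice_removed=int(practice.sum()),
        n_no_response=int(no_resp.sum()),
        n_rpt_out_of_range=int(out_of_range.sum()),
        n_retained=int(keep.sum()),
    )
    kept = TrialTable(
        df.loc[keep].reset_index(drop=True),
        experiment=table.experiment,
        deadline_ms=table.deadline_ms,
        source=table.source,
    )
    return kept, report
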