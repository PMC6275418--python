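"""Trial-level data model for Simon-task experiments.

A trial table is a long-format :class:`pandas.DataFrame` with one row per
behavioral trial.  The canonical columns are

``subject_id``
    Subject identifier (string).
``selection_mode``
    ``no_active`` when the movement type is fixed within a block,
    ``active`` when two movement types are interleaved and the action
    itself must be selected on every trial.
``movement``
    Movement label, e.g. ``lifting``, ``reaching``, ``index_lifting``.
``congruence``
    ``congruent`` when the stimulus appears on the same side as the
    responding hand, ``incongruent`` otherwise.
``stimulus_side`` / ``response_hand``
    ``left`` or ``right``.  ``response_hand`` is the hand *assigned* by the
    task rule (the correct hand); on kinematic-error trials the action was
    actually initiated with the other hand.
``rt_ms``
    Reaction time in milliseconds: stimulus onset to movement initiation.
``mt_ms``
    Movement time in milliseconds (initiation to movement end).  Present
    only for transport movements (reaching); empty otherwise.
``ke`` / ``me``
    Kinematic error (response initiated with the wrong hand) and movement
    error (wrong or inaccurate end point) flags, serialized as 0/1.
``trial_index``
    1-based position of the trial within the subject's session.

All other modules consume tables in this layout.  Unknown columns are
carried through untouched by :func:`read_trials` / :func:`write_trials`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "TRANSPORT_MOVEMENTS",
    "SchemaError",
    "TrialTableError",
    "ExperimentDesign",
    "BlockSpec",
    "ValidationReport",
    "read_trials",
    "write_trials",
    "validate_trials",
]

#: Canonical column order of a trial table.
COLUMNS = [
    "subject_id",
    "selection_mode",
    "movement",
    "congruence",
    "stimulus_side",
    "response_hand",
    "rt_ms",
    "mt_ms",
    "ke",
    "me",
    "trial_index",
]

#: Movements with a transport phase; only these carry a movement time.
TRANSPORT_MOVEMENTS = frozenset({"reaching"})

SELECTION_MODES = ("no_active", "active")
CONGRUENCE_LEVELS = ("congruent", "incongruent")
SIDES = ("left", "right")

_NUMERIC = {"rt_ms": float, "mt_ms": float, "trial_index": int}
_BOOLEAN = ("ke", "me")


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


class TrialTableError(ValueError):
    """A cell value cannot be parsed; carries the offending row and field."""

    def __init__(self, row: int, column: str, message: str):
        self.row = row
        self.column = column
        super().__init__(f"row {row}, column {column!r}: {message}")


@dataclass(frozen=True)
class BlockSpec:
    """One experimental block: fixed or interleaved movement types."""

    selection_mode: str
    movements: tuple[str, ...]
    n_trials: int

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not self.movements:
            raise ValueError("movements must be nonempty")
        if self.selection_mode == "active" and len(self.movements) < 2:
            raise ValueError("active-selection (mixed) blocks need >= 2 movements")
        if self.selection_mode not in SELECTION_MODES:
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")


@dataclass(frozen=True)
class ExperimentDesign:
    """Block structure of one experiment (practice trials are pre-removed)."""

    n_subjects: int
    blocks: tuple[BlockSpec, ...]
    practice_trials: int = 16

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not self.blocks:
            raise ValueError("design needs at least one block")

    @property
    def trials_per_subject(self) -> int:
        return sum(b.n_trials for b in self.blocks)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_trials`: every invariant violation found."""

    n_rows: int
    problems: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems

    def add(self, row: int, column: str, message: str) -> None:
        self.problems.append((row, column, message))


def _parse_bool(series: pd.Series, column: str, report: ValidationReport | None):
    mapping = {
        "0": False, "1": True, "false": False, "true": True,
        "False": False, "True": True,
    }
    out = np.zeros(len(series), dtype=bool)
    for pos, raw in enumerate(series.to_numpy()):
        key = str(raw).strip()
        if key in mapping:
            out[pos] = mapping[key]
        elif report is not None:
            report.add(pos, column, f"not a boolean 0/1 value: {raw!r}")
        else:
            raise TrialTableError(pos, column, f"not a boolean 0/1 value: {raw!r}")
    return out


def read_trials(path, *, collect_errors: bool = False):
    """Read a trial table from CSV.

    Parameters
    ----------
    path
        CSV file with a header containing at least the canonical columns
        (:data:`COLUMNS`).  Extra columns are preserved.
    collect_errors
        If true, unparseable cells are reported in the returned
        :class:`ValidationReport` instead of raising.

    Returns
    -------
    (DataFrame, ValidationReport)
        Table in canonical order (extra columns appended) and the parse
        report.  Row order of the file is preserved.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    report = ValidationReport(n_rows=len(raw))
    sink = report if collect_errors else None
    out = pd.DataFrame(index=raw.index)
    for col in COLUMNS:
        values = raw[col]
        if col in _NUMERIC:
            if col == "mt_ms":
                blank = values.str.strip() == ""
                parsed = pd.to_numeric(values.where(~blank, np.nan), errors="coerce")
                bad = parsed.isna() & ~blank
            else:
                parsed = pd.to_numeric(values, errors="coerce")
                bad = parsed.isna()
            for pos in np.flatnonzero(bad.to_numpy()):
                if sink is not None:
                    sink.add(int(pos), col, f"not numeric: {values.iat[pos]!r}")
                else:
                    raise TrialTableError(int(pos), col,
                                          f"not numeric: {values.iat[pos]!r}")
            if col == "trial_index" and not bad.any():
                parsed = parsed.astype(int)
            out[col] = parsed
        elif col in _BOOLEAN:
            out[col] = _parse_bool(values, col, sink)
        else:
            out[col] = values
    extras = [c for c in raw.columns if c not in COLUMNS]
    for col in extras:
        out[col] = raw[col]
    return out, report


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table as RFC-4180 CSV (UTF-8, header, canonical order).

    Booleans are serialized as 0/1 and missing ``mt_ms`` as an empty cell,
    so that ``read_trials(write_trials(T)) == T`` field for field.
    """
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"table lacks required column(s): {', '.join(missing)}")
    extras = [c for c in table.columns if c not in COLUMNS]
    out = table[COLUMNS + extras].copy()
    for col in _BOOLEAN:
        out[col] = out[col].astype(bool).astype(int)
    out.to_csv(path, index=False, na_rep="")


def validate_trials(table: pd.DataFrame) -> ValidationReport:
    """Check every row against the trial-record invariants.

    Violations are reported, never raised; a fully valid table yields an
    empty problem list.  The function is pure: repeated calls on the same
    table give identical reports.
    """
    report = ValidationReport(n_rows=len(table))
    if len(table) == 0:
        return report

    def check_enum(col, allowed):
        bad = ~table[col].isin(allowed)
        for pos in np.flatnonzero(bad.to_numpy()):
            report.add(int(pos), col,
                       f"value {table[col].iat[pos]!r} not in {sorted(allowed)}")

    check_enum("selection_mode", SELECTION_MODES)
    check_enum("congruence", CONGRUENCE_LEVELS)
    check_enum("stimulus_side", SIDES)
    check_enum("response_hand", SIDES)

    rt = table["rt_ms"]
    for pos in np.flatnonzero((rt.isna() | (rt < 0)).to_numpy()):
        report.add(int(pos), "rt_ms", "reaction time must be a nonnegative number")

    ti = table["trial_index"]
    for pos in np.flatnonzero((ti < 1).to_numpy()):
        report.add(int(pos), "trial_index", "trial_index must be >= 1")

    mt = table["mt_ms"]
    transport = table["movement"].isin(TRANSPORT_MOVEMENTS)
    for pos in np.flatnonzero((mt.notna() & ~transport).to_numpy()):
        report.add(int(pos), "mt_ms",
                   "movement time recorded for a movement without a transport phase")
    for pos in np.flatnonzero((mt.notna() & (mt < 0)).to_numpy()):
        report.add(int(pos), "mt_ms", "movement time must be nonnegative")

    # Congruence is defined by stimulus side vs the hand assigned by the
    # task rule (response_hand), independent of whether the trial was a KE.
    expected = (table["stimulus_side"] == table["response_hand"]).to_numpy()
    congruent = (table["congruence"] == "congruent").to_numpy()
    valid_enum = (
        table["congruence"].isin(CONGRUENCE_LEVELS)
        & table["stimulus_side"].isin(SIDES)
        & table["response_hand"].isin(SIDES)
    ).to_numpy()
    for pos in np.flatnonzero((congruent != expected) & valid_enum):
        report.add(int(pos), "congruence",
                   "congruence label inconsistent with stimulus side and response hand")
    return report
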