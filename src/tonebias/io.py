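"""Trial-table serialization and validation.

Trial tables are plain delimited text (TSV by default) with one row per
trial and the documented header. Frequencies are written with full float
precision (shortest round-trip repr, always >= 6 significant digits), so
write -> read is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "block_id",
    "trial_index",
    "f1_hz",
    "f2_hz",
    "response_first_higher",
    "correct",
    "analysis_eligible",
    "condition",
]


class TrialTableError(ValueError):
    """Raised for malformed trial tables; message carries line numbers."""


@dataclass
class ValidationReport:
    n_rows: int
    n_rejected: int
    rejected_lines: list[tuple[int, str]] = field(default_factory=list)

    def describe(self) -> str:
        if not self.rejected_lines:
            return f"{self.n_rows} rows, all valid"
        lines = "; ".join(f"line {ln}: {why}" for ln, why in self.rejected_lines)
        return f"{self.n_rows} rows, {self.n_rejected} rejected ({lines})"


def write_trials(trials: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write the canonical trial table as delimited text."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialTableError(f"missing columns: {missing}")
    out = trials[TRIAL_COLUMNS].copy()
    out["analysis_eligible"] = out["analysis_eligible"].astype(int)
    out.to_csv(path, sep=sep, index=False)


def read_trials(
    path: str | Path, sep: str = "\t", on_invalid: str = "raise"
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a trial table.

    Checks positive frequencies, binary response/correct flags, and that
    the recorded correctness matches ``response == (f1 > f2)`` recomputed
    from the frequencies. ``on_invalid='raise'`` raises
    :class:`TrialTableError` listing offending line numbers;
    ``on_invalid='drop'`` drops the rows and reports them.
    """
    if on_invalid not in ("raise", "drop"):
        raise ValueError("on_invalid must be 'raise' or 'drop'")
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise TrialTableError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path}: missing columns {missing}")

    bad: list[tuple[int, str]] = []
    # data line numbers: header is line 1
    line_no = np.arange(2, len(df) + 2)

    for col in ("f1_hz", "f2_hz"):
        vals = pd.to_numeric(df[col], errors="coerce")
        mask = ~np.isfinite(vals) | (vals <= 0)
        for ln in line_no[mask.to_numpy()]:
            bad.append((int(ln), f"non-positive or unparseable {col}"))
        df[col] = vals
    for col in ("response_first_higher", "correct"):
        vals = pd.to_numeric(df[col], errors="coerce")
        mask = ~vals.isin([0, 1])
        for ln in line_no[mask.to_numpy()]:
            bad.append((int(ln), f"non-binary {col}"))
        df[col] = vals

    ok = ~df.index.isin([ln - 2 for ln, _ in bad])
    recomputed = (
        df.loc[ok, "response_first_higher"]
        == (df.loc[ok, "f1_hz"] > df.loc[ok, "f2_hz"]).astype(int)
    ).astype(int)
    mismatch = df.loc[ok, "correct"] != recomputed
    for idx in df.loc[ok].index[mismatch.to_numpy()]:
        bad.append((int(idx) + 2, "correct inconsistent with response and tones"))

    bad.sort()
    report = ValidationReport(
        n_rows=len(df), n_rejected=len(bad), rejected_lines=bad
    )
    if bad and on_invalid == "raise":
        raise TrialTableError(f"{path}: {report.describe()}")
    if bad:
        df = df.drop(index=[ln - 2 for ln, _ in bad]).reset_index(drop=True)
    df["analysis_eligible"] = df["analysis_eligible"].astype(bool)
    df["response_first_higher"] = df["response_first_higher"].astype(int)
    df["correct"] = df["correct"].astype(int)
    return df, report


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
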