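"""Reading and writing trial-level choice data and result files.

The on-disk trial format is a plain CSV with one row per trial and header

    subject_id, group, session, trial_index, ambiguity, win_pence,
    loss_pence, choice, rt_ms

Choices are the strings REW / SAFE (case-insensitive on input; an empty
field marks a design-only trial).  Validation is strict: malformed rows are
reported with their line numbers and reading fails rather than silently
dropping data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Choice, Params, SubjectData, TrialRecord

__all__ = ["TRIAL_COLUMNS", "read_trials", "write_trials", "write_truth", "read_truth"]

TRIAL_COLUMNS = [
    "subject_id", "group", "session", "trial_index", "ambiguity",
    "win_pence", "loss_pence", "choice", "rt_ms",
]


class TrialFileError(ValueError):
    """Raised when a trial CSV fails validation; carries per-line messages."""

    def __init__(self, path, problems: list[str]):
        self.problems = problems
        shown = "\n  ".join(problems[:20])
        more = "" if len(problems) <= 20 else f"\n  ... and {len(problems) - 20} more"
        super().__init__(f"invalid trial file {path}:\n  {shown}{more}")


def read_trials(path: str | Path) -> dict[str, SubjectData]:
    """Load a trial CSV into per-subject data, validating every row."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str, "choice": str},
                     float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "rt_ms"]
    if missing:
        raise TrialFileError(path, [f"missing columns: {missing}"])
    if "rt_ms" not in df.columns:
        df["rt_ms"] = np.nan

    problems: list[str] = []
    subjects: dict[str, SubjectData] = {}
    rows: dict[str, list[tuple[int, TrialRecord]]] = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        try:
            raw_choice = row.choice
            if raw_choice is None or (isinstance(raw_choice, float) and np.isnan(raw_choice)) \
                    or str(raw_choice).strip() == "":
                choice = None
            else:
                token = str(raw_choice).strip().upper()
                if token not in ("REW", "SAFE"):
                    raise ValueError(f"unknown choice token {raw_choice!r}")
                choice = Choice(token)
            win, loss = int(row.win_pence), int(row.loss_pence)
            if win == 0 and loss == 0:
                raise ValueError("win_pence and loss_pence both zero")
            rt = None if pd.isna(row.rt_ms) else float(row.rt_ms)
            record = TrialRecord(
                ambiguity=float(row.ambiguity),
                win_pence=win,
                loss_pence=loss,
                choice=choice,
                rt_ms=rt,
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line}: {exc}")
            continue
        sid = str(row.subject_id)
        rows.setdefault(sid, []).append((int(row.trial_index), record))
        if sid not in subjects:
            subjects[sid] = SubjectData(subject_id=sid, group=str(row.group), trials=[])
        elif subjects[sid].group != str(row.group):
            problems.append(f"line {line}: subject {sid} has conflicting group labels")
    if problems:
        raise TrialFileError(path, problems)
    for sid, indexed in rows.items():
        indexed.sort(key=lambda pair: pair[0])
        subjects[sid].trials = [rec for _, rec in indexed]
    return subjects


def write_trials(subjects: dict[str, SubjectData] | list[SubjectData],
                 path: str | Path, session: str = "S3",
                 overwrite: bool = False) -> None:
    """Write per-subject trials to the CSV trial format."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    if isinstance(subjects, dict):
        subjects = list(subjects.values())
    records = []
    for subject in subjects:
        for idx, t in enumerate(subject.trials):
            records.append({
                "subject_id": subject.subject_id,
                "group": subject.group,
                "session": session,
                "trial_index": idx,
                "ambiguity": t.ambiguity,
                "win_pence": t.win_pence,
                "loss_pence": t.loss_pence,
                "choice": "" if t.choice is None else t.choice.value,
                "rt_ms": "" if t.rt_ms is None else t.rt_ms,
            })
    pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def write_truth(truth: dict[str, Params], path: str | Path,
                overwrite: bool = False) -> None:
    """Ground-truth simulation parameters as a JSON side file."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    payload = {sid: params.as_dict() for sid, params in truth.items()}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_truth(path: str | Path) -> dict[str, Params]:
    data = json.loads(Path(path).read_text())
    return {sid: Params(**values) for sid, values in data.items()}
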