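"""Wide-format trial table: schema, validation, CSV round-trip."""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

FIXED_COLUMNS = ("participant_id", "arm", "centre", "maternal_education", "ethnicity")
DIAGNOSTIC_COLUMN = "diagnostic_outcome"
DIAGNOSTIC_LEVELS = ("typical", "atypical", "ASD")
ARM_LEVELS = ("control", "intervention")

#: outcome/age columns are `<name>_<time-in-months>`
_TIMED_RE = re.compile(r"^([a-z][a-z0-9_]*)_(\d+)$")

#: per-prefix observed-scale range checks
_RANGE_RULES = (
    ("maci_", 1.0, 7.0),
    ("dcma_", 0.0, 1.0),
    ("aosi_", 0.0, np.inf),
    ("ados_", 0.0, np.inf),
)


class SchemaError(ValueError):
    """Dataset violates the trial-table schema; message lists every violation."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            f"{len(self.violations)} schema violation(s):\n  " + "\n  ".join(self.violations)
        )


def timed_columns(columns) -> dict:
    """Map column -> (name, time) for every `<name>_<time>` column."""
    out = {}
    for c in columns:
        m = _TIMED_RE.match(c)
        if m:
            out[c] = (m.group(1), int(m.group(2)))
    return out


@dataclass
class TrialDataset:
    """One row per participant; missing cells are NaN."""

    df: pd.DataFrame

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, TrialDataset) and self.df.equals(other.df)

    @property
    def occasion_times(self) -> tuple:
        return tuple(sorted({t for _, t in timed_columns(self.df.columns).values()}))

    def validate(self) -> None:
        """Raise SchemaError listing all violations, or return silently."""
        df = self.df
        violations = []
        for col in ("participant_id", "arm"):
            if col not in df.columns:
                violations.append(f"required column {col!r} missing")
        if violations:
            raise SchemaError(violations)

        dupes = df["participant_id"][df["participant_id"].duplicated()].unique()
        if len(dupes):
            violations.append(f"duplicate participant_id values: {sorted(map(str, dupes))}")
        bad_arm = set(df["arm"].dropna().unique()) - set(ARM_LEVELS)
        if bad_arm:
            violations.append(f"column 'arm': unknown levels {sorted(bad_arm)}")

        timed = timed_columns(df.columns)
        known = set(FIXED_COLUMNS) | {DIAGNOSTIC_COLUMN} | set(timed)
        unknown = [c for c in df.columns if c not in known]
        for c in unknown:
            violations.append(f"unknown column {c!r}")

        for c, (name, _t) in timed.items():
            if name.startswith("age"):
                continue
            vals = pd.to_numeric(df[c], errors="coerce")
            for prefix, lo, hi in _RANGE_RULES:
                if c.startswith(prefix) and not name.startswith("ados_module"):
                    bad = df.index[(vals < lo) | (vals > hi)]
                    for i in bad:
                        violations.append(
                            f"row {i} column {c!r}: value {df.at[i, c]} outside [{lo}, {hi}]"
                        )
                    break

        age_cols = sorted(
            (c for c, (name, t) in timed.items() if name == "age"), key=lambda c: timed[c][1]
        )
        if len(age_cols) >= 2:
            ages = df[age_cols].to_numpy(dtype=float)
            nondecr = np.diff(ages, axis=1) <= 0
            for i in np.nonzero(nondecr.any(axis=1))[0]:
                violations.append(f"row {i}: ages not strictly increasing across occasions")

        if DIAGNOSTIC_COLUMN in df.columns:
            vals = df[DIAGNOSTIC_COLUMN].dropna()
            bad = set(vals.unique()) - set(DIAGNOSTIC_LEVELS)
            if bad:
                violations.append(f"column {DIAGNOSTIC_COLUMN!r}: unknown levels {sorted(bad)}")

        outcome_times = sorted({t for c, (name, t) in timed.items() if name != "age"})
        if outcome_times:
            baseline = outcome_times[0]
            base_cols = [c for c, (name, t) in timed.items() if name != "age" and t == baseline]
            all_missing = df[base_cols].isna().all(axis=1)
            for i in df.index[all_missing]:
                violations.append(f"row {i}: all outcomes missing at baseline occasion {baseline}")

        if violations:
            raise SchemaError(violations)


def write_dataset(dataset: TrialDataset, path) -> None:
    """Write as CSV; missing cells become empty fields."""
    dataset.df.to_csv(path, index=False)


def read_dataset(path, validate: bool = True) -> TrialDataset:
    """Read a trial CSV; empty cells parse as missing. Inverse of write_dataset."""
    df = pd.read_csv(path)
    timed = timed_columns(df.columns)
    for c in timed:
        df[c] = pd.to_numeric(df[c], errors="coerce").astype(float)
    ds = TrialDataset(df)
    if validate:
        ds.validate()
    return ds
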