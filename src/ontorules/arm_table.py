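"""The arm-level data container used throughout the package.

One row per study arm: a study id, an arm id, an outcome percentage (the
percentage of participants abstinent at follow-up; may be missing), and a
set of literal membership columns in [0, 1].  Thin wrapper around a pandas
DataFrame so the standard CSV/TSV machinery applies directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ArmTable", "META_COLUMNS"]

META_COLUMNS = ("study_id", "arm_id", "outcome")

#: column kinds: how a literal column was produced, which controls whether it
#: gets a negated complement during literal expansion.
COLUMN_KINDS = ("presence", "negated", "range", "flag", "numeric", "categorical", "percentage")


@dataclass
class ArmTable:
    """A feature table over study arms.

    Parameters
    ----------
    df:
        DataFrame with columns ``study_id``, ``arm_id``, ``outcome`` plus one
        column per literal; memberships must lie in [0, 1].
    column_kinds:
        Mapping from literal column name to its kind.  ``presence`` columns
        are eligible for negated complements; ``range``/``flag`` columns
        (value-range literals, reported-flags) are not.  Columns not listed
        default to ``presence``.
    """

    df: pd.DataFrame
    column_kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"arm table missing required columns {missing}")
        dup = self.df.duplicated(subset=["study_id", "arm_id"])
        if dup.any():
            bad = self.df.loc[dup, ["study_id", "arm_id"]].iloc[0].tolist()
            raise ValueError(f"duplicate (study_id, arm_id): {bad}")
        vals = self.memberships()
        if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9):
            raise ValueError("memberships must lie in [0, 1]")

    # ------------------------------------------------------------------
    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in META_COLUMNS]

    @property
    def schema(self) -> list[str]:
        """The literal schema: every membership column, in table order."""
        return self.feature_columns

    @property
    def n_arms(self) -> int:
        return len(self.df)

    @property
    def n_studies(self) -> int:
        return self.df["study_id"].nunique()

    def kind(self, column: str) -> str:
        return self.column_kinds.get(column, "presence")

    def memberships(self, columns: list[str] | None = None) -> np.ndarray:
        cols = columns if columns is not None else self.feature_columns
        if not cols:
            return np.empty((len(self.df), 0))
        return self.df[cols].to_numpy(dtype=float)

    def outcomes(self) -> np.ndarray:
        return self.df["outcome"].to_numpy(dtype=float)

    def study_ids(self) -> np.ndarray:
        return self.df["study_id"].to_numpy()

    def with_outcomes_only(self) -> "ArmTable":
        """Rows whose outcome is reported."""
        keep = self.df["outcome"].notna()
        return ArmTable(self.df.loc[keep].reset_index(drop=True), dict(self.column_kinds))

    def subset(self, mask) -> "ArmTable":
        return ArmTable(self.df.loc[mask].reset_index(drop=True), dict(self.column_kinds))

    def subset_studies(self, studies) -> "ArmTable":
        keep = self.df["study_id"].isin(set(studies))
        return self.subset(keep)

    # ------------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, column_kinds: dict[str, str] | None = None) -> "ArmTable":
        path = Path(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep)
        return cls(df, column_kinds or {})

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        self.df.to_csv(path, sep=sep, index=False)
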