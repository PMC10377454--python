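"""Binary symptom datasets.

The unit of analysis throughout the package is a participants x symptoms
matrix of 0/1 indicators (symptom absent/present) carrying a group label,
e.g. one cohort of women with a major depressive episode (MDE) and one
with postpartum depression (PPD), each scored on the nine DSM-5 MDE
criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The nine DSM-5 criteria for a major depressive episode, in the order
#: used by all bundled parameter sets. The first two are the cardinal
#: symptoms (criterion A requires at least one of them).
DSM5_SYMPTOMS: tuple[str, ...] = (
    "sadness",
    "anhedonia",
    "appetite",
    "sleep",
    "psychomotor",
    "fatigue",
    "culpability",
    "concentration",
    "suicidal_ideations",
)

GROUP_COLUMN = "group"


@dataclass
class SymptomDataset:
    """An n x p matrix of binary symptom indicators for one group.

    Parameters
    ----------
    values
        Array of shape (n, p) with entries in {0, 1}.
    labels
        Unique symptom names, length p.
    group
        Group identifier (e.g. ``"MDE"`` or ``"PPD"``).
    """

    values: np.ndarray
    labels: list[str] = field(default_factory=list)
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("symptom indicators must be 0 or 1 with no missing values")
        self.values = self.values.astype(np.uint8)
        if not self.labels:
            self.labels = [f"s{i}" for i in range(self.values.shape[1])]
        self.labels = list(self.labels)
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("number of labels must match number of columns")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("symptom labels must be unique")
        if self.values.shape[1] < 2:
            raise ValueError("need at least two symptoms")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.labels)
        df[GROUP_COLUMN] = self.group
        return df

    def to_csv(self, path) -> None:
        """Write as CSV: one header row of symptom labels plus a group column."""
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group: str | None = None) -> "SymptomDataset":
        df = df.copy()
        if GROUP_COLUMN in df.columns:
            groups = df[GROUP_COLUMN].unique()
            if group is None:
                if len(groups) > 1:
                    raise ValueError(
                        f"dataframe holds several groups {list(groups)}; pass group="
                    )
                group = str(groups[0])
            df = df[df[GROUP_COLUMN] == group]
            df = df.drop(columns=[GROUP_COLUMN])
        return cls(df.to_numpy(), list(df.columns), group or "")

    @classmethod
    def read_csv(cls, path, group: str | None = None) -> "SymptomDataset":
        return cls.from_dataframe(pd.read_csv(path), group=group)


def read_cohorts(path) -> dict[str, SymptomDataset]:
    """Read a CSV holding several groups; returns one dataset per group label."""
    df = pd.read_csv(path)
    if GROUP_COLUMN not in df.columns:
        raise ValueError(f"cohort CSV needs a '{GROUP_COLUMN}' column")
    return {
        str(g): SymptomDataset.from_dataframe(df, group=str(g))
        for g in df[GROUP_COLUMN].unique()
    }


def write_cohorts(datasets: dict[str, SymptomDataset], path) -> None:
    pd.concat([d.to_dataframe() for d in datasets.values()], ignore_index=True).to_csv(
        path, index=False
    )
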