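"""Typed data container for decoding analyses.

A :class:`Dataset` couples a per-subject target vector (age in years) with a
design matrix whose columns carry *roles*: grey-matter region means, white-matter
region means, acquisition-site indicators, and a +1/-1 gender regressor. The
role tags make the block structure of the design matrix recoverable after the
blocks have been concatenated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Recognised column roles, in canonical block order.
ROLES = ("gm_region", "wm_region", "site", "gender")


@dataclass
class Dataset:
    """Per-subject ages plus a role-tagged design matrix.

    Parameters
    ----------
    ages : ndarray of shape (n,)
        Target variable in years.
    design : ndarray of shape (n, p)
        Design matrix; columns ordered [GM | WM | site indicators | gender].
    column_roles : sequence of str, length p
        One role tag per column, each in :data:`ROLES`.
    subject_ids : sequence of str, length n
    attrs : dict
        Free-form metadata (e.g. generating parameters for synthetic data).
    """

    ages: np.ndarray
    design: np.ndarray
    column_roles: np.ndarray
    subject_ids: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.design = np.asarray(self.design, dtype=float)
        self.column_roles = np.asarray(self.column_roles, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.design.ndim != 2:
            raise ValueError("design must be 2-dimensional")
        n, p = self.design.shape
        if self.ages.shape != (n,):
            raise ValueError(
                f"ages has length {self.ages.shape[0]} but design has {n} rows"
            )
        if self.column_roles.shape != (p,):
            raise ValueError("column_roles length must equal design column count")
        if self.subject_ids.shape != (n,):
            raise ValueError("subject_ids length must equal design row count")
        unknown = set(self.column_roles) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown column roles: {sorted(unknown)}")

    # ------------------------------------------------------------------ views
    @property
    def n(self) -> int:
        return self.design.shape[0]

    @property
    def p(self) -> int:
        return self.design.shape[1]

    def block(self, role: str) -> np.ndarray:
        """Columns carrying ``role``, in design order."""
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return self.design[:, self.column_roles == role]

    @property
    def indicator_mask(self) -> np.ndarray:
        """Boolean mask over columns: True for site/gender indicator columns."""
        return np.isin(self.column_roles, ("site", "gender"))

    def subset(self, index: np.ndarray) -> "Dataset":
        """Row subset (new Dataset; attrs are shared by reference)."""
        index = np.asarray(index)
        return Dataset(
            ages=self.ages[index],
            design=self.design[index],
            column_roles=self.column_roles.copy(),
            subject_ids=self.subject_ids[index],
            attrs=self.attrs,
        )

    # --------------------------------------------------------------------- io
    def to_frame(self) -> pd.DataFrame:
        """Design + age as a DataFrame with role-tagged column names."""
        counters: dict[str, int] = {}
        names = []
        for role in self.column_roles:
            counters[role] = counters.get(role, 0) + 1
            names.append(f"{role}_{counters[role]:03d}")
        frame = pd.DataFrame(self.design, columns=names)
        frame.insert(0, "subject_id", self.subject_ids)
        frame.insert(1, "age", self.ages)
        return frame

    def to_csv(self, path: str | Path) -> None:
        """Write design + ages as CSV with a sidecar JSON of column roles."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(".roles.json")
        sidecar.write_text(json.dumps({"column_roles": list(self.column_roles)}))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        frame = pd.read_csv(path)
        sidecar = path.with_suffix(".roles.json")
        roles = json.loads(sidecar.read_text())["column_roles"]
        design_cols = [c for c in frame.columns if c not in ("subject_id", "age")]
        return cls(
            ages=frame["age"].to_numpy(float),
            design=frame[design_cols].to_numpy(float),
            column_roles=np.asarray(roles, dtype=object),
            subject_ids=frame["subject_id"].to_numpy(dtype=object),
        )
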