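"""Cohort tables: per-subject records with variable metadata.

A :class:`CohortTable` wraps a pandas DataFrame (one row per subject, a
``group`` column with the two study arms) together with per-variable
metadata — measurement type, units, assay limit of detection, and any
transform already applied.  It is the common currency between the
biomarker-preparation and screening-statistics stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = ["VariableMeta", "CohortTable", "GROUP_CONTROL", "GROUP_CASE"]

GROUP_CONTROL = "control"
GROUP_CASE = "post-MI"

BELOW_LOD_SUFFIX = "_below_lod"


@dataclass
class VariableMeta:
    name: str
    kind: str = "continuous"      # "continuous" | "binary"
    units: str = ""
    lod: float | None = None
    transform: str | None = None  # e.g. "log10"
    display: str | None = None

    @property
    def display_name(self) -> str:
        base = self.display or self.name
        if self.transform == "log10":
            return f"Log10 {base}"
        return base


@dataclass
class CohortTable:
    """One row per subject; ``group`` column holds the study arm."""

    data: pd.DataFrame
    variables: dict[str, VariableMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "group" not in self.data.columns:
            raise ValueError("cohort table requires a 'group' column")
        if "subject_id" in self.data.columns:
            if self.data["subject_id"].duplicated().any():
                raise ValueError("subject_id values must be unique")
        for name in self.data.columns:
            if name in ("subject_id", "group") or name.endswith(BELOW_LOD_SUFFIX):
                continue
            self.variables.setdefault(name, VariableMeta(name=name))

    # ------------------------------------------------------------------
    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.data["group"]))

    def group_values(self, variable: str, group: str) -> pd.Series:
        if variable not in self.data.columns:
            raise KeyError(f"unknown variable {variable!r}")
        sel = self.data.loc[self.data["group"] == group, variable]
        return sel.dropna()

    def meta(self, variable: str) -> VariableMeta:
        return self.variables.get(variable, VariableMeta(name=variable))

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(),
                           {k: replace(v) for k, v in self.variables.items()})

    # ------------------------------------------------------------------ IO
    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index=False)
        meta = pd.DataFrame(
            [{"name": v.name, "kind": v.kind, "units": v.units,
              "lod": v.lod, "transform": v.transform}
             for v in self.variables.values()])
        meta.to_csv(path.with_suffix(".meta.csv"), index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        path = Path(path)
        data = pd.read_csv(path)
        variables: dict[str, VariableMeta] = {}
        meta_path = path.with_suffix(".meta.csv")
        if meta_path.exists():
            meta = pd.read_csv(meta_path)
            for _, row in meta.iterrows():
                lod = row.get("lod")
                transform = row.get("transform")
                variables[row["name"]] = VariableMeta(
                    name=row["name"], kind=row.get("kind", "continuous"),
                    units=row.get("units", "") or "",
                    lod=None if pd.isna(lod) else float(lod),
                    transform=None if pd.isna(transform) else str(transform))
        return cls(data=data, variables=variables)
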