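"""Biomarker handling rules and per-patient aggregation.

Assay results below the limit of detection (LOD) are imputed as 90% of the
LOD and flagged; right-skewed markers are base-10 log transformed before
modelling; per-segment ocular measurements from up to four videos of both
eyes are pooled into one unweighted patient mean per parameter; and a
Shapiro-Wilk gate (p > 0.05) decides parametric vs rank-based group tests.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .tables import BELOW_LOD_SUFFIX, CohortTable
from .velocimetry import SegmentHaemodynamics

__all__ = [
    "AssayDefinition",
    "load_assay_lods",
    "impute_below_lod",
    "impute_table",
    "apply_log10",
    "aggregate_patient",
    "shapiro_wilk_gate",
    "OCULAR_PARAMETERS",
    "DEFAULT_LOG10_VARIABLES",
]

#: ocular parameters aggregated per patient
OCULAR_PARAMETERS = ("diameter", "va", "vs", "flow", "wsr")

#: variables log10-transformed by default (the right-skewed panel members
#: the screening models use on the log scale)
DEFAULT_LOG10_VARIABLES = ("nt_probnp", "adiponectin", "h_fabp", "wsr")


@dataclass(frozen=True)
class AssayDefinition:
    name: str
    lod: float | None
    units: str = ""

    def __post_init__(self) -> None:
        if self.lod is not None and not self.lod > 0:
            raise ValueError(f"{self.name}: LOD must be > 0 when present")


def load_assay_lods() -> dict[str, AssayDefinition]:
    """The packaged table of the 20 assay detection limits."""
    with resources.files("ocuflow.data").joinpath("assay_lods.csv").open() as fh:
        df = pd.read_csv(fh)
    return {row["name"]: AssayDefinition(row["name"], float(row["lod"]),
                                         row["units"])
            for _, row in df.iterrows()}


# ------------------------------------------------------------------ LOD rule
def impute_below_lod(value: float | None, assay: AssayDefinition,
                     below_lod: bool | None = None) -> tuple[float, bool]:
    """Apply the 90%-of-LOD rule to one assay result.

    ``value`` may be ``None`` for a result reported only as "< LOD".  When
    ``below_lod`` is not given it is inferred by comparing against the
    assay's LOD.  Returns ``(imputed_value, was_imputed)``; detectable
    values pass through unchanged (idempotent).
    """
    if below_lod is None:
        if value is None:
            below_lod = True
        elif assay.lod is None:
            below_lod = False
        else:
            below_lod = bool(value < assay.lod)
    if not below_lod:
        if value is None:
            raise ValueError(f"{assay.name}: missing value not flagged below-LOD")
        return float(value), False
    if assay.lod is None:
        raise ValueError(
            f"{assay.name}: below-LOD result but no LOD on record")
    return 0.9 * assay.lod, True


def impute_table(table: CohortTable) -> CohortTable:
    """Apply the LOD rule to every variable with an LOD on record."""
    out = table.copy()
    for name, meta in out.variables.items():
        if meta.lod is None or name not in out.data.columns:
            continue
        flag_col = name + BELOW_LOD_SUFFIX
        vals = out.data[name]
        if flag_col in out.data.columns:
            flags = out.data[flag_col].astype(bool)
        else:
            flags = vals < meta.lod
        flags = flags | (vals < meta.lod)
        out.data.loc[flags, name] = 0.9 * meta.lod
        out.data[flag_col] = flags.astype(bool)
    return out


# ------------------------------------------------------------------ transform
def apply_log10(table: CohortTable, variables: Sequence[str]) -> CohortTable:
    """Replace the listed variables by their base-10 logarithm."""
    out = table.copy()
    for name in variables:
        if name not in out.data.columns:
            raise KeyError(f"unknown variable {name!r}")
        vals = out.data[name]
        bad = vals.notna() & (vals <= 0)
        if bad.any():
            idx = bad.idxmax()
            sid = (out.data.loc[idx, "subject_id"]
                   if "subject_id" in out.data.columns else idx)
            raise ValueError(
                f"cannot log10-transform {name!r}: non-positive value "
                f"{vals.loc[idx]} for subject {sid}")
        out.data[name] = np.log10(vals)
        out.variables[name].transform = "log10"
    return out


# ------------------------------------------------------------------ pooling
def aggregate_patient(
    segments_by_video: Mapping[str, Sequence[SegmentHaemodynamics]],
    weighting: str = "segment",
) -> dict[str, float] | None:
    """Pool per-segment haemodynamics into one patient mean per parameter.

    ``weighting='segment'`` (default) gives every included segment equal
    weight across all videos of both eyes; ``'video'`` averages per-video
    means.  Returns ``None`` ("ocular missing") when no segments remain.
    """
    if weighting not in ("segment", "video"):
        raise ValueError("weighting must be 'segment' or 'video'")

    def as_row(h: SegmentHaemodynamics) -> np.ndarray:
        return np.array([h.diameter_um, h.axial_velocity_mm_s,
                         h.cross_velocity_mm_s, h.flow_pl_s, h.wsr_per_s])

    if weighting == "segment":
        rows = [as_row(h) for segs in segments_by_video.values() for h in segs]
        if not rows:
            return None
        means = np.mean(rows, axis=0)
    else:
        video_means = [np.mean([as_row(h) for h in segs], axis=0)
                       for segs in segments_by_video.values() if segs]
        if not video_means:
            return None
        means = np.mean(video_means, axis=0)
    return dict(zip(OCULAR_PARAMETERS, means.tolist()))


# ------------------------------------------------------------------ normality
class ShapiroResult(NamedTuple):
    statistic: float
    p_value: float
    is_normal: bool


def shapiro_wilk_gate(values: Sequence[float]) -> ShapiroResult:
    """Shapiro-Wilk W and p, with the parametric gate at p > 0.05."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got {x.size}")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk limited to n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = stats.shapiro(x)
    return ShapiroResult(float(w), float(p), bool(p > 0.05))
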