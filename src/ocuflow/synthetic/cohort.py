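"""Two-group case-control cohort simulator.

Continuous variables are drawn per group from a normal or lognormal family
whose *arithmetic* mean and SD match the configured values (the lognormal
is moment-matched), coupled across variables by a Gaussian copula with an
exchangeable latent correlation.  Binary history variables are Bernoulli.
Values that fall below a variable's assay limit of detection are flagged
censored; the generated value is retained so tests can recount censoring.

Default parameters reproduce the published group summaries for the
post-myocardial-infarction vs healthy-control comparison (n = 66 / 66):
demographics and clinical history, the five ocular microvascular
parameters (D, Va, Vs, Q, WSR), and the biomarker panel used by the
screening models (NT-proBNP, adiponectin, H-FABP, CRP, IL-6, ...).
Right-skewed markers whose SD exceeds their mean are lognormal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..tables import CohortTable, VariableMeta, GROUP_CASE, GROUP_CONTROL

__all__ = [
    "VariableSpec",
    "BinarySpec",
    "CohortSimConfig",
    "simulate_cohort",
    "default_variable_specs",
    "default_binary_specs",
]


@dataclass
class VariableSpec:
    """Group-wise moments for one continuous variable."""

    name: str
    control_mean: float
    control_sd: float
    case_mean: float
    case_sd: float
    family: str = "normal"        # "normal" | "lognormal"
    lod: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.control_sd <= 0 or self.case_sd <= 0:
            raise ValueError(f"{self.name}: SDs must be > 0")
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"{self.name}: unknown family {self.family!r}")
        if self.family == "lognormal" and (self.control_mean <= 0
                                           or self.case_mean <= 0):
            raise ValueError(f"{self.name}: lognormal means must be > 0")


@dataclass
class BinarySpec:
    name: str
    control_proportion: float
    case_proportion: float

    def __post_init__(self) -> None:
        for p in (self.control_proportion, self.case_proportion):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: proportions must be in [0,1]")


def default_variable_specs() -> list[VariableSpec]:
    """Continuous-variable conditions from the published group summaries."""
    V = VariableSpec
    return [
        # demographics / clinical
        V("age", 52.50, 9.73, 56.73, 11.41, units="years"),
        V("height", 168.21, 10.68, 170.77, 9.34, units="cm"),
        V("weight", 81.40, 22.72, 83.59, 14.93, units="kg"),
        V("bmi", 28.71, 7.66, 28.62, 4.68, units="kg/m2"),
        V("systolic_bp", 128, 16, 120, 16, units="mmHg"),
        V("diastolic_bp", 76, 10, 73, 11, units="mmHg"),
        V("heart_rate", 71, 10, 73, 12, units="beats/min"),
        # ocular microvascular parameters
        V("diameter", 21.45, 3.03, 22.79, 3.07, units="um"),
        V("va", 0.54, 0.05, 0.50, 0.06, units="mm/s"),
        V("vs", 0.38, 0.04, 0.35, 0.04, units="mm/s"),
        V("flow", 159.66, 47.27, 161.0, 48.12, units="pl/s"),
        V("wsr", 167.78, 34.37, 143.59, 28.56, units="1/s"),
        # biomarkers (right-skewed markers lognormal; LODs where assayed)
        V("crp", 3.24, 6.39, 20.96, 42.49, family="lognormal", units="mg/l"),
        V("nt_probnp", 74.70, 186.68, 1049.11, 1663.65, family="lognormal",
          units="ng/l"),
        V("adiponectin", 11.15, 6.20, 8.58, 5.92, lod=0.18, units="ug/ml"),
        V("h_fabp", 3.62, 2.04, 13.75, 29.73, family="lognormal", lod=2.94,
          units="ng/ml"),
        V("il6", 1.92, 2.36, 8.17, 16.77, family="lognormal", lod=0.12,
          units="pg/ml"),
        V("hdl3", 20.17, 4.51, 17.73, 4.75, lod=4.0, units="mg/dl"),
        V("folate", 8.23, 6.06, 6.45, 4.15, family="lognormal", lod=2.72,
          units="nmol/l"),
        V("homocysteine", 14.35, 6.96, 15.81, 7.15, lod=1.74, units="umol/l"),
        V("vitamin_b12", 436.97, 210.39, 396.92, 174.68, lod=73.8,
          units="pmol/l"),
        V("adma", 3.15, 1.68, 3.63, 11.93, family="lognormal", lod=0.938,
          units="umol/l"),
        V("lrg1", 14.79, 9.44, 11.93, 4.92, lod=0.0047, units="ug/ml"),
        V("hdl", 1.48, 0.48, 1.13, 0.30, units="mmol/l"),
        V("total_cholesterol", 5.11, 0.89, 4.65, 1.44, units="mmol/l"),
    ]


def default_binary_specs() -> list[BinarySpec]:
    """Binary history variables with the published group proportions."""
    B = BinarySpec
    return [
        B("gender_male", 45 / 66, 52 / 66),
        B("hypertension", 8 / 66, 31 / 66),
        B("diabetes", 2 / 66, 15 / 66),
        B("copd", 6 / 66, 8 / 66),
        B("smoking", 29 / 66, 43 / 66),
        B("family_history_ihd", 21 / 66, 38 / 66),
    ]


@dataclass
class CohortSimConfig:
    n_control: int = 66
    n_case: int = 66
    variable_specs: list[VariableSpec] = field(
        default_factory=default_variable_specs)
    binary_specs: list[BinarySpec] = field(default_factory=default_binary_specs)
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need at least 2 subjects per group")
        k = len(self.variable_specs)
        if k > 1 and not (-1.0 / (k - 1) < self.correlation < 1.0 + 1e-12):
            raise ValueError(
                "exchangeable correlation matrix is not positive semi-definite "
                f"for rho={self.correlation} with {k} variables")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log scale matching an arithmetic mean/SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return mu, np.sqrt(sigma2)


def _latent_normal(rng: np.random.Generator, n: int, k: int,
                   rho: float) -> np.ndarray:
    """n x k standard normals with exchangeable correlation rho."""
    z = rng.standard_normal((n, k))
    if rho == 0.0 or k == 1:
        return z
    shared = rng.standard_normal((n, 1))
    if rho < 0:
        # valid negative exchangeable correlation via centred residuals
        cov = np.full((k, k), rho, dtype=float)
        np.fill_diagonal(cov, 1.0)
        chol = np.linalg.cholesky(cov)  # raises if not PSD
        return z @ chol.T
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z


def simulate_cohort(config: CohortSimConfig) -> CohortTable:
    """Draw one seeded case-control cohort table.

    Below-LOD values keep their generated value in the data column and are
    flagged in a companion ``<name>_below_lod`` column; imputation is a
    separate, downstream decision.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.variable_specs)

    rows: dict[str, np.ndarray] = {}
    n_total = cfg.n_control + cfg.n_case
    rows["subject_id"] = np.array(
        [f"S{i:04d}" for i in range(1, n_total + 1)])
    rows["group"] = np.array([GROUP_CONTROL] * cfg.n_control
                             + [GROUP_CASE] * cfg.n_case)

    variables: dict[str, VariableMeta] = {}
    if k:
        z = np.vstack([
            _latent_normal(rng, cfg.n_control, k, cfg.correlation),
            _latent_normal(rng, cfg.n_case, k, cfg.correlation),
        ])
        is_case = np.arange(n_total) >= cfg.n_control
        for j, spec in enumerate(cfg.variable_specs):
            mean = np.where(is_case, spec.case_mean, spec.control_mean)
            sd = np.where(is_case, spec.case_sd, spec.control_sd)
            if spec.family == "normal":
                vals = mean + sd * z[:, j]
            else:
                mu = np.empty(n_total)
                sig = np.empty(n_total)
                for grp_mask, m, s in (
                        (~is_case, spec.control_mean, spec.control_sd),
                        (is_case, spec.case_mean, spec.case_sd)):
                    gm, gs = _lognormal_params(m, s)
                    mu[grp_mask], sig[grp_mask] = gm, gs
                vals = np.exp(mu + sig * z[:, j])
            rows[spec.name] = vals
            variables[spec.name] = VariableMeta(
                name=spec.name, kind="continuous", units=spec.units,
                lod=spec.lod)
            if spec.lod is not None:
                rows[spec.name + "_below_lod"] = vals < spec.lod

    for spec in cfg.binary_specs:
        p = np.where(np.arange(n_total) >= cfg.n_control,
                     spec.case_proportion, spec.control_proportion)
        rows[spec.name] = (rng.random(n_total) < p).astype(int)
        variables[spec.name] = VariableMeta(name=spec.name, kind="binary")

    return CohortTable(data=pd.DataFrame(rows), variables=variables)
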