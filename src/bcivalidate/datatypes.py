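"""Shared domain types for morphometric condition-index analysis.

The central object is the :class:`MorphometricRecord` — one necropsied
animal with its snout–vent length (SVL, cm), total body mass (g) and
dissected coelomic wet-fat mass (g) — together with the configuration
and result containers used by the generator, the line-fitting engines,
the segmented size-class model and the validation pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "DegenerateInputError",
    "SEXES",
    "EXCLUSION_FLAGS",
    "MorphometricRecord",
    "MomentMassModel",
    "SegmentedMassModel",
    "FatModel",
    "SexEffect",
    "GeneratorConfig",
    "LineFit",
    "CommonSlopeTest",
    "SegmentedModel",
    "SmiParams",
    "TestResult",
    "CleaningReport",
    "ValidationReport",
    "records_to_frame",
    "frame_to_records",
]


class ConfigurationError(ValueError):
    """Invalid generator or pipeline configuration."""


class DegenerateInputError(ValueError):
    """Input data on which the requested statistic is undefined."""


SEXES = ("female", "male", "unknown")

#: Exclusion flags a record can carry (captivity duration is a separate
#: numeric field, screened against a threshold at cleaning time).
EXCLUSION_FLAGS = frozenset({"incomplete_necropsy", "abnormal", "unknown_sex"})


@dataclass
class MorphometricRecord:
    """One animal: lengths, masses, fat, sex, quality flags.

    Measurement precisions follow field practice for large lizards:
    SVL to 0.1 cm by flexible tape, total mass to 1 g on a digital
    scale, dissected wet-fat mass to 0.0001 g.
    """

    id: str
    sex: str
    svl_cm: float
    mass_g: float
    fat_g: float
    days_held: int = 0
    flags: frozenset = field(default_factory=frozenset)
    size_class: Optional[int] = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ConfigurationError(f"unknown sex {self.sex!r} on record {self.id}")
        if not self.svl_cm > 0:
            raise ConfigurationError(f"non-positive SVL on record {self.id}")
        if not self.mass_g > 0:
            raise ConfigurationError(f"non-positive mass on record {self.id}")
        if self.fat_g < 0:
            raise ConfigurationError(f"negative fat mass on record {self.id}")
        if self.fat_g >= self.mass_g:
            raise ConfigurationError(f"fat mass >= body mass on record {self.id}")
        if self.days_held < 0:
            raise ConfigurationError(f"negative days_held on record {self.id}")
        if not set(self.flags) <= EXCLUSION_FLAGS:
            raise ConfigurationError(f"unknown flag on record {self.id}: {set(self.flags) - EXCLUSION_FLAGS}")
        if (self.sex == "unknown") != ("unknown_sex" in self.flags):
            raise ConfigurationError(
                f"record {self.id}: sex='unknown' must coincide with the unknown_sex flag"
            )


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------


@dataclass
class MomentMassModel:
    """ln-mass jointly Gaussian with ln-length.

    Parameterized through the moments the type II (SMA) estimator
    targets: the slope is the ratio sd(ln M)/sd(ln L), so the sample
    SMA slope is a consistent estimator of ``sma_slope`` at any
    correlation — unlike a vertical-noise regression model, under which
    the SMA estimator is inflated by 1/|r|.
    """

    sma_slope: float = 3.13
    correlation: float = 0.995
    mean_ln_mass: float = 6.0

    def validate(self) -> None:
        if not (0.0 < self.correlation <= 1.0):
            raise ConfigurationError("mass correlation must be in (0, 1]")
        if not (math.isfinite(self.sma_slope) and self.sma_slope > 0):
            raise ConfigurationError("mass sma_slope must be finite and positive")


@dataclass
class SegmentedMassModel:
    """Mean mass continuous piecewise-linear in SVL on the gram scale.

    ``intercept`` is the extrapolated mean mass at SVL = 0 for the first
    segment; when None it is anchored so that the mean mass at
    ``anchor_svl_cm`` equals ``anchor_mass_g`` (defaults place ~158 g on
    a 17 cm animal, the juvenile group's centre). The mean is floored
    at a small positive value so multiplicative noise is well defined
    over the whole length range.
    """

    breakpoints: Sequence[float] = (20.2, 30.0)
    segment_slopes: Sequence[float] = (30.0, 90.0, 180.0)
    intercept: Optional[float] = None
    anchor_svl_cm: float = 17.0
    anchor_mass_g: float = 158.2
    noise_cv: float = 0.10

    def validate(self) -> None:
        psi = np.asarray(self.breakpoints, dtype=float)
        if psi.ndim != 1 or len(psi) < 1:
            raise ConfigurationError("at least one breakpoint required")
        if np.any(np.diff(psi) <= 0):
            raise ConfigurationError("breakpoints must be strictly increasing")
        if len(self.segment_slopes) != len(psi) + 1:
            raise ConfigurationError("need one more segment slope than breakpoints")
        if not all(math.isfinite(s) and s > 0 for s in self.segment_slopes):
            raise ConfigurationError("segment slopes must be finite and positive")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")


@dataclass
class FatModel:
    """ln wet-fat mass jointly Gaussian with ln-length.

    Defaults emulate strong positive fat allometry (SMA slope ~6.9)
    with only moderate correlation (r^2 ~ 0.37), and a median fat mass
    of ~1.8 g at the mean length, i.e. small coelomic stores of order
    1–2% of body mass.
    """

    sma_slope: float = 6.91
    correlation: float = math.sqrt(0.37)
    mean_ln_fat_at_mean_svl: float = 0.6

    def validate(self) -> None:
        if not (0.0 < self.correlation <= 1.0):
            raise ConfigurationError("fat correlation must be in (0, 1]")
        if not (math.isfinite(self.sma_slope) and self.sma_slope > 0):
            raise ConfigurationError("fat sma_slope must be finite and positive")


@dataclass
class SexEffect:
    """Additive per-sex offset on the fat allometry slope.

    Defaults make the female fat–length slope steeper (~7.4) than the
    male slope (~6.6) around the common value; the mass–length slope is
    deliberately sex-free.
    """

    delta_fat_slope: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.47, "male": -0.36}
    )

    def validate(self) -> None:
        for sex, d in self.delta_fat_slope.items():
            if sex not in SEXES:
                raise ConfigurationError(f"sex effect for unknown sex {sex!r}")
            if not math.isfinite(d):
                raise ConfigurationError("sex slope offsets must be finite")


@dataclass
class GeneratorConfig:
    """Full configuration of the synthetic morphometric generator."""

    n: int = 883
    seed: int = 0
    svl_range_cm: tuple = (10.0, 46.4)
    mean_ln_svl: float = math.log(24.65)
    sd_ln_svl: float = 0.22
    mass_model: object = field(default_factory=MomentMassModel)
    fat_model: FatModel = field(default_factory=FatModel)
    sex_effect: Optional[SexEffect] = field(default_factory=SexEffect)
    male_prob: float = 0.56
    zero_fat_prob: float = 0.02
    flag_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "incomplete_necropsy": 0.01,
            "abnormal": 0.01,
            "unknown_sex": 0.01,
        }
    )
    days_held_range: tuple = (0, 8)

    def validate(self) -> None:
        if self.n < 2:
            raise ConfigurationError("n must be >= 2")
        lo, hi = self.svl_range_cm
        if not (0 < lo < hi):
            raise ConfigurationError("svl_range_cm must satisfy 0 < min < max")
        if not (self.sd_ln_svl > 0 and math.isfinite(self.sd_ln_svl)):
            raise ConfigurationError("sd_ln_svl must be positive and finite")
        if not (0.0 <= self.zero_fat_prob < 1.0):
            raise ConfigurationError("zero_fat_prob must be in [0, 1)")
        if not (0.0 <= self.male_prob <= 1.0):
            raise ConfigurationError("male_prob must be in [0, 1]")
        for name, p in self.flag_probs.items():
            if name not in EXCLUSION_FLAGS:
                raise ConfigurationError(f"unknown flag probability {name!r}")
            if not (0.0 <= p < 1.0):
                raise ConfigurationError(f"flag probability {name} must be in [0, 1)")
        d0, d1 = self.days_held_range
        if not (0 <= d0 <= d1):
            raise ConfigurationError("days_held_range must satisfy 0 <= min <= max")
        self.mass_model.validate()
        self.fat_model.validate()
        if self.sex_effect is not None:
            self.sex_effect.validate()

    def to_json(self) -> str:
        d = asdict(self)
        d["mass_model_kind"] = (
            "moment" if isinstance(self.mass_model, MomentMassModel) else "segmented"
        )
        return json.dumps(d, indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        d = json.loads(text)
        kind = d.pop("mass_model_kind", "moment")
        mm = d.pop("mass_model")
        mass_model = MomentMassModel(**mm) if kind == "moment" else SegmentedMassModel(**mm)
        fat_model = FatModel(**d.pop("fat_model"))
        se = d.pop("sex_effect", None)
        sex_effect = SexEffect(**se) if se is not None else None
        d["svl_range_cm"] = tuple(d["svl_range_cm"])
        d["days_held_range"] = tuple(d["days_held_range"])
        return cls(mass_model=mass_model, fat_model=fat_model, sex_effect=sex_effect, **d)


# ---------------------------------------------------------------------------
# Regression containers
# ---------------------------------------------------------------------------


@dataclass
class LineFit:
    """A fitted straight line y = a + b x (OLS, MA or SMA).

    Residuals are vertical (y − a − b x) for all three methods so that
    residual-based condition indices share a common scale.
    """

    method: str
    slope: float
    intercept: float
    n: int
    r2: float
    adj_r2: float
    slope_ci: tuple
    residuals: np.ndarray

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "slope": self.slope,
            "intercept": self.intercept,
            "n": self.n,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "slope_ci": list(self.slope_ci),
        }


@dataclass
class CommonSlopeTest:
    """Likelihood-ratio test that several groups share one SMA slope."""

    lr_stat: float
    df: int
    p_value: float
    common_slope: float
    group_slopes: tuple = ()


@dataclass
class SegmentedModel:
    """A broken-line GLM of mass on SVL.

    The linear predictor is continuous piecewise-linear in SVL with
    ``k`` estimated breakpoints ``psi``; the mean is the inverse link
    of that predictor. ``coefficients`` holds (intercept, base slope,
    slope change at each breakpoint).
    """

    family: str
    k: int
    psi: np.ndarray
    psi_se: np.ndarray
    coefficients: np.ndarray
    loglik: float
    bic: float
    converged: bool
    n_iter: int
    n: int
    dispersion: float = float("nan")
    bic_trace: Optional[dict] = None
    #: two-sided Wald p-value of each slope-change coefficient
    #: (heteroscedasticity-robust under the gaussian family)
    slope_change_p: np.ndarray = field(default_factory=lambda: np.empty(0))

    def linear_predictor(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        eta = self.coefficients[0] + self.coefficients[1] * x
        for j, psi_j in enumerate(self.psi):
            eta = eta + self.coefficients[2 + j] * np.clip(x - psi_j, 0.0, None)
        return eta

    def predict_mean(self, x) -> np.ndarray:
        eta = self.linear_predictor(x)
        if self.family == "gamma_neg_inverse":
            return -1.0 / eta
        return eta

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "k": self.k,
            "psi": list(map(float, self.psi)),
            "psi_se": list(map(float, self.psi_se)),
            "coefficients": list(map(float, self.coefficients)),
            "loglik": self.loglik,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n": self.n,
            "bic_trace": self.bic_trace,
            "slope_change_p": list(map(float, self.slope_change_p)),
        }


@dataclass
class SmiParams:
    """Reference length and scaling exponent for scaled-mass indices."""

    l0: float
    b_sma: float
    source_group: str = "all"

    def validate(self) -> None:
        if not (self.l0 > 0 and math.isfinite(self.l0)):
            raise ConfigurationError("l0 must be positive and finite")
        if not math.isfinite(self.b_sma):
            raise ConfigurationError("b_sma must be finite")


@dataclass
class TestResult:
    """A single statistical test: statistic, degrees of freedom, p."""

    name: str
    statistic: float
    df: object
    p_value: float
    n: int
    note: str = ""


@dataclass
class CleaningReport:
    """Per-rule exclusion counts from the data-cleaning stage."""

    n_input: int
    n_retained: int
    excluded: Mapping[str, int]
    max_days: int = 4

    def total_excluded(self) -> int:
        return sum(self.excluded.values())


@dataclass
class ValidationReport:
    """Associations of every condition index with fat stores and SVL."""

    grouping: str
    cells: pd.DataFrame
    fat_measure_bias: pd.DataFrame
    bci_correlation: Mapping[object, tuple]
    ranking: pd.DataFrame
    skipped_groups: tuple = ()


# ---------------------------------------------------------------------------
# record <-> DataFrame converters
# ---------------------------------------------------------------------------

_FRAME_COLUMNS = ["id", "sex", "svl_cm", "mass_g", "fat_g", "days_held", "flags", "size_class"]


def records_to_frame(records: Sequence[MorphometricRecord]) -> pd.DataFrame:
    """Tabulate records; ``flags`` become a semicolon-joined string."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "sex": r.sex,
                "svl_cm": r.svl_cm,
                "mass_g": r.mass_g,
                "fat_g": r.fat_g,
                "days_held": r.days_held,
                "flags": ";".join(sorted(r.flags)),
                "size_class": r.size_class,
                **dict(r.extra),
            }
        )
    df = pd.DataFrame(rows, columns=None)
    if df.empty:
        df = pd.DataFrame(columns=_FRAME_COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list:
    records = []
    extra_cols = [c for c in df.columns if c not in _FRAME_COLUMNS]
    for _, row in df.iterrows():
        flags = row.get("flags", "")
        if isinstance(flags, float) and math.isnan(flags):
            flags = ""
        flagset = frozenset(f for f in str(flags).split(";") if f)
        sc = row.get("size_class")
        if sc is None or (isinstance(sc, float) and math.isnan(sc)):
            size_class = None
        else:
            size_class = int(sc)
        records.append(
            MorphometricRecord(
                id=str(row["id"]),
                sex=str(row["sex"]),
                svl_cm=float(row["svl_cm"]),
                mass_g=float(row["mass_g"]),
                fat_g=float(row["fat_g"]),
                days_held=int(row.get("days_held", 0)),
                flags=flagset,
                size_class=size_class,
                extra={c: row[c] for c in extra_cols},
            )
        )
    return records
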