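"""Synthetic morphometric datasets with a controlled statistical structure.

The generator emulates a necropsy dataset of a large lizard population:
snout–vent lengths on roughly 10–46 cm, strongly allometric ln-mass vs
ln-length (SMA slope ≈ 3.1 at correlation ≈ 0.995), weakly correlated
but steeply allometric ln-fat vs ln-length (SMA slope ≈ 6.9, r² ≈
0.37), occasional animals with exactly zero dissectable fat, quality
flags that the cleaning stage must remove, and a raw-scale mass–length
relationship that is continuous piecewise-linear with known breakpoints
when the segmented mass model is selected.

Two mass models are deliberately provided. The *moment* model draws
(ln L, ln M) jointly Gaussian parameterized by the sd ratio and
correlation, under which the sample SMA slope is a consistent estimator
of the configured slope; a vertical-noise model would inflate the SMA
estimand by 1/|r|. The *segmented* model instead makes the raw-scale
mean mass piecewise-linear in SVL so that breakpoint estimation has a
well-defined truth to recover.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    ConfigurationError,
    GeneratorConfig,
    MomentMassModel,
    MorphometricRecord,
    SegmentedMassModel,
)

__all__ = [
    "generate_lengths",
    "generate_mass_moment",
    "generate_mass_segmented",
    "segmented_mean_mass",
    "generate_fat",
    "generate_dataset",
]

#: floor (g) applied to the piecewise-linear mean so multiplicative
#: noise stays defined where a straight first segment would extrapolate
#: through zero.
_MEAN_MASS_FLOOR_G = 1.0


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_lengths(cfg: GeneratorConfig, rng=None) -> np.ndarray:
    """Draw n snout–vent lengths (cm), log-normal truncated to range.

    ln-SVL is Gaussian with the configured mean and sd; draws outside
    ``svl_range_cm`` are rejected and redrawn, so the realized ln-sd is
    mildly below nominal under tight ranges.
    """
    cfg.validate()
    rng = _rng(cfg.seed if rng is None else rng)
    lo, hi = cfg.svl_range_cm
    out = np.empty(cfg.n, dtype=float)
    filled = 0
    while filled < cfg.n:
        draw = np.exp(rng.normal(cfg.mean_ln_svl, cfg.sd_ln_svl, size=2 * (cfg.n - filled)))
        keep = draw[(draw >= lo) & (draw <= hi)][: cfg.n - filled]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def _conditional_gaussian(ln_x: np.ndarray, slope: float, rho: float, mean_y: float,
                          rng: np.random.Generator, slopes=None) -> np.ndarray:
    """ln-y jointly Gaussian with ln-x: sd ratio = slope, corr = rho.

    Uses the realized sample moments of ln_x, so the in-sample sd ratio
    targets the configured slope even when ln_x was truncated.
    ``slopes`` optionally supplies a per-point slope (sex offsets).
    """
    if not (0.0 < rho <= 1.0):
        raise ConfigurationError("correlation must be in (0, 1]")
    ln_x = np.asarray(ln_x, dtype=float)
    b = np.full(len(ln_x), float(slope)) if slopes is None else np.asarray(slopes, float)
    if np.any(b <= 0):
        raise ConfigurationError("slopes must be positive")
    sd_x = ln_x.std()
    if sd_x == 0:
        raise ConfigurationError("ln-length sample is constant")
    centered = ln_x - ln_x.mean()
    noise_sd = b * sd_x * np.sqrt(1.0 - rho * rho)
    return mean_y + b * rho * centered + rng.normal(0.0, 1.0, len(ln_x)) * noise_sd


def generate_mass_moment(ln_svl, sma_slope: float, rho: float, mean_ln_mass: float,
                         seed) -> np.ndarray:
    """Body masses (g) with ln-mass jointly Gaussian with ln-SVL.

    sd(ln M)/sd(ln L) = ``sma_slope`` and corr = ``rho`` in expectation;
    at rho = 1 the points fall exactly on the line.
    """
    rng = _rng(seed)
    ln_m = _conditional_gaussian(np.asarray(ln_svl, float), sma_slope, rho, mean_ln_mass, rng)
    return np.exp(ln_m)


def segmented_mean_mass(svl, psi, slopes, intercept: float) -> np.ndarray:
    """Continuous piecewise-linear mean mass (g), floored at 1 g."""
    svl = np.asarray(svl, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if np.any(np.diff(psi) <= 0):
        raise ConfigurationError("breakpoints must be strictly increasing")
    if len(slopes) != len(psi) + 1:
        raise ConfigurationError("need one more slope than breakpoints")
    mean = intercept + slopes[0] * svl
    for j, p in enumerate(psi):
        mean = mean + (slopes[j + 1] - slopes[j]) * np.clip(svl - p, 0.0, None)
    return np.maximum(mean, _MEAN_MASS_FLOOR_G)


def intercept_for_anchor(psi, slopes, anchor_svl: float, anchor_mass: float) -> float:
    """Intercept making the (un-floored) mean pass through an anchor point."""
    psi = np.asarray(psi, dtype=float)
    mean_at_zero_icpt = slopes[0] * anchor_svl
    for j, p in enumerate(psi):
        mean_at_zero_icpt += (slopes[j + 1] - slopes[j]) * max(anchor_svl - p, 0.0)
    return anchor_mass - mean_at_zero_icpt


def generate_mass_segmented(svl, psi, slopes, intercept: float, noise_cv: float,
                            seed) -> np.ndarray:
    """Masses (g) around a continuous broken-line mean, multiplicative noise.

    Noise is log-normal with coefficient of variation ``noise_cv``, so
    all masses are strictly positive; noise_cv = 0 returns the mean.
    """
    rng = _rng(seed)
    mean = segmented_mean_mass(svl, psi, slopes, intercept)
    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be >= 0")
    if noise_cv == 0:
        return mean
    sigma2 = np.log1p(noise_cv**2)
    factor = np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), len(mean)))
    return mean * factor


def generate_fat(ln_svl, sma_slope: float, rho: float, mean_ln_fat: float, sex,
                 sex_effect=None, zero_fat_prob: float = 0.0, seed=None) -> np.ndarray:
    """Wet-fat masses (g): ln-fat jointly Gaussian with ln-SVL.

    Optional per-sex slope offsets steepen or flatten the fat allometry
    by sex; with probability ``zero_fat_prob`` a record's fat is set to
    exactly 0 (emulating animals with no dissectable fat bodies, which
    the cleaning stage must drop before any log transform).
    """
    rng = _rng(seed)
    ln_svl = np.asarray(ln_svl, dtype=float)
    slopes = None
    if sex_effect is not None:
        sex = np.asarray(sex)
        delta = np.zeros(len(ln_svl))
        for s, d in sex_effect.delta_fat_slope.items():
            delta[sex == s] = d
        slopes = sma_slope + delta
    ln_f = _conditional_gaussian(ln_svl, sma_slope, rho, mean_ln_fat, rng, slopes=slopes)
    fat = np.exp(ln_f)
    if not (0.0 <= zero_fat_prob < 1.0):
        raise ConfigurationError("zero_fat_prob must be in [0, 1)")
    if zero_fat_prob > 0:
        fat[rng.random(len(fat)) < zero_fat_prob] = 0.0
    return fat


def generate_dataset(cfg: GeneratorConfig) -> list:
    """Compose a full synthetic dataset of :class:`MorphometricRecord`.

    Deterministic given ``cfg.seed``. Lengths, masses and fat are drawn
    from the configured models; sexes, exclusion flags and days held
    are planted by the configured probabilities; measurements are
    rounded to field precision (0.1 cm, 1 g, 0.0001 g) and fat is
    capped strictly below body mass.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    r_len, r_sex, r_mass, r_fat, r_flag, r_days = [
        np.random.default_rng(s) for s in ss.spawn(6)
    ]

    svl = generate_lengths(cfg, rng=r_len)
    ln_svl = np.log(svl)

    sex = np.where(r_sex.random(cfg.n) < cfg.male_prob, "male", "female").astype(object)

    flag_sets = [set() for _ in range(cfg.n)]
    for name, p in sorted(cfg.flag_probs.items()):
        hit = r_flag.random(cfg.n) < p
        for i in np.nonzero(hit)[0]:
            flag_sets[i].add(name)
    for i, fs in enumerate(flag_sets):
        if "unknown_sex" in fs:
            sex[i] = "unknown"

    if isinstance(cfg.mass_model, MomentMassModel):
        mm = cfg.mass_model
        mass = generate_mass_moment(ln_svl, mm.sma_slope, mm.correlation, mm.mean_ln_mass, r_mass)
    elif isinstance(cfg.mass_model, SegmentedMassModel):
        sm = cfg.mass_model
        icpt = sm.intercept
        if icpt is None:
            icpt = intercept_for_anchor(sm.breakpoints, sm.segment_slopes,
                                        sm.anchor_svl_cm, sm.anchor_mass_g)
        mass = generate_mass_segmented(svl, sm.breakpoints, sm.segment_slopes, icpt,
                                       sm.noise_cv, r_mass)
    else:
        raise ConfigurationError(f"unknown mass model {type(cfg.mass_model)!r}")

    fm = cfg.fat_model
    fat = generate_fat(ln_svl, fm.sma_slope, fm.correlation, fm.mean_ln_fat_at_mean_svl,
                       sex, cfg.sex_effect, cfg.zero_fat_prob, r_fat)

    d0, d1 = cfg.days_held_range
    days = r_days.integers(d0, d1 + 1, size=cfg.n)

    svl_r = np.round(svl, 1)
    mass_r = np.maximum(np.round(mass), 1.0)
    fat_r = np.round(fat, 4)
    # keep fat strictly below body mass after rounding
    fat_r = np.where(fat_r >= mass_r, mass_r / 2.0, fat_r)

    records = []
    width = len(str(cfg.n))
    for i in range(cfg.n):
        rec = MorphometricRecord(
            id=f"T{i + 1:0{width}d}",
            sex=str(sex[i]),
            svl_cm=float(svl_r[i]),
            mass_g=float(mass_r[i]),
            fat_g=float(fat_r[i]),
            days_held=int(days[i]),
            flags=frozenset(flag_sets[i]),
        )
        rec.validate()
        records.append(rec)
    return records
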