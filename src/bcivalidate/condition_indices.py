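"""Body-condition indices (BCIs) and fat-store measures.

Eleven indices are computed per animal from body mass M (g) and
snout–vent length L (cm):

========================  =====================================================
column                    definition
========================  =====================================================
``M/L``                   ratio index, mass over length
``M/L^2``                 Quetelet index, mass over length squared
``M/L^3``                 Fulton's index, mass over length cubed
``M/prM``                 relative index: mass over SMA-predicted mass
``logM/logL``             log ratio index ln M / ln L
``logM/log(prM)``         log relative index ln M / ln(SMA-predicted mass)
``OLSres``                vertical residuals of OLS ln M ~ ln L
``MAres``                 vertical residuals of MA ln M ~ ln L
``SMAres``                vertical residuals of SMA ln M ~ ln L
``res(M~L^3)``            vertical residuals of SMA M ~ L³
``SMI``                   scaled mass index M (L0/L)^b_SMA
========================  =====================================================

plus three fat-store measures from wet-fat mass F: ``percent_fat``
(100 F/M), ``scaled_fat`` (the SMI scaling applied to F with the
fat-length SMA exponent) and ``residual_fat`` (vertical residuals of
SMA ln F ~ ln L).

Predicted masses are back-transformed as exp(a + b ln L) without a
smearing correction. Under by-size-class grouping, every
regression-derived quantity (predicted mass, residual indices, the SMI
exponent and reference length, scaled/residual fat) is refit within
each size class; pure ratio indices do not depend on the grouping.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import DegenerateInputError, LineFit, SmiParams
from .regression import fit_ma, fit_ols, fit_sma

__all__ = [
    "BCI_COLUMNS",
    "FAT_COLUMNS",
    "ratio_index",
    "log_ratio_index",
    "relative_index",
    "log_relative_index",
    "residual_index",
    "cubed_regression_index",
    "scaled_mass_index",
    "percent_fat",
    "scaled_fat",
    "residual_fat",
    "compute_bci_table",
]

BCI_COLUMNS = (
    "M/L",
    "M/L^2",
    "M/L^3",
    "M/prM",
    "logM/logL",
    "logM/log(prM)",
    "OLSres",
    "MAres",
    "SMAres",
    "res(M~L^3)",
    "SMI",
)

FAT_COLUMNS = ("percent_fat", "scaled_fat", "residual_fat")


def _pos(name, v):
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise DegenerateInputError(f"{name} must be strictly positive")
    return v


def ratio_index(mass_g, svl_cm, power: int) -> np.ndarray:
    """Mass divided by length to a power in {1, 2, 3}; units g·cm⁻ᵖ."""
    if power not in (1, 2, 3):
        raise DegenerateInputError("power must be 1, 2 or 3")
    m = _pos("mass", mass_g)
    l = _pos("svl", svl_cm)
    return m / l**power


def log_ratio_index(mass_g, svl_cm) -> np.ndarray:
    """ln(mass)/ln(length); undefined at L = 1 cm."""
    m = _pos("mass", mass_g)
    l = _pos("svl", svl_cm)
    if np.any(l == 1.0):
        raise DegenerateInputError("log ratio index undefined at svl = 1 cm")
    return np.log(m) / np.log(l)


def relative_index(mass_g, svl_cm, sma_fit_lnln: LineFit) -> np.ndarray:
    """M / prM with prM = exp(a + b ln L) from the ln–ln SMA fit."""
    m = _pos("mass", mass_g)
    l = _pos("svl", svl_cm)
    pr_m = np.exp(sma_fit_lnln.predict(np.log(l)))
    return m / pr_m


def log_relative_index(mass_g, svl_cm, sma_fit_lnln: LineFit) -> np.ndarray:
    """ln M / ln prM; undefined where the predicted mass is exactly 1 g."""
    m = _pos("mass", mass_g)
    l = _pos("svl", svl_cm)
    ln_pr_m = sma_fit_lnln.predict(np.log(l))
    if np.any(ln_pr_m == 0.0):
        raise DegenerateInputError("log relative index undefined where predicted mass = 1 g")
    return np.log(m) / ln_pr_m


def residual_index(mass_g, svl_cm, method: str = "ols") -> np.ndarray:
    """Vertical residuals of the ln M ~ ln L line fit by OLS, MA or SMA."""
    m = _pos("mass", mass_g)
    l = _pos("svl", svl_cm)
    fit = {"ols": fit_ols, "ma": fit_ma, "sma": fit_sma}[method](np.log(l), np.log(m))
    return fit.residuals


def cubed_regression_index(mass_g, svl_cm) -> np.ndarray:
    """Vertical residuals of the SMA fit of raw mass on length cubed."""
    m = _pos("mass", mass_g)
    l = _pos("svl", svl_cm)
    return fit_sma(l**3, m).residuals


def scaled_mass_index(mass_g, svl_cm, params: SmiParams) -> np.ndarray:
    """Scaled mass index M (L0/L)^b_SMA: mass standardized to length L0."""
    params.validate()
    m = _pos("mass", mass_g)
    l = _pos("svl", svl_cm)
    return m * (params.l0 / l) ** params.b_sma


def percent_fat(fat_g, mass_g) -> np.ndarray:
    """Wet-fat mass as a percentage of total body mass."""
    m = _pos("mass", mass_g)
    f = np.asarray(fat_g, dtype=float)
    if np.any(f < 0):
        raise DegenerateInputError("fat mass must be non-negative")
    return 100.0 * f / m


def scaled_fat(fat_g, svl_cm, params: SmiParams) -> np.ndarray:
    """The SMI scaling applied to fat: F (L0/L)^b with b from SMA(ln F ~ ln L)."""
    params.validate()
    f = _pos("fat (zero-fat records must be excluded first)", fat_g)
    l = _pos("svl", svl_cm)
    return f * (params.l0 / l) ** params.b_sma


def residual_fat(fat_g, svl_cm) -> np.ndarray:
    """Vertical residuals of the SMA regression of ln fat on ln length."""
    f = _pos("fat (zero-fat records must be excluded first)", fat_g)
    l = _pos("svl", svl_cm)
    return fit_sma(np.log(l), np.log(f)).residuals


def _group_labels(records, grouping: str) -> np.ndarray:
    if grouping == "all":
        return np.array(["all"] * len(records), dtype=object)
    if grouping == "by_size_class":
        labels = []
        for r in records:
            if r.size_class is None:
                raise DegenerateInputError(
                    f"record {r.id} has no size class; assign classes before grouping"
                )
            labels.append(r.size_class)
        return np.array(labels, dtype=object)
    raise DegenerateInputError("grouping must be 'all' or 'by_size_class'")


def compute_bci_table(records: Sequence, grouping: str = "all") -> pd.DataFrame:
    """All 11 BCIs plus the three fat measures, one row per record.

    Regression-derived columns are fit within each analysis group
    (the whole dataset, or each size class under ``by_size_class``);
    groups with fewer than 3 records are skipped with a warning.
    Records must already be cleaned: ln-based fat measures reject
    zero-fat animals.
    """
    if len(records) == 0:
        raise DegenerateInputError("no records")
    labels = _group_labels(records, grouping)
    ids = np.array([r.id for r in records], dtype=object)
    svl = np.array([r.svl_cm for r in records])
    mass = np.array([r.mass_g for r in records])
    fat = np.array([r.fat_g for r in records])

    out = pd.DataFrame({"id": ids, "group": labels})
    out["M/L"] = ratio_index(mass, svl, 1)
    out["M/L^2"] = ratio_index(mass, svl, 2)
    out["M/L^3"] = ratio_index(mass, svl, 3)
    out["logM/logL"] = log_ratio_index(mass, svl)
    out["percent_fat"] = percent_fat(fat, mass)
    for col in ("M/prM", "logM/log(prM)", "OLSres", "MAres", "SMAres",
                "res(M~L^3)", "SMI", "scaled_fat", "residual_fat"):
        out[col] = np.nan

    for g in pd.unique(labels):
        sel = labels == g
        if sel.sum() < 3:
            warnings.warn(f"group {g!r} has fewer than 3 records; regression "
                          "indices skipped", stacklevel=2)
            continue
        l_g, m_g, f_g = svl[sel], mass[sel], fat[sel]
        sma_lnln = fit_sma(np.log(l_g), np.log(m_g))
        out.loc[sel, "M/prM"] = relative_index(m_g, l_g, sma_lnln)
        out.loc[sel, "logM/log(prM)"] = log_relative_index(m_g, l_g, sma_lnln)
        out.loc[sel, "OLSres"] = residual_index(m_g, l_g, "ols")
        out.loc[sel, "MAres"] = residual_index(m_g, l_g, "ma")
        out.loc[sel, "SMAres"] = residual_index(m_g, l_g, "sma")
        out.loc[sel, "res(M~L^3)"] = cubed_regression_index(m_g, l_g)
        l0 = float(l_g.mean())
        out.loc[sel, "SMI"] = scaled_mass_index(
            m_g, l_g, SmiParams(l0=l0, b_sma=sma_lnln.slope, source_group=str(g))
        )
        sma_fat = fit_sma(np.log(l_g), np.log(f_g))
        out.loc[sel, "scaled_fat"] = scaled_fat(
            f_g, l_g, SmiParams(l0=l0, b_sma=sma_fat.slope, source_group=str(g))
        )
        out.loc[sel, "residual_fat"] = sma_fat.residuals

    return out[["id", "group", *BCI_COLUMNS, *FAT_COLUMNS]]
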