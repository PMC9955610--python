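"""End-to-end orchestration of the condition-index validation analysis.

Stages: read or simulate the record CSV → clean (exclusion rules) →
screen captivity-duration associations → sex comparison → detect size
classes by segmented regression → compute the index table, assumption
battery and validation report under the whole-dataset and by-size-class
groupings → write TSV/JSON outputs and a run log.

The validation logic follows the standard design for BCI studies: each
index is judged by its rank correlation (Kendall τ) and OLS adjusted r²
against the three fat-store measures — percent fat is the designated
reference because it is the least length-entangled — and its
association with SVL flags size bias.
"""

from __future__ import annotations

import dataclasses
import json
import math
import platform
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import __version__
from .condition_indices import BCI_COLUMNS, FAT_COLUMNS, compute_bci_table
from .datatypes import (
    CleaningReport,
    ConfigurationError,
    DegenerateInputError,
    GeneratorConfig,
    ValidationReport,
    frame_to_records,
    records_to_frame,
)
from .diagnostics import assumption_battery, kendall_tau, mann_whitney_u, shapiro_wilk
from .regression import common_slope_test, fit_sma
from .segmentation import assign_size_classes, binned_mass_table, select_breakpoints
from .synthetic_data import generate_dataset

__all__ = [
    "read_records",
    "write_records",
    "write_dataset",
    "clean",
    "days_held_screen",
    "sex_comparison",
    "SexComparisonResult",
    "validate_bcis",
    "RunConfig",
    "run_full",
]

_REQUIRED_COLUMNS = ("id", "sex", "svl_cm", "mass_g", "fat_g")

#: fixed order in which exclusion rules are applied; a record is counted
#: once, under the first rule it matches.
EXCLUSION_ORDER = (
    "incomplete_necropsy",
    "unknown_sex",
    "abnormal",
    "days_held_gt_max",
    "zero_fat",
)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_records(path) -> list:
    """Parse the canonical record CSV into :class:`MorphometricRecord` list.

    Required columns: id, sex, svl_cm, mass_g, fat_g. Optional:
    days_held, flags (semicolon-separated), size_class; any other
    column is preserved as opaque per-record metadata.
    """
    df = pd.read_csv(path, dtype={"id": str, "sex": str, "flags": str})
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ConfigurationError(f"input CSV is missing required column {col!r}")
    for col in ("svl_cm", "mass_g", "fat_g"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ConfigurationError(
                f"non-numeric value in column {col!r} at data row {row + 1}"
            )
        df[col] = pd.to_numeric(df[col])
    if "days_held" not in df.columns:
        df["days_held"] = 0
    if "flags" not in df.columns:
        df["flags"] = ""
    df["flags"] = df["flags"].fillna("")
    records = frame_to_records(df)
    for r in records:
        r.validate()
    return records


def write_records(records: Sequence, path) -> None:
    """Write records as the canonical CSV (flags semicolon-joined)."""
    df = records_to_frame(records)
    df.to_csv(path, index=False)


def write_dataset(records: Sequence, cfg: GeneratorConfig, path) -> None:
    """Write a generated dataset plus a JSON sidecar echoing its config."""
    path = Path(path)
    write_records(records, path)
    path.with_suffix(".config.json").write_text(cfg.to_json())


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


def clean(records: Sequence, max_days: int = 4) -> tuple:
    """Apply the exclusion rules; return (retained records, report).

    Rules, in fixed order: incomplete necropsy, unknown sex, physical
    abnormality, held in captivity strictly more than ``max_days``
    days, wet-fat mass exactly zero (untransformable by ln).
    """
    counts = {rule: 0 for rule in EXCLUSION_ORDER}
    kept = []
    for r in records:
        if "incomplete_necropsy" in r.flags:
            counts["incomplete_necropsy"] += 1
        elif "unknown_sex" in r.flags or r.sex == "unknown":
            counts["unknown_sex"] += 1
        elif "abnormal" in r.flags:
            counts["abnormal"] += 1
        elif r.days_held > max_days:
            counts["days_held_gt_max"] += 1
        elif r.fat_g == 0.0:
            counts["zero_fat"] += 1
        else:
            kept.append(r)
    report = CleaningReport(
        n_input=len(records), n_retained=len(kept), excluded=counts, max_days=max_days
    )
    return kept, report


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------


def days_held_screen(records: Sequence) -> pd.DataFrame:
    """Kendall τ of days held against morphometrics and all 11 BCIs.

    Fourteen tests: SVL, total mass, wet-fat mass, and each index
    (computed under the whole-dataset grouping). A constant days-held
    column renders every row undefined (NaN, flagged).
    """
    days = np.array([r.days_held for r in records], dtype=float)
    table = compute_bci_table(records, grouping="all")
    variables = {
        "svl_cm": np.array([r.svl_cm for r in records], dtype=float),
        "mass_g": np.array([r.mass_g for r in records], dtype=float),
        "fat_g": np.array([r.fat_g for r in records], dtype=float),
    }
    for col in BCI_COLUMNS:
        variables[col] = table[col].to_numpy()
    rows = []
    for name, v in variables.items():
        if np.ptp(days) == 0:
            rows.append({"variable": name, "tau": np.nan, "p_value": np.nan,
                         "n": len(days), "note": "days_held constant; undefined"})
            continue
        t = kendall_tau(days, v)
        rows.append({"variable": name, "tau": t.statistic, "p_value": t.p_value,
                     "n": t.n, "note": ""})
    return pd.DataFrame(rows)


@dataclass
class SexComparisonResult:
    """Sex-difference screens: location tests, slope tests, normality."""

    tests: pd.DataFrame
    normality: pd.DataFrame


def sex_comparison(records: Sequence) -> SexComparisonResult:
    """Compare the sexes on morphometrics and allometric slopes.

    Mann–Whitney U on SVL, mass and fat; likelihood-ratio common-slope
    tests between sexes for SMA(ln M ~ ln L) and SMA(ln F ~ ln L);
    Shapiro–Wilk normality checks of the three morphometrics. Requires
    both sexes present with n ≥ 3 (zero-fat records must be gone).
    """
    females = [r for r in records if r.sex == "female"]
    males = [r for r in records if r.sex == "male"]
    if len(females) < 3 or len(males) < 3:
        raise DegenerateInputError("need both sexes with n >= 3")

    def arrs(rs, attr):
        return np.array([getattr(r, attr) for r in rs], dtype=float)

    rows = []
    for var in ("svl_cm", "mass_g", "fat_g"):
        t = mann_whitney_u(arrs(females, var), arrs(males, var))
        rows.append({"test": "mann_whitney_u", "variable": var,
                     "statistic": t.statistic, "p_value": t.p_value, "n": t.n})
    for var, label in (("mass_g", "SMA(lnM~lnL)"), ("fat_g", "SMA(lnF~lnL)")):
        groups = [
            (np.log(arrs(females, "svl_cm")), np.log(arrs(females, var))),
            (np.log(arrs(males, "svl_cm")), np.log(arrs(males, var))),
        ]
        t = common_slope_test(groups)
        rows.append({"test": f"common_slope:{label}", "variable": var,
                     "statistic": t.lr_stat, "p_value": t.p_value,
                     "n": len(females) + len(males)})
    norm_rows = []
    everyone = females + males
    for var in ("svl_cm", "mass_g", "fat_g"):
        t = shapiro_wilk(arrs(everyone, var))
        norm_rows.append({"test": "shapiro_wilk", "variable": var,
                          "statistic": t.statistic, "p_value": t.p_value, "n": t.n})
    return SexComparisonResult(tests=pd.DataFrame(rows),
                               normality=pd.DataFrame(norm_rows))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_REFERENCES = ("percent_fat", "scaled_fat", "residual_fat", "svl")
_MIN_VALIDATION_N = 10


def _ols_cell(x: np.ndarray, y: np.ndarray) -> tuple:
    """adjusted r² and two-sided slope p of OLS y ~ x."""
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.rsquared_adj), float(res.pvalues[1])


def validate_bcis(records: Sequence, grouping: str = "all") -> ValidationReport:
    """Associate every BCI with the fat-store measures and SVL.

    For each group: Kendall τ (with p) and OLS adjusted r² (with slope
    p) of each of the 11 indices against percent fat, scaled fat,
    residual fat and SVL; the OLS bias block of each fat measure on
    ln SVL; the BCI × BCI τ correlation matrix; and a ranking of the
    indices by adjusted r² against percent fat, each flagged as
    size-biased when its τ against SVL is significant at 0.05.
    Groups with fewer than 10 records are skipped.
    """
    table = compute_bci_table(records, grouping=grouping)
    svl_by_id = {r.id: r.svl_cm for r in records}
    table = table.assign(svl=[svl_by_id[i] for i in table["id"]])
    ln_svl = np.log(table["svl"].to_numpy())

    cells = []
    bias_rows = []
    matrices = {}
    ranking_rows = []
    skipped = []
    for g in pd.unique(table["group"]):
        sub = table[table["group"] == g]
        n = len(sub)
        if n < _MIN_VALIDATION_N:
            warnings.warn(f"group {g!r} has n={n} < {_MIN_VALIDATION_N}; skipped",
                          stacklevel=2)
            skipped.append(g)
            continue
        for bci in BCI_COLUMNS:
            v = sub[bci].to_numpy()
            for ref in _REFERENCES:
                w = sub[ref].to_numpy()
                t = kendall_tau(w, v)
                a_r2, slope_p = _ols_cell(w, v)
                cells.append({"group": g, "bci": bci, "reference": ref,
                              "tau": t.statistic, "tau_p": t.p_value,
                              "adj_r2": a_r2, "slope_p": slope_p, "n": n})
        ln_l_g = np.log(sub["svl"].to_numpy())
        for fm in FAT_COLUMNS:
            res = sm.OLS(sub[fm].to_numpy(), sm.add_constant(ln_l_g)).fit()
            bias_rows.append({"group": g, "fat_measure": fm,
                              "slope": float(res.params[1]),
                              "slope_p": float(res.pvalues[1]),
                              "adj_r2": float(res.rsquared_adj), "n": n})
        k = len(BCI_COLUMNS)
        tau_m = np.eye(k)
        p_m = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                t = kendall_tau(sub[BCI_COLUMNS[i]].to_numpy(),
                                sub[BCI_COLUMNS[j]].to_numpy())
                tau_m[i, j] = tau_m[j, i] = t.statistic
                p_m[i, j] = p_m[j, i] = t.p_value
        matrices[g] = (
            pd.DataFrame(tau_m, index=BCI_COLUMNS, columns=BCI_COLUMNS),
            pd.DataFrame(p_m, index=BCI_COLUMNS, columns=BCI_COLUMNS),
        )

    cells_df = pd.DataFrame(cells)
    for g in pd.unique(cells_df["group"]) if len(cells_df) else []:
        sub = cells_df[cells_df["group"] == g]
        perf = sub[sub["reference"] == "percent_fat"].set_index("bci")["adj_r2"]
        svl_p = sub[sub["reference"] == "svl"].set_index("bci")["tau_p"]
        order = perf.sort_values(ascending=False)
        for rank, (bci, r2) in enumerate(order.items(), start=1):
            ranking_rows.append({"group": g, "rank": rank, "bci": bci,
                                 "adj_r2_percent_fat": r2,
                                 "size_biased": bool(svl_p[bci] < 0.05)})
    return ValidationReport(
        grouping=grouping,
        cells=cells_df,
        fat_measure_bias=pd.DataFrame(bias_rows),
        bci_correlation=matrices,
        ranking=pd.DataFrame(ranking_rows),
        skipped_groups=tuple(skipped),
    )


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Provide either ``input_csv`` or a ``generator`` config (the
    generator's own seed is used for simulation).
    """

    input_csv: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    out_dir: str = "bcivalidate_out"
    alpha: float = 0.05
    max_days: int = 4
    k_max: int = 10
    family: str = "gaussian_identity"
    group_mode: str = "both"  # all | by-size-class | both

    def validate(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise ConfigurationError("provide exactly one of input_csv or generator")
        if self.group_mode not in ("all", "by-size-class", "both"):
            raise ConfigurationError("group_mode must be all, by-size-class or both")
        if self.k_max < 0:
            raise ConfigurationError("k_max must be >= 0")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_full(config: RunConfig) -> dict:
    """Execute the whole analysis; write outputs; return the bundle.

    The returned dict holds every intermediate product (records,
    cleaning report, screens, segmented model, index tables,
    assumption batteries, validation reports) keyed by stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    notes: list = []

    def stage(name, fn):
        try:
            bundle[name] = fn()
            return bundle[name]
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc

    def load():
        if config.input_csv is not None:
            return read_records(config.input_csv)
        records = generate_dataset(config.generator)
        write_dataset(records, config.generator, out / "simulated.csv")
        return records

    records = stage("load", load)

    def do_clean():
        kept, report = clean(records, max_days=config.max_days)
        (out / "cleaning_report.json").write_text(
            json.dumps(dataclasses.asdict(report), indent=2)
        )
        return kept, report

    cleaned, _ = stage("clean", do_clean)

    def do_sex():
        res = sex_comparison(cleaned)
        _write_tsv(res.tests, out / "sex_comparison.tsv")
        _write_tsv(res.normality, out / "sex_normality.tsv")
        return res

    stage("sex_comparison", do_sex)

    def do_days():
        df = days_held_screen(cleaned)
        _write_tsv(df, out / "days_held_screen.tsv")
        return df

    stage("days_held_screen", do_days)

    def do_segment():
        svl = np.array([r.svl_cm for r in cleaned])
        mass = np.array([r.mass_g for r in cleaned])
        model = select_breakpoints(svl, mass, k_max=config.k_max, family=config.family)
        (out / "breakpoints.json").write_text(json.dumps(model.to_dict(), indent=2))
        basic = fit_sma(np.log(svl), np.log(mass))
        lo = math.floor(svl.min() / 2.0) * 2.0
        table = binned_mass_table(cleaned, bin_width=2.0, svl_range=(lo, svl.max()))
        _write_tsv(table, out / "binned_means.tsv")
        try:
            from .segmentation import compare_models_plot
            import matplotlib.pyplot as plt

            _, ax = compare_models_plot(cleaned, basic, model, bin_width=2.0,
                                        svl_range=(lo, svl.max()))
            ax.figure.savefig(out / "model_comparison.png", dpi=120)
            plt.close(ax.figure)
        except Exception as exc:  # plotting must never sink the analysis
            notes.append(f"comparison plot skipped: {exc}")
        return model

    model = stage("size_classes", do_segment)

    groupings = []
    if config.group_mode in ("all", "both"):
        groupings.append("all")
    if config.group_mode in ("by-size-class", "both"):
        if model.k == 0:
            notes.append("segmented model selected k=0; by_size_class analysis skipped")
        else:
            groupings.append("by_size_class")

    analyzed = assign_size_classes(cleaned, model.psi) if model.k > 0 else cleaned
    bundle["records"] = analyzed

    for grouping in groupings:
        suffix = grouping
        stage(f"bci_table:{grouping}", lambda g=grouping: compute_bci_table(analyzed, g))
        _write_tsv(bundle[f"bci_table:{grouping}"], out / f"bci_table_{suffix}.tsv")
        stage(f"assumptions:{grouping}",
              lambda g=grouping: assumption_battery(analyzed, g, alpha=config.alpha))
        _write_tsv(bundle[f"assumptions:{grouping}"], out / f"assumptions_{suffix}.tsv")
        stage(f"validation:{grouping}", lambda g=grouping: validate_bcis(analyzed, g))
        report = bundle[f"validation:{grouping}"]
        _write_tsv(report.cells, out / f"validation_cells_{suffix}.tsv")
        _write_tsv(report.fat_measure_bias, out / f"fat_measure_bias_{suffix}.tsv")
        _write_tsv(report.ranking, out / f"ranking_{suffix}.tsv")
        for g, (tau_m, _) in report.bci_correlation.items():
            tau_m.to_csv(out / f"bci_correlation_{suffix}_{g}.tsv", sep="\t",
                         float_format="%.10g")

    log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": None if config.generator is None else config.generator.seed,
        "alpha": config.alpha,
        "max_days": config.max_days,
        "k_max": config.k_max,
        "family": config.family,
        "group_mode": config.group_mode,
        "selected_breakpoints": [float(p) for p in model.psi],
        "notes": notes,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    bundle["run_log"] = log
    return bundle
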