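"""Cohort assembly and orchestration: eligibility, summaries, full pipeline.

Eligibility mirrors the study design: unilateral triple-negative tumors
without prior cancer, metastasis, pre-PET surgery, or sub-threshold uptake
(SUVmax < 2.5). Filters apply in that fixed order and each excluded record is
attributed to the first criterion it fails, which makes the flow counts
deterministic and conserving (screened = enrolled + sum of exclusions).

``run_full_pipeline`` drives the whole analysis on synthetic data: per-patient
lesion volumes → SUV conversion → SUV2.5 segmentation → feature extraction →
scanner comparison (Kruskal–Wallis) and optional harmonization with a gPCA
report → log transform of non-Gaussian features → univariate Cox on the 11
features plus clinical factors → backward-AIC multivariate on the univariately
significant ones → 24-month ROC/Youden thresholds for MTV, TLG and entropy →
dichotomized Kaplan–Meier with log-rank tests. All tables, curves and the
exact seed/config are written to the output directory.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import harmonization as hz
from . import simulate as sim
from . import survival as sv
from .features import FEATURE_COLUMNS, extract_features
from .imaging import ValidationError, compute_suv

__all__ = [
    "FlowCounts",
    "PipelineStageError",
    "ELIGIBILITY_ORDER",
    "apply_eligibility",
    "summarize_cohort",
    "compare_features_by_scanner",
    "log_transform_features",
    "feature_factor_association",
    "run_full_pipeline",
    "DEFAULT_CONFIG",
]

logger = logging.getLogger("tnbcpet")

#: Exclusion criteria in attribution order: (reason, predicate on a row).
ELIGIBILITY_ORDER = (
    ("receptor_positive", lambda r: bool(r["er_positive"] or r["pr_positive"] or r["her2_positive"])),
    ("prior_cancer", lambda r: bool(r["prior_cancer"])),
    ("metastatic", lambda r: bool(r["metastatic"])),
    ("surgery_before_pet", lambda r: bool(r["surgery_before_pet"])),
    ("low_uptake", lambda r: float(r["suv_max"]) < 2.5),
)

_ELIGIBILITY_BOOL_COLS = (
    "er_positive",
    "pr_positive",
    "her2_positive",
    "prior_cancer",
    "metastatic",
    "surgery_before_pet",
)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass(frozen=True)
class FlowCounts:
    """Screening flow: conservation screened = enrolled + sum(excluded)."""

    screened: int
    excluded: dict[str, int]
    enrolled: int

    def __post_init__(self) -> None:
        if self.screened != self.enrolled + sum(self.excluded.values()):
            raise ValidationError("flow counts do not conserve")


def apply_eligibility(records: pd.DataFrame) -> tuple[pd.DataFrame, FlowCounts]:
    """Filter screened records; each exclusion attributed to its first reason."""
    for col in _ELIGIBILITY_BOOL_COLS:
        if col not in records.columns:
            raise ValidationError(f"records lack eligibility column {col!r}")
        bad = ~records[col].isin([True, False])
        if bad.any():
            raise ValidationError(f"unknown value in eligibility column {col!r}")
    if records["suv_max"].isna().any():
        raise ValidationError("unknown value in eligibility column 'suv_max'")

    excluded = {reason: 0 for reason, _ in ELIGIBILITY_ORDER}
    keep = np.ones(len(records), dtype=bool)
    for i, (_, row) in enumerate(records.iterrows()):
        for reason, fails in ELIGIBILITY_ORDER:
            if fails(row):
                excluded[reason] += 1
                keep[i] = False
                break
    enrolled = records.loc[keep].copy()
    counts = FlowCounts(screened=len(records), excluded=excluded, enrolled=int(keep.sum()))
    return enrolled, counts


def summarize_cohort(
    records: pd.DataFrame,
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Descriptive tables: count/percent per category level (1 decimal, over
    the non-missing denominator) and mean/SD/median/min/max/IQR per continuous
    variable."""
    if categorical is None:
        categorical = [
            c
            for c in ("scanner", "n_pet", "t_stage", "inflammatory", "grade", "multifocal",
                      "dfs_event", "os_event", "relapse_type")
            if c in records.columns
        ]
    if continuous is None:
        continuous = [
            c
            for c in ("age", "suv_max", "suv_mean", "suv_peak", "mtv_cm3", "tlg",
                      "homogeneity", "entropy", "sre", "lre", "lgze", "hgze")
            if c in records.columns
        ]
    cat_rows = []
    for var in categorical:
        col = records[var].dropna()
        denom = len(col)
        counts = col.value_counts(sort=False)
        for level in counts.index:
            n = int(counts[level])
            cat_rows.append(
                {
                    "variable": var,
                    "level": level,
                    "count": n,
                    "percent": round(100.0 * n / denom, 1) if denom else 0.0,
                    "denominator": denom,
                }
            )
    cont_rows = []
    for var in continuous:
        col = records[var].dropna().astype(float)
        if col.empty:
            continue
        q1, q3 = col.quantile([0.25, 0.75])
        cont_rows.append(
            {
                "variable": var,
                "mean": col.mean(),
                "sd": col.std(ddof=1),
                "median": col.median(),
                "min": col.min(),
                "max": col.max(),
                "iqr_low": q1,
                "iqr_high": q3,
                "n": len(col),
            }
        )
    return {
        "categorical": pd.DataFrame(cat_rows),
        "continuous": pd.DataFrame(cont_rows),
    }


def compare_features_by_scanner(
    table: pd.DataFrame, batch_col: str = "scanner", features: list[str] | None = None
) -> pd.DataFrame:
    """Kruskal–Wallis test of each feature across scanner batches."""
    if features is None:
        features = hz.feature_columns(table, batch_col)
    groups = list(table.groupby(batch_col, sort=False))
    if len(groups) < 2:
        raise ValidationError("need at least two scanner batches to compare")
    rows = []
    for feat in features:
        samples = [g[feat].to_numpy(dtype=float) for _, g in groups]
        h, p = stats.kruskal(*samples)
        rows.append({"feature": feat, "statistic": float(h), "p_value": float(p)})
    return pd.DataFrame(rows)


def log_transform_features(
    table: pd.DataFrame,
    features: list[str] | None = None,
    alpha: float = 0.05,
    batch_col: str = "scanner",
) -> tuple[pd.DataFrame, list[str]]:
    """Natural-log transform features that fail Shapiro–Wilk normality at alpha.

    Returns the transformed table and the list of transformed columns.
    Non-positive values in a feature selected for log are an error.
    """
    if features is None:
        features = hz.feature_columns(table, batch_col)
    out = table.copy()
    transformed = []
    for feat in features:
        vals = out[feat].to_numpy(dtype=float)
        _, p = stats.shapiro(vals)
        if p < alpha:
            if np.any(vals <= 0):
                raise ValidationError(f"feature {feat!r} has non-positive values; cannot log")
            out[feat] = np.log(vals)
            transformed.append(feat)
    return out, transformed


def feature_factor_association(feature, factor) -> tuple[float, float]:
    """Wald test of a feature against a binary factor via simple linear
    regression; returns (slope, p). The slope sign is the direction of the
    association."""
    import statsmodels.api as smapi

    y = np.asarray(feature, dtype=float)
    x = np.asarray(factor, dtype=float)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValidationError("factor must be binary 0/1")
    X = smapi.add_constant(x)
    fit = smapi.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_patients": 111,
    "suv_threshold": 2.5,
    "horizon_months": 24.0,
    "harmonize": "none",  # none | standardize | rbe | combat
    "gpca_permutations": 500,
    "psf_fwhm_mm": 6.0,
    "spacing_mm": [3.0, 3.0, 3.0],
    "threshold_features": ["mtv_cm3", "tlg", "entropy"],
    "clinical_covariates": ["n_pet", "t34", "inflammatory"],
    "scanner_shift": 0.0,  # additive batch shift (in pooled SDs) injected on DIQ5
    "make_plots": True,
}

_HARMONIZERS = {
    "standardize": hz.standardize,
    "rbe": hz.remove_batch_effect,
    "combat": hz.combat,
}


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as err:  # noqa: BLE001 — re-raise with stage context
            raise PipelineStageError(f"stage {name!r} failed: {err}") from err
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        return result

    return wrap


def _prune_collinear(table: pd.DataFrame, cols: list[str], tol: float = 1e-8) -> list[str]:
    """Keep a maximal prefix-greedy subset of columns with full column rank.

    Columns are standardized and added in order; one that is (numerically) a
    linear combination of those already kept is dropped.
    """
    kept: list[str] = []
    basis: list[np.ndarray] = []
    for col in cols:
        v = table[col].to_numpy(dtype=float)
        v = v - v.mean()
        norm = np.linalg.norm(v)
        if norm == 0:
            continue
        v = v / norm
        r = v.copy()
        for b in basis:
            r -= (r @ b) * b
        if np.linalg.norm(r) > tol:
            basis.append(r / np.linalg.norm(r))
            kept.append(col)
    return kept


def _simulate_and_extract(cfg: dict, rng: np.random.Generator) -> pd.DataFrame:
    """Generate per-patient lesion volumes and extract the 11 features.

    Mirrors the study's enrolment: a simulated patient whose tumor is not
    measurable (below the SUV threshold after blurring, or a VOI too small
    for texture matrices) is replaced by the next screened candidate.
    """
    n = cfg["n_patients"]
    scanners = rng.choice(["DST", "D690", "DIQ5"], size=n, p=[45 / 111, 49 / 111, 17 / 111])
    rows = []
    for i in range(n):
        pid = f"P{i:04d}"
        for _attempt in range(50):
            severity = float(rng.normal())
            vol, roi = sim.make_patient_volume(
                severity=severity,
                seed=int(rng.integers(2**31 - 1)),
                spacing=tuple(cfg["spacing_mm"]),
                psf_fwhm_mm=cfg["psf_fwhm_mm"],
                scanner=str(scanners[i]),
            )
            suv = compute_suv(vol)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # tiny-VOI texture warning
                try:
                    fv = extract_features(suv, roi=roi, threshold=cfg["suv_threshold"])
                except ValidationError:
                    continue  # no hypermetabolic lesion: screen the next candidate
            if any(np.isnan(v) for v in fv.as_dict().values() if isinstance(v, float)):
                continue
            break
        else:
            raise PipelineStageError(f"could not simulate a measurable tumor for {pid}")
        row = {"patient_id": pid, **fv.as_dict()}
        row["severity"] = severity
        rows.append(row)
    return pd.DataFrame(rows)[FEATURE_COLUMNS + ["severity"]]


def run_full_pipeline(config: dict | None = None, out_dir: str | Path = "pipeline_out") -> dict:
    """Run the complete synthetic study; returns the report bundle.

    Stages: simulate volumes → extract features → attach outcomes → scanner
    comparison → optional harmonization (+ gPCA) → log transform → univariate
    Cox → backward-AIC multivariate → horizon ROC/Youden → dichotomized
    KM/log-rank. Deterministic given the config seed.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg["seed"])
    manifest: dict = {"config": cfg, "outputs": {}}

    def save_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        manifest["outputs"][name] = str(path)

    # 1. simulate + extract
    features = _stage("simulate_extract")(_simulate_and_extract, cfg, rng)

    # optional injected scanner batch shift (to exercise harmonization)
    if cfg["scanner_shift"]:
        feat_cols = hz.feature_columns(features.drop(columns=["patient_id"]), "scanner")
        shift_rows = features["scanner"] == "DIQ5"
        pooled_sd = features[feat_cols].std(ddof=1)
        features.loc[shift_rows, feat_cols] += cfg["scanner_shift"] * pooled_sd

    # 2. outcomes from extracted features
    nodal = (features["severity"] + rng.normal(0, 0.5, size=len(features)) > 0.1).astype(int)
    features["n_pet"] = nodal
    cohort_spec = sim.CohortSpec(n=max(len(features), 10), seed=int(rng.integers(2**31 - 1)))
    cohort = _stage("outcomes")(sim.make_cohort, cohort_spec, features)
    cohort["t34"] = (cohort["mtv_cm3"] > np.quantile(cohort["mtv_cm3"], 0.718)).astype(int)
    cohort["inflammatory"] = (
        (cohort["severity"] + rng.normal(0, 0.8, size=len(cohort))) > 1.6
    ).astype(int)
    save_csv(cohort.drop(columns=["severity"]), "cohort_features.csv")

    # 3. scanner comparison on raw features
    kw = _stage("scanner_comparison")(compare_features_by_scanner, cohort)
    save_csv(kw, "kruskal_wallis_by_scanner.csv")

    # 4. gPCA diagnostic and optional harmonization
    feat_cols = [c for c in FEATURE_COLUMNS if c not in ("patient_id", "scanner")]
    gtable = cohort[["scanner"] + feat_cols]
    gpca = _stage("gpca")(
        hz.gpca_delta, gtable, "scanner", cfg["gpca_permutations"], int(rng.integers(2**31 - 1))
    )
    (out / "gpca_report.json").write_text(
        json.dumps(
            {
                "delta": gpca.delta,
                "p_value": gpca.p_value,
                "n_permutations": gpca.n_permutations,
                "seed": cfg["seed"],
                "harmonize": cfg["harmonize"],
            },
            indent=2,
        )
    )
    manifest["outputs"]["gpca_report.json"] = str(out / "gpca_report.json")

    # 5. log transform for regression modelling, then (optional) harmonization
    # on the modelling scale — ComBat assumes roughly Gaussian features, which
    # holds for the log-transformed table, and keeps adjusted values loggable.
    model_table, transformed = _stage("log_transform")(
        log_transform_features, cohort, feat_cols
    )
    manifest["log_transformed_features"] = transformed
    if cfg["harmonize"] != "none":
        harmonizer = _HARMONIZERS[cfg["harmonize"]]
        harmonized = _stage("harmonize")(harmonizer, model_table[["scanner"] + feat_cols])
        model_table[feat_cols] = harmonized[feat_cols]
        save_csv(model_table.drop(columns=["severity"]), "cohort_features_harmonized.csv")

    # 6. univariate Cox (11 features + clinical factors), per endpoint
    covariate_pool = feat_cols + list(cfg["clinical_covariates"])
    cox_tables: dict[str, dict] = {}
    significant: dict[str, list[str]] = {}
    for endpoint, (tcol, ecol) in {
        "dfs": ("dfs_months", "dfs_event"),
        "os": ("os_months", "os_event"),
    }.items():
        uni = {}
        for cov in covariate_pool:
            try:
                fit = sv.cox_fit(model_table, tcol, ecol, [cov])
            except sv.DiagnosticError as err:
                uni[cov] = {"error": str(err)}
                continue
            uni[cov] = {
                "hr": fit.hr[cov],
                "ci95": list(fit.ci95[cov]),
                "p": fit.p[cov],
            }
        sig = [c for c, r in uni.items() if "p" in r and r["p"] < sv.ALPHA]
        significant[endpoint] = sig
        multi = None
        if sig:
            # TLG is the product of SUVmean and MTV, so the log-transformed
            # trio is exactly collinear; prune candidates that add no rank.
            independent = _prune_collinear(model_table, sig)
            manifest[f"collinear_dropped_{endpoint}"] = [c for c in sig if c not in independent]
            fit, retained = _stage(f"backward_aic_{endpoint}")(
                sv.backward_aic, model_table, tcol, ecol, independent
            )
            multi = {
                "retained": retained,
                "hr": fit.hr if fit else {},
                "ci95": {k: list(v) for k, v in fit.ci95.items()} if fit else {},
                "p": fit.p if fit else {},
                "aic": fit.aic if fit else None,
            }
        cox_tables[endpoint] = {"univariate": uni, "multivariate": multi}
    (out / "cox_models.json").write_text(json.dumps(cox_tables, indent=2))
    manifest["outputs"]["cox_models.json"] = str(out / "cox_models.json")

    # 7. horizon ROC / Youden thresholds on the raw-scale features, then KM
    threshold_rows = []
    km_rows = []
    for endpoint, (tcol, ecol) in {
        "dfs": ("dfs_months", "dfs_event"),
        "os": ("os_months", "os_event"),
    }.items():
        for feat in cfg["threshold_features"]:
            roc = sv.roc_at_horizon(
                cohort[tcol], cohort[ecol], cohort[feat], horizon=cfg["horizon_months"]
            )
            thr = sv.youden_threshold(roc)
            cmp_res = sv.compare_at_threshold(cohort[tcol], cohort[ecol], cohort[feat], thr.cutoff)
            threshold_rows.append(
                {
                    "endpoint": endpoint,
                    "feature": feat,
                    "cutoff": thr.cutoff,
                    "sensitivity": thr.sensitivity,
                    "specificity": thr.specificity,
                    "youden_j": thr.youden_j,
                    "auc": roc.auc,
                    "n_positive": roc.n_positive,
                    "n_negative": roc.n_negative,
                    "n_excluded": roc.n_excluded,
                    "logrank_p": cmp_res.p_value,
                    "n_high": cmp_res.n_high,
                    "n_low": cmp_res.n_low,
                }
            )
            for arm, km in (("high", cmp_res.km_high), ("low", cmp_res.km_low)):
                for t, s in zip(km.times, km.survival):
                    km_rows.append(
                        {"endpoint": endpoint, "feature": feat, "group": arm,
                         "time_months": t, "survival": s}
                    )
    thresholds = pd.DataFrame(threshold_rows)
    save_csv(thresholds, "youden_thresholds.csv")
    km_df = pd.DataFrame(km_rows)
    save_csv(km_df, "km_curves.csv")

    if cfg["make_plots"]:
        _plot_km(km_df, out, manifest)

    manifest["significant_univariate"] = significant
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "features": cohort,
        "flow": None,
        "kruskal_wallis": kw,
        "gpca": gpca,
        "cox": cox_tables,
        "thresholds": thresholds,
        "manifest": manifest,
        "out_dir": out,
    }


def _plot_km(km_df: pd.DataFrame, out: Path, manifest: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for (endpoint, feat), sub in km_df.groupby(["endpoint", "feature"]):
        fig, ax = plt.subplots(figsize=(5, 4))
        for arm, arm_df in sub.groupby("group"):
            ax.step(arm_df["time_months"], arm_df["survival"], where="post", label=arm)
        ax.set_xlabel("months")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.set_title(f"{endpoint.upper()} by {feat}")
        ax.legend()
        name = f"km_{endpoint}_{feat}.png"
        fig.savefig(out / name, dpi=100)
        plt.close(fig)
        manifest["outputs"][name] = str(out / name)
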