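"""Statistical layer: mixed-effects regression of median A/V-ratio on mean
ICP, slope comparison across the 15 mmHg split, group-mean comparison at the
20 mmHg boundary, ROC/AUC, and sensitivity/specificity at a cutoff.

Observations are repeated within patients, so every regression carries a
patient random intercept (fitted by REML through statsmodels MixedLM) with
Wald 95% intervals.  The ROC is the empirical curve with the strict
``median_av < threshold`` positivity convention used for the clinical
cut-off; its AUC therefore equals the Wilcoxon-Mann-Whitney statistic
(ties counted half).  Confidence intervals for sensitivity and specificity
are exact Clopper-Pearson at the observation level; the AUC interval comes
from a seeded, class-stratified bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .errors import ConvergenceError, SchemaError

__all__ = [
    "REQUIRED_COLUMNS", "validate_observation_table", "MixedModelFit",
    "SlopeComparison", "GroupMeansResult", "ROCResult", "SensSpecResult",
    "fit_mixed_model", "compare_slopes", "compare_group_means",
    "roc_analysis", "sens_spec_at",
]

REQUIRED_COLUMNS = ("patient_id", "mean_icp_mmHg", "median_av")
_COLUMN_ALIASES = {"mean_icp": "mean_icp_mmHg", "icp": "mean_icp_mmHg", "av": "median_av"}


def validate_observation_table(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize and validate an observation table.

    Requires ``patient_id``, ``mean_icp_mmHg`` (alias ``mean_icp``) and
    ``median_av`` columns; ``epoch`` is optional.  Raises
    :class:`SchemaError` naming the offending column or row.
    """
    df = table.rename(columns=_COLUMN_ALIASES).copy()
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"observation table is missing column {col!r}")
    for col in ("mean_icp_mmHg", "median_av"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals)
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise SchemaError(f"column {col!r} has a non-finite value at row {row}")
        df[col] = vals.astype(float)
    if (df["median_av"] <= 0).any():
        row = int(np.argmax((df["median_av"] <= 0).to_numpy()))
        raise SchemaError(f"column 'median_av' must be > 0 (violated at row {row})")
    if "epoch" not in df.columns:
        df["epoch"] = df.groupby("patient_id").cumcount()
    return df


@dataclass(frozen=True)
class MixedModelFit:
    slope: float
    intercept: float
    sd_random_intercept: float
    sd_residual: float
    slope_se: float
    slope_ci95: tuple[float, float]
    p_slope: float
    n_obs: int
    n_patients: int
    converged: bool


@dataclass(frozen=True)
class SlopeComparison:
    delta_slope: float
    p_interaction: float
    slope_low: float
    slope_high: float
    n_low: int
    n_high: int


@dataclass(frozen=True)
class GroupMeansResult:
    mean_low_group: float      # boundary-exclusive stratum (<= boundary - 1)
    mean_high_group: float     # >= boundary stratum
    ci_low: tuple[float, float]
    ci_high: tuple[float, float]
    p: float
    n_low: int
    n_high: int


@dataclass(frozen=True)
class SensSpecResult:
    cutoff: float
    sensitivity: float
    specificity: float
    sensitivity_ci95: tuple[float, float]
    specificity_ci95: tuple[float, float]
    lr_positive: float
    n_diseased: int
    n_healthy: int


@dataclass(frozen=True)
class ROCResult:
    auc: float
    auc_ci95: tuple[float, float]
    curve: list[tuple[float, float, float]]  # (threshold, sensitivity, specificity)
    chosen_cutoff: float
    at_cutoff: SensSpecResult
    bootstrap_seed: int
    n_bootstrap: int = field(default=2000)


def _fit_mixedlm(formula: str, df: pd.DataFrame):
    """REML fit with an optimizer fallback chain; boundary fits (random-
    intercept variance near 0) often need a derivative-free restart."""
    y = df["median_av"].to_numpy()
    scale = float(np.std(y)) + 1e-12

    def sane(fit) -> bool:
        # optimizers occasionally report convergence at a degenerate point
        # with absurd fixed effects; reject fits whose marginal predictions
        # sit far outside the data
        resid = y - fit.model.exog @ np.asarray(fit.fe_params)
        return bool(np.all(np.isfinite(resid)) and np.max(np.abs(resid)) <= 10 * scale)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["patient_id"])
        fit = None
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:
                cand = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if cand.converged and sane(cand):
                fit = cand
                break
    if fit is None:
        raise ConvergenceError("mixed-effects fit did not converge; "
                               "no estimates reported")
    return fit


def fit_mixed_model(table: pd.DataFrame, icp_filter=None) -> MixedModelFit:
    """REML fit of ``median_av ~ mean_icp`` with patient random intercepts.

    ``icp_filter`` optionally restricts the rows (a callable on the mean-ICP
    array, e.g. ``lambda icp: icp < 15``).  Needs at least two patients.
    """
    df = validate_observation_table(table)
    if icp_filter is not None:
        df = df[np.asarray(icp_filter(df["mean_icp_mmHg"].to_numpy()))]
    if df.empty:
        raise SchemaError("no rows left after applying the ICP filter")
    n_patients = df["patient_id"].nunique()
    if n_patients < 2:
        raise SchemaError("random intercepts need at least 2 patients "
                          f"(got {n_patients})")
    fit = _fit_mixedlm("median_av ~ mean_icp_mmHg", df)
    slope = float(fit.params["mean_icp_mmHg"])
    se = float(fit.bse["mean_icp_mmHg"])
    z = sps.norm.ppf(0.975)
    return MixedModelFit(
        slope=slope,
        intercept=float(fit.params["Intercept"]),
        sd_random_intercept=float(np.sqrt(max(fit.cov_re.values[0, 0], 0.0))),
        sd_residual=float(np.sqrt(max(fit.scale, 0.0))),
        slope_se=se,
        slope_ci95=(slope - z * se, slope + z * se),
        p_slope=float(fit.pvalues["mean_icp_mmHg"]),
        n_obs=len(df),
        n_patients=int(n_patients),
        converged=bool(fit.converged),
    )


def compare_slopes(table: pd.DataFrame, split_mmHg: float = 15.0) -> SlopeComparison:
    """One joint mixed model with group, centred ICP and their interaction;
    the slope difference is the interaction coefficient (Wald test)."""
    df = validate_observation_table(table)
    df["icp_c"] = df["mean_icp_mmHg"] - split_mmHg
    df["high"] = (df["mean_icp_mmHg"] >= split_mmHg).astype(int)
    n_low = int((df["high"] == 0).sum())
    n_high = int((df["high"] == 1).sum())
    if n_low == 0 or n_high == 0:
        raise SchemaError(f"both sides of the {split_mmHg:g} mmHg split must "
                          f"be populated (low={n_low}, high={n_high})")
    fit = _fit_mixedlm("median_av ~ icp_c * high", df)
    delta = float(fit.params["icp_c:high"])
    slope_low = float(fit.params["icp_c"])
    return SlopeComparison(
        delta_slope=delta,
        p_interaction=float(fit.pvalues["icp_c:high"]),
        slope_low=slope_low,
        slope_high=slope_low + delta,
        n_low=n_low,
        n_high=n_high,
    )


def compare_group_means(table: pd.DataFrame, boundary_mmHg: float = 20.0
                        ) -> GroupMeansResult:
    """Marginal mean median-A/V for ICP >= boundary vs below, from a mixed
    model with a binary indicator and patient random intercepts."""
    df = validate_observation_table(table)
    df["high20"] = (df["mean_icp_mmHg"] >= boundary_mmHg).astype(int)
    n_low = int((df["high20"] == 0).sum())
    n_high = int((df["high20"] == 1).sum())
    if n_low == 0 or n_high == 0:
        raise SchemaError(f"both groups at the {boundary_mmHg:g} mmHg boundary "
                          f"must be non-empty (low={n_low}, high={n_high})")
    fit = _fit_mixedlm("median_av ~ high20", df)
    b0 = float(fit.params["Intercept"])
    b1 = float(fit.params["high20"])
    cov = fit.cov_params().loc[["Intercept", "high20"], ["Intercept", "high20"]].to_numpy()
    se_low = float(np.sqrt(max(cov[0, 0], 0.0)))
    se_high = float(np.sqrt(max(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1], 0.0)))
    z = sps.norm.ppf(0.975)
    p = float(fit.pvalues["high20"])
    if np.isnan(p) and abs(b1) < 1e-12:
        p = 1.0  # exactly identical groups: zero difference, zero variance
    return GroupMeansResult(
        mean_low_group=b0,
        mean_high_group=b0 + b1,
        ci_low=(b0 - z * se_low, b0 + z * se_low),
        ci_high=(b0 + b1 - z * se_high, b0 + b1 + z * se_high),
        p=p,
        n_low=n_low,
        n_high=n_high,
    )


def _classes(df: pd.DataFrame, boundary: float) -> tuple[np.ndarray, np.ndarray]:
    diseased = df.loc[df["mean_icp_mmHg"] >= boundary, "median_av"].to_numpy()
    healthy = df.loc[df["mean_icp_mmHg"] < boundary, "median_av"].to_numpy()
    if len(diseased) == 0 or len(healthy) == 0:
        raise SchemaError("ROC / sensitivity analysis needs both classes "
                          f"(diseased={len(diseased)}, healthy={len(healthy)})")
    return diseased, healthy


def _empirical_curve(diseased: np.ndarray, healthy: np.ndarray
                     ) -> list[tuple[float, float, float]]:
    """Step ROC with strict positivity (score < threshold is positive):
    (threshold, sensitivity, specificity) over all distinct thresholds."""
    thresholds = np.concatenate([[-np.inf], np.unique(np.concatenate([diseased, healthy])),
                                 [np.inf]])
    curve = []
    for t in thresholds:
        sens = float(np.mean(diseased < t))
        spec = float(np.mean(healthy >= t))
        curve.append((float(t), sens, spec))
    return curve


def _auc_from_curve(curve) -> float:
    fpr = np.array([1.0 - spec for _, _, spec in curve])
    tpr = np.array([sens for _, sens, _ in curve])
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def _fast_auc(diseased: np.ndarray, healthy: np.ndarray) -> float:
    """Rank-based Wilcoxon-Mann-Whitney AUC, P(diseased < healthy) with ties
    counted half; identical to the trapezoid over the strict-threshold step
    ROC, but O(n log n) for the bootstrap loop."""
    scores = np.concatenate([diseased, healthy])
    ranks = sps.rankdata(scores)
    n_d, n_h = len(diseased), len(healthy)
    r_h = ranks[n_d:].sum()
    return float((r_h - n_h * (n_h + 1) / 2.0) / (n_d * n_h))


def sens_spec_at(table: pd.DataFrame, cutoff: float = 0.8015,
                 boundary_mmHg: float = 20.0) -> SensSpecResult:
    """Sensitivity/specificity of ``median_av < cutoff`` for detecting
    ICP >= boundary, with exact Clopper-Pearson 95% intervals and LR+."""
    df = validate_observation_table(table)
    diseased, healthy = _classes(df, boundary_mmHg)
    tp = int(np.sum(diseased < cutoff))
    tn = int(np.sum(healthy >= cutoff))
    sens = tp / len(diseased)
    spec = tn / len(healthy)
    sens_ci = proportion_confint(tp, len(diseased), alpha=0.05, method="beta")
    spec_ci = proportion_confint(tn, len(healthy), alpha=0.05, method="beta")
    if spec < 1.0:
        lr = sens / (1.0 - spec)
    else:  # no false positives: LR+ diverges, or is undefined with sens 0
        lr = float("inf") if sens > 0 else float("nan")
    return SensSpecResult(
        cutoff=float(cutoff), sensitivity=float(sens), specificity=float(spec),
        sensitivity_ci95=(float(sens_ci[0]), float(sens_ci[1])),
        specificity_ci95=(float(spec_ci[0]), float(spec_ci[1])),
        lr_positive=float(lr), n_diseased=len(diseased), n_healthy=len(healthy),
    )


def roc_analysis(table: pd.DataFrame, boundary_mmHg: float = 20.0,
                 cutoff: float = 0.8015, n_bootstrap: int = 2000,
                 seed: int = 0) -> ROCResult:
    """Empirical ROC of median A/V against ICP >= boundary (lower A/V is
    test-positive), trapezoidal AUC, and a stratified bootstrap AUC interval."""
    df = validate_observation_table(table)
    diseased, healthy = _classes(df, boundary_mmHg)
    curve = _empirical_curve(diseased, healthy)
    auc = _auc_from_curve(curve)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        d = rng.choice(diseased, size=len(diseased), replace=True)
        h = rng.choice(healthy, size=len(healthy), replace=True)
        boot[b] = _fast_auc(d, h)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ROCResult(
        auc=auc, auc_ci95=(float(lo), float(hi)), curve=curve,
        chosen_cutoff=float(cutoff),
        at_cutoff=sens_spec_at(df, cutoff=cutoff, boundary_mmHg=boundary_mmHg),
        bootstrap_seed=seed, n_bootstrap=n_bootstrap,
    )
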