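"""Cox radiomics risk score (RRS), optimal cutoff and KM stratification.

The RRS of a patient is the linear predictor of a multivariate Cox
proportional-hazards model over the four-feature signature,

    RRS = sum_k beta_k * x_k ,

with no baseline term.  The cohort is split into high- and low-risk groups
at the cutoff (searched over a central percentile band of the observed
scores) that maximizes the log-rank statistic; group difference is reported
as the log-rank p-value and the hazard ratio of a single-covariate Cox fit
on the binary group label.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)


@dataclass
class RiskModel:
    """Fitted Cox signature weights plus the chosen risk cutoff."""

    signature: list[str]
    coefficients: pd.Series
    cutoff: float | None = None
    cutoff_percentile: float | None = None
    summary: pd.DataFrame | None = None


@dataclass
class StratificationReport:
    """Per-patient scores/groups and the group-difference statistics."""

    scores: pd.Series
    groups: pd.Series  # "high" / "low"
    hazard_ratio: float
    hr_ci: tuple[float, float]
    logrank_p: float
    logrank_statistic: float
    km_curves: dict[str, pd.DataFrame]


def _check_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    required = {"time", "event"}
    if not required <= set(outcomes.columns):
        raise ValueError(f"outcome table needs columns {sorted(required)}")
    if (outcomes["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    return outcomes


def fit_rrs_model(
    features: pd.DataFrame, outcomes: pd.DataFrame, weights: np.ndarray | None = None
) -> RiskModel:
    """Multivariate Cox fit of the signature features (Efron ties).

    ``features`` holds exactly the signature columns, indexed like
    ``outcomes`` (patient order is taken as aligned).  Optional case
    ``weights`` enter the partial likelihood; scaling all weights by a
    constant leaves the estimates unchanged.
    """
    _check_outcomes(outcomes)
    if int(outcomes["event"].sum()) < 1:
        raise ValueError("no events in the outcome table; Cox model undefined")
    data = features.reset_index(drop=True).copy()
    data["time"] = outcomes["time"].to_numpy()
    data["event"] = outcomes["event"].to_numpy()
    fit_kwargs = {}
    if weights is not None:
        data["w"] = np.asarray(weights, dtype=float)
        fit_kwargs["weights_col"] = "w"
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*weights are not integers.*")
            cph.fit(data, duration_col="time", event_col="event", **fit_kwargs)
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    coef = cph.params_.copy()
    coef.index.name = "feature"
    return RiskModel(signature=list(features.columns), coefficients=coef, summary=cph.summary)


def compute_rrs(model: RiskModel, features: pd.DataFrame | pd.Series) -> pd.Series | float:
    """Linear predictor ``sum(beta_k * x_k)`` for one patient or a table."""
    if isinstance(features, pd.Series):
        missing = [f for f in model.signature if f not in features.index]
        if missing:
            raise KeyError(f"missing signature feature(s): {missing}")
        return float(sum(model.coefficients[f] * features[f] for f in model.signature))
    missing = [f for f in model.signature if f not in features.columns]
    if missing:
        raise KeyError(f"missing signature feature(s): {missing}")
    scores = features[model.signature].to_numpy(dtype=float) @ model.coefficients[
        model.signature
    ].to_numpy(dtype=float)
    return pd.Series(scores, index=features.index, name="RRS")


def _two_group_logrank_stat(time: np.ndarray, event: np.ndarray, high: np.ndarray) -> float:
    """Standard two-group log-rank chi-square, vectorized.

    Matches ``lifelines.statistics.logrank_test(...).test_statistic``.
    """
    order = np.argsort(time)
    t, e, g = time[order], event[order].astype(bool), high[order].astype(bool)
    n = len(t)
    # at-risk counts just before each distinct event time, via searchsorted
    uniq = np.unique(t[e])
    at_risk_total = n - np.searchsorted(t, uniq, side="left")
    cum_high = np.concatenate([[0], np.cumsum(g)])
    at_risk_high = g.sum() - cum_high[np.searchsorted(t, uniq, side="left")]
    # events at each distinct time
    te = t[e]
    d_total = np.searchsorted(te, uniq, side="right") - np.searchsorted(te, uniq, side="left")
    te_high = t[e & g]
    d_high = np.searchsorted(te_high, uniq, side="right") - np.searchsorted(te_high, uniq, side="left")

    frac = at_risk_high / at_risk_total
    o_minus_e = float(np.sum(d_high - d_total * frac))
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d_total * frac * (1 - frac) * (at_risk_total - d_total) / (at_risk_total - 1)
    var = float(np.nansum(var_terms))
    if var <= 0:
        return 0.0
    return o_minus_e**2 / var


def optimal_cutoff(
    scores: pd.Series,
    outcomes: pd.DataFrame,
    search_band: tuple[float, float] = (15.0, 85.0),
) -> tuple[float, float]:
    """Grid search for the score cutoff maximizing the log-rank statistic.

    Candidates are the unique score values whose percentile lies in
    ``search_band`` (percent units); ties in the statistic are broken toward
    the median score.  Returns (cutoff, percentile-in-[0,1]).
    """
    _check_outcomes(outcomes)
    s = np.asarray(scores, dtype=float)
    if np.ptp(s) == 0:
        raise ValueError("constant scores; no cutoff exists")
    lo, hi = np.percentile(s, search_band)
    candidates = np.unique(s[(s >= lo) & (s <= hi)])
    time = outcomes["time"].to_numpy()
    event = outcomes["event"].to_numpy()
    median = float(np.median(s))

    best: tuple[float, float] | None = None  # (statistic, -|c - median|)
    best_c = None
    for c in candidates:
        high = s > c
        if high.sum() < 1 or (~high).sum() < 1:
            continue
        stat = _two_group_logrank_stat(time, event, high)
        key = (stat, -abs(c - median))
        if best is None or key > best:
            best, best_c = key, float(c)
    if best_c is None:
        raise ValueError("no admissible cutoff in the search band")
    percentile = float(np.mean(s <= best_c))
    return best_c, percentile


def cutoff_permutation_p(
    scores: pd.Series,
    outcomes: pd.DataFrame,
    search_band: tuple[float, float] = (15.0, 85.0),
    n_permutations: int = 200,
    seed: int = 0,
) -> float:
    """Permutation-adjusted p-value of the optimized-cutoff log-rank test.

    Maximally selected log-rank statistics inflate the nominal type-I error,
    so the unadjusted p at the chosen cutoff is anti-conservative.  Here the
    observed maximal statistic is referred to its permutation null: outcomes
    are shuffled against scores and the maximal statistic recomputed
    ``n_permutations`` times.
    """
    _check_outcomes(outcomes)
    s = np.asarray(scores, dtype=float)
    time = outcomes["time"].to_numpy()
    event = outcomes["event"].to_numpy()

    def max_stat(t, e):
        lo, hi = np.percentile(s, search_band)
        best = 0.0
        for c in np.unique(s[(s >= lo) & (s <= hi)]):
            high = s > c
            if high.sum() < 1 or (~high).sum() < 1:
                continue
            best = max(best, _two_group_logrank_stat(t, e, high))
        return best

    observed = max_stat(time, event)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(s))
        if max_stat(time[perm], event[perm]) >= observed:
            exceed += 1
    return (exceed + 1) / (n_permutations + 1)


def km_logrank(
    scores: pd.Series, cutoff: float, outcomes: pd.DataFrame
) -> StratificationReport:
    """Stratify at the cutoff; KM curves, log-rank test and group HR."""
    _check_outcomes(outcomes)
    s = pd.Series(np.asarray(scores, dtype=float), index=outcomes.index)
    high = s > cutoff
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValueError("cutoff produces an empty risk group")
    time = outcomes["time"].to_numpy()
    event = outcomes["event"].to_numpy()

    res = logrank_test(time[high], time[~high], event[high], event[~high])

    cox = pd.DataFrame({"high": high.astype(int).to_numpy(), "time": time, "event": event})
    cph = CoxPHFitter()
    try:
        cph.fit(cox, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["high"]))
        ci = tuple(np.exp(cph.confidence_intervals_.loc["high"]).tolist())
    except ConvergenceError:
        logger.warning("group Cox fit failed to converge (separated groups?); HR set to inf")
        hr, ci = float("inf"), (float("nan"), float("nan"))

    curves = {}
    for name, sel in (("high", high.to_numpy()), ("low", (~high).to_numpy())):
        km = KaplanMeierFitter()
        km.fit(time[sel], event[sel], label=name)
        curve = km.survival_function_.copy()
        curve["at_risk"] = [
            int((time[sel] >= t).sum()) for t in curve.index
        ]
        curves[name] = curve

    return StratificationReport(
        scores=s,
        groups=pd.Series(np.where(high, "high", "low"), index=outcomes.index, name="group"),
        hazard_ratio=hr,
        hr_ci=(float(ci[0]), float(ci[1])),
        logrank_p=float(res.p_value),
        logrank_statistic=float(res.test_statistic),
        km_curves=curves,
    )


def plot_km(report: StratificationReport, path) -> None:
    """Write a Kaplan-Meier plot of the high/low-risk groups to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in report.km_curves.items():
        ax.step(curve.index, curve.iloc[:, 0], where="post",
                label=f"{name} risk (n={int((report.groups == name).sum())})")
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(
        f"HR = {report.hazard_ratio:.2f}, log-rank p = {report.logrank_p:.2g}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def validate_rrs(
    features_val: pd.DataFrame,
    outcomes_val: pd.DataFrame,
    signature: list[str],
    search_band: tuple[float, float] = (15.0, 85.0),
) -> tuple[RiskModel, StratificationReport]:
    """Validation-cohort protocol: keep the signature, refit weights + cutoff.

    Mirrors external validation where the discovery model's *feature names*
    transfer but coefficients and cutoff are re-estimated on the new cohort.
    """
    missing = [f for f in signature if f not in features_val.columns]
    if missing:
        raise KeyError(f"signature feature(s) absent from validation table: {missing}")
    model = fit_rrs_model(features_val[list(signature)], outcomes_val)
    scores = compute_rrs(model, features_val)
    cutoff, pct = optimal_cutoff(scores, outcomes_val, search_band)
    model.cutoff, model.cutoff_percentile = cutoff, pct
    report = km_logrank(scores, cutoff, outcomes_val)
    return model, report
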