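"""Physical-activity-arm validation statistics.

Each filtered prompt-occasion pairs a self-reported intensity level with an
accelerometer-derived one: the mean counts per minute over the five minutes
before the report (half-open window over epoch starts), classified by the
Freedson cut points. The arm then computes:

* the 4x4 reported-vs-derived cross-tabulation with margins;
* six agreement parameters per level — match rate (row-conditioned),
  sensitivity and specificity (column-conditioned: positives are defined by
  the *derived* level), the positive and negative likelihood ratios, and a
  mixed-logistic odds ratio with random participant intercepts;
* two-sample Kolmogorov-Smirnov comparisons of the derived count
  distributions between every pair of reported levels;
* a mixed linear model of log(counts + 1) on reported level with all
  pairwise contrasts, back-transformed to raw-CPM differences relative to
  the model's sedentary mean;
* a per-participant mean-by-level audit that reports ordering inversions
  (participants whose average counts are *lower* at a higher reported
  level — the within-person paradox).

:class:`PAValidation` is the model object; :meth:`PAValidation.fit` returns
a :class:`PAValidationResults` with a ``summary()`` table.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .config import PA_LEVELS, FilterThresholds
from .ingest import EpochIndex, FilterResult, filter_pa_prompts
from .intensity import classify_intensity
from .mixedlogit import RandomInterceptLogit

logger = logging.getLogger(__name__)

#: Minimum number of distinct participants in the level's diagonal cell for
#: the mixed OR to be defined (with a single participant the odds are not
#: computed).
OR_MIN_DIAG_PARTICIPANTS = 2


def preprompt_mean(
    epochs, t, window_min: int = 5
) -> tuple[float, int] | None:
    """Mean CPM over the half-open window [t - window_min, t).

    ``epochs`` is either one participant's epoch frame or an
    ``(EpochIndex, participant_id)`` pair. Returns (mean, n contributing
    epochs), or None when no epoch start falls in the window.
    """
    t = pd.Timestamp(t)
    if isinstance(epochs, tuple):
        index, pid = epochs
        counts = index.window_counts(pid, t - pd.Timedelta(minutes=window_min), t)
    else:
        ts = pd.to_datetime(epochs["epoch_start"])
        mask = (ts >= t - pd.Timedelta(minutes=window_min)) & (ts < t)
        counts = epochs.loc[mask, "counts"].to_numpy()
    if counts.size == 0:
        return None
    return float(np.mean(counts)), int(counts.size)


def build_occasions(
    prompts: pd.DataFrame,
    epochs: pd.DataFrame,
    window_min: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach derived intensity to each kept prompt.

    Returns (occasions, dropped): occasions carry participant_id,
    timestamp, reported_level, preprompt_mean_cpm, n_epochs and
    derived_level; prompts with no epoch in the pre-window are dropped
    with a logged reason.
    """
    index = EpochIndex(epochs)
    rows, dropped = [], []
    for i, row in prompts.iterrows():
        res = preprompt_mean((index, row["participant_id"]), row["timestamp"], window_min)
        if res is None:
            dropped.append(
                {"row": i, "participant_id": row["participant_id"],
                 "timestamp": row["timestamp"], "reason": "no epochs in pre-window"}
            )
            continue
        mean_cpm, n = res
        rows.append(
            {
                "participant_id": row["participant_id"],
                "timestamp": row["timestamp"],
                "reported_level": row["reported_pa_level"],
                "preprompt_mean_cpm": mean_cpm,
                "n_epochs": n,
                "derived_level": classify_intensity(mean_cpm),
            }
        )
    if dropped:
        logger.warning("%d occasions dropped: no epochs in pre-window", len(dropped))
    occasions = pd.DataFrame(
        rows,
        columns=["participant_id", "timestamp", "reported_level", "preprompt_mean_cpm",
                 "n_epochs", "derived_level"],
    )
    return occasions, pd.DataFrame(dropped, columns=["row", "participant_id", "timestamp", "reason"])


def crosstab(occasions: pd.DataFrame) -> pd.DataFrame:
    """4x4 counts, rows = reported level, columns = derived level."""
    if len(occasions) == 0:
        raise ValueError("cannot tabulate an empty occasion set")
    ct = pd.crosstab(occasions["reported_level"], occasions["derived_level"])
    return ct.reindex(index=PA_LEVELS, columns=PA_LEVELS, fill_value=0)


def agreement_from_crosstab(ct: pd.DataFrame) -> pd.DataFrame:
    """The level-conditioned agreement suite from a 4x4 cross-tab.

    Per level L (all proportions in [0, 1]):

    * match_rate: diagonal / row total (share of L-reports that derived L);
    * sensitivity: diagonal / column total (share of derived-L occasions
      reported L) — positives defined by the derived level;
    * specificity: among occasions not derived L, share not reported L;
    * lr_plus = sens / (1 - spec), lr_minus = (1 - sens) / spec (NaN where
      the denominator is zero).
    """
    ct = ct.reindex(index=PA_LEVELS, columns=PA_LEVELS, fill_value=0)
    arr = ct.to_numpy(float)
    if (arr < 0).any():
        raise ValueError("cross-tab cells must be nonnegative")
    total = arr.sum()
    rows = []
    for i, level in enumerate(PA_LEVELS):
        diag = arr[i, i]
        row_total = arr[i, :].sum()
        col_total = arr[:, i].sum()
        tn = total - row_total - col_total + diag
        fp = row_total - diag
        match = diag / row_total if row_total else np.nan
        sens = diag / col_total if col_total else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        lr_plus = np.nan
        lr_minus = np.nan
        if not (np.isnan(sens) or np.isnan(spec)):
            if spec < 1:
                lr_plus = sens / (1 - spec)
            if spec > 0:
                lr_minus = (1 - sens) / spec
        rows.append(
            {
                "level": level,
                "n_reported": int(row_total),
                "n_derived": int(col_total),
                "match_rate": match,
                "sensitivity": sens,
                "specificity": spec,
                "lr_plus": lr_plus,
                "lr_minus": lr_minus,
            }
        )
    return pd.DataFrame(rows)


def crosstab_and_agreement(occasions: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tab plus the agreement suite, from raw occasions."""
    ct = crosstab(occasions)
    return ct, agreement_from_crosstab(ct)


def pa_or_mixed_logit(occasions: pd.DataFrame, level: str) -> dict:
    """Mixed-logistic odds ratio that reported and derived level coincide.

    Outcome: derived level == L; predictor: reported level == L; random
    participant intercepts. Declared undefined (NaN, ``defined=False``)
    when fewer than :data:`OR_MIN_DIAG_PARTICIPANTS` participants
    contribute to the L-by-L diagonal cell.
    """
    if level not in PA_LEVELS:
        raise ValueError(f"unknown level {level!r}")
    occ = occasions.assign(
        outcome=(occasions["derived_level"] == level).astype(float),
        predictor=(occasions["reported_level"] == level).astype(float),
    )
    diag = occ[(occ["outcome"] == 1) & (occ["predictor"] == 1)]
    n_diag_participants = diag["participant_id"].nunique()
    out = {
        "level": level,
        "n": len(occ),
        "n_diag_participants": int(n_diag_participants),
        "or": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "p": np.nan,
        "sigma": np.nan,
        "defined": False,
        "converged": False,
    }
    if n_diag_participants < OR_MIN_DIAG_PARTICIPANTS:
        return out
    if occ["outcome"].nunique() < 2 or occ["predictor"].nunique() < 2:
        return out
    fit = RandomInterceptLogit.from_frame(occ, "outcome", ["predictor"], "participant_id").fit()
    orr = fit.odds_ratio("predictor")
    out.update(
        {
            "or": orr["or"],
            "ci_low": orr["ci_low"],
            "ci_high": orr["ci_high"],
            "p": orr["p"],
            "sigma": fit.sigma,
            "defined": True,
            "converged": fit.converged,
        }
    )
    return out


def ks_pairwise(occasions: pd.DataFrame) -> pd.DataFrame:
    """Two-sample KS tests of derived counts between reported levels.

    All six pairs among sedentary/light/moderate/vigorous; D is the maximum
    vertical ECDF distance, p asymptotic. Pairs where either group has
    fewer than two occasions are skipped with a notice.
    """
    samples = {
        lv: occasions.loc[occasions["reported_level"] == lv, "preprompt_mean_cpm"].to_numpy()
        for lv in PA_LEVELS
    }
    rows = []
    for a, b in itertools.combinations(PA_LEVELS, 2):
        xa, xb = samples[a], samples[b]
        if len(xa) < 2 or len(xb) < 2:
            rows.append(
                {"level_a": a, "level_b": b, "n_a": len(xa), "n_b": len(xb),
                 "d": np.nan, "p": np.nan, "skipped": True}
            )
            logger.info("KS %s vs %s skipped: fewer than 2 observations", a, b)
            continue
        res = stats.ks_2samp(xa, xb, method="asymp")
        rows.append(
            {"level_a": a, "level_b": b, "n_a": len(xa), "n_b": len(xb),
             "d": float(res.statistic), "p": float(res.pvalue), "skipped": False}
        )
    return pd.DataFrame(rows)


@dataclass
class LogCountFit:
    """Mixed-linear-model fit of log(CPM + 1) on reported level.

    ``contrasts`` holds every pairwise level difference on the log scale
    with Wald 95% CI, p-value, and the raw-CPM correspondence
    exp(b0 + diff) - exp(b0) relative to the model's sedentary mean b0.
    """

    intercept: float
    level_effects: dict
    sigma_participant: float
    sigma_resid: float
    contrasts: pd.DataFrame
    converged: bool


def logcount_mixed_lm(occasions: pd.DataFrame) -> LogCountFit:
    """Fit ln(preprompt_mean_cpm + 1) ~ reported level + (1 | participant).

    Maximum likelihood (not REML); reference level is sedentary. All six
    pairwise contrasts are returned with Wald intervals from the fixed-
    effect covariance. Raises when every occasion sits at one level.
    """
    occ = occasions.copy()
    if occ["reported_level"].nunique() < 2:
        raise ValueError("log-count model needs at least two reported levels")
    occ["logcpm"] = np.log(occ["preprompt_mean_cpm"].astype(float) + 1.0)
    levels_present = [lv for lv in PA_LEVELS if (occ["reported_level"] == lv).any()]
    X = pd.DataFrame({"const": 1.0}, index=occ.index)
    for lv in levels_present[1:]:
        X[lv] = (occ["reported_level"] == lv).astype(float)
    import warnings

    fit = None
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(occ["logcpm"], X, groups=occ["participant_id"])
            fit = model.fit(reml=False, method="lbfgs", maxiter=500)
        except np.linalg.LinAlgError:
            fit = None
    if fit is not None:
        params = fit.params
        cov = fit.cov_params().loc[X.columns, X.columns]
        sigma_u = float(np.sqrt(max(float(fit.cov_re.iloc[0, 0]), 0.0)))
        sigma_e = float(np.sqrt(fit.scale))
        converged = bool(fit.converged)
    else:
        # random-intercept variance at the singular boundary: the model
        # degenerates to ordinary least squares (zero between-person
        # variance), which is the fit we report
        logger.warning("mixed LM singular at the boundary; reporting the OLS limit")
        ols = sm.OLS(occ["logcpm"], X).fit()
        params = ols.params
        cov = ols.cov_params().loc[X.columns, X.columns]
        sigma_u = 0.0
        sigma_e = float(np.sqrt(ols.scale))
        converged = True
    b0 = float(params["const"])
    effects = {levels_present[0]: 0.0}
    effects.update({lv: float(params[lv]) for lv in levels_present[1:]})

    def _var(lv):
        return float(cov.loc[lv, lv]) if lv in cov.index else 0.0

    def _cov(a, b):
        if a in cov.index and b in cov.index:
            return float(cov.loc[a, b])
        return 0.0

    z = stats.norm.ppf(0.975)
    rows = []
    for a, b in itertools.combinations(levels_present, 2):
        diff = effects[b] - effects[a]
        var = _var(a) + _var(b) - 2 * _cov(a, b)
        se = np.sqrt(max(var, 0.0))
        pval = 2 * stats.norm.sf(abs(diff) / se) if se > 0 else np.nan
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "diff": diff,
                "se": se,
                "ci_low": diff - z * se,
                "ci_high": diff + z * se,
                "p": pval,
                "raw_cpm_diff": float(np.exp(b0 + diff) - np.exp(b0)),
            }
        )
    return LogCountFit(
        intercept=b0,
        level_effects=effects,
        sigma_participant=sigma_u,
        sigma_resid=sigma_e,
        contrasts=pd.DataFrame(rows),
        converged=converged,
    )


def participant_level_summary(occasions: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant mean derived counts by reported level, with the
    within-person ordering audit.

    Returns (means, inversions). ``means`` is participant x level (NaN when
    the participant never reported the level). ``inversions`` lists, per
    adjacent level pair, how many participants reported both levels and for
    how many the mean counts *decreased* at the higher reported level.
    """
    means = occasions.pivot_table(
        index="participant_id", columns="reported_level", values="preprompt_mean_cpm",
        aggfunc="mean",
    ).reindex(columns=PA_LEVELS)
    rows = []
    for lo, hi in zip(PA_LEVELS[:-1], PA_LEVELS[1:]):
        both = means[[lo, hi]].dropna()
        inverted = both[both[hi] < both[lo]]
        rows.append(
            {
                "lower_level": lo,
                "higher_level": hi,
                "n_both": len(both),
                "n_inverted": len(inverted),
                "inverted_participants": ";".join(inverted.index.astype(str)),
            }
        )
    return means, pd.DataFrame(rows)


@dataclass
class PAValidationResults:
    """Results of the activity-arm validation."""

    occasions: pd.DataFrame
    occasion_ledger: pd.DataFrame
    crosstab: pd.DataFrame
    agreement: pd.DataFrame
    mixed_or: pd.DataFrame
    ks: pd.DataFrame
    logcount: LogCountFit | None
    participant_means: pd.DataFrame
    inversions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> str:
        lines = ["Activity-arm validation", "=" * 23]
        lines.append(
            f"Analysed occasions: {len(self.occasions)} "
            f"(excluded prompts: {len(self.occasion_ledger)})"
        )
        lines.append("")
        lines.append("Reported (rows) x derived (columns) cross-tab:")
        lines.append(self.crosstab.to_string())
        lines.append("")
        lines.append("Agreement by level:")
        header = f"{'level':<11}{'match %':>9}{'sens %':>8}{'spec %':>8}{'LR+':>8}{'LR-':>8}{'OR':>22}"
        lines.append(header)
        for _, r in self.agreement.iterrows():
            orr = self.mixed_or[self.mixed_or["level"] == r["level"]].iloc[0]
            or_txt = (
                f"{orr['or']:.2f} ({orr['ci_low']:.2f}-{orr['ci_high']:.2f})"
                if orr["defined"] and orr["converged"]
                else "not computed"
            )
            fmt = lambda v, nd: "--" if pd.isna(v) else f"{v:.{nd}f}"
            lines.append(
                f"{r['level']:<11}"
                f"{fmt(100 * r['match_rate'], 1):>9}"
                f"{fmt(100 * r['sensitivity'], 0):>8}"
                f"{fmt(100 * r['specificity'], 0):>8}"
                f"{fmt(r['lr_plus'], 2):>8}"
                f"{fmt(r['lr_minus'], 2):>8}"
                f"{or_txt:>22}"
            )
        if self.logcount is not None:
            lines.append("")
            lines.append("Log-count mixed model contrasts (higher minus lower level):")
            for _, r in self.logcount.contrasts.iterrows():
                lines.append(
                    f"  {r['level_a']} vs {r['level_b']}: {r['diff']:.2f} "
                    f"({r['ci_low']:.2f}-{r['ci_high']:.2f}), p={r['p']:.3g}, "
                    f"raw {r['raw_cpm_diff']:.0f} CPM"
                )
        return "\n".join(lines)


class PAValidation:
    """Model object for the activity validation arm.

    Built from loaded prompts and epochs; ``fit()`` applies the coverage
    and wear filters, derives the occasion set, and computes the cross-tab,
    agreement suite, mixed ORs, KS comparisons and the log-count model.
    """

    def __init__(
        self,
        prompts: pd.DataFrame,
        epochs: pd.DataFrame,
        thresholds: FilterThresholds | None = None,
        include_retrospective: bool = False,
    ):
        self.prompts = prompts
        self.epochs = epochs
        self.thresholds = thresholds or FilterThresholds()
        self.include_retrospective = include_retrospective

    @classmethod
    def from_tables(cls, tables, **kwargs) -> "PAValidation":
        return cls(tables.prompts, tables.epochs, **kwargs)

    def fit(self, logcount_model: bool = True) -> PAValidationResults:
        filt: FilterResult = filter_pa_prompts(
            self.prompts, self.epochs, self.thresholds, self.include_retrospective
        )
        occasions, dropped = build_occasions(
            filt.kept, self.epochs, self.thresholds.preprompt_avg_min
        )
        frames = [f for f in (filt.ledger, dropped) if len(f)]
        ledger = (
            pd.concat(frames, ignore_index=True) if frames else filt.ledger
        )
        ct, agreement = crosstab_and_agreement(occasions)
        mixed = pd.DataFrame([pa_or_mixed_logit(occasions, lv) for lv in PA_LEVELS])
        ks = ks_pairwise(occasions)
        logfit = None
        if logcount_model and occasions["reported_level"].nunique() >= 2:
            logfit = logcount_mixed_lm(occasions)
        means, inversions = participant_level_summary(occasions)
        return PAValidationResults(
            occasions=occasions,
            occasion_ledger=ledger,
            crosstab=ct,
            agreement=agreement,
            mixed_or=mixed,
            ks=ks,
            logcount=logfit,
            participant_means=means,
            inversions=inversions,
        )
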