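"""Diet-arm validation statistics.

Compares momentary food-group endorsements against 24-hour-recall eating
instances in two ways:

* **Day level** — per food group, the numerator is the sum over
  participant-days of min(momentary count, recall count) and the
  denominator the total momentary endorsements; e.g. four momentary
  fruit/vegetable reports against three recall instances score 3 of 4
  (75%), the converse 3 of 3 (100%).
* **Window level** — per food group and half-width w (default 6-480 min in
  6-min steps), the fraction of momentary endorsements with a same-group
  recall instance within the closed interval [t-w, t+w] (a positive
  predictive value), plus sensitivity/specificity over the full
  prompt-occasion set with the recall side as reference.

Subgroup chi-square tests and a per-group mixed logistic model (momentary
endorsement predicted by recall-day endorsement, random participant
intercepts) complete the arm. The :class:`DietValidation` model class ties
the pieces together; its :meth:`DietValidation.fit` returns a
:class:`DietValidationResults` with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import NAMED_FOOD_GROUPS, FilterThresholds
from .ingest import FilterResult, filter_diet_days
from .mixedlogit import RandomInterceptLogit

#: Default half-width grid: 6 minutes to 8 hours in 6-minute increments.
DEFAULT_WINDOW_GRID = tuple(range(6, 481, 6))


def _explode_endorsements(prompts: pd.DataFrame) -> pd.DataFrame:
    """One row per (prompt, endorsed food group)."""
    sub = prompts[prompts["food_groups"] != ""]
    if len(sub) == 0:
        return pd.DataFrame(columns=["participant_id", "date", "timestamp", "food_group"])
    out = sub.assign(food_group=sub["food_groups"].str.split(";")).explode("food_group")
    return out[["participant_id", "date", "timestamp", "food_group"]].reset_index(drop=True)


def _restrict_to_days(df: pd.DataFrame, days: pd.DataFrame) -> pd.DataFrame:
    keys = set(zip(days["participant_id"], days["date"]))
    mask = [(p, d) in keys for p, d in zip(df["participant_id"], df["date"])]
    return df[mask]


@dataclass
class DayMatchSummary:
    """Per-group day-level totals and the per-day audit rows."""

    per_group: pd.DataFrame  # food_group, n_mema, n_recall, n_matched, match_rate
    per_day: pd.DataFrame  # participant_id, date, food_group, n_mema, n_recall, n_matched


def day_match_rates(
    prompts: pd.DataFrame,
    recalls: pd.DataFrame,
    days: pd.DataFrame,
    groups=NAMED_FOOD_GROUPS,
    include_retrospective: bool = False,
) -> DayMatchSummary:
    """Day-level match rates per food group.

    For each kept participant-day and group, the matched count is
    min(number of momentary endorsements, number of recall instances);
    totals are summed over days and the match rate is 100 * matched /
    momentary endorsements (missing, not zero, for a group never endorsed).
    """
    pr = prompts if include_retrospective else prompts[prompts["prompt_type"] == "real_time"]
    endorsements = _restrict_to_days(_explode_endorsements(pr), days)
    recall_inst = _restrict_to_days(recalls, days)

    m = (
        endorsements.groupby(["participant_id", "date", "food_group"]).size()
        if len(endorsements)
        else pd.Series(dtype=int)
    )
    r = (
        recall_inst.groupby(["participant_id", "date", "food_group"]).size()
        if len(recall_inst)
        else pd.Series(dtype=int)
    )
    per_day = (
        pd.concat([m.rename("n_mema"), r.rename("n_recall")], axis=1)
        .fillna(0)
        .astype(int)
        .reset_index()
    )
    if len(per_day) == 0:
        per_day = pd.DataFrame(
            columns=["participant_id", "date", "food_group", "n_mema", "n_recall", "n_matched"]
        )
    else:
        per_day["n_matched"] = np.minimum(per_day["n_mema"], per_day["n_recall"])

    rows = []
    for g in groups:
        sub = per_day[per_day["food_group"] == g] if len(per_day) else per_day
        n_mema = int(sub["n_mema"].sum()) if len(sub) else 0
        n_recall = int(sub["n_recall"].sum()) if len(sub) else 0
        n_matched = int(sub["n_matched"].sum()) if len(sub) else 0
        rows.append(
            {
                "food_group": g,
                "n_mema": n_mema,
                "n_recall": n_recall,
                "n_matched": n_matched,
                "match_rate": 100.0 * n_matched / n_mema if n_mema else np.nan,
            }
        )
    return DayMatchSummary(per_group=pd.DataFrame(rows), per_day=per_day)


def _min_offsets(
    prompts: pd.DataFrame, recalls: pd.DataFrame, groups
) -> pd.DataFrame:
    """Per (real-time prompt, group): endorsement flag and the minimal
    |offset| in minutes to a same-group recall instance of that participant
    (inf when none exists)."""
    rec_by = {
        (pid, g): grp["timestamp"].astype("int64").to_numpy() // 60_000_000_000
        for (pid, g), grp in recalls.groupby(["participant_id", "food_group"])
    }
    rows = []
    for i, row in prompts.iterrows():
        t = int(pd.Timestamp(row["timestamp"]).value // 60_000_000_000)
        endorsed = set(row["food_groups"].split(";")) if row["food_groups"] else set()
        for g in groups:
            times = rec_by.get((row["participant_id"], g))
            dist = float(np.abs(times - t).min()) if times is not None and len(times) else np.inf
            rows.append(
                {
                    "prompt_row": i,
                    "participant_id": row["participant_id"],
                    "food_group": g,
                    "endorsed": g in endorsed,
                    "min_offset": dist,
                }
            )
    return pd.DataFrame(rows)


def window_match_curve(
    prompts: pd.DataFrame,
    recalls: pd.DataFrame,
    grid=DEFAULT_WINDOW_GRID,
    groups=NAMED_FOOD_GROUPS,
) -> pd.DataFrame:
    """Window match rate (PPV) per food group and half-width.

    Denominator: momentary reports endorsing the group. Numerator: those
    with at least one same-group recall instance within the closed window
    [t-w, t+w]. Monotone non-decreasing in w by construction.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("window grid must be non-empty")
    offs = _min_offsets(prompts, recalls, groups)
    rows = []
    for g in groups:
        sub = offs[(offs["food_group"] == g) & offs["endorsed"]]
        n = len(sub)
        for w in grid:
            matched = int((sub["min_offset"] <= w).sum())
            rows.append(
                {
                    "food_group": g,
                    "w": w,
                    "n_endorsements": n,
                    "n_matched": matched,
                    "ppv": 100.0 * matched / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def window_sens_spec(
    prompts: pd.DataFrame,
    recalls: pd.DataFrame,
    grid=DEFAULT_WINDOW_GRID,
    groups=NAMED_FOOD_GROUPS,
    eating_prompts_only: bool = False,
) -> pd.DataFrame:
    """Sensitivity/specificity of momentary endorsement vs windowed recall.

    Occasions are all completed real-time prompts (or only those endorsing
    some food group when ``eating_prompts_only``). For each group and
    half-width w the reference is "a same-group recall instance lies within
    [t-w, t+w]" and the test is "the group was endorsed in this report";
    sensitivity = TP/(TP+FN) (missing when no reference-positives),
    specificity = TN/(TN+FP). TP+FP+FN+TN equals the occasion count at
    every w.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("window grid must be non-empty")
    occ = prompts[prompts["prompt_type"] == "real_time"]
    if eating_prompts_only:
        occ = occ[occ["food_groups"] != ""]
    offs = _min_offsets(occ, recalls, groups)
    rows = []
    for g in groups:
        sub = offs[offs["food_group"] == g]
        endorsed = sub["endorsed"].to_numpy(bool)
        dist = sub["min_offset"].to_numpy(float)
        for w in grid:
            ref = dist <= w
            tp = int((endorsed & ref).sum())
            fp = int((endorsed & ~ref).sum())
            fn = int((~endorsed & ref).sum())
            tn = int((~endorsed & ~ref).sum())
            rows.append(
                {
                    "food_group": g,
                    "w": w,
                    "tp": tp,
                    "fp": fp,
                    "fn": fn,
                    "tn": tn,
                    "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else np.nan,
                    "specificity": 100.0 * tn / (tn + fp) if tn + fp else np.nan,
                }
            )
    return pd.DataFrame(rows)


def subgroup_chisq(
    per_day: pd.DataFrame,
    participants: pd.DataFrame,
    attribute: str,
    groups=NAMED_FOOD_GROUPS,
) -> pd.DataFrame:
    """Chi-square test of day-level match proportion by a binary attribute.

    Each momentary endorsement is classified matched/unmatched at the day
    level (matched = the min-count rule's numerator); a 2x2 matched-by-
    subgroup table per food group is tested with the uncorrected chi-square.
    Results with any expected cell below 1 are flagged unreliable.
    """
    merged = per_day.merge(
        participants[["participant_id", attribute]], on="participant_id", how="left"
    )
    merged["unmatched"] = merged["n_mema"] - merged["n_matched"]
    rows = []
    for g in groups:
        sub = merged[merged["food_group"] == g]
        tab = sub.groupby(attribute)[["n_matched", "unmatched"]].sum()
        arr = tab.to_numpy()
        degenerate = (
            tab.shape != (2, 2)
            or arr.sum() == 0
            or (arr.sum(axis=0) == 0).any()
            or (arr.sum(axis=1) == 0).any()
        )
        if degenerate:
            rows.append(
                {"food_group": g, "chi2": np.nan, "df": np.nan, "p": np.nan,
                 "min_expected": np.nan, "reliable": False}
            )
            continue
        chi2, p, dof, expected = stats.chi2_contingency(tab.to_numpy(), correction=False)
        rows.append(
            {
                "food_group": g,
                "chi2": float(chi2),
                "df": int(dof),
                "p": float(p),
                "min_expected": float(expected.min()),
                "reliable": bool(expected.min() >= 1),
            }
        )
    return pd.DataFrame(rows)


def diet_mixed_logit(
    prompts: pd.DataFrame,
    recalls: pd.DataFrame,
    days: pd.DataFrame,
    groups=NAMED_FOOD_GROUPS,
    include_retrospective: bool = False,
) -> pd.DataFrame:
    """Mixed logistic model of momentary endorsement on recall endorsement.

    One occasion per kept participant-day and food group: outcome = group
    endorsed in any momentary report that day, predictor = group present in
    that day's recall; random participant intercepts. Returns OR with 95%
    Wald CI per group; separation or non-convergence yields a flagged NA
    row rather than an exception.
    """
    pr = prompts if include_retrospective else prompts[prompts["prompt_type"] == "real_time"]
    endorsements = _restrict_to_days(_explode_endorsements(pr), days)
    recall_inst = _restrict_to_days(recalls, days)
    rows = []
    for g in groups:
        e_sub = endorsements[endorsements["food_group"] == g] if len(endorsements) else endorsements
        r_sub = recall_inst[recall_inst["food_group"] == g] if len(recall_inst) else recall_inst
        e_days = set(zip(e_sub["participant_id"], e_sub["date"])) if len(e_sub) else set()
        r_days = set(zip(r_sub["participant_id"], r_sub["date"])) if len(r_sub) else set()
        occ = days.assign(
            mema=[(p, d) in e_days for p, d in zip(days["participant_id"], days["date"])],
            recall=[(p, d) in r_days for p, d in zip(days["participant_id"], days["date"])],
        )
        occ["mema"] = occ["mema"].astype(float)
        occ["recall"] = occ["recall"].astype(float)
        result = {"food_group": g, "n_days": len(occ), "or": np.nan, "ci_low": np.nan,
                  "ci_high": np.nan, "p": np.nan, "sigma": np.nan, "converged": False}
        if occ["mema"].nunique() > 1 and occ["recall"].nunique() > 1:
            model = RandomInterceptLogit.from_frame(occ, "mema", ["recall"], "participant_id")
            fit = model.fit()
            orr = fit.odds_ratio("recall")
            if fit.converged and np.isfinite(orr["or"]):
                result.update(
                    {"or": orr["or"], "ci_low": orr["ci_low"], "ci_high": orr["ci_high"],
                     "p": orr["p"], "sigma": fit.sigma, "converged": True}
                )
        rows.append(result)
    return pd.DataFrame(rows)


@dataclass
class DietValidationResults:
    """Results of the diet-arm validation.

    Attributes mirror the analysis stages: ``days``/``day_ledger`` from the
    plausibility filter, ``day_match`` (per-group summary + per-day audit),
    ``ppv_curve`` and ``sens_spec`` over the window grid, optional
    ``subgroups`` chi-squares and the ``mixed_or`` table.
    """

    days: pd.DataFrame
    day_ledger: pd.DataFrame
    day_match: DayMatchSummary
    ppv_curve: pd.DataFrame
    sens_spec: pd.DataFrame
    subgroups: dict = field(default_factory=dict)
    mixed_or: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = ["Diet-arm validation", "=" * 19]
        lines.append(
            f"Analysed participant-days: {len(self.days)} "
            f"(excluded: {len(self.day_ledger)})"
        )
        lines.append("")
        lines.append("Day-level match rates (min-count rule):")
        lines.append(f"{'food group':<20}{'mEMA':>6}{'recall':>8}{'matched':>9}{'match %':>9}")
        for _, r in self.day_match.per_group.iterrows():
            rate = "--" if pd.isna(r["match_rate"]) else f"{r['match_rate']:.1f}"
            lines.append(
                f"{r['food_group']:<20}{r['n_mema']:>6d}{r['n_recall']:>8d}"
                f"{r['n_matched']:>9d}{rate:>9}"
            )
        if self.mixed_or is not None and len(self.mixed_or):
            lines.append("")
            lines.append("Mixed logistic OR (momentary ~ recall-day endorsement):")
            for _, r in self.mixed_or.iterrows():
                if r["converged"]:
                    lines.append(
                        f"  {r['food_group']:<20}OR {r['or']:.2f} "
                        f"(95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f}), p={r['p']:.3g}"
                    )
                else:
                    lines.append(f"  {r['food_group']:<20}OR not estimable")
        for attr, tab in self.subgroups.items():
            lines.append("")
            lines.append(f"Match-rate difference by {attr} (chi-square):")
            for _, r in tab.iterrows():
                if pd.isna(r["chi2"]):
                    lines.append(f"  {r['food_group']:<20}not testable")
                else:
                    flag = "" if r["reliable"] else " [low expected counts]"
                    lines.append(
                        f"  {r['food_group']:<20}chi2={r['chi2']:.2f}, p={r['p']:.3f}{flag}"
                    )
        return "\n".join(lines)


class DietValidation:
    """Model object for the diet validation arm.

    Built from the loaded study tables; ``fit()`` applies the plausibility
    filter and computes every diet-arm statistic.

    Parameters
    ----------
    prompts, recalls : validated tables from ``ingest.load_study``
    participants : optional attribute table for subgroup tests
    thresholds : exclusion constants (defaults are the study's)
    grid : window half-width grid in minutes
    include_retrospective : include retrospective prompts (default False:
        only real-time reports enter the momentary side)
    """

    def __init__(
        self,
        prompts: pd.DataFrame,
        recalls: pd.DataFrame,
        participants: pd.DataFrame | None = None,
        thresholds: FilterThresholds | None = None,
        grid=DEFAULT_WINDOW_GRID,
        include_retrospective: bool = False,
    ):
        self.prompts = prompts
        self.recalls = recalls
        self.participants = participants
        self.thresholds = thresholds or FilterThresholds()
        self.grid = list(grid)
        self.include_retrospective = include_retrospective

    @classmethod
    def from_tables(cls, tables, **kwargs) -> "DietValidation":
        """Build from an ``ingest.StudyTables`` bundle."""
        return cls(tables.prompts, tables.recalls, tables.participants, **kwargs)

    def fit(
        self,
        subgroups: tuple[str, ...] = (),
        mixed_model: bool = True,
    ) -> DietValidationResults:
        filt: FilterResult = filter_diet_days(
            self.prompts, self.recalls, self.thresholds, self.include_retrospective
        )
        days = filt.kept
        kept_prompts = _restrict_to_days(self.prompts, days)
        kept_recalls = _restrict_to_days(self.recalls, days)
        day_match = day_match_rates(
            kept_prompts, kept_recalls, days, include_retrospective=self.include_retrospective
        )
        pr = (
            kept_prompts
            if self.include_retrospective
            else kept_prompts[kept_prompts["prompt_type"] == "real_time"]
        )
        ppv = window_match_curve(pr, kept_recalls, self.grid)
        ss = window_sens_spec(kept_prompts, kept_recalls, self.grid)
        sub_results = {}
        if subgroups and self.participants is not None:
            for attr in subgroups:
                if attr in self.participants.columns:
                    sub_results[attr] = subgroup_chisq(
                        day_match.per_day, self.participants, attr
                    )
        mixed = (
            diet_mixed_logit(
                kept_prompts, kept_recalls, days, include_retrospective=self.include_retrospective
            )
            if mixed_model and len(days)
            else None
        )
        return DietValidationResults(
            days=days,
            day_ledger=filt.ledger,
            day_match=day_match,
            ppv_curve=ppv,
            sens_spec=ss,
            subgroups=sub_results,
            mixed_or=mixed,
        )
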