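"""Reading the three study tables and applying the exclusion filters.

Input files are comma-separated text with one header row and ISO-8601
timestamps (naive local time, minute resolution):

``prompts.csv``
    participant_id, timestamp, prompt_type, behaviors, food_groups,
    reported_pa_level, sedentary_activity — one completed momentary survey
    per row; multi-valued fields are semicolon-joined.
``recall.csv``
    participant_id, date, clock_time, food_group (or food_code with a
    user-supplied mapping), day_kcal — one recall-derived eating instance
    per row.
``epochs.csv``
    participant_id, epoch_start, counts — 60-second accelerometer epochs,
    contiguous within each calendar day.
``participants.csv`` (optional)
    participant_id plus subgroup attributes (gender, race, pell).

Two exclusion filters reproduce the analysis sets: ``filter_diet_days``
keeps participant-days with at least one momentary food entry and a
biologically plausible recall (500-5000 kcal, closed interval), and
``filter_pa_prompts`` keeps real-time prompts with accelerometer coverage
(neither 30-minute flank entirely zero, at least 5 hours of wear that day).
Both return the kept set together with an exclusion ledger; kept + ledger
always partition the input exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import BEHAVIORS, FOOD_GROUPS, PA_LEVELS, FilterThresholds

logger = logging.getLogger(__name__)

#: Instrument label for the top intensity category, unified with "vigorous".
_LEVEL_ALIASES = {"strenuous": "vigorous"}


class StudyDataError(ValueError):
    """Hard error for missing files or structurally invalid epoch streams."""


@dataclass
class StudyTables:
    """Typed, validated study tables plus the record-level rejection report."""

    prompts: pd.DataFrame
    recalls: pd.DataFrame
    epochs: pd.DataFrame
    participants: pd.DataFrame | None = None
    rejections: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["table", "row", "reason"])
    )


@dataclass
class FilterResult:
    """Kept records and the exclusion ledger from one filter pass."""

    kept: pd.DataFrame
    ledger: pd.DataFrame


def _split_multi(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return []
    return [tok for tok in str(value).split(";") if tok]


def _parse_prompts(df: pd.DataFrame, rejections: list) -> pd.DataFrame:
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    except ValueError:
        ts = pd.to_datetime(df["timestamp"], errors="coerce")
    rows = []
    for i, row in df.iterrows():
        if pd.isna(ts.loc[i]):
            rejections.append(("prompts", i, f"malformed timestamp {row['timestamp']!r}"))
            continue
        level = _LEVEL_ALIASES.get(str(row["reported_pa_level"]), str(row["reported_pa_level"]))
        if level not in PA_LEVELS:
            rejections.append(("prompts", i, f"unknown activity level {row['reported_pa_level']!r}"))
            continue
        behaviors = _split_multi(row.get("behaviors"))
        groups = _split_multi(row.get("food_groups"))
        if any(b not in BEHAVIORS for b in behaviors):
            rejections.append(("prompts", i, f"unknown behavior in {behaviors!r}"))
            continue
        if any(g not in FOOD_GROUPS for g in groups):
            rejections.append(("prompts", i, f"unknown food group in {groups!r}"))
            continue
        if groups and "eating" not in behaviors:
            rejections.append(("prompts", i, "food groups present without eating endorsement"))
            continue
        if (level == "sedentary") == ("physically_active" in behaviors):
            rejections.append(
                ("prompts", i, "activity level inconsistent with physically_active endorsement")
            )
            continue
        if str(row["prompt_type"]) not in ("real_time", "retrospective"):
            rejections.append(("prompts", i, f"unknown prompt type {row['prompt_type']!r}"))
            continue
        rows.append(
            {
                "participant_id": str(row["participant_id"]),
                "timestamp": ts.loc[i].floor("min"),
                "prompt_type": str(row["prompt_type"]),
                "behaviors": ";".join(behaviors),
                "food_groups": ";".join(groups),
                "reported_pa_level": level,
                "sedentary_activity": "" if pd.isna(row.get("sedentary_activity")) else str(row.get("sedentary_activity", "")),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "timestamp",
            "prompt_type",
            "behaviors",
            "food_groups",
            "reported_pa_level",
            "sedentary_activity",
        ],
    )
    if len(out):
        out["date"] = out["timestamp"].dt.normalize()
    else:
        out["timestamp"] = pd.to_datetime(out["timestamp"])
        out["date"] = pd.to_datetime(out["timestamp"])
    return out


def _parse_recalls(
    df: pd.DataFrame, mapping: pd.DataFrame | None, rejections: list
) -> pd.DataFrame:
    code_map = None
    if mapping is not None:
        code_map = dict(zip(mapping["food_code"].astype(str), mapping["food_group"].astype(str)))
    dates = pd.to_datetime(df["date"], errors="coerce")
    rows = []
    n_unmapped = 0
    for i, row in df.iterrows():
        if pd.isna(dates.loc[i]):
            rejections.append(("recall", i, f"malformed date {row['date']!r}"))
            continue
        clock = pd.to_datetime(str(row["clock_time"]), format="%H:%M", errors="coerce")
        if pd.isna(clock):
            rejections.append(("recall", i, f"malformed clock time {row['clock_time']!r}"))
            continue
        if "food_group" in df.columns and not pd.isna(row.get("food_group")):
            group = str(row["food_group"])
            if group not in FOOD_GROUPS:
                if code_map is not None and group in code_map:
                    group = code_map[group]
                else:
                    rejections.append(("recall", i, f"unknown food group {group!r}"))
                    continue
        else:
            code = str(row.get("food_code", ""))
            group = code_map.get(code) if code_map else None
            if group is None or group not in FOOD_GROUPS:
                n_unmapped += 1
                group = "other"
        kcal = float(row["day_kcal"])
        if not np.isfinite(kcal) or kcal < 0:
            rejections.append(("recall", i, f"invalid day kcal {row['day_kcal']!r}"))
            continue
        rows.append(
            {
                "participant_id": str(row["participant_id"]),
                "date": dates.loc[i].normalize(),
                "clock_time": f"{clock.hour:02d}:{clock.minute:02d}",
                "food_group": group,
                "day_kcal": kcal,
            }
        )
    if n_unmapped:
        logger.warning("recall: %d food codes unmapped, coded as 'other'", n_unmapped)
    out = pd.DataFrame(
        rows, columns=["participant_id", "date", "clock_time", "food_group", "day_kcal"]
    )
    if len(out):
        hh = out["clock_time"].str.slice(0, 2).astype(int)
        mm = out["clock_time"].str.slice(3, 5).astype(int)
        out["timestamp"] = out["date"] + pd.to_timedelta(hh * 60 + mm, unit="min")
    else:
        out["timestamp"] = pd.to_datetime(out["date"])
    return out


def _validate_epochs(df: pd.DataFrame) -> pd.DataFrame:
    ts = pd.to_datetime(df["epoch_start"], errors="coerce")
    if ts.isna().any():
        bad = df.loc[ts.isna(), "epoch_start"].iloc[0]
        raise StudyDataError(f"epochs: malformed timestamp {bad!r}")
    counts = pd.to_numeric(df["counts"], errors="coerce")
    if counts.isna().any() or (counts < 0).any():
        raise StudyDataError("epochs: counts must be nonnegative integers")
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"].astype(str),
            "epoch_start": ts,
            "counts": counts.astype(int),
        }
    ).sort_values(["participant_id", "epoch_start"], kind="stable")
    out["date"] = out["epoch_start"].dt.normalize()
    for (pid, date), grp in out.groupby(["participant_id", "date"], sort=False):
        deltas = grp["epoch_start"].diff().dropna()
        irregular = deltas[deltas != pd.Timedelta(minutes=1)]
        if len(irregular):
            j = irregular.index[0]
            prev = grp["epoch_start"].iloc[grp.index.get_loc(j) - 1]
            raise StudyDataError(
                f"epochs: irregular interval for {pid} between "
                f"{prev:%Y-%m-%dT%H:%M} and {grp.loc[j, 'epoch_start']:%Y-%m-%dT%H:%M}"
            )
    return out.reset_index(drop=True)


def load_study(paths, mapping: pd.DataFrame | None = None) -> StudyTables:
    """Load and validate the three study tables.

    ``paths`` is either a directory containing ``prompts.csv``,
    ``recall.csv``, ``epochs.csv`` (and optionally ``participants.csv``),
    or a mapping with those keys. ``mapping`` optionally translates raw
    recall food codes to the six-group vocabulary; unmapped codes are coded
    ``other`` with a logged count. Malformed rows are rejected record by
    record (see ``StudyTables.rejections``); a missing file or an epoch
    stream with an irregular interval is a hard error.
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {
            "prompts": base / "prompts.csv",
            "recall": base / "recall.csv",
            "epochs": base / "epochs.csv",
        }
        if (base / "participants.csv").exists():
            paths["participants"] = base / "participants.csv"
    for key in ("prompts", "recall", "epochs"):
        if key not in paths or not Path(paths[key]).exists():
            raise StudyDataError(f"missing input file for {key!r}")
    rejections: list = []
    prompts = _parse_prompts(pd.read_csv(paths["prompts"]), rejections)
    recalls = _parse_recalls(pd.read_csv(paths["recall"]), mapping, rejections)
    epochs = _validate_epochs(pd.read_csv(paths["epochs"]))
    participants = None
    if "participants" in paths and Path(paths["participants"]).exists():
        participants = pd.read_csv(paths["participants"]).astype({"participant_id": str})
    for table, i, reason in rejections:
        logger.warning("%s row %s rejected: %s", table, i, reason)
    return StudyTables(
        prompts=prompts,
        recalls=recalls,
        epochs=epochs,
        participants=participants,
        rejections=pd.DataFrame(rejections, columns=["table", "row", "reason"]),
    )


class EpochIndex:
    """Fast per-participant window lookup over a validated epoch table."""

    def __init__(self, epochs: pd.DataFrame):
        self._data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for pid, grp in epochs.groupby("participant_id", sort=False):
            mins = (grp["epoch_start"].astype("int64") // 60_000_000_000).to_numpy()
            self._data[str(pid)] = (mins, grp["counts"].to_numpy())

    @staticmethod
    def _minute(t: pd.Timestamp) -> int:
        return int(pd.Timestamp(t).value // 60_000_000_000)

    def window_counts(self, pid: str, start: pd.Timestamp, end: pd.Timestamp) -> np.ndarray:
        """Counts of epochs whose start lies in the half-open [start, end)."""
        if pid not in self._data:
            return np.array([], dtype=int)
        mins, counts = self._data[pid]
        i = np.searchsorted(mins, self._minute(start), side="left")
        j = np.searchsorted(mins, self._minute(end), side="left")
        return counts[i:j]

    def participants(self):
        return self._data.keys()


def wear_minutes(
    epochs: pd.DataFrame, date, zero_run_min: int = 60
) -> int:
    """Minutes of device wear on ``date`` for one participant's epoch table.

    An epoch counts as wear unless it sits inside a run of at least
    ``zero_run_min`` consecutive zero-count epochs (the standard
    consecutive-zero non-wear convention). Returns 0 when the date has no
    epochs.
    """
    date = pd.Timestamp(date).normalize()
    if "date" in epochs.columns:
        day = epochs[epochs["date"] == date]
    else:
        day = epochs[pd.to_datetime(epochs["epoch_start"]).dt.normalize() == date]
    counts = day.sort_values("epoch_start")["counts"].to_numpy()
    if counts.size == 0:
        return 0
    is_zero = counts == 0
    # run-length encode the zero mask
    change = np.flatnonzero(np.diff(is_zero.astype(int)) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [counts.size]))
    nonwear = 0
    for s, e in zip(starts, ends):
        if is_zero[s] and (e - s) >= zero_run_min:
            nonwear += e - s
    return int(counts.size - nonwear)


def filter_diet_days(
    prompts: pd.DataFrame,
    recalls: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    include_retrospective: bool = False,
) -> FilterResult:
    """Select the paired participant-days for the diet arm.

    A participant-day is kept when it has (1) at least one momentary report
    endorsing a food group (real-time prompts only, unless
    ``include_retrospective``) and (2) a recall day whose energy total lies
    in the closed plausibility interval [kcal_min, kcal_max]. The universe
    is every participant-day appearing in either table; kept days and the
    exclusion ledger partition it exactly.
    """
    thresholds = thresholds or FilterThresholds()
    pr = prompts if include_retrospective else prompts[prompts["prompt_type"] == "real_time"]
    has_food = pr[pr["food_groups"] != ""]
    food_days = set(zip(has_food["participant_id"], has_food["date"]))
    prompt_days = set(zip(prompts["participant_id"], prompts["date"]))

    kcal_by_day = (
        recalls.groupby(["participant_id", "date"])["day_kcal"].first()
        if len(recalls)
        else pd.Series(dtype=float)
    )
    universe = sorted(prompt_days | set(kcal_by_day.index))

    kept_rows, ledger_rows = [], []
    for pid, date in universe:
        if (pid, date) not in food_days:
            ledger_rows.append({"participant_id": pid, "date": date, "reason": "no mEMA food entry"})
            continue
        if (pid, date) not in kcal_by_day.index:
            ledger_rows.append({"participant_id": pid, "date": date, "reason": "no recall day"})
            continue
        kcal = float(kcal_by_day.loc[(pid, date)])
        if not (thresholds.kcal_min <= kcal <= thresholds.kcal_max):
            ledger_rows.append(
                {"participant_id": pid, "date": date, "reason": "implausible recall"}
            )
            continue
        kept_rows.append({"participant_id": pid, "date": date, "day_kcal": kcal})
    kept = pd.DataFrame(kept_rows, columns=["participant_id", "date", "day_kcal"])
    ledger = pd.DataFrame(ledger_rows, columns=["participant_id", "date", "reason"])
    return FilterResult(kept=kept, ledger=ledger)


def filter_pa_prompts(
    prompts: pd.DataFrame,
    epochs: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    include_retrospective: bool = False,
) -> FilterResult:
    """Select the prompt-occasions for the activity arm.

    A completed prompt is kept when (a) it has accelerometer coverage on
    both 30-minute flanks, (b) neither flank is entirely zero counts, and
    (c) the participant wore the device at least ``min_wear_hours`` on the
    prompt's day. Retrospective prompts are excluded by default. The kept
    set and the ledger partition the input prompt rows exactly.
    """
    thresholds = thresholds or FilterThresholds()
    index = EpochIndex(epochs)
    wear_cache: dict[tuple[str, pd.Timestamp], int] = {}
    zero_w = pd.Timedelta(minutes=thresholds.zero_window_min)

    kept_idx, ledger_rows = [], []
    for i, row in prompts.iterrows():
        pid, t = row["participant_id"], row["timestamp"]
        if not include_retrospective and row["prompt_type"] == "retrospective":
            ledger_rows.append({"row": i, "participant_id": pid, "timestamp": t, "reason": "retrospective prompt"})
            continue
        before = index.window_counts(pid, t - zero_w, t)
        after = index.window_counts(pid, t, t + zero_w)
        if before.size == 0 or after.size == 0:
            ledger_rows.append({"row": i, "participant_id": pid, "timestamp": t, "reason": "no accelerometry"})
            continue
        if not before.any() or not after.any():
            ledger_rows.append({"row": i, "participant_id": pid, "timestamp": t, "reason": "zero 30-min flank"})
            continue
        key = (pid, row["date"])
        if key not in wear_cache:
            wear_cache[key] = wear_minutes(
                epochs[epochs["participant_id"] == pid],
                row["date"],
                thresholds.nonwear_zero_run_min,
            )
        if wear_cache[key] < thresholds.min_wear_minutes:
            ledger_rows.append({"row": i, "participant_id": pid, "timestamp": t, "reason": "insufficient wear"})
            continue
        kept_idx.append(i)
    kept = prompts.loc[kept_idx].copy()
    ledger = pd.DataFrame(ledger_rows, columns=["row", "participant_id", "timestamp", "reason"])
    return FilterResult(kept=kept, ledger=ledger)
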