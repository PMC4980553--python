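"""Synthetic study cohort generator.

Emulates the data structure of a mobile momentary-assessment validation
study: randomly scheduled prompts in four daily time blocks, true eating
occasions reported both in the moment and through a noisy 24-hour recall,
and a per-minute activity track emitted as accelerometer epoch counts.
Every emitted record traces to ground truth, so downstream match rates and
agreement statistics have known generating values.

The three analysis tables (prompt reports, recall instances, epoch counts)
are plain comma-separated text with ISO-8601 timestamps; see
:meth:`StudyBundle.write` for the file layout shared with the ingest module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as date_cls
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    FOOD_GROUPS,
    PA_LEVELS,
    SEDENTARY_ACTIVITIES,
    CohortConfig,
    ConfigurationError,
)
from .intensity import CUTPOINTS

logger = logging.getLogger(__name__)

#: First monitoring day (a Wednesday; collection ran Wednesday-Saturday).
BASE_DATE = pd.Timestamp("2023-03-01")

#: Hours looked back by the daily retrospective prompt.
RETROSPECTIVE_HOURS = 3

#: Survey availability around the SMS: 5 minutes before to 30 after.
LATENCY_RANGE_MIN = (-5, 30)

_EATING_WINDOW = ("08:00", "22:00")  # true occasions fall in waking hours

PROMPT_COLUMNS = [
    "participant_id",
    "timestamp",
    "prompt_type",
    "behaviors",
    "food_groups",
    "reported_pa_level",
    "sedentary_activity",
]
RECALL_COLUMNS = ["participant_id", "date", "clock_time", "food_group", "day_kcal"]
EPOCH_COLUMNS = ["participant_id", "epoch_start", "counts"]
PARTICIPANT_COLUMNS = ["participant_id", "gender", "race", "pell"]


@dataclass
class GroundTruth:
    """Generating truth behind a synthetic bundle.

    ``true_events`` are all eating occasions (with event ids);
    ``omitted_event_ids`` marks those absent from the recall table;
    ``recall_days`` lists the completed recall days with their energy total;
    ``true_track`` is the per-minute intensity level (wear flag included).
    """

    true_events: pd.DataFrame
    true_track: pd.DataFrame
    omitted_event_ids: np.ndarray
    recall_days: pd.DataFrame


@dataclass
class StudyBundle:
    """One synthetic study: the three analysis tables plus ground truth."""

    config: CohortConfig
    participants: pd.DataFrame
    prompts: pd.DataFrame
    recalls: pd.DataFrame
    epochs: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir) -> dict[str, Path]:
        """Write all tables as comma-separated text; returns the file map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        prompts = self.prompts[PROMPT_COLUMNS].copy()
        prompts["timestamp"] = prompts["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
        paths["prompts"] = outdir / "prompts.csv"
        prompts.to_csv(paths["prompts"], index=False)

        recalls = self.recalls[RECALL_COLUMNS].copy()
        recalls["date"] = pd.to_datetime(recalls["date"]).dt.strftime("%Y-%m-%d")
        paths["recall"] = outdir / "recall.csv"
        recalls.to_csv(paths["recall"], index=False)

        epochs = self.epochs[EPOCH_COLUMNS].copy()
        epochs["epoch_start"] = epochs["epoch_start"].dt.strftime("%Y-%m-%dT%H:%M")
        paths["epochs"] = outdir / "epochs.csv"
        epochs.to_csv(paths["epochs"], index=False)

        paths["participants"] = outdir / "participants.csv"
        self.participants[PARTICIPANT_COLUMNS].to_csv(paths["participants"], index=False)

        truth_events = self.truth.true_events.copy()
        truth_events["timestamp"] = truth_events["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
        truth_events["omitted"] = truth_events["event_id"].isin(self.truth.omitted_event_ids).astype(int)
        paths["truth_events"] = outdir / "truth_events.csv"
        truth_events.to_csv(paths["truth_events"], index=False)

        recall_days = self.truth.recall_days.copy()
        recall_days["date"] = pd.to_datetime(recall_days["date"]).dt.strftime("%Y-%m-%d")
        paths["truth_recall_days"] = outdir / "truth_recall_days.csv"
        recall_days.to_csv(paths["truth_recall_days"], index=False)
        return paths


def _participant_id(i: int) -> str:
    return f"P{i + 1:03d}"


def _schedule_rng(config: CohortConfig, participant: int, day: int) -> np.random.Generator:
    # independent stream per participant-day so schedules are reproducible
    # regardless of generation order
    return np.random.default_rng([config.seed, 7919, participant, day])


def sample_prompt_schedule(config: CohortConfig, participant: int, day: int) -> pd.DataFrame:
    """Draw one day's prompt schedule for a participant.

    Interval-contingent sampling: ``prompts_per_block`` SMS times drawn
    uniformly (minute resolution) within each of the four daily time blocks,
    sorted. The last prompt of the day is flagged retrospective (asks about
    the past 3 hours); all others are real-time. Deterministic for a fixed
    config seed, participant index and day index.

    Returns a frame with columns ``sms_time`` (Timestamp) and
    ``prompt_type`` ('real_time' | 'retrospective').
    """
    config.validate()
    rng = _schedule_rng(config, participant, day)
    day_start = BASE_DATE + pd.Timedelta(days=day)
    times = []
    for start, end in config.blocks():
        lo = start.hour * 60 + start.minute
        hi = end.hour * 60 + end.minute
        offsets = np.sort(rng.integers(lo, hi, size=config.prompts_per_block))
        times.extend(day_start + pd.Timedelta(minutes=int(m)) for m in offsets)
    out = pd.DataFrame({"sms_time": pd.to_datetime(times)})
    out["prompt_type"] = "real_time"
    if len(out):
        out.iloc[-1, out.columns.get_loc("prompt_type")] = "retrospective"
    return out


def apply_recall_noise(
    events: pd.DataFrame, config: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Degrade true eating events into a recall table.

    Each event is independently dropped with ``recall_omission_prob``;
    survivors' clock times are displaced by centred Gaussian noise with SD
    ``recall_time_sd_min`` minutes (clamped to the event's day — recall
    instances stay on the day being recalled). Food groups are preserved.

    ``events`` needs columns participant_id, timestamp, food_group and
    (optionally) event_id; the returned frame carries participant_id, date,
    clock_time, food_group and the surviving event_ids.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    events = events.reset_index(drop=True)
    if "event_id" not in events.columns:
        events = events.assign(event_id=np.arange(len(events)))
    if len(events) == 0:
        return pd.DataFrame(
            columns=["participant_id", "date", "clock_time", "food_group", "event_id"]
        )
    keep = rng.random(len(events)) >= config.recall_omission_prob
    kept = events.loc[keep].copy()
    ts = pd.to_datetime(kept["timestamp"])
    noise = rng.normal(0.0, config.recall_time_sd_min, size=len(kept))
    minutes = ts.dt.hour * 60 + ts.dt.minute + np.round(noise).astype(int)
    minutes = minutes.clip(0, 1439)
    kept["date"] = ts.dt.normalize()
    kept["clock_time"] = [f"{m // 60:02d}:{m % 60:02d}" for m in minutes]
    return kept[["participant_id", "date", "clock_time", "food_group", "event_id"]].reset_index(
        drop=True
    )


def simulate_epoch_counts(
    track: pd.DataFrame, config: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Emit one accelerometer count per 60-s epoch from a true-level track.

    Counts are drawn from a per-level lognormal truncated to the level's
    cut-point band; an independent ``count_spillover`` mass per epoch is
    drawn from the untruncated lognormal, producing controlled
    misclassification. Non-wear minutes emit zero counts. With the default
    parameters at least 90% of wear epochs classify back to their
    generating level.

    ``track`` needs columns participant_id, minute (Timestamp), level and
    (optionally) wear; returns participant_id, epoch_start, counts.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if len(track) == 0:
        return pd.DataFrame(columns=EPOCH_COLUMNS)
    track = track.reset_index(drop=True)
    wear = track["wear"].to_numpy(bool) if "wear" in track.columns else np.ones(len(track), bool)
    counts = np.zeros(len(track), dtype=float)
    spill = rng.random(len(track)) < config.count_spillover
    for level in PA_LEVELS:
        mu, sigma = config.count_params[level]
        if sigma <= 0:
            raise ConfigurationError(f"count_params[{level!r}] needs a positive scale")
        lo, hi = CUTPOINTS[level]
        mask = wear & (track["level"].to_numpy() == level)
        n = int(mask.sum())
        if n == 0:
            continue
        in_band = mask & ~spill
        n_band = int(in_band.sum())
        if n_band:
            a = -np.inf if lo <= 0 else (np.log(lo) - mu) / sigma
            b = np.inf if not np.isfinite(hi) else (np.log(hi) - mu) / sigma
            draws = np.exp(stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n_band, random_state=rng))
            # integer counts, clipped so non-spill epochs stay inside the band
            vals = np.rint(draws)
            vals = np.clip(vals, max(lo, 0.0), hi - 1 if np.isfinite(hi) else np.inf)
            counts[in_band] = vals
        free = mask & spill
        n_free = int(free.sum())
        if n_free:
            counts[free] = np.rint(np.exp(rng.normal(mu, sigma, size=n_free)))
    if (counts < 0).any():
        logger.warning("clamped %d negative epoch counts to 0", int((counts < 0).sum()))
        counts = np.maximum(counts, 0.0)
    return pd.DataFrame(
        {
            "participant_id": track["participant_id"].to_numpy(),
            "epoch_start": pd.to_datetime(track["minute"]),
            "counts": counts.astype(int),
        }
    )


def _simulate_track_day(
    config: CohortConfig, rng: np.random.Generator, pid: str, day_start: pd.Timestamp
) -> pd.DataFrame:
    minutes = day_start + pd.to_timedelta(np.arange(1440), unit="min")
    nonwear = int(round(config.nonwear_hours * 60))
    wear = np.arange(1440) >= nonwear
    levels = np.full(1440, "sedentary", dtype=object)
    n_wear = 1440 - nonwear
    if n_wear > 0:
        bout = max(1, int(config.activity_bout_min))
        n_bouts = int(np.ceil(n_wear / bout))
        bout_levels = rng.choice(PA_LEVELS, size=n_bouts, p=np.asarray(config.pa_level_probs))
        levels[nonwear:] = np.repeat(bout_levels, bout)[:n_wear]
    return pd.DataFrame({"participant_id": pid, "minute": minutes, "level": levels, "wear": wear})


def _assign_events_to_prompts(
    events: pd.DataFrame, prompt_times: pd.Series, window_min: float
) -> dict[int, list[int]]:
    """Credit each true event to the earliest real-time prompt completed
    within ``window_min`` minutes after it (at most one prompt per event)."""
    assignment: dict[int, list[int]] = {}
    if len(events) == 0 or len(prompt_times) == 0:
        return assignment
    pt = prompt_times.sort_values()
    for _, ev in events.iterrows():
        lo, hi = ev["timestamp"], ev["timestamp"] + pd.Timedelta(minutes=window_min)
        covering = pt[(pt >= lo) & (pt <= hi)]
        if len(covering):
            assignment.setdefault(covering.index[0], []).append(int(ev["event_id"]))
    return assignment


def generate_cohort(config: CohortConfig) -> StudyBundle:
    """Generate a full synthetic study bundle.

    Deterministic given config (including its seed): identical configs give
    byte-identical written bundles. See the module docstring for the data
    model; the bundle is accepted unchanged by ``ingest.load_study``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 104729])
    e_lo = int(_EATING_WINDOW[0][:2]) * 60
    e_hi = int(_EATING_WINDOW[1][:2]) * 60

    participants = pd.DataFrame(
        {
            "participant_id": [_participant_id(i) for i in range(config.n_participants)],
            "gender": np.where(rng.random(config.n_participants) < config.p_female, "female", "male"),
            "race": np.where(rng.random(config.n_participants) < config.p_white, "white", "nonwhite"),
            "pell": np.where(rng.random(config.n_participants) < config.p_pell, "yes", "no"),
        }
    )

    prompt_rows, event_rows, track_frames = [], [], []
    event_counter = 0
    misreport = np.asarray(config.misreport_matrix, dtype=float)
    level_index = {lv: i for i, lv in enumerate(PA_LEVELS)}

    for p in range(config.n_participants):
        pid = _participant_id(p)
        for d in range(config.n_days):
            day_start = BASE_DATE + pd.Timedelta(days=d)
            track = _simulate_track_day(config, rng, pid, day_start)
            track_frames.append(track)
            day_levels = track["level"].to_numpy()

            # true eating occasions
            n_events = rng.poisson(config.eating_rate)
            if n_events:
                offs = np.sort(rng.integers(e_lo, e_hi, size=n_events))
                groups = rng.choice(FOOD_GROUPS, size=n_events, p=np.asarray(config.food_group_probs))
                for off, grp in zip(offs, groups):
                    event_rows.append(
                        {
                            "event_id": event_counter,
                            "participant_id": pid,
                            "timestamp": day_start + pd.Timedelta(minutes=int(off)),
                            "food_group": grp,
                        }
                    )
                    event_counter += 1

            schedule = sample_prompt_schedule(config, p, d)
            answered = rng.random(len(schedule)) < config.prompt_response_prob
            latencies = rng.integers(LATENCY_RANGE_MIN[0], LATENCY_RANGE_MIN[1] + 1, size=len(schedule))
            day_events = pd.DataFrame([r for r in event_rows if r["participant_id"] == pid])
            if len(day_events):
                day_events = day_events[day_events["timestamp"].dt.normalize() == day_start]

            completed = schedule.loc[answered].copy()
            completed["timestamp"] = completed["sms_time"] + pd.to_timedelta(
                latencies[answered], unit="min"
            )
            rt = completed[completed["prompt_type"] == "real_time"]
            assignment = _assign_events_to_prompts(
                day_events, rt["timestamp"], config.eating_report_window_min
            )

            for idx, row in completed.iterrows():
                minute_of_day = int(
                    (row["timestamp"] - day_start).total_seconds() // 60
                )
                minute_of_day = int(np.clip(minute_of_day, 0, 1439))
                true_level = day_levels[minute_of_day]
                reported = rng.choice(PA_LEVELS, p=misreport[level_index[true_level]])
                if row["prompt_type"] == "retrospective":
                    lo = row["timestamp"] - pd.Timedelta(hours=RETROSPECTIVE_HOURS)
                    if len(day_events):
                        in_win = day_events[
                            (day_events["timestamp"] >= lo)
                            & (day_events["timestamp"] <= row["timestamp"])
                        ]
                        groups = sorted(set(in_win["food_group"]))
                    else:
                        groups = []
                else:
                    ev_ids = assignment.get(idx, [])
                    if ev_ids and len(day_events):
                        sub = day_events[day_events["event_id"].isin(ev_ids)]
                        groups = sorted(set(sub["food_group"]))
                    else:
                        groups = []
                behaviors = []
                if groups:
                    behaviors.append("eating")
                if rng.random() < config.drinking_prob:
                    behaviors.append("drinking")
                if reported != "sedentary":
                    behaviors.append("physically_active")
                if not behaviors:
                    behaviors = ["none"]
                sedentary_activity = (
                    rng.choice(SEDENTARY_ACTIVITIES) if reported == "sedentary" else ""
                )
                prompt_rows.append(
                    {
                        "participant_id": pid,
                        "timestamp": row["timestamp"],
                        "prompt_type": row["prompt_type"],
                        "behaviors": ";".join(behaviors),
                        "food_groups": ";".join(groups),
                        "reported_pa_level": reported,
                        "sedentary_activity": sedentary_activity,
                    }
                )

    prompts = pd.DataFrame(prompt_rows, columns=PROMPT_COLUMNS)
    if len(prompts):
        prompts = prompts.sort_values(["participant_id", "timestamp"], kind="stable").reset_index(
            drop=True
        )
    true_events = pd.DataFrame(
        event_rows, columns=["event_id", "participant_id", "timestamp", "food_group"]
    )
    if len(true_events) == 0:
        true_events = true_events.astype({"timestamp": "datetime64[ns]"})
    true_events["date"] = pd.to_datetime(true_events["timestamp"]).dt.normalize()
    track = pd.concat(track_frames, ignore_index=True) if track_frames else pd.DataFrame(
        columns=["participant_id", "minute", "level", "wear"]
    )
    epochs = simulate_epoch_counts(track, config, rng)

    # recall: each participant completes 1-3 recall days (random subset)
    recall_day_rows = []
    for p in range(config.n_participants):
        pid = _participant_id(p)
        n_recall = int(rng.choice([1, 2, 3], p=np.asarray(config.recall_days_probs)))
        n_recall = min(n_recall, config.n_days)
        days = sorted(rng.choice(config.n_days, size=n_recall, replace=False)) if n_recall else []
        for d in days:
            if rng.random() < config.implausible_kcal_prob:
                kcal = (
                    float(rng.integers(100, 481))
                    if rng.random() < 0.9
                    else float(rng.integers(5200, 6001))
                )
            else:
                lo, hi = config.day_kcal_range
                kcal = float(np.round(rng.uniform(lo, hi)))
            recall_day_rows.append(
                {"participant_id": pid, "date": BASE_DATE + pd.Timedelta(days=int(d)), "day_kcal": kcal}
            )
    recall_days = pd.DataFrame(recall_day_rows, columns=["participant_id", "date", "day_kcal"])

    if len(true_events) and len(recall_days):
        keys = set(zip(recall_days["participant_id"], recall_days["date"]))
        on_recall_days = true_events[
            [
                (pid, dt) in keys
                for pid, dt in zip(true_events["participant_id"], true_events["date"])
            ]
        ]
    else:
        on_recall_days = true_events.iloc[0:0]
    recalls = apply_recall_noise(on_recall_days, config, rng)
    omitted = np.setdiff1d(
        on_recall_days["event_id"].to_numpy(int) if len(on_recall_days) else np.array([], int),
        recalls["event_id"].to_numpy(int) if len(recalls) else np.array([], int),
    )
    recalls = recalls.merge(recall_days, on=["participant_id", "date"], how="left")
    recalls = recalls[RECALL_COLUMNS + ["event_id"]]

    truth = GroundTruth(
        true_events=true_events,
        true_track=track,
        omitted_event_ids=omitted,
        recall_days=recall_days,
    )
    return StudyBundle(
        config=config,
        participants=participants,
        prompts=prompts,
        recalls=recalls,
        epochs=epochs,
        truth=truth,
    )


def zero_noise_config(**overrides) -> CohortConfig:
    """A cohort config in which every noise source is switched off.

    No recall omission or time displacement, perfect intensity reporting
    (identity misreport matrix), no count spill-over, full prompt response,
    full-day wear, and one constant intensity level per participant-day so
    every pre-prompt window is homogeneous. Under this config both analysis
    arms agree perfectly: day-level match rates are 100% for every food
    group present and the reported-vs-derived cross-tab is diagonal.
    """
    base = dict(
        recall_omission_prob=0.0,
        recall_time_sd_min=0.0,
        misreport_matrix=np.eye(4).tolist(),
        count_spillover=0.0,
        prompt_response_prob=1.0,
        implausible_kcal_prob=0.0,
        nonwear_hours=0.0,
        activity_bout_min=1440,
    )
    base.update(overrides)
    return CohortConfig(**base)
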