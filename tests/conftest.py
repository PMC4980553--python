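import numpy as np
import pandas as pd
import pytest

from emaval import CohortConfig, generate_cohort, load_study, zero_noise_config


@pytest.fixture(scope="session")
def small_bundle():
    """A small noisy cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(n_participants=8, n_days=2, seed=3))


@pytest.fixture(scope="session")
def small_tables(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    small_bundle.write(outdir)
    return load_study(outdir)


@pytest.fixture(scope="session")
def zero_noise_tables(tmp_path_factory):
    bundle = generate_cohort(zero_noise_config(n_participants=6, n_days=2, seed=11))
    outdir = tmp_path_factory.mktemp("zero_noise")
    bundle.write(outdir)
    return load_study(outdir)


def make_prompts(rows):
    """Prompt frame from (pid, iso_timestamp, food_groups, level) tuples."""
    recs = []
    for pid, ts, groups, level in rows:
        behaviors = []
        if groups:
            behaviors.append("eating")
        if level != "sedentary":
            behaviors.append("physically_active")
        recs.append(
            {
                "participant_id": pid,
                "timestamp": pd.Timestamp(ts),
                "prompt_type": "real_time",
                "behaviors": ";".join(behaviors) or "none",
                "food_groups": groups,
                "reported_pa_level": level,
                "sedentary_activity": "",
            }
        )
    out = pd.DataFrame(recs)
    out["date"] = out["timestamp"].dt.normalize()
    return out


def make_recalls(rows):
    """Recall frame from (pid, iso_date, clock, group, kcal) tuples."""
    out = pd.DataFrame(
        rows, columns=["participant_id", "date", "clock_time", "food_group", "day_kcal"]
    )
    out["date"] = pd.to_datetime(out["date"])
    hh = out["clock_time"].str.slice(0, 2).astype(int)
    mm = out["clock_time"].str.slice(3, 5).astype(int)
    out["timestamp"] = out["date"] + pd.to_timedelta(hh * 60 + mm, unit="min")
    return out


def make_epochs(pid, start, counts):
    """Contiguous 60-s epoch frame from a counts sequence."""
    start = pd.Timestamp(start)
    out = pd.DataFrame(
        {
            "participant_id": pid,
            "epoch_start": start + pd.to_timedelta(np.arange(len(counts)), unit="min"),
            "counts": np.asarray(counts, dtype=int),
        }
    )
    out["date"] = out["epoch_start"].dt.normalize()
    return out
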