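"""Freedson cut points: accelerometer counts-per-minute intensity bands.

The four bands partition the nonnegative reals: sedentary < 100 CPM,
light 100-1951 CPM, moderate 1952-5724 CPM, vigorous >= 5725 CPM.
"""

from __future__ import annotations

import numpy as np

from .config import PA_LEVELS

#: level -> [lower, upper) band in counts per minute.
CUTPOINTS: dict[str, tuple[float, float]] = {
    "sedentary": (0.0, 100.0),
    "light": (100.0, 1952.0),
    "moderate": (1952.0, 5725.0),
    "vigorous": (5725.0, np.inf),
}

_EDGES = np.array([100.0, 1952.0, 5725.0])


def classify_intensity(cpm):
    """Classify counts-per-minute into an intensity level.

    Accepts a scalar or array; returns the level name(s). Boundaries go to
    the higher band: 100 -> light, 1952 -> moderate, 5725 -> vigorous.

    Raises
    ------
    ValueError
        If any input is negative or non-finite.
    """
    arr = np.asarray(cpm, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("counts per minute must be finite and nonnegative")
    idx = np.searchsorted(_EDGES, arr, side="right")
    if arr.ndim == 0:
        return PA_LEVELS[int(idx)]
    return np.asarray(PA_LEVELS, dtype=object)[idx]
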