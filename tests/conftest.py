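"""Shared fixtures: seeded patches and a measure-level study simulator."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter

MEASURES = ("SampEn", "FuzzEn", "PermEn", "DispEn", "DistEn")
COMPONENTS = ("gray", "red", "green", "blue")
ROIS = ("ROI1_withers", "ROI2_thoracic")
GROUPS = ("L", "M", "H")


def smooth_noise_patch(seed: int, shape=(16, 16), smooth_sd: float = 4.0,
                       noise_amp: float = 1.0, scale: float = 2.0) -> np.ndarray:
    """Smooth correlated background plus i.i.d. noise, float valued."""
    rng = np.random.default_rng(seed)
    bg = gaussian_filter(rng.standard_normal(shape), scale)
    sd = bg.std()
    if sd > 0:
        bg *= smooth_sd / sd
    return 100.0 + bg + noise_amp * rng.standard_normal(shape)


@pytest.fixture
def smooth_patch():
    return smooth_noise_patch(0, (16, 16))


def simulate_measure_table(
    seed: int,
    affected: set[tuple[str, str]] | None = None,
    prepost_shift: float = 1.5,
    group_slope: float = 0.0,
    n_horses: int = 12,
    pair_corr: float = 0.5,
) -> pd.DataFrame:
    """Tidy measure table emulating the study at the measure level.

    One value per (horse, rider, session, roi, component, measure); the
    combinations in ``affected`` (keys (measure, component)) get a
    ``prepost_shift``-SD post-exercise shift in every group, plus
    ``group_slope`` times the group index (0/1/2 for L/M/H) so group
    dependence can be planted too.  Pre/post values share a horse-level
    random effect (``pair_corr``) to emulate pairing.
    """
    rng = np.random.default_rng(seed)
    affected = affected or set()
    riders = [(f"rider{i}", g) for i, g in enumerate(["L", "L", "M", "M", "H", "H"], 1)]
    rows = []
    for roi in ROIS:
        for comp in COMPONENTS:
            for meas in MEASURES:
                hit = (meas, comp) in affected or (meas, comp, roi) in affected
                for h in range(n_horses):
                    for rider, g in riders:
                        base = np.sqrt(pair_corr) * rng.standard_normal()
                        eps = np.sqrt(1 - pair_corr)
                        gi = GROUPS.index(g)
                        pre = base + eps * rng.standard_normal()
                        post = base + eps * rng.standard_normal()
                        if hit:
                            post += prepost_shift + group_slope * gi
                        for session, value in (("pre", pre), ("post", post)):
                            rows.append(
                                {
                                    "horse": f"horse{h + 1:02d}", "rider": rider,
                                    "group": g, "session": session, "roi": roi,
                                    "component": comp, "measure": meas,
                                    "kind": "entropy", "value": value,
                                    "ratio_pct": 11.2 + 2.85 * gi + 0.1 * rng.standard_normal(),
                                }
                            )
    return pd.DataFrame(rows)
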