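import numpy as np
import pandas as pd
import pytest

import nightscan as ns


def small_cells(per_cell: int = 2) -> dict:
    """A minimal design: `per_cell` plants in every (period, fert, group) cell."""
    return {
        (p, f, a): per_cell
        for p in ns.synth_scene.PERIODS
        for f in ns.synth_scene.FERTILIZERS
        for a in (False, True)
    }


@pytest.fixture()
def tiny_config() -> ns.SceneConfig:
    return ns.SceneConfig(
        crop="bok_choy", plants_per_cell=small_cells(2), pixels_per_plant=20, seed=42
    )


@pytest.fixture(scope="session")
def bok_profiles() -> pd.DataFrame:
    """Default bok choy campaign (344 profiles, native 116-band grid)."""
    profiles, _ = ns.simulate_dataset(ns.bok_choy_preset(seed=1))
    return profiles


@pytest.fixture(scope="session")
def bok_deriv(bok_profiles) -> pd.DataFrame:
    """31-band derivative profiles of the default bok choy campaign."""
    return ns.profiles_to_derivatives(bok_profiles)


@pytest.fixture(scope="session")
def bok_screen(bok_deriv):
    """Full 31x3 band screen of the default bok choy campaign."""
    return ns.screen_all(bok_deriv, crop="bok_choy")


@pytest.fixture(scope="session")
def separable_frame() -> pd.DataFrame:
    """15 classes, 8 profiles each, far apart in feature space.

    Feature means are far larger than the within-class spread, so any sane
    linear classifier separates them perfectly.
    """
    rng = np.random.default_rng(0)
    rows = []
    pid = 0
    for code in range(1, 16):
        period, fert, inf = ns.decode_class(code)
        for k in range(8):
            pid += 1
            rows.append(
                {
                    "plant_id": pid,
                    "series": 1 if k < 4 else 2,
                    "period": period,
                    "fertilizer": fert,
                    "infested": inf,
                    "assigned": inf or (period == "baseline" and k % 2 == 0),
                    "n_pixels": 1,
                }
            )
    frame = pd.DataFrame(rows)
    codes = np.array([ns.encode_class(p, f, i) for p, f, i in
                      zip(frame.period, frame.fertilizer, frame.infested)])
    # one indicator feature per class: classes sit far apart along
    # mutually orthogonal directions
    for j in range(15):
        frame[f"d{700 + j:.2f}"] = 10.0 * (codes == j + 1) + rng.normal(
            0, 0.01, len(frame)
        )
    return frame
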