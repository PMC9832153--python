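"""Regenerate the bundled `study_2017` calibration constants.

Run from the repository root:

    python scripts/calibrate_study.py

Deterministic: uses fixed internal seeds.  Prints the calibrated structural
bin effects, redistribution mixture weight and frozen ground truth to paste
into ``src/heatrhythm/fixtures.py``.
"""

from __future__ import annotations

import logging
import pprint

import numpy as np

from heatrhythm.calibrate import (
    ClimateSample,
    calibrate,
    daily_estimand,
    hourly_estimand,
    implied_timeshift,
    profile_estimands,
)
from heatrhythm.fixtures import STUDY_2017_BIN_EFFECTS, study_2017_config
from heatrhythm.synth import dense_timeshift

N_REPS = 48
N_REPS_TRUTH = 72  # larger sample for the frozen truth evaluation

DT_TARGET_MINUTES = 27.0


def main() -> None:
    logging.basicConfig(level=logging.INFO)
    base = study_2017_config()
    calibrated = calibrate(
        base,
        targets=dict(STUDY_2017_BIN_EFFECTS),
        dt_target_minutes=DT_TARGET_MINUTES,
        n_reps=N_REPS,
        n_outer=4,
    )

    # Evaluate the frozen truth on a larger independent climate sample.
    sample = ClimateSample(base, n_reps=N_REPS_TRUTH, seed=20269001)
    est = hourly_estimand(calibrated, sample)
    q = daily_estimand(calibrated, sample)
    profiles = profile_estimands(calibrated, sample)
    dt = {}
    for g, prof in profiles.items():
        if g == "15-20":
            dt[g] = 0.0
        elif g in q:
            try:
                dt[g] = round(
                    dense_timeshift(profiles["15-20"], prof, q[g], 20.0), 3
                )
            except Exception:
                dt[g] = None

    print("\n# ---- paste into src/heatrhythm/fixtures.py ----\n")
    print("STUDY_2017_DIRECT_EFFECTS =")
    pprint.pprint({k: round(v, 6) for k, v in calibrated.direct_bin_effects.items()})
    print("\nSTUDY_2017_MIX_MAX =", round(calibrated.profile.mix_max, 6))
    print("\n# verification on the larger sample:")
    print("hourly estimand:", {k: round(v, 5) for k, v in est.items()})
    print("targets:        ", {k: round(v, 5) for k, v in STUDY_2017_BIN_EFFECTS.items()})
    print("\nSTUDY_2017_TRUTH q:", {k: round(v, 5) for k, v in q.items()})
    print("STUDY_2017_TRUTH dt:", dt)
    print("STUDY_2017_TRUTH profiles:")
    pprint.pprint({g: np.round(p, 6).tolist() for g, p in profiles.items()})


if __name__ == "__main__":
    main()
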