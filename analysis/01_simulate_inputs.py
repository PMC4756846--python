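"""Generate every synthetic input the downstream analyses consume.

Writes, under scratch/inputs/: bivariate induction matrices (long CSV, 3
replicates, 5% multiplicative noise) for the three model systems,
post-induction expression/growth time courses, a two-stage calibration
table pair, and uninduced/induced cytometry event samples.
"""

import numpy as np

from common import INPUTS, MU, RATES, SEED, SYSTEMS, matrix_path
from gatefit import (
    NoiseModel,
    simulate_calibration,
    simulate_events,
    simulate_matrix,
    simulate_timecourse,
)
from gatefit import io as gio


def main() -> None:
    INPUTS.mkdir(parents=True, exist_ok=True)
    header = gio.provenance_header(seed=SEED)

    for idx, (name, params) in enumerate(SYSTEMS.items()):
        m = simulate_matrix(
            params, replicates=3, noise=NoiseModel(cv=0.05, seed=SEED + idx)
        )
        gio.write_matrix(m, matrix_path(name), dialect="long", header=header)
        print(f"{name}: {m.i_levels.size}x{m.p_levels.size} grid, "
              f"{m.n_replicates} replicates -> {matrix_path(name).name}")

    for idx, name in enumerate(SYSTEMS):
        tc = simulate_timecourse(
            rate=RATES[name], mu=MU[name], od0=0.8,
            t_grid=np.linspace(0, 5, 11),
            noise=NoiseModel(cv=0.05, seed=SEED + 10 + idx),
        )
        tc.condition.update({"replicate": 0})
        gio.write_timecourse(tc, INPUTS / f"timecourse_{name}.csv", header=header)
        print(f"{name}: time course 0-5 h at {RATES[name]:.0f} RFU/OD/h")

    standards, samples = simulate_calibration(
        slope1=2.0, slope2=10.0, n_points=8, noise=NoiseModel(cv=0.03, seed=SEED + 20)
    )
    standards.to_csv(INPUTS / "calibration_standards.csv", index=False)
    samples.to_csv(INPUTS / "calibration_samples.csv", index=False)
    print("calibration: 8 standards spanning 70-500 ng")

    # uninduced reference plus a well-induced, mostly-homogeneous population
    ref = simulate_events([1.0], [np.log(8.0)], [0.35], n_events=100_000,
                          seed=SEED + 30)
    induced = simulate_events(
        [0.08, 0.92], [np.log(8.0), np.log(2500.0)], [0.35, 0.30],
        n_events=100_000, seed=SEED + 31,
    )
    ref.condition["sample_id"] = "uninduced"
    induced.condition["sample_id"] = "induced"
    gio.write_events(ref, INPUTS / "events_uninduced.csv", header=header)
    gio.write_events(induced, INPUTS / "events_induced.csv", header=header)
    print("cytometry: 100000 events per sample (uninduced + induced)")


if __name__ == "__main__":
    main()
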