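#!/usr/bin/env python
"""Generate the synthetic study dataset every later stage consumes.

Emulates the field design: 42 biannual trapping occasions (October 1993
to May 2014, alternating 7-month winters and 5-month summers), two sexes
with sex-specific capture probabilities, season-specific monthly survival
and recruitment, Mediterranean daily weather, and a smooth ENSO-like index.
Writes encounter histories (.inp), long-format capture records, the
occasion calendar, daily weather, the ONI series and the generating truth
under results/synthetic/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import pradelts as pt

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20140501


def synthetic_oni(calendar, seed):
    """AR(1) ENSO-like anomaly on the monthly grid spanning the study."""
    rng = np.random.default_rng(seed)
    idx = pd.period_range(calendar.dates[0] - 8, calendar.dates[-1], freq="M")
    x = np.empty(len(idx))
    x[0] = rng.normal(0, 0.5)
    for i in range(1, len(idx)):
        x[i] = 0.93 * x[i - 1] + rng.normal(0, 0.22)
    return pd.Series(np.round(x, 2), index=idx, name="oni")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = pt.SimulationConfig(
        seed=SEED,
        n_initial=320,
        phi_m=dict(pt.recovery.SEASON["phi_m"]),
        f_m=dict(pt.recovery.SEASON["f_m"]),
        p=dict(pt.recovery.SEX_P),
    )
    pop = pt.simulate_population(cfg)
    chs = pop.histories

    pt.write_inp(chs, OUT / "histories.inp")
    pt.records_from_population(pop).to_csv(OUT / "records.csv", index=False)
    cfg.calendar.to_csv(OUT / "calendar.csv")
    weather = pt.simulate_weather(cfg)
    weather.to_csv(OUT / "weather.csv", index=False)
    oni = synthetic_oni(cfg.calendar, SEED + 2)
    oni.rename_axis("month").reset_index().assign(
        month=lambda d: d.month.astype(str)
    ).to_csv(OUT / "oni.csv", index=False)

    truth = {
        "seed": SEED,
        "n_initial": cfg.n_initial,
        "phi_m": pt.recovery.SEASON["phi_m"],
        "f_m": pt.recovery.SEASON["f_m"],
        "p": pt.recovery.SEX_P,
        "n_marked": pop.n_marked(),
        "realized_n": pop.realized_n.tolist(),
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2))

    print(f"calendar: {cfg.calendar}")
    print(f"marked adults: {pop.n_marked()} "
          f"({chs.total_individuals('F')} F, {chs.total_individuals('M')} M)")
    print(f"distinct history patterns: {chs.n_patterns}")
    print(f"realized abundance: start {pop.realized_n[0]}, "
          f"max {pop.realized_n.max()}, end {pop.realized_n[-1]}")
    print(f"wrote {len(list(OUT.iterdir()))} files to {OUT}")


if __name__ == "__main__":
    main()
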