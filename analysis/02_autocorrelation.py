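#!/usr/bin/env python
"""Positional autocorrelation of the simulated tracks.

Computes each individual's empirical semivariogram and the minimum number
of days until the autocorrelation becomes insignificant (variogram within
2 SE of its plateau).  The headline finding this reproduces: time to
independence far exceeds even the coarsest tracking regime (one fix per
month), so thinning alone cannot satisfy the independence assumption of
kernel density estimators.  Outputs a per-individual CSV plus one
variogram CSV per individual.
"""

import argparse
from pathlib import Path

import pandas as pd

from herpranges.landscape import generate_fbm_landscape
from herpranges.movement import simulate_population
from herpranges.variogram import empirical_variogram, time_to_independence

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n-per-species", type=int, default=3)
parser.add_argument("--out-dir", type=Path, default=Path("results/autocorrelation"))
args = parser.parse_args()

args.out_dir.mkdir(parents=True, exist_ok=True)
land = generate_fbm_landscape(512, 512, 10.0, hurst=0.5, seed=args.seed)
pop = simulate_population(land, n_per_species=args.n_per_species, seed=args.seed)

rows = []
for tr in pop:
    vg = time_to_independence(empirical_variogram(tr, n_lag_bins=30))
    pd.DataFrame(
        {"lag_s": vg.lag_s, "gamma_m2": vg.gamma, "n_pairs": vg.n_pairs}
    ).to_csv(args.out_dir / f"variogram_{tr.individual_id}.csv", index=False)
    rows.append(
        dict(
            species=tr.species_id,
            individual_id=tr.individual_id,
            independence_days=vg.independence_days,
            censored=vg.censored,
        )
    )
df = pd.DataFrame(rows)
df.to_csv(args.out_dir / "independence_days.csv", index=False)
print(df.to_string(index=False))
print(
    "\nindividuals with autocorrelation outlasting the coarsest regime (30 d): "
    f"{(df['independence_days'] > 30).sum()} / {len(df)}"
)
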