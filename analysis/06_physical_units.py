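#!/usr/bin/env python
"""Convert the best fit to biological units with the study's calibration.

Mutation rate from outgroup synonymous divergence 0.058 over an 18.4 MY
split at 4-year generations (6.3e-9 /bp/generation); the ancestral size
follows from N_A = theta/(4 mu L) with L the callable synonymous length of
the dataset; sizes then scale to diploid individuals, times to years, and
migration to per-generation fractions and effective migrants per generation.

Reads results/fits/ and results/sfs/, writes results/units/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from newtflow.models import model_registry
from newtflow.units import CalibrationInputs, physical_params

best = pd.read_csv("results/fits/bic.tsv", sep="\t").model.iloc[0]
d = json.load(open(f"results/fits/fit_{best}.json"))
meta = json.load(open("results/sfs/sfs_meta.json"))
m = model_registry(best)
params = np.array([d["params"][n] for n in m.param_names])

calib = CalibrationInputs(divergence=0.058, split_years=18.4e6,
                          gen_years=4.0, L=meta["L"])
table = physical_params(m, params, d["theta"], calib)

out = Path("results/units")
out.mkdir(parents=True, exist_ok=True)
table.to_csv(out / "physical_params.tsv", sep="\t", index=False)

print(f"calibration: mu = {calib.mu:.3g} /bp/gen, L = {meta['L']} bp, "
      f"theta = {d['theta']:.1f}")
for row in table.itertuples():
    print(f"  {row.parameter:28s} {row.value:.4g}")
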