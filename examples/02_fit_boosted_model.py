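"""Fit the boosted stump ensemble and inspect one predictor's effect.

The model is MP = f(X1..X10): a 400-stump ensemble fitted to untransformed
counts with shrinkage 0.1 and 50% row subsampling (the survey
configuration ntrees=400, depth=1, minobs=10).
"""

import numpy as np

import seabedlitter as sl

table, _ = sl.generate_station_dataset(n=56, seed=1)
params = sl.BoostParams(ntrees=400, depth=1, minobs=10, seed=0)
model = sl.fit_boosted_model(table, "mp_count", sl.DEFAULT_PREDICTORS, params)

resid = table.mp_count.to_numpy() - model.predict(table)
print(f"ensemble of {model.ntrees} stumps, baseline {model.baseline:.0f} particles/kg")
print(f"training MAE: {np.abs(resid).mean():.0f} particles/kg")

# partial dependence: average prediction with one predictor clamped to a
# grid, all other predictors held at their observed station values
grid = np.linspace(-2, 2, 5)
_, curve = sl.partial_dependence(model, table, "wave_orbital_velocity", grid)
print("partial dependence of wave_orbital_velocity:")
for v, c in zip(grid, curve):
    print(f"  x = {v:+.1f} -> mean prediction {c:.0f} particles/kg")
# A rising curve means the model attributes higher storage potential to
# stations with larger values of that predictor, other things equal.
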