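#!/usr/bin/env python
"""Deviation, fluctuation, size and shape of the study ensemble.

Computes the per-frame backbone RMSD against the first frame, per-residue
Cα RMSF, the radius of gyration with gyration-tensor shape descriptors,
and the mean Cα–Cα contact map.  Tables land in results/.
"""

import pandas as pd

from idpkit.geometry import rmsd_series, rmsf, shape_series
from idpkit.interactions import contact_map

from _study import RESULTS, get_ensemble

traj, _ = get_ensemble()

r = rmsd_series(traj, selection="backbone")
per_frame, shape_summary = shape_series(traj, selection="protein")
stats = pd.DataFrame({
    "statistic": ["mean", "sd", "max"],
    "rmsd": [r.mean(), r.std(), r.max()],
    "rg": [per_frame["rg"].mean(), per_frame["rg"].std(),
           per_frame["rg"].max()],
}).set_index("statistic").round(3)
stats.to_csv(RESULTS / "rmsd_rg_stats.csv")

fluct = rmsf(traj, selection="calpha").round(3)
fluct.to_csv(RESULTS / "rmsf_per_residue.csv", index=False)
shape_summary.round(4).to_csv(RESULTS / "shape_descriptors.csv")
contact_map(traj).round(2).to_csv(RESULTS / "contact_map.csv")

print(stats.to_string())
print("\nmean anisotropy: %.3f (0 = rod ... 1 = sphere-symmetric)"
      % shape_summary.loc["mean", "anisotropy"])
print("most mobile residue: %s%d (RMSF %.2f Å); least mobile: %s%d (%.2f Å)"
      % (*fluct.loc[fluct.rmsf.idxmax(), ["residue_name", "residue_index",
                                          "rmsf"]],
         *fluct.loc[fluct.rmsf.idxmin(), ["residue_name", "residue_index",
                                          "rmsf"]]))
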