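"""Negative-vs-positive group comparison on synthetic feature tables.

Builds a feature table with planted group shifts in ten features (the
pattern reported for bleeding vs non-bleeding records) and runs the
Mann-Whitney comparison with the flat p < 0.01 rule.
"""

import numpy as np
import pandas as pd

from ppgrisk import group_report

rng = np.random.default_rng(0)
n = 200

# negative-group feature distributions; ten features get a shift in the
# positive group (bleeding records): earlier/weaker reflected wave and
# lower harmonic power
shifted = {"Td": -7.0, "RI": +0.032, "Rarea": -0.013, "W50": +10.0,
           "H1": -0.014, "H2": -0.021, "H3": -0.021, "H4": -0.028,
           "H5": -0.033, "Eall": -3.5}
scales = {"Td": 45.0, "RI": 0.103, "Rarea": 0.106, "W50": 71.0, "H1": 0.062,
          "H2": 0.078, "H3": 0.132, "H4": 0.127, "H5": 0.130, "Eall": 5.9}

cols = {}
for name, sd in scales.items():
    base = rng.normal(0.0, sd, size=2 * n)
    base[n:] += shifted[name] * 6  # exaggerated shift for this small demo
    cols[name] = base
for extra in ("Tp", "HR", "SI", "VDab", "VDae"):
    cols[extra] = rng.normal(0.0, 1.0, size=2 * n)
table = pd.DataFrame(cols)
table["event_label"] = np.repeat([0, 1], n)

rows = group_report(table)
print(f"{'feature':>8s}  {'neg mean±SD':>16s}  {'pos mean±SD':>16s} "
      f"{'p':>9s}  sig")
for r in rows:
    print(f"{r.feature:>8s}  {r.mean_neg:8.3f}±{r.sd_neg:6.3f} "
          f"{r.mean_pos:9.3f}±{r.sd_pos:6.3f} {r.p_value:9.2e}   "
          f"{'*' if r.significant else ''}")
n_sig = sum(r.significant for r in rows)
print(f"\n{n_sig} features significant at p < 0.01 "
      "(the ten with planted shifts should be flagged; the rest not)")
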