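"""The HAS-BLED clinical baseline scorer.

One point per risk factor; 0-2 is low bleeding risk, >= 3 increased.
"""

from ppgrisk import hasbled_score
from ppgrisk.io import HASBLED_FACTORS

patients = {
    "well-controlled": (),
    "two factors": ("hypertension", "age_over_65"),
    "boundary case": ("hypertension", "age_over_65", "bleeding_history"),
    "heavily loaded": ("hypertension", "age_over_65", "bleeding_history",
                       "labile_inr", "stroke"),
}
for name, present in patients.items():
    factors = {f: f in present for f in HASBLED_FACTORS}
    score, risk = hasbled_score(factors)
    print(f"{name:>16s}: score {score}  ->  {risk} risk")
print("\nThe class flips from low to increased exactly at a score of 3.")
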