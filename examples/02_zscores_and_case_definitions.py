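"""LMS z-scores and malnutrition case definitions.

A growth reference gives, for each sex and age, the Box-Cox power L, the
median M and the coefficient of variation S of a measurement; the z-score
of an observed value x is ((x/M)^L - 1)/(L*S).  A child is wasted/stunted
when the relevant z-score is strictly below -2, and has low MUAC when the
mid-upper arm circumference is strictly below 125 mm.
"""

import pandas as pd

from nutsurv import LMSReference, classify, lms_zscore

# a height-for-age style reference point: median 87 cm at some sex/age
z = lms_zscore(80.0, L=0.5, M=87.0, S=0.035)
print(f"height 80 cm against median 87 cm -> z = {z:.3f}")  # about -2.35: stunted

flags = classify(whz=-2.01, haz=z, muac_mm=126.0)
print(f"wasted={flags.wasted}, stunted={flags.stunted}, low_muac={flags.low_muac}")

# boundaries are strict: exactly -2 / exactly 125 mm is NOT a case
boundary = classify(whz=-2.0, haz=-2.0, muac_mm=125.0)
print(f"at the boundary: wasted={boundary.wasted}, stunted={boundary.stunted}, "
      f"low_muac={boundary.low_muac}")

# references are pluggable: load a (here synthetic) sex x age LMS table
ref = LMSReference(pd.DataFrame({
    "sex": ["male", "female"], "age_months": [24, 24],
    "L": [0.2, 0.25], "M": [87.0, 85.5], "S": [0.035, 0.036],
}))
print(f"z for an 84 cm girl at 24 months: {ref.zscore(84.0, 'female', 24):.3f}")
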