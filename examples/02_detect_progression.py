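"""Detect confirmed disability progression (CDP) on an EDSS trajectory.

A CDP is a worsening over the baseline EDSS of at least 1.0 point (0.5 when
the baseline exceeds 5.5) that is sustained for at least 91 days and
confirmed by another valid measurement; measurements within 84 days of a
relapse do not count.
"""

import numpy as np

from dmtrank import cohort

trajectory = cohort.EdssTrajectory(
    patient_id="demo",
    times=np.array([-20.0, 120.0, 230.0, 350.0]),
    edss=np.array([2.5, 3.5, 3.5, 3.5]),
    relapse_days=np.array([-150.0]),
)

baseline = cohort.baseline_edss(trajectory, cycle_start=0.0)
occurred, onset = cohort.detect_cdp(trajectory, cycle_start=0.0, cycle_end=400.0)
print(f"baseline EDSS: {baseline}")
print(f"CDP detected: {occurred}, onset day: {onset}")
# Expected: baseline 2.5; the 1.0-point rise at day 120 is sustained through
# day 230 (>= 91 days later) and confirmed, so a CDP is reported at day 120.

transient = cohort.EdssTrajectory(
    "demo2", np.array([-20.0, 120.0, 170.0, 300.0]), np.array([2.5, 3.5, 2.5, 3.5])
)
print("transient rise ->", cohort.detect_cdp(transient, 0.0, 360.0)[0])
# The relapse-like bump reverts within 91 days and the late rise is never
# confirmed, so no CDP is reported.
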