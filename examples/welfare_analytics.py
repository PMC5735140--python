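"""Post-surgical welfare analytics: clinical scores and activity.

The total clinical score is the sum of eight factors rated 0-3.
Activity from cage-floor sensor crossings is normalized per animal to
its mean over the three days before surgery, so 1.0 means pre-surgical
baseline.
"""

import numpy as np
import pandas as pd

from limbquant import cohort

print("total clinical score examples:")
for subs in ([1, 1, 1, 1, 0, 0, 0, 0], [0] * 8, [3] * 8):
    print(f"  {subs} -> {cohort.total_score(subs)}")

rng = np.random.default_rng(0)
days = list(range(-3, 15))
rows = []
for subject in ("m1", "m2", "m3"):
    recovery = np.where(
        np.array(days) < 0, 1.0, np.minimum(1.0, 0.5 + 0.5 * np.array(days) / 14.0)
    )
    crossings = np.maximum(120.0 * recovery * (1 + rng.normal(0, 0.08, len(days))), 1.0)
    rows.append(
        pd.DataFrame({"subject": subject, "day": days, "crossings": crossings.round(0)})
    )
records = pd.concat(rows, ignore_index=True)

norm = cohort.normalize_activity(records, surgery_day=0)
daily = norm.groupby("day")["normalized_activity"].mean().round(2)
print("\nmean normalized activity by day (1.0 = pre-surgical baseline):")
print(daily.to_string())
print(
    "\nActivity drops to about half immediately after surgery and returns\n"
    "to baseline within two weeks; the pre-surgery mean is 1 by construction."
)
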