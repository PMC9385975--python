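"""Convert HAMD scores to the BDI scale (H2B) and label a cohort.

The four HAMD severity categories (minimum 0-7, mild 8-13, moderate
14-18, severe 19-48) are mapped linearly onto the matching BDI categories
(0-13, 14-19, 20-28, 29-63).  A subject's H2B score is the converted HAMD
when available, otherwise the raw BDI.
"""

import numpy as np
import pandas as pd

from depspeech.scales import assign_h2b, depression_label, hamd_to_h2b

print("HAMD -> H2B at the category endpoints and one interior point:")
for hamd in (0, 7, 8, 13, 14, 18, 19, 48, 10):
    print(f"  HAMD {hamd:2d} -> H2B {hamd_to_h2b(hamd):5.1f}")

subjects = pd.DataFrame({
    "subject_id": ["s01", "s02", "s03", "s04"],
    "bdi": [5, 25, 25, 40],
    "hamd": [np.nan, np.nan, 14, 30],
})
labelled = assign_h2b(subjects)
labelled["depressed"] = depression_label(labelled["h2b"].to_numpy())
print("\nCohort with H2B assignment (set II = HAMD available):")
print(labelled.to_string(index=False))

# s02 and s03 share BDI 25 but s03's clinician assessment (HAMD 14, the
# lower edge of moderate) converts to H2B 20 and overrides the
# self-report; the depression boundary on the BDI scale is 14.
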