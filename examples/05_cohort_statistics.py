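"""Cohort-scale run: 116 synthetic patients through the full analysis chain,
then the statistical battery (Shapiro-Wilk, one-sample t vs 1500, Pearson and
Spearman TEE-age correlations).

The cohort generator ties each phantom's true TEE to age with a negative
slope (-40 kcal/m^2/day per year around an 1800 intercept, residual sd 150),
echoing the physiological decline of per-area energy expenditure with age.
The pipeline should recover that trend from the images alone.
"""

import pandas as pd

from thermotee import phantom
from thermotee.cohort import cohort_run
from thermotee.energetics import full_energy_report
from thermotee.heat import MaterialSpec, partition_and_correct

material = MaterialSpec("fleece-blanket", 0.15)
rows = []
for frame, truth, record in phantom.generate_cohort(116, seed=1):
    part = partition_and_correct(frame, truth.mask, material, k=2)
    rep = full_energy_report(frame, part, record, include_corrected=True)
    rows.append({"age_years": record.age_years, "tee_area": rep.tee_area})

summary = cohort_run(pd.DataFrame(rows), mu0=1500.0)
print(summary.report_text())
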