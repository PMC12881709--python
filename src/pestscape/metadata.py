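"""Bookkeeping for the motivating GB tree pest/disease datasets.

The pipeline was designed around two restricted-access occurrence datasets
covering mainland Great Britain, 2000–2022. Neither can be redistributed, so
only their summary structure is recorded here; the synthetic-data module
emulates that structure.

* Plant-health inspection records (presence–absence): repeat-visit surveys
  at registered premises; detections out of surveys per site; visits per
  site range from 1 to 81 with median 1.
* Public diagnostic reports (presence-background): expert-confirmed
  presence-only records with no effort information.
"""

from __future__ import annotations

# Record counts after the study's subsetting rules (wider-environment site
# types, grown plants/established plantings, records from 2000 onward).
PA_INSPECTION_RECORDS = 17_147
PB_REPORT_RECORDS = 1_724

PA_SITES = 1_995
VISITS_PER_SITE_RANGE = (1, 81)
VISITS_PER_SITE_MEDIAN = 1

STUDY_YEARS = (2000, 2022)


def total_records() -> int:
    """Combined record count across both observation streams."""
    return PA_INSPECTION_RECORDS + PB_REPORT_RECORDS
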