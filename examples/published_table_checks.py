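"""Internal-consistency checks of the shipped published reference tables.

The package ships small published summary tables from a large FAERS/JADER
analysis of checkpoint-inhibitor neurological adverse events.  This script
verifies the arithmetic relations those columns satisfy using the
package's own statistics: IC = log2(EBGM), EBGM05 ≈ EBGM·exp(−1.645/√N),
mortality = deaths/reports, and the annual-trend Spearman correlation.
"""

import math

from pvsignals import datasets
from pvsignals.cohort_analytics import mortality_rate, percentage, spearman_trend
from pvsignals.empirical_bayes import ebgm05_normal_approx

table = datasets.load_ici_aie_signal_table()
print("drug (database): published IC vs log2(EBGM), published vs approx EBGM05")
for row in table.itertuples():
    ic_from_ebgm = round(math.log2(row.ebgm), 2)
    approx05 = ebgm05_normal_approx(row.ebgm, row.n)
    print(
        f"  {row.drug:14s} ({row.database}): IC {row.ic:5.2f} vs {ic_from_ebgm:5.2f}; "
        f"EBGM05 {row.ebgm05:6.2f} vs {approx05:6.2f}"
    )

annual = datasets.load_annual_nae_counts()
r, p = spearman_trend(annual["year"].to_numpy(), annual["nae"].to_numpy())
print(f"\nannual NAE trend: Spearman r = {r:.4f} (p = {p:.2g})")

groups = datasets.load_nae_group_outcomes()
print("\nmortality rates recomputed from published counts:")
for row in groups.itertuples():
    print(f"  {row.group:20s} {row.deaths:4d}/{row.reports:4d} -> "
          f"{mortality_rate(row.deaths, row.reports).rate_pct:6.2f}%")

nae = int(annual["nae"].sum())
total = int(annual["total"].sum())
print(f"\nNAE share of all reports: {nae}/{total} -> {percentage(nae, total)}%")
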