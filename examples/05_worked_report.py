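"""Worked-example arithmetic on a published stranding-survey comparison.

The evaluation module consumes raw counts (flagged pixels, on-whale
pixels, whales found, survey totals) and derives the standard report
percentages; here it is fed the counts of a documented mass-stranding
satellite survey.
"""

from strandscan import count_comparison, report_row_from_counts, \
    within_distance_summary
from strandscan.evaluate import NearMatch

# 39 pixels flagged along one sound; 26 lay on carcasses; 14 of the 21
# manually confirmed whales attracted at least one pixel.
row = report_row_from_counts(0.0, total_pixels=39, whale_pixels=26,
                             whales_identified=14, n_whales=21)
print(f"on-whale pixel share:   {row.pct_whale_pixels}%   "
      f"(errors of commission: {row.pct_commission}%)")
print(f"whales identified:      {row.whales_identified}/{row.n_whales} "
      f"= {row.pct_whales_identified}%   "
      f"(errors of omission: {row.omission_whales})")

# Nearest-distance concordance between satellite and aerial positions:
# 19 of 24 matched within 100 m.
matches = [NearMatch(str(i), "aerial", 50.0) for i in range(19)]
matches += [NearMatch(str(19 + i), "aerial", 150.0) for i in range(5)]
s = within_distance_summary(matches, [100.0])[0]
print(f"within 100 m of an aerial fix: {s['count']}/{s['n']} = {s['percent']}%")

# Satellite survey counted 23 whale-like objects (14 obvious, 3 probable,
# 6 possible) where the aerial survey logged 14.
cmp_ = count_comparison({1: 14, 2: 3, 3: 6}, ground_count=14,
                        satellite_count=23)
print(f"satellite excess over aerial: +{cmp_.excess} whales "
      f"({cmp_.excess_pct}%)")
print("the imagery sees more carcasses than the later aerial survey — "
      "consistent with carcass loss between acquisitions.")
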