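"""Per-region summary statistics and collection seasonality.

Builds the full statistic battery (min, mean, SD, 10% trimmed mean,
median, scaled MAD, max, skew, excess kurtosis, SE, 95% CI half-width)
per region and period, then checks whether type-specimen collecting is
spread evenly over the year (every month >= 40% of the peak month).
"""

from taxalag import (GeneratorConfig, generate, is_evenly_distributed,
                     lag_table, seasonality_matrix, summary_table)

records, _ = generate(GeneratorConfig(seed=1))
lag = lag_table(records)

table = summary_table(lag, "region")
overall = table[table.period == "overall"]
cols = ["group", "n", "mean_y", "median_y", "sd_y", "skew", "se_y"]
print(overall[cols].round(2).to_string(index=False))

print("\ncollection evenness (every month >= 40% of the peak month):")
for region in sorted({r.region for r in records}):
    m = seasonality_matrix(records, region)
    even, ratios = is_evenly_distributed(m)
    print(f"  {region:11s} even={str(even):5s} "
          f"weakest month at {100 * ratios.min():.0f}% of peak")

# Positive skew with median < mean in every region reproduces the
# right-tailed lag signature; the seasonal regions show uneven collecting.
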