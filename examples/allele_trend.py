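"""Pre/post-application resistance-allele trend (experiment 2).

Loads the packaged pre/post genotype counts, computes the resistant allele
frequency (RAF) per stratum and the per-location and pooled odds ratios of
finding a resistant allele after a field application of lambda-cyhalothrin.
"""

from kdrmon.io import load_trend_fixture, trend_report

report = trend_report(load_trend_fixture())
cols = ["year", "locus", "location", "raf_pre", "raf_post", "odds_ratio", "p_value"]
print(report[cols].to_string(index=False))
# raf_* are resistant allele frequencies in percent; odds_ratio compares the
# odds of a resistant allele post- vs pre-application (per location from raw
# allele counts; the 'All' rows from the equal-weight marginal contrast of
# the interaction logit model).  Values > 1 indicate selection for resistance.
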