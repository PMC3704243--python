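"""Unique vs shared polymorphism and the independence null.

A site segregating within exactly one arrangement is 'unique'; one
segregating in two or more is 'shared'.  Without genetic flux between
arrangements the infinite-sites model produces no shared polymorphisms at
all, so this example generates a panel with gene-conversion tract copies
(the flux mechanism) before classifying.  The independence null expects the
2^K presence/absence configurations to follow the product of the marginal
polymorphism probabilities; an excess of unique sites rejects it.
"""

from collections import Counter

from invpopgen import SynthConfig, build_site_table
from invpopgen.siteclasses import (
    classify_sites,
    independence_null_test,
    unique_excess_test,
)
from invpopgen.synthetic import generate_dataset

dataset = generate_dataset(SynthConfig(seed=5, conversion_rate=1.0))
table = build_site_table(dataset.alignments)
classes, config_counts, arrangements = classify_sites(table)

tally = Counter(c.site_class for c in classes)
print(f"arrangements analysed: {', '.join(arrangements)}")
print(
    f"{len(classes)} polymorphic sites: {tally['unique']} unique, "
    f"{tally['shared']} shared, {tally['monomorphic']} fixed between arrangements"
)

indep = independence_null_test(config_counts, len(arrangements))
print(
    f"\nindependence null over the {2**len(arrangements)} configurations:"
    f"  X2 = {indep.chi2:.1f}, df = {indep.df}, P = {indep.p:.2e}"
)

unique_by_arr = {
    arr: sum(1 for c in classes if c.site_class == "unique" and c.configuration[i])
    for i, arr in enumerate(arrangements)
}
seg_totals = {
    arr: sum(1 for c in classes if c.configuration[i])
    for i, arr in enumerate(arrangements)
}
chi2, df, p = unique_excess_test(unique_by_arr, seg_totals)
print(f"unique counts by arrangement: {unique_by_arr}")
print(f"excess-of-unique test: X2 = {chi2:.2f}, df = {df}, P = {p:.3f}")
print(
    "\nThe huge independence X2 says polymorphism does NOT occur"
    "\nindependently across arrangements: recombination suppression makes"
    "\nvariants arrangement-private far more often than chance predicts."
)
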