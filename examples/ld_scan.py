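"""Linkage-disequilibrium scan with validity filtering and q-value FDR.

Concatenates the loci of a synthetic panel over the shared strains, tests
every pair of biallelic sites whose margins could possibly reach
significance (Fisher exact, two-tailed), controls the false-discovery rate
at 1% with Storey q-values, and summarises the significant fraction per
locus pair -- the numbers behind an LD heat map -- plus a homogeneity
chi-square across cells.
"""

from invpopgen import SynthConfig, build_site_table
from invpopgen.ld import homogeneity_chisq, ld_scan
from invpopgen.synthetic import generate_dataset

dataset = generate_dataset(SynthConfig(n_loci=5, seed=3))
table = build_site_table(dataset.alignments)
print(f"{table.n_sites} biallelic segregating sites across {table.n_strains} strains")

result = ld_scan(table, fdr=0.01)
print(
    f"valid pairs: {result.valid_pairs}/{result.total_pairs}"
    f"  significant: {result.n_significant}"
    f"  (largest significant P = {result.q_cutoff_p:.2e})"
)
fractions = result.aggregate_fractions()
print(
    f"significant fraction within loci: {100 * fractions['within']:.1f}%"
    f"   between loci: {100 * fractions['between']:.1f}%"
)

matrix = result.locus_pair_matrix()
print("\nlocus-pair heat-map cells:")
print(matrix.to_string(index=False, float_format=lambda x: f"{x:.3f}"))

hom = homogeneity_chisq(matrix.significant.tolist(), matrix.valid.tolist())
print(
    f"\nhomogeneity of significant counts: X2 = {hom.chi2:.1f}, df = {hom.df},"
    f" P = {hom.p:.2e}"
)
print(
    "\nWithin-locus LD is strong (no recombination inside a locus in these"
    "\npanels) and between-locus LD reflects shared arrangement structure;"
    "\nthe homogeneity test asks whether significant pairs concentrate in"
    "\nparticular locus pairs (the heat map's black/white dots)."
)
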