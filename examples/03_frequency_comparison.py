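"""Compare cohort allele frequencies and ancestry composition against
reference cohorts with exact binomial tests and BH-FDR correction.
"""

from recurvar import (
    VariantKey,
    compare_ancestry_composition,
    compare_cohort_frequencies,
    significant_enriched,
)

# --- variant mode: alt allele counts over 2n = 20 chromosomes ---------------
observed = {
    VariantKey("chr1", 1000, "G", "A"): 19,  # nearly fixed in the cohort
    VariantKey("chr1", 2000, "C", "T"): 10,  # matches the reference
    VariantKey("chr2", 3000, "T", "G"): 4,
}
reference = {
    "gnomad": {
        VariantKey("chr1", 1000, "G", "A"): 0.03,
        VariantKey("chr1", 2000, "C", "T"): 0.50,
        VariantKey("chr2", 3000, "T", "G"): 0.25,
    }
}
results, excluded = compare_cohort_frequencies(observed, reference, trials=20)
print("variant              obs/trials  ref_af   p_raw      p_adj      enriched")
for r in results:
    print(
        f"{str(r.key):<20} {r.observed}/{r.trials:<9} {r.ref_freq:<8.3f} "
        f"{r.p_raw:<10.3g} {r.p_adj:<10.3g} {r.enriched}"
    )
sig = significant_enriched(results, alpha=0.05)
print(f"significantly enriched after BH: {[str(r.key) for r in sig]}")

# --- composition mode: individuals over n = 10 -------------------------------
cohort = {"AFR": 2, "AMR": 1, "ASN": 2, "EUR": 5}
reference_comp = {"kg1000": {"AFR": 0.26, "AMR": 0.14, "ASN": 0.39, "EUR": 0.21}}
comp = compare_ancestry_composition(cohort, reference_comp)
print("\nancestry group tests (n = 10 individuals):")
for r in comp:
    print(f"  {r.key}: {r.observed}/10 vs {r.ref_freq:.2f}  p_adj = {r.p_adj:.3f}")

# Only the variant far from its reference frequency survives correction;
# a ten-person cohort cannot distinguish its ancestry mix from any
# plausible reference composition.
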