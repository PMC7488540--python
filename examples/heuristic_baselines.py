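"""The single-tissue thresholding baselines for u-/ts-eQTL calling.

Heuristic 1 labels an eQTL tissue-specific in a tissue when it is strong
there (within 100x the eGene's most extreme p-value, and in that tissue's
credible set) and quiet (p > 0.001) in nearly all other tissues; ubiquitous
when it sits in credible sets of at least 5 tissues. Heuristic 2 applies
the same logic to predefined subsets of similar tissues.
"""

from snspmf import VariantRecord, heuristic1_classify, heuristic2_classify

TISSUES = [f"t{i:02d}" for i in range(49)]

def make_variant(vid, focal_p, credible, background_p=0.5):
    pvals = {t: background_p for t in TISSUES}
    pvals.update(focal_p)
    return VariantRecord(
        variant_id=vid, chrom="chr1", pos=1000, gene_id="GENE1", maf=0.2,
        tss_distance=-800, pvals=pvals,
        in_credible_set={t: True for t in credible},
    )

# The "strong" rule compares each variant against the eGene's most extreme
# p-value per tissue, so the gene needs an anchor: its overall best variant.
anchor = make_variant("rs_best", {t: 1e-9 for t in TISSUES}, credible=[],
                      background_p=1e-9)

variants = [
    anchor,
    make_variant("rs_liver", {"t00": 1e-8}, credible=["t00"]),        # liver-only
    make_variant("rs_broad", {t: 1e-8 for t in TISSUES[:6]},
                 credible=TISSUES[:6]),                               # broad
    make_variant("rs_weak", {"t00": 5e-3}, credible=["t00"]),         # weak focal
]

for label in heuristic1_classify(variants, n_tissues=49):
    print(f"heuristic1 {label.variant_id:>9}: u={label.u_eqtl} "
          f"ts_tissues={sorted(label.ts_tissues)}")

subsets = {"brain": set(TISSUES[:3]), "gut": set(TISSUES[3:5]),
           "s3": {TISSUES[5]}, "s4": {TISSUES[6]}, "s5": {TISSUES[7]}}
brainy = make_variant("rs_brain", {t: 1e-8 for t in TISSUES[:2]},
                      credible=TISSUES[:2])
for label in heuristic2_classify([brainy, anchor], subsets, n_tissues=49):
    print(f"heuristic2 {label.variant_id:>9}: u={label.u_eqtl} "
          f"ts_subsets={sorted(label.ts_subsets)}")
# rs_liver is tissue-specific in t00; rs_broad is ubiquitous (credible in
# >= 5 tissues) but not specific anywhere; rs_weak fails the strength rule.
# rs_brain is specific to the brain subset: strong in 2 of 3 member tissues.
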