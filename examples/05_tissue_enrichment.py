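"""Tissue-specificity flags and Fisher enrichment on a synthetic atlas.

Rescales tissue columns to the whole-organism baseline using the
unexpressed-gene set, flags 2-fold tissue-specific transcripts, and runs
the one-tailed Fisher test with Bonferroni correction for a planted
gene list.
"""

from antagene import simulate_tissue_atlas
from antagene.tissue import (
    flag_tissue_specific,
    rescale_to_baseline,
    tissue_enrichment,
    unexpressed_set,
)

atlas, truth = simulate_tissue_atlas(
    5000, n_tissues=17, frac_specific_per_tissue=0.02,
    unexpressed_frac=0.03, seed=0,
)
print(f"unexpressed genes (whole-fly < 3.4): {len(unexpressed_set(atlas))}")

rescaled = rescale_to_baseline(atlas)
flags = flag_tissue_specific(rescaled, fold=2)
print(f"tissue-specific flags per tissue (mean): {flags.sum().mean():.0f}")

interest = truth.tissue_specific["tissue07"]
res = tissue_enrichment(flags, {"planted_set": interest}, n_tissues=17)
top = res.sort_values("p").head(3)
for _, row in top.iterrows():
    print(f"{row['tissue']}: OR(cond-MLE) = {row['odds_ratio_cmle']:.2f}, "
          f"Bonferroni p = {row['p_bonferroni']:.2e}")

# The planted tissue should top the list with adjusted p << 0.01; other
# tissues sit near p = 1 because the planted set is specific elsewhere.
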