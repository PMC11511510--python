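"""Fit the all-random model by REML and estimate entry-mean heritability.

For each of three traits, fits random genotype, year, genotype x year, block,
block x year and column effects, then applies the entry-mean formula
h2 = s2_g / (s2_g + s2_gxy/2 + s2_e/6) for the 2-year, 3-block design.
"""

from metsel import estimate_heritability, fit_trait, generate_trial

data = generate_trial(seed=42)

print(f"{'trait':>14} {'s2_g':>8} {'s2_gxy':>8} {'s2_resid':>8} {'h2':>6}")
for trait in ["dtf", "plant_height", "seed_yield"]:
    vc, _, _ = fit_trait(data, trait, model="all_random")
    h = estimate_heritability(vc, n_years=2, n_blocks=3, trait=trait)
    print(
        f"{trait:>14} {h.sigma2_g:8.3f} {h.sigma2_gxy:8.3f} "
        f"{h.sigma2_resid:8.3f} {h.h2:6.2f}"
    )

print(
    "\nh2 is the share of variance among two-year accession means due to"
    "\ngenotype: the genotype-by-year variance is averaged over 2 years and"
    "\nthe plot residual over all 6 plots per accession.  Values near the"
    "\ngenerating ones (dtf ~0.78, plant height ~0.70, yield ~0.85) are"
    "\nexpected up to sampling noise of a single 48-accession trial."
)
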