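"""Simulate a two-year quinoa-style field trial and summarize its traits.

Generates the default panel — 48 accessions x 2 years x 3 blocks, 13 traits
with published variance magnitudes and a realistic genotype-level correlation
structure — and prints per-trait summaries (min, max, mean, SD, CV%).
"""

from metsel import generate_trial, summarize_traits, write_trial

data = generate_trial(seed=42)
print(f"simulated {len(data)} plot observations "
      f"({len(data.accessions)} accessions x {len(data.years)} years x "
      f"{len(data.blocks)} blocks x {len(data.traits)} traits)\n")

summary = summarize_traits(data)
print(summary.round(2).to_string())
print(
    "\nEach row is one trait over all 288 plots of both years; CV% = 100*SD/mean."
    "\nDays to flowering spans a narrow window (the panel is pre-selected for"
    "\nearliness) while lodging and yield vary several-fold, as in real trials."
)

write_trial(data, "trial_long.csv", dialect="long")
print("\nwrote trial_long.csv (accession,year,block,column,trait,value)")
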