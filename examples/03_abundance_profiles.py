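"""Coverage-based abundance: the IQR position filter discounts repeat
pileups, contig coverages combine length-weighted per genome, and the
result normalises to relative abundances that recover the planted
community weights. Also: the "Rest" collapse and Bray-Curtis PCoA."""

import numpy as np

from curdcat.profiles import (
    bray_curtis_ordination,
    collapse_profile,
    genome_coverage,
    iqr_mean_coverage,
    relative_abundance,
)
from curdcat.records import DepthProfile, TaxProfile
from curdcat.simulate import make_abundance_scenario

# IQR filter on a toy profile: the 100x outlier position is discarded
p = DepthProfile("toy", np.array([1, 2, 3, 4, 100]))
print(f"depths [1,2,3,4,100]: raw mean {p.depths.mean():.1f}, "
      f"IQR-filtered mean {iqr_mean_coverage(p):.1f}")

# planted community: 5 genomes at weights 0.40/0.25/0.15/0.12/0.08
depth_items, weights = make_abundance_scenario(seed=2)
cov = {g: genome_coverage([prof for _, prof in items])
       for g, items in depth_items.items()}
rel = relative_abundance(cov)
print("genome  planted  recovered")
for g, w in weights.items():
    print(f"  {g}   {w:.3f}    {rel[g]:.3f}")

# taxa under 1% fold into "Rest"; totals are conserved exactly
profile = TaxProfile("rind", "week13",
                     {"Psychrobacter": 60.0, "Halomonas": 30.0,
                      "Vibrio": 9.2, "Mesonia": 0.5, "Myroides": 0.3})
collapsed = collapse_profile(profile)
print(f"collapsed profile: {collapsed.counts}")

# three time points ordinated by Bray-Curtis PCoA
tps = [
    TaxProfile("rind", "week2", {"Debaryomyces": 70, "Psychrobacter": 20, "Vibrio": 10}),
    TaxProfile("rind", "week4", {"Debaryomyces": 20, "Psychrobacter": 55, "Vibrio": 25}),
    TaxProfile("rind", "week13", {"Debaryomyces": 5, "Psychrobacter": 70, "Vibrio": 25}),
]
coords, explained = bray_curtis_ordination(tps, n_axes=2)
print(coords.round(3))
print(f"axis 1 explains {explained[0]:.0%} of the Bray-Curtis variation "
      "— samples order along the ripening succession")
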