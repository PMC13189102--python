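"""Simulate one imaging plate and recover the planted synaptic-density effect.

Builds a plate where mutant wells carry 2x the wild-type neurite puncta
density, runs segmentation + detection + normalization, and prints the
recovered per-genotype ddPC (fold change vs the same-plate wild-type wells).
A value near 2 for the mutant and near 1 for the wild type means the pipeline
recovered the planted biology.
"""

from compartquant import quantify
from compartquant.pipeline import RunConfig, analyze_plate
from compartquant.sim.images import ImageSimConfig, generate_plate_images

cfg = ImageSimConfig(
    genotype_effects={"wildtype": {}, "hom_mutant": {"neurite": 2.0}},
    rng_seed=7,
)
plate, truth = generate_plate_images(cfg)
print(f"simulated {len(plate.images)} wells "
      f"({(plate.plate_map.role == 'negative_control').sum()} negative control)")

table = analyze_plate(plate, truth, RunConfig(colocalization=False))
table["plate"] = 0
fc = quantify.plate_fold_changes(table)

summary = (fc[fc.compartment == "neurite"]
           .groupby("genotype")[["delta_pc", "ddpc"]].mean().round(3))
print("\nneurite puncta per um (dPC) and fold change vs wild type (ddPC):")
print(summary)
print("\nThe mutant ddPC should sit near the planted 2.0x density multiplier;")
print("the wild-type reference wells average to 1.0 by construction.")
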