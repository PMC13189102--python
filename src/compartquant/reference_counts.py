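"""Published per-clone MAP2+ neuron counts from the ZNF804A imaging experiments.

Three high-content imaging experiments on day-7 glutamatergic neurons reported
the number of MAP2+ neurons analyzed per CRISPR clone (two clones per
genotype: wild type +E3/+E3, heterozygous +E3/-E3 and homozygous -E3/-E3
exon 3 deletion): the postsynaptic GluN1 staining run, the presynaptic VGLUT1
run, and the ribosomal-protein RPS6 run. These per-clone counts are inputs for
aggregation checks; :func:`total_neurons` recomputes each experiment's total.
"""

from __future__ import annotations

__all__ = ["PER_CLONE_NEURON_COUNTS", "total_neurons"]

PER_CLONE_NEURON_COUNTS: dict[str, dict[str, int]] = {
    "GluN1": {
        "wt_4": 4681, "wt_61": 11445,
        "het_10.23": 5323, "het_42.13": 7323,
        "hom_20": 6833, "hom_44": 19049,
    },
    "VGLUT1": {
        "wt_4": 4241, "wt_61": 10302,
        "het_10.23": 5257, "het_42.13": 5580,
        "hom_20": 5550, "hom_44": 14441,
    },
    "RPS6": {
        "wt_4": 6712, "wt_61": 13241,
        "het_10.23": 8984, "het_42.13": 4838,
        "hom_20": 7772, "hom_44": 13603,
    },
}


def total_neurons(experiment: str) -> int:
    """Total MAP2+ neurons analyzed in one experiment (sum over the six clones)."""
    return sum(PER_CLONE_NEURON_COUNTS[experiment].values())
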