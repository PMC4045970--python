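"""Published summary tables of the lotus F1 ddRAD mapping study whose
design the synthetic generator emulates.

These are inputs for reproduction: the table-arithmetic checks recompute
every derived quantity (percentages, ratios, totals, averages) from the
raw printed counts through the package's own functions.
"""

from __future__ import annotations

import pandas as pd

#: scored and mapped marker counts per reference dialect used for
#: marker scoring (unmasked scaffolds / gene models / repeat-masked)
REFERENCE_COMPARISON = pd.DataFrame(
    {
        "mode": ["unmasked", "genemodels", "masked"],
        "scored": [8501, 776, 4098],
        "mapped": [5534, 582, 3603],
    }
).set_index("mode")

#: within-genome heterozygosity (variants/kb) per megascaffold
MEGASCAFFOLD_HET = pd.Series(
    [0.39, 0.31, 0.24, 0.31, 0.42, 0.24, 0.22, 0.37, 0.46],
    index=[f"megascaffold_{i}" for i in range(1, 10)],
    name="per_kb",
)

#: per-linkage-group map and anchoring summary
#: (distance cM, markers, SSR markers, RADseq bins, anchored Mb,
#:  involved scaffolds)
LINKAGE_GROUP_SUMMARY = pd.DataFrame(
    [
        ("LG1", 97.7, 203, 39, 164, 165.90, 91),
        ("LG2", 75.8, 79, 16, 63, 59.25, 17),
        ("LG3", 69.1, 114, 14, 100, 97.35, 37),
        ("LG4", 58.3, 83, 14, 69, 40.61, 17),
        ("LG5", 51.1, 61, 18, 43, 47.89, 4),
        ("LG6", 48.2, 80, 19, 61, 36.68, 17),
        ("LG7", 44.9, 33, 3, 30, 30.01, 21),
        ("LG8", 27.7, 32, 10, 22, 44.88, 17),
        ("LG9", 21.5, 13, 3, 10, 20.78, 13),
    ],
    columns=["lg", "distance_cm", "markers", "ssrs", "bins", "physical_mb",
             "n_scaffolds"],
).set_index("lg")

#: draft assembly span (Mb) and repeat content of the reference genome
ASSEMBLY_MB = 804
ASSEMBLY_REPEAT_FRACTION = 0.57
GENE_MODEL_FRACTION = 0.05
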