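"""Pathway over-representation of a differential-metabolite set.

The significant metabolites from a pairwise comparison are tested for
over-representation in each pathway of the bundled (curated) annotation via
the upper-tail hypergeometric probability; pathways with raw p < 0.01 pass,
mirroring the usual compound-enrichment report.
"""

import nmrmetab as nm
from nmrmetab.enrichment import results_to_frame

pathway_map = nm.load_pathway_map()
library = nm.load_library()

# the amino-acid signature of the well- vs poorly-differentiated contrast
query = {"Ala", "Gly", "His", "Tyr", "Ile", "Leu", "Lys", "Phe", "Thr",
         "Trp", "Val", "Glu", "Gln"}
results = nm.enrich(query, pathway_map, threshold=0.01)

frame = results_to_frame(results)
cols = ["pathway_name", "hits", "pathway_size", "p_value", "passes_threshold"]
print(frame[cols].head(6).to_string(index=False))
# 'hits' of 'pathway_size' members found among the 13 query metabolites out
# of the annotated universe; small p = more members than chance predicts.
# Aminoacyl-tRNA biosynthesis and the amino-acid transport/metabolism
# pathways dominate, as expected for an amino-acid-heavy signature.
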