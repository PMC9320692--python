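"""Partition concordance and synonymy detection.

Compares a phylogenomic species partition against an external labeling
(think GTDB species) and flags named species whose type strains land in the
same phylogenomic species — a synonymy candidate.
"""

from genotax import compare_partitions, detect_synonyms
from genotax.delineation import PgsPartition

assignment = {"strainA": "pgs3", "strainB": "pgs3", "strainC": "pgs3",
              "strainD": "pgs5", "strainE": "pgs5", "strainF": "pgs9"}
partition = PgsPartition(assignment, {})

external = {"strainA": "sp_x", "strainB": "sp_x", "strainC": "sp_y",
            "strainD": "sp_z", "strainE": "sp_z", "strainF": "sp_w"}
report = compare_partitions(partition, external)
print(report.to_text())

type_strains = {"strainA": "Species alpha", "strainC": "Species beta",
                "strainD": "Species gamma"}
groups = detect_synonyms(partition, type_strains)
for names in groups:
    print("synonymy candidate (type strains share one phylogenomic species):",
          " = ".join(names))
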