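"""Matrisome curation and orthogroup sharing on a toy protein set.

Builds a handful of annotated wall proteins, curates them (dedup, nine
functional classes, binding category, 20-156 kDa band), then clusters
them across species by k-mer similarity and tabulates family sharing.
"""

from matrisome.curation import ProteinRecord, class_distribution, curate
from matrisome.io import AMINOACID, SequenceRecord
from matrisome.orthogroups import cluster, sharing_table, similarity_matrix


def rec(pid, organism, seq, keywords, pI, mw):
    return ProteinRecord(
        seq=SequenceRecord(pid, "", seq, AMINOACID), organism=organism,
        keywords=keywords, pI=pI, MW_kDa=mw,
    )


prx = "MKVLSAAGIWPQRSTYHNEDKLMVVAGH"
exp = "GGPLRSTDEFNIKQWYAVMMKLHECNTS"
proteins = [
    rec("Ca_prx1", "Cicer arietinum", prx, ("peroxidase",), 4.5, 35.0),
    rec("Ca_prx1b", "Cicer arietinum", prx, ("peroxidase",), 4.5, 35.0),  # duplicate
    rec("Gm_prx1", "Glycine max", prx[:20] + "AAAGHKLM", ("peroxidase",), 5.0, 34.0),
    rec("Os_exp1", "Oryza sativa", exp, ("expansin",), 8.2, 27.0),
    rec("Ca_unk1", "Cicer arietinum", exp[::-1], ("DUF642",), 6.5, 210.0),
]

curated, mapping = curate(proteins)
print(f"curated {len(curated)} proteins; collapsed duplicates: {mapping}")
print(class_distribution(curated).to_string(index=False))

seqs = {r.id: r.seq.residues for r in curated}
species_of = {r.id: r.organism.replace(" ", "_") for r in curated}
clusters = cluster(similarity_matrix(seqs, k=4), threshold=0.3, species_of=species_of)
print("clusters:", clusters.clusters)

family_of = {"Cicer_arietinum": "Fabaceae", "Glycine_max": "Fabaceae",
             "Oryza_sativa": "Poaceae"}
print(sharing_table(clusters, family_of).to_string(index=False))
# the two peroxidases cluster across chickpea and soybean (a shared
# Fabaceae orthogroup); single-family rows are in-paralog clusters.
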