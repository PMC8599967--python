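"""ceRNA network assembly by seed matching and MCODE clustering of a PPI.

Sponge edges (lncRNA/circRNA -> miRNA) and targeting edges (miRNA ->
mRNA 3'UTR) come from canonical 8mer/7mer seed sites; the PPI edge list is
clustered with the core-density MCODE procedure.
"""

import itertools

from plaqomics import build_cerna, mcode_cluster, seed_match

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"
SITE = "CUACCUCA"  # reverse complement of the let-7 seed, plus the A1

lnc = {"lnc-sponge": "GGGG" + SITE + "GGGG"}
utrs = {"CKB-3utr": "AA" + SITE + "AA", "CEMIP-3utr": "GG" * 20}
edges = build_cerna(lnc, {"let-7": LET7}, utrs)
print(edges.to_string(index=False))
print("sites on sponge:", seed_match(LET7, lnc["lnc-sponge"]))

ppi = list(itertools.combinations(["ACTA2", "MYL9", "TPM2", "CNN1", "TAGLN"], 2))
ppi += [("TAGLN", "ALB"), ("ALB", "APOA1")]
clusters = mcode_cluster(ppi)
for c in clusters:
    print(f"cluster {c.cluster_id}: {c.members} (score {c.score:.2f})")
# The five contractile-protein nodes form a clique and are returned as one
# dense complex; the pendant chain is excluded by the haircut step.
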