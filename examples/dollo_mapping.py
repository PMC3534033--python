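"""Dollo-parsimony mapping of shared insertion sites on the species tree:
each site gains once (above the MRCA of its carriers) and is lost freely
below; taxa that lost the host gene are inapplicable and constrain nothing."""
from plastintron.phylo_mapping import (ascii_cladogram, dollo_map, load_tree,
                                       sharing_matrix)
from plastintron.site_mapping import load_site_fixture

groups = load_site_fixture()
species = ["Maen", "Egra", "Evir", "Egym"]  # photosynthetic taxa
sm = sharing_matrix(groups, species)
print("Pairwise shared insertion sites (diagonal = totals):")
print(sm.to_frame().to_string())
print("\nShared twintron sites (bracketed counts):")
print(sm.to_frame(twintrons=True).to_string())

tree = load_tree("((((Egra,Elon)n1,Maen)n2,Evir)n3,Egym)root;")
gmap = dollo_map(groups, tree, inapplicable={"Elon": {"psbC"}})
print("\nCladogram with per-branch gain counts:")
print(ascii_cladogram(gmap))
print("\nOne site (psbC) maps to the photosynthetic common ancestor; most "
      "others gained along the Monomorphina/Euglena lineages.")
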