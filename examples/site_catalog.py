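"""Cross-species insertion-site catalog from the shipped transcription of
the published shared/unique site tables.

Cognate sites share (gene, alignment column, codon phase); the summary
counts the focal species' total, shared and unique sites and the sites
whose partner introns display twintrons."""
from plastintron.site_mapping import load_site_fixture, site_catalog

groups = load_site_fixture()
df, summary = site_catalog(groups, focal_species="Maen")
print(df.head(10).to_string(index=False))
print("...")
print(summary)
print("\n53 insertion sites in the focal genome; 41 shared with at least "
      "one other euglenid, 12 unique; 12 fall at twintron-bearing sites.")
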