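# Methods

## Coordinates and genome model

Genomes are held with 0-based half-open intervals on the forward strand;
strand is recorded per gene and user-facing reports (GFF3, TSV) use 1-based
inclusive coordinates. Intron sequences are stored in transcript
orientation. Nested introns attach as children of their enclosing intron;
a nested stack is one insertion site. Circular genomes are assumed to be
annotated without origin-spanning features (records are rotated upstream if
necessary; the rotation offset field is retained for reporting).

Partition accounting classifies each position exactly once, with precedence
intron > exon > intergenic, so `gene_bp + intron_bp + intergenic_bp` equals
the genome length by construction. This makes two deliberate choices:

- A position inside any exon of any gene is "gene", including gene-overlap
  regions; an intron overlapping another gene's exon is still "intron".
- Intron-encoded ORFs (maturases) are genes wholly contained in an intron
  interval; their positions are intronic, they are excluded from gene
  counts and reported separately, mirroring organelle-annotation
  convention.

Gene counts count duplicated genes (same `duplicate_group`) once, while
their base pairs are physical and count every occurrence; free-standing
ORFs are excluded from counts. A protein gene whose exon lengths do not sum
to a multiple of three warns rather than errors: in divergent genes a small
unannotated exon can hide inside an apparent intron, and aborting would
block the rest of the analysis.

## Alignment

Pairwise protein alignment is affine-gap global Needleman–Wunsch
(Bio.Align.PairwiseAligner) with BLOSUM62, gap open 10 and gap extend 0.5
(a gap of length L costs `open + (L-1)·extend`). Ties between co-optimal
tracebacks are resolved by the aligner's deterministic enumeration order;
scores are tie-invariant, and tests verify the optimum against exhaustive
path enumeration on short peptides.

Multiple alignment is center-star progressive: the center maximizes summed
pairwise score; peripheral rows merge through their pairwise alignment to
the center with "once a gap, always a gap" propagation. This is adequate
for the near-identical ortholog sets used to carry insertion-site
coordinates; it is not an L-INS-i replacement, and externally computed
alignments can be imported (aligned FASTA) and take precedence.

Nucleotide comparison of intron components uses semi-global (glocal)
alignment — reference fully aligned, target flanks free — with match +1,
mismatch −3, gap open 16, gap extend 0.5. These defaults encode the shape
of real differences between cognate introns: presence/absence of a whole
internal intron is one long indel (one opening, cheap extension), while
pairing through unrelated AT-rich sequence has negative expectation and
scores worse than gapping it out. They were set by construction on
synthetic cohorts so that an absent 70–130 nt component collapses to low
coverage instead of force-pairing at inflated identity.

## Insertion-site homology

The interrupted residue of an intron with coding offset *c* (coding
nucleotides 5′ of the insertion point) is residue `c // 3`; its phase is
`c mod 3`. A phase-0 insertion falls exactly between codons and is assigned
to the following residue's column — a convention that must simply be fixed
and applied uniformly. Sites cluster iff they share (gene, alignment
column, phase). A site whose interrupted residue is gapped in a partner row
has no column in that partner and cannot be cognate with it. Sites flagged
ambiguous (weakly conserved genes where column homology is doubtful) stay
distinct from everything. Species lacking a gene are "inapplicable" rather
than "absent" downstream.

The shipped shared/unique site-catalog transcriptions have no published
alignment columns, so each catalog row receives its own synthetic column
with phase 0; this preserves exactly the grouping structure the catalog
asserts and nothing more.

## Group III consensus scanning

The 5′ test is positional: position 2 is U and position 5 is G (T≡U); of
the 1024 pentamers, exactly 64 pass. The pseudo-domain VI layout spans
`13 + loop + tail` nt (six 5′ stem bases, loop of 3–8, three 3′ stem bases,
the bulged A, three more stem bases, tail of exactly 4 by default,
configurable 2–6) and must end at the intron 3′ terminus, starting within a
40-nt 3′ window. Stem pairs are Watson–Crick plus optional G·U wobble,
with a mismatch budget (default 0). Hits are ordered by fewest mismatches,
shortest loop, most-3′ placement. Relaxing any parameter only adds hits
(verified as a property test).

Classification: group III requires the 5′ consensus, at least one
pseudo-domain VI hit, and length ≤ 150 nt; a long intron with a
pseudo-domain VI is group II; everything else is unclassified. The 150-nt
ceiling is an operational knob, not an established bound, and is echoed in
every report; U content is reported as a diagnostic only, since composition
thresholds would be circular on AT-rich genomes.

## Twintron classification

Evidence per candidate site: coverage (fraction of reference-component
residues paired with target residues) and identity (matches over paired
columns) for the full twintron span, the external, and each internal
component. A component is supported at coverage ≥ 0.5 AND identity ≥ 0.5;
the thresholds are configurable and deliberately loose — cognate introns
here diverge ~10–20%, while an absent component collapses to coverage well
under 0.5 under the scoring above. The published analyses relied on expert
judgment of the same two-way alignments; fixed thresholds trade some
fidelity for reproducibility, and the raw evidence is always reported
alongside the call.

Status: complete (external + all internals), partial (external + proper
non-empty subset — the intermediate stage), external_only, unrelated
(external unsupported). "Shares a twintron" counts complete + partial.
When unsupported internals leave a length surplus > 60 nt, the surplus
region is scanned for the 5′/pseudo-domain VI consensuses and the result
attached — corroboration that the extra length is or is not an
unrecognized intron, never a gate.

Nested decomposition emits an innermost-first excision plan (children must
nest properly) and can reconstitute the mature external sequence, e.g.
verifying that a maturase ORF fragmented by internal introns becomes
contiguous after their excision.

## Phylogenetic mapping

The sharing matrix counts, for each species pair, the site groups
containing both; the diagonal holds per-species totals, and a parallel
matrix restricted to twintron-flagged groups gives the bracketed twintron
counts. Dollo parsimony places the single gain on the branch above the
MRCA of the carriers and charges one loss per maximal subtree below it
containing no carrier but at least one applicable absent taxon;
inapplicable-only subtrees cost nothing. Tests verify loss minimality
against exhaustive search over all single-gain placements and loss-subset
sizes. Dollo is the model of choice because insertion-site homology
implies unique origin; an unordered Fitch length is available for
sensitivity comparison. Trees are inputs (rooted newick), never inferred.

## Synthetic clades

The simulator is the package's test bed and defines its study conditions:

- per-branch gains ~ Poisson(intensity), default 3.0 per branch; bursts are
  branches with a higher intensity, not a separate process;
- per-site per-branch loss probability (default 0); twintron nesting
  probability per site per branch (default 0), inserting a fresh group III
  internal at a random interior position and annotating the nested child;
- sites occupy uniformly drawn (gene, interior codon, phase) positions,
  unique per clade, mirroring the distinctness rule the mapper honors;
- group III intron sequences (70% of sites by default, 60–140 nt) start
  N-T-N-N-G, have a 0.45 U-fraction interior, and end in a planted
  pseudo-domain VI; group II sequences (250–500 nt) start GTGCG with the
  same planted 3′ domain — so scanner completeness is testable by
  construction;
- exons and spacers are ~70% A+T; genes alternate strands to exercise
  transcript-orientation arithmetic.

What the generator does not emulate: substitution on exons (ortholog
alignments are exact, so recovery tests probe coordinate handling and
reconstruction, not alignment robustness), realistic intron length or
composition variation, and origin-spanning features. Passing recovery
tests therefore shows the pipeline is correct on its own terms, not that
the alignment stage would survive deep divergence — for that, imported
curated alignments are the intended route.

The twintron cohort builder emulates the observed cross-species
composition: 12 candidate sites — 4 carrying the reference external plus
all internals, 2 carrying the external plus only the last internal (the
intermediate stage), 6 external-only — with references of 250–450 nt
externals and 1–3 internals of 70–130 nt, and targets diverged by 10%
point substitutions. Classification at default thresholds recovers the
built composition, giving 6 sites sharing a twintron.

## Problem sizes and determinism

All randomness flows through seeded numpy generators; fixed seeds give
byte-identical genomes and reports. Default test and acceptance runs use
clades of 5–6 taxa, 8 genes of 80–220 codons, a few dozen sites per
simulated clade, 20 replicates for loss-recovery checks, 200-sequence
scanner oracle sweeps and 500-pattern Dollo oracle sweeps — sizes chosen to
exercise every code path many times while keeping a full run in seconds to
a couple of minutes.

## Known limitations

- The star MSA is not consistency-based; with highly divergent orthologs,
  import an external alignment.
- Twintron support thresholds are heuristic stand-ins for expert judgment;
  borderline sites should be read from the evidence table, not the label.
- The group III length ceiling (150 nt) and surplus threshold (60 nt) are
  operational defaults, both configurable and echoed in reports.
- Dollo assumes site homology is never convergent; genuinely ambiguous
  sites should be flagged distinct upstream instead.
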