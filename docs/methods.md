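# Methods

`rrescout` implements a desk-scale version of a structure-guided mining
workflow for RiPP recognition elements (RREs): small winged
helix-turn-helix domains that bind the leader region of ribosomally
synthesized and post-translationally modified peptide (RiPP) precursors.
This note records the models, conventions, numerical choices and known
limitations of each stage.

## Strict fold definition and secondary-structure assignment

An RRE is accepted only when a chain contains, in N-to-C order, three
beta strands followed by three alpha helices (beta1-beta2-beta3-
alpha1-alpha2-alpha3), the chain is at least 65 residues long, and the
span from beta1's first residue to alpha3's last is at most 130 residues
(`max_domain_span`, configurable; RRE domains run ~65–110 aa, and the
allowance covers linkers). Reversed element order (helices first), too few
elements, or an over-long span are reported as distinct failure reasons
(`wrong_order`, `missing_elements`, `span_exceeded`); chains under 65
residues fail as `too_short` regardless of element content. When several
element subsequences qualify, the most N-terminal one is reported
(deterministic greedy choice; for a fixed beta1 the greedy earliest pick
of each later element also minimizes the span, so no qualifying start is
missed). Elements are maximal runs of at least 3 identical labels
(`min_element_len`; shorter runs are not physically meaningful strands or
helices). Sheet topology (parallel/antiparallel pairing between beta1–3)
is deliberately not checked; the grammar tests element order only.

Secondary structure uses the Kabsch–Sander electrostatic hydrogen-bond
model: amide H placed 1.0 Å from N along the previous residue's C→O
direction, energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

with a bond below −0.5 kcal/mol (configurable). Helices come from pairs
of consecutive n→n+4 turns; strands from parallel/antiparallel bridge
patterns over the H-bond set (inter-chain partners included). One
deliberate extension: runs of ≥3 residues with beta-region backbone
dihedrals (φ ∈ [−170°, −70°], ψ ∈ [90°, 180°]) are also labeled E. A pure
ladder criterion cannot label an isolated strand — the common situation in
a single-chain model whose strands are built or predicted without a
paired partner — and geometric strand criteria have long precedent
(STRIDE, P-SEA). Ladder detection is still exercised independently on a
two-chain antiparallel sheet fixture. Residues with incomplete backbone
are labeled C and excluded from H-bond analysis.

## Contacts, binding cleft, and superposition

Peptide–RRE contacts are minimum heavy-atom distances per residue pair at
a 4.0 Å cutoff (hydrogens are absent from typical crystal structures, so
they are never used). The binding cleft is alpha3 + beta3; a peptide
"engages the cleft" when any contact touches either element. Predicted
models are filtered at pTM ≥ 0.60 (inclusive); models without a pTM score
are routed to a `needs_review` bin rather than silently kept.
Superposition RMSD uses the Kabsch SVD algorithm with the determinant
correction that enforces a proper rotation.

## Screening cascade

Structural-search hit tables are reduced to one row per target (maximum
bitscore), then filtered in fixed order: (i) bitscore ≥ 40, (ii) target
sequence length ≥ 65 aa (full length, not alignment length), (iii) no
blocklisted Pfam annotation. All boundaries are inclusive. Unannotated
proteins pass stage (iii): a large share of genuine candidates has no Pfam
match, and removing them would discard exactly the sequence-divergent
proteins the approach is meant to find. The blocklist builder flags a
family only when it has ≥100 members and none of ≤100 sampled members
(seeded sampling) classifies as an RRE fold; a single positive saves the
family. The shipped blocklist is an empty template — the published
196-family list lives in supplementary material not reproduced here.

## Threshold calibration

Per-model bitscore thresholds are chosen from a labeled validation set by
sweeping every distinct observed score t and predicting positive at score
≥ t (inclusive, matching the screening convention):

    precision = TP / (TP + FP),  recall = TP / (TP + FN),
    F1 = 2 * precision * recall / (precision + recall).

Precision is defined as 0 when nothing is predicted positive, which keeps
F1 total. The recommended threshold maximizes F1, ties broken toward the
lower threshold (higher recall). Both full-sequence and per-domain
bitscores are carried; per-domain is the default (the domain score is the
quantity the excision acts on) with a switch for full-sequence. Domain
excision uses envelope coordinates (envelopes bound the homologous region
in profile-HMM practice), 1-based inclusive, optional symmetric padding
clipped at the sequence ends; excised FASTA headers carry
`|env:start-end` provenance and round-trip exactly. Discrete vs fused
classification: ≤110 aa is discrete; longer with a second non-RRE
annotation is fused; longer with no other annotation is ambiguous.

## Genomic neighborhood

The window is the seven nearest genes on each side of the query by rank
along the contig (strand-agnostic; base-pair distances are not used
because gene density varies). CDS features only. Markers are matched by
accession equality against a curated set of RiPP biosynthetic domains
(lasso cyclase PF00733, ATP-grasp PF02222, PatG PF04297, LanB PF04738,
LanC PF14028, SagB PF00881, MftB IPR023850, PqqB IPR011842, rSAM PF04055,
YcaO PF02624, MNIO PF05114). A marker on the query gene itself counts as
a fusion and makes the candidate RiPP-associated. Candidate precursors
are window genes of ≤120 aa with no annotation — the "very short,
unannotated ORF" heuristic; the 120 aa default is our choice (no
published number exists) and is printed in every report.

## Similarity networks

Pairwise scores are Needleman–Wunsch global alignments (BLOSUM62, gap
open 10 / extend 0.5, via Biopython's PairwiseAligner). Identity and
similarity are percentages over the aligned region after trimming
terminal overhangs, internal gaps counted as columns, similarity counting
positive-scoring substitutions. The default edge metric is an explicit
Karlin–Altschul-style proxy, −log10(K·m·n·e^(−λS)) with gapped BLOSUM62
constants λ = 0.267, K = 0.041. This is documented as an approximation of
SSN-service "alignment scores": monotone in the same direction, not
numerically interchangeable, so thresholds are user-set rather than
copied from published figures. RepNode collapsing is greedy
length-sorted centroid clustering (CD-HIT-style): deterministic, and each
member is within the identity threshold of its representative. Groups
are connected components of at least `min_size` nodes (default 10).

## Recognition-sequence mapping

Leader numbering: the residue immediately N-terminal to the core is −1;
an isolated fragment can instead anchor its C-terminus at a stated
coordinate (the PbtA 13-mer NLNDLPMDVFEMA anchored at Ala = −21 spans
Asn(−33)..Ala(−21)). Groups enter motif analysis only with ≥10 members
and ≥50% of members linked to a precursor (both inclusive).

Conservation profiles are per-column residue frequencies with gaps
excluded from the denominator (gap fraction recorded separately, so
gap-rich columns cannot masquerade as conserved) and information content
IC = log2(20) + Σ p·log2 p, no small-sample correction. Motif extraction
turns columns with IC ≥ 2.0 bits into fixed residues or alternative sets
(all residues at frequency ≥ 0.2), keeps the window containing the most
conserved columns with internal wildcard runs ≤ 4 (long enough to admit
Lx4F), and drops flanking wildcards. The 2.0-bit and 0.2 defaults are
package choices, exposed in configuration and printed in report headers.
An all-wildcard outcome is returned as an explicit empty-pattern signal,
distinct from an error — the behaviour groups whose precursors carry
signal peptides rather than a specific motif should produce. Scanning
reports all overlapping placements; a placement is "validated" when a
non-wildcard matched residue contacts alpha3 or beta3 in a peptide–RRE
complex, "not_in_cleft" otherwise, "no_contacts" when no contact list is
available.

The built-in catalog carries the named motifs with class labels: YxxP
(lasso), Lx4F (thiopeptide), HIxxI (sactipeptide), FxLD (lanthipeptide),
KPxWxxP (StsA-type sactipeptide) and the degenerate [WYL]xx[PLI]. The
claim that thirteen distinct motifs exist in the full data set is a
statement about the original database-scale analysis, not a library
invariant.

## Synthetic data: what it emulates and what it does not

The fixtures module stands in for database-scale inputs. Fold panels
build poly-Ala backbones from ideal torsions (helix φ=−57°, ψ=−47°;
strand φ=−119°, ψ=+113°; coil torsions chosen outside both element
regions) with standard bond geometry, in four classes: true
strand×3+helix×3 folds, reversed-order decoys, undersized (<65 aa)
decoys, and helix-bundle decoys (partial structural features without the
intact fold), each under a random rigid placement. The two-chain
antiparallel sheet fixture uses a rigid partner placement chosen once by
maximizing Kabsch–Sander inter-strand bonds over clash-free placements of
the ideal geometry; it reproduces the textbook symmetric ladder.
Screening tables plant known counts of violations per stage including
exact-boundary rows (bitscore 40.0, length 65). Labeled score sets draw
from two normal components, by default 5 SD apart (means 65/25, SD 8) —
a well-calibrated model against background; with 100 draws per component
the extreme tails can just touch, so separability is exact for the
default seed but not a mathematical guarantee at every seed. Genomes are
single synthetic contigs with markers planted at stated rank offsets and
one short unannotated ORF. Motif groups plant each catalog motif at a
fixed leader position with 10% per-position substitution noise outside
the motif; residue alternatives rotate round-robin so every declared
alternative occurs near its nominal frequency. All generators are pure
functions of a seeded `FixtureSpec`.

A green test on this synthetic world establishes that the algorithms
implement their stated rules exactly; it does not establish performance
on real structures, which carry missing density, irregular torsions,
bulges, and chain breaks that the idealized geometry deliberately omits,
nor on real genomes with pseudo-genes and nested features.

## Known limitations

- The secondary-structure assigner is a 3-state approximation; 3-10 and
  pi helices collapse into H or C depending on their H-bond pattern, and
  beta bulges can split a strand.
- The fold grammar does not verify that the three strands share a sheet,
  nor annotate the "wing" loop.
- The network edge metric is not calibrated against any database;
  thresholds are not comparable to published SSN alignment scores.
- Precursor candidate listing is a length/annotation heuristic, not a
  precursor predictor.
- The Pfam blocklist ships empty; only the construction rule is provided.
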