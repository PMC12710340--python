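# rrescout

Structure-guided mining of **RiPP recognition elements (RREs)** — the
small winged helix-turn-helix domains that steer ribosomally synthesized
and post-translationally modified peptide (RiPP) biosynthesis by binding
the precursor peptide's leader region.

Genome mining for RiPPs is hard precisely where it is most interesting:
RRE domains keep their fold while their sequences diverge beyond the
reach of profile searches, and structural searches that do find them
drown the results in look-alike small domains. `rrescout` provides the
desk-scale toolkit for working through that problem:

- **`structmodel`** — parse PDB/mmCIF structures, assign 3-state
  secondary structure (Kabsch–Sander hydrogen bonds plus an
  extended-dihedral strand criterion), and classify the *strict* RRE fold:
  three beta strands followed by three alpha helices (β1β2β3-α1α2α3), at
  least 65 aa, with distinct failure reasons for reversed element order,
  undersized chains and over-long spans. Also: peptide–RRE contact
  mapping at 4 Å, the α3/β3 binding-cleft test, Kabsch RMSD, and a
  pTM ≥ 0.60 confidence filter for predicted models.
- **`foldseek_screen`** — staged filtering of structural-search hit
  tables (bitscore ≥ 40 → length ≥ 65 aa → Pfam false-positive
  blocklist, boundaries inclusive) and automated blocklist construction
  from per-family fold classification.
- **`hmm_calibrate`** — RRE domain excision on HMM envelope coordinates,
  precision/recall/F1 bitscore-threshold calibration, iterative seed-set
  expansion bookkeeping, and discrete (≤110 aa) vs fused classification.
- **`neighborhood`** — ±7-gene genomic-context scan for RiPP marker
  domains (lasso cyclase, ATP-grasp, LanB/LanC, rSAM, YcaO, …) from
  GenBank/GFF3, plus short-unannotated-ORF precursor candidates.
- **`ssn`** — BLOSUM62 global alignments, sequence similarity networks
  with a documented −log10-expectation edge metric, CD-HIT-style RepNode
  collapsing, connected-component group extraction.
- **`recognition_map`** — negative leader numbering, conservation
  profiles with information content, recognition-motif extraction and
  scanning (Lx4F, YxxP, KPxWxxP, …), and cross-validation of motif
  placements against binding-cleft contacts.
- **`fixtures`** — seeded synthetic data for every stage: idealized fold
  panels with decoys, screening tables with planted violations, labeled
  score mixtures, marker-bearing contigs, motif-planted precursor groups.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

The purified 13-residue PbtA leader fragment, whose co-crystal structure
with its partner RRE anchors the recognition-sequence analysis:

```python
from rrescout import recognition_map as rm

peptide = "NLNDLPMDVFEMA"                      # PbtA 13-mer
numb = rm.leader_number(peptide, cterm_coordinate=-21)
print(numb.coordinate_of(1))                   # -33  (Asn)
matches = rm.scan_motif(rm.parse_pattern("Lx4F"), peptide, numb)
print(matches[0].anchor_coordinates)           # {-29: 'L', -24: 'F'}
```

Anchoring the C-terminal Ala at −21 places the fragment at
Asn(−33)..Ala(−21); the single Lx4F site puts the two recognition
residues at Leu(−29) and Phe(−24), and the crystal-resolved stretch
Leu(−29)..Met(−22) covers 8 residues.

Classifying a structure and checking the binding cleft:

```python
from rrescout import structmodel as sm

s = sm.parse_structure("complex.pdb")
ss = sm.assign_secondary_structure(s, "A")
cls = sm.detect_rre_fold(ss)            # is_rre, matched β1..α3, failure_reason
contacts = sm.map_recognition_contacts(s, peptide_chain="B", rre_chain="A",
                                       rre_class=cls, cutoff=4.0)
sm.peptide_engages_cleft(contacts)      # True iff any contact hits α3/β3
```

## Command line

```
rre-scout simulate --what fold-panel --seed 0 --out panel/
rre-scout classify-fold --in panel/ --min-len 65 --min-ptm 0.60
rre-scout screen --hits hits.tsv --pfam ann.tsv --blocklist pfam_block.txt
rre-scout excise --domains domains.tsv --fasta seqs.fasta
rre-scout calibrate --domains domains.tsv --labels labels.tsv
rre-scout neighborhood --genome contig.gbk --query LOCUS --window 7
rre-scout ssn --in seqs.fasta --threshold 20 --repnode 90
rre-scout map-motifs --groups groups/
rre-scout contacts --complex complex.pdb --peptide-chain B --rre-chain A
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computations from
scratch — the PbtA 13-mer worked example, fold-panel classification
(sensitivity/specificity on ≥20 positives and ≥60 decoys), the screening
cascade against generator bookkeeping, threshold calibration on a
two-component score mixture, the ±7-gene neighborhood scan, similarity
network construction with RepNode collapsing, and catalog-motif recovery
at 10% noise — logging each stage's numbers to stderr and writing the
results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
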