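"""Deterministic synthetic data for every stage of the mining pipeline.

The generators stand in for the database-scale inputs the real workflow
consumes (AlphaFold models, structural-search hit tables, Pfam annotation
dumps, bacterial genomes): idealized fold panels with decoys, screening
tables with planted filter violations, labeled bitscore mixtures, GenBank
contigs with RiPP-marker genes at known rank offsets, and precursor-peptide
groups with recognition motifs planted at known leader coordinates.
All outputs are pure functions of a seeded :class:`FixtureSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import geometry
from .structmodel import Atom, Chain, ProteinStructure, Residue

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for the synthetic generators; identical spec => identical output."""

    seed: int = 0
    # fold panel
    n_positives: int = 20
    n_decoys_per_class: int = 20
    strand_len: tuple[int, int] = (5, 7)       # inclusive ranges, residues
    helix_len: tuple[int, int] = (9, 13)
    linker_len: tuple[int, int] = (3, 5)
    # screening tables
    n_clean: int = 30
    n_low_bitscore: int = 8
    n_too_short: int = 6
    n_blocklisted: int = 5
    # labeled score mixture (two normal components, 5 SD apart by default)
    pos_mean: float = 65.0
    neg_mean: float = 25.0
    score_sd: float = 8.0
    n_pos: int = 100
    n_neg: int = 100
    # motif planting
    n_peptides_per_group: int = 20
    leader_len: int = 30
    noise_rate: float = 0.10


# ---------------------------------------------------------------------------
# structures

def _poly_ala(backbone: list[dict[str, np.ndarray]], chain_id: str,
              first_index: int = 1) -> Chain:
    residues = []
    for i, atoms in enumerate(backbone):
        residues.append(Residue(first_index + i, "ALA", [
            Atom("N", "N", atoms["N"]),
            Atom("CA", "C", atoms["CA"]),
            Atom("C", "C", atoms["C"]),
            Atom("O", "O", atoms["O"]),
        ]))
    return Chain(chain_id, residues)


def _build_chain_from_elements(elements: Sequence[tuple[str, int]], chain_id: str = "A",
                               rng: Optional[np.random.Generator] = None) -> Chain:
    torsions = geometry.torsions_for_elements(elements)
    backbone = geometry.build_backbone(torsions)
    if rng is not None:
        axis = rng.normal(size=3)
        R = geometry.rotation_about_axis(axis, float(rng.uniform(0, 360)))
        t = rng.uniform(-50, 50, size=3)
        for atoms in backbone:
            for k in atoms:
                atoms[k] = R @ atoms[k] + t
    return _poly_ala(backbone, chain_id)


def _rand(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def fold_panel_structures(spec: FixtureSpec = FixtureSpec()
                          ) -> list[tuple[str, ProteinStructure, dict]]:
    """The fold panel in memory: (name, structure, truth) triples.

    Classes: ``positive`` (strict beta1-3 + alpha1-3 order, >=65 aa),
    ``reversed`` (helices before strands), ``undersized`` (correct order,
    <65 aa), ``bundle`` (helices only — partial structural features without
    the intact fold). Each structure gets a random rigid placement.
    """
    rng = np.random.default_rng(spec.seed)
    panel: list[tuple[str, ProteinStructure, dict]] = []

    def elements_for(cls: str) -> list[tuple[str, int]]:
        E = lambda: ("E", _rand(rng, spec.strand_len))
        H = lambda: ("H", _rand(rng, spec.helix_len))
        L = lambda: ("C", _rand(rng, spec.linker_len))
        tail = lambda: ("C", int(rng.integers(2, 5)))
        if cls == "positive":
            parts = [tail(), E(), L(), E(), L(), E(), L(), H(), L(), H(), L(), H(), tail()]
        elif cls == "reversed":
            parts = [tail(), H(), L(), H(), L(), H(), L(), E(), L(), E(), L(), E(), tail()]
        elif cls == "undersized":
            parts = [("E", 3), ("C", 3), ("E", 3), ("C", 3), ("E", 3), ("C", 3),
                     ("H", 5), ("C", 3), ("H", 5), ("C", 3), ("H", 5)]
        elif cls == "bundle":
            parts = [tail(), H(), L(), H(), L(), H(), L(), H(), tail()]
        else:
            raise ValueError(cls)
        total = sum(n for _, n in parts)
        if cls in ("positive", "reversed", "bundle") and total < 65:
            parts.append(("H" if cls != "positive" else "H", 65 - total))
        return parts

    def ptm_for(cls: str) -> float:
        # positives emulate confidently predicted models; decoys span the
        # pTM range so the confidence filter has work to do
        return round(float(rng.uniform(0.62, 0.92) if cls == "positive"
                           else rng.uniform(0.30, 0.90)), 2)

    classes = (["positive"] * spec.n_positives
               + ["reversed"] * spec.n_decoys_per_class
               + ["undersized"] * spec.n_decoys_per_class
               + ["bundle"] * spec.n_decoys_per_class)
    counters: dict[str, int] = {}
    for cls in classes:
        counters[cls] = counters.get(cls, 0) + 1
        name = f"{cls}_{counters[cls]:03d}"
        chain = _build_chain_from_elements(elements_for(cls), rng=rng)
        structure = ProteinStructure(chains=[chain], ptm=ptm_for(cls), name=name)
        truth = {"class": cls, "is_rre": cls == "positive", "length": len(chain)}
        panel.append((name, structure, truth))
    return panel


# Frozen rigid placement of an ideal antiparallel partner strand: rotate
# 180 deg about the in-sheet axis perpendicular to the strand direction,
# then offset along (strand axis, sheet normal-ish, perpendicular). The
# offsets were chosen once, by maximizing the number of Kabsch-Sander
# inter-strand hydrogen bonds over a grid of clash-free placements of the
# ideal geometry; they yield the textbook symmetric ladder.
_SHEET_TORSIONS = (-139.0, 135.0)
_SHEET_OFFSETS = (29.0, 7.0, 0.1)


def make_sheet_complex(n_res: int = 8) -> ProteinStructure:
    """Two-chain idealized antiparallel beta sheet (chains A and B)."""
    torsions = [_SHEET_TORSIONS] * n_res
    bbA = geometry.build_backbone(torsions)
    ca = np.array([r["CA"] for r in bbA])
    axis = ca[-1] - ca[0]
    axis = axis / np.linalg.norm(axis)
    perp1 = np.cross(axis, [0.0, 0.0, 1.0])
    perp1 /= np.linalg.norm(perp1)
    perp2 = np.cross(axis, perp1)
    R = geometry.rotation_about_axis(perp2, 180.0)
    dx, d1, d2 = _SHEET_OFFSETS
    t = dx * axis + d1 * perp1 + d2 * perp2
    bbB = [{k: R @ v + t for k, v in r.items()} for r in bbA]
    return ProteinStructure(chains=[_poly_ala(bbA, "A"), _poly_ala(bbB, "B")],
                            name="sheet_complex")


def make_ideal_helix(n_res: int = 12) -> ProteinStructure:
    backbone = geometry.build_backbone([geometry.HELIX_PHI_PSI] * n_res)
    return ProteinStructure(chains=[_poly_ala(backbone, "A")], name="ideal_helix")


def make_coil(n_res: int = 5) -> ProteinStructure:
    torsions = geometry.torsions_for_elements([("C", n_res)])
    backbone = geometry.build_backbone(torsions)
    return ProteinStructure(chains=[_poly_ala(backbone, "A")], name="coil")


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Minimal PDB writer (ATOM records + REMARK 250 PTM/IPTM metadata)."""
    lines = []
    if structure.ptm is not None:
        lines.append(f"REMARK 250 PTM {structure.ptm:.2f}")
    if structure.iptm is not None:
        lines.append(f"REMARK 250 IPTM {structure.iptm:.2f}")
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                x, y, z = atom.coord
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name}{'':1s}{res.name:>3s} {chain.chain_id}"
                    f"{res.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2s}")
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def make_fold_panel(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write the fold panel as PDB files plus a ``labels.tsv`` truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["name\tclass\tis_rre\tlength"]
    for name, structure, truth in fold_panel_structures(spec):
        write_pdb(structure, out_dir / f"{name}.pdb")
        rows.append(f"{name}\t{truth['class']}\t{int(truth['is_rre'])}\t{truth['length']}")
    (out_dir / "labels.tsv").write_text("\n".join(rows) + "\n")
    return out_dir


# ---------------------------------------------------------------------------
# screening tables

def make_screen_tables(spec: FixtureSpec = FixtureSpec(), out_dir: Optional[str | Path] = None):
    """Structural-search hit table + Pfam table + blocklist with planted
    violations of each filter stage.

    Returns (hits rows, pfam map, blocklist set, bookkeeping dict). The
    clean set includes exact-boundary rows (bitscore 40.0, length 65) that
    must survive the inclusive thresholds.
    """
    rng = np.random.default_rng(spec.seed + 1)
    hits = []          # dicts: query, target, fident, alnlen, evalue, bits, tlen
    pfam: dict[str, set[str]] = {}
    blocklist = {"PF90001", "PF90002"}
    good_pfams = ["PF05402", "PF00733", ""]

    def add(target, bits, tlen, accession):
        hits.append({"query": "rre_query", "target": target,
                     "fident": round(float(rng.uniform(15, 95)), 1),
                     "alnlen": int(min(tlen, rng.integers(40, 120))),
                     "evalue": float(10 ** rng.uniform(-20, -3)),
                     "bits": float(bits), "tlen": int(tlen)})
        if accession:
            pfam.setdefault(target, set()).add(accession)

    for i in range(spec.n_clean):
        if i == 0:
            bits, tlen = 40.0, 65          # both boundaries, inclusive
        else:
            bits = round(float(rng.uniform(41, 300)), 1)
            tlen = int(rng.integers(66, 400))
        add(f"clean_{i:03d}", bits, tlen, good_pfams[i % 3])
    for i in range(spec.n_low_bitscore):
        bits = 39.5 if i == 0 else round(float(rng.uniform(5, 39.9)), 1)
        add(f"lowbit_{i:03d}", bits, int(rng.integers(66, 400)), good_pfams[i % 3])
    for i in range(spec.n_too_short):
        tlen = 64 if i == 0 else int(rng.integers(20, 64))
        add(f"short_{i:03d}", round(float(rng.uniform(41, 300)), 1), tlen, good_pfams[i % 3])
    for i in range(spec.n_blocklisted):
        add(f"blocked_{i:03d}", round(float(rng.uniform(41, 300)), 1),
            int(rng.integers(66, 400)), sorted(blocklist)[i % len(blocklist)])

    order = rng.permutation(len(hits))
    hits = [hits[i] for i in order]
    bookkeeping = {
        "total": len(hits),
        "survive_bitscore": spec.n_clean + spec.n_too_short + spec.n_blocklisted,
        "survive_length": spec.n_clean + spec.n_blocklisted,
        "survive_blocklist": spec.n_clean,
        "removed_low_bitscore": spec.n_low_bitscore,
        "removed_too_short": spec.n_too_short,
        "removed_blocklisted": spec.n_blocklisted,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cols = ["query", "target", "fident", "alnlen", "evalue", "bits", "tlen"]
        with open(out_dir / "hits.tsv", "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for h in hits:
                fh.write("\t".join(str(h[c]) for c in cols) + "\n")
        with open(out_dir / "pfam.tsv", "w") as fh:
            fh.write("protein\taccession\tenv_start\tenv_end\n")
            for protein, accs in sorted(pfam.items()):
                for acc in sorted(accs):
                    fh.write(f"{protein}\t{acc}\t1\t60\n")
        with open(out_dir / "blocklist.txt", "w") as fh:
            fh.write("# synthetic false-positive Pfam families\n")
            for acc in sorted(blocklist):
                fh.write(acc + "\n")
    return hits, pfam, blocklist, bookkeeping


# ---------------------------------------------------------------------------
# labeled score mixture

def make_labeled_scores(spec: FixtureSpec = FixtureSpec()):
    """Two-component normal bitscore mixture with truth labels.

    Defaults put the components 5 SD apart (65 vs 25, SD 8), emulating a
    well-calibrated profile HMM whose true hits separate cleanly from
    background; overlap is controlled through the spec means/SD.
    """
    from .hmm_calibrate import DomainHit, LabeledHit

    rng = np.random.default_rng(spec.seed + 2)
    labeled = []
    pos = rng.normal(spec.pos_mean, spec.score_sd, spec.n_pos)
    neg = rng.normal(spec.neg_mean, spec.score_sd, spec.n_neg)
    for i, s in enumerate(pos):
        hit = DomainHit(protein_id=f"pos_{i:03d}", model_id="hmm1",
                        full_bitscore=float(s), domain_bitscore=float(s),
                        env_start=1, env_end=80)
        labeled.append(LabeledHit(hit=hit, is_rre=True))
    for i, s in enumerate(neg):
        hit = DomainHit(protein_id=f"neg_{i:03d}", model_id="hmm1",
                        full_bitscore=float(s), domain_bitscore=float(s),
                        env_start=1, env_end=80)
        labeled.append(LabeledHit(hit=hit, is_rre=False))
    order = rng.permutation(len(labeled))
    return [labeled[i] for i in order]


# ---------------------------------------------------------------------------
# genomes

def make_genome_record(spec: FixtureSpec = FixtureSpec(),
                       marker_offsets: Sequence[int] = (-8, 7),
                       marker_accession: str = "PF00733",
                       precursor_offset: Optional[int] = -2,
                       flank: int = 9):
    """One synthetic contig as a Bio.SeqRecord: a query gene flanked by
    ``flank`` genes on each side, with RiPP-marker accessions planted at the
    requested rank offsets and one short unannotated ORF (putative
    precursor) at ``precursor_offset``."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio.SeqFeature import SeqFeature, FeatureLocation

    rng = np.random.default_rng(spec.seed + 3)
    n_genes = 2 * flank + 1
    query_rank = flank
    features = []
    pos = 100
    for rank in range(n_genes):
        offset = rank - query_rank
        if offset == 0:
            locus, length_aa, accs = "QUERY_0001", 90, {"PF05402"}
        elif precursor_offset is not None and offset == precursor_offset:
            locus, length_aa, accs = f"ORF_{rank:04d}", 45, set()
        elif offset in marker_offsets:
            locus, length_aa, accs = f"MARK_{rank:04d}", 300, {marker_accession}
        else:
            locus, length_aa, accs = f"GENE_{rank:04d}", int(rng.integers(150, 400)), {"PF99999"}
        start = pos
        end = start + 3 * length_aa + 2  # CDS incl. stop codon
        strand = 1 if rng.random() < 0.5 else -1
        quals = {"locus_tag": [locus],
                 "translation": ["M" + "A" * (length_aa - 1)]}
        if accs:
            quals["db_xref"] = [f"Pfam:{a}" if a.startswith("PF") else f"InterPro:{a}"
                                for a in sorted(accs)]
        features.append(SeqFeature(FeatureLocation(start, end, strand=strand),
                                   type="CDS", qualifiers=quals))
        pos = end + int(rng.integers(50, 200))
    seq_len = pos + 100
    seq = Seq("".join(rng.choice(list("ACGT"), size=seq_len)))
    record = SeqRecord(seq, id="ctg001", name="ctg001",
                       description="synthetic RiPP-like contig")
    record.annotations["molecule_type"] = "DNA"
    record.features = features
    return record


def make_genome(spec: FixtureSpec, out_path: str | Path, **kwargs) -> Path:
    """Write the synthetic contig as a GenBank file."""
    from Bio import SeqIO

    record = make_genome_record(spec, **kwargs)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        SeqIO.write([record], fh, "genbank")
    return out_path


# ---------------------------------------------------------------------------
# sequences & motifs

def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([a for a in AA20 if a != ch]))
        else:
            out.append(ch)
    return "".join(out)


def make_sequence_families(spec: FixtureSpec = FixtureSpec(), n_families: int = 2,
                           family_size: int = 10, length: int = 80,
                           within_rate: float = 0.10) -> dict[str, list[tuple[str, str]]]:
    """Families of sequences derived from unrelated random seeds by point
    mutation at ``within_rate``; ground truth for network component tests."""
    rng = np.random.default_rng(spec.seed + 4)
    families: dict[str, list[tuple[str, str]]] = {}
    for f in range(n_families):
        seed_seq = random_protein(rng, length)
        members = [(f"fam{f}_{i:02d}", mutate(seed_seq, rng, within_rate))
                   for i in range(family_size)]
        families[f"fam{f}"] = members
    return families


def make_motif_groups(spec: FixtureSpec = FixtureSpec(),
                      catalog=None) -> dict[str, dict]:
    """Per catalog motif: peptides with the motif planted at a fixed leader
    position, substitution noise everywhere outside the motif.

    Leader numbering anchors the core at position ``leader_len + 1``
    (sequence index), so residue i has leader coordinate i - leader_len - 1.
    Returns {motif name: {"pattern", "peptides": [(id, seq)], "start_index",
    "leader_start", "core_start"}}.
    """
    from .recognition_map import motif_catalog

    if catalog is None:
        catalog = motif_catalog()
    rng = np.random.default_rng(spec.seed + 5)
    groups: dict[str, dict] = {}
    for entry in catalog:
        pattern = entry.pattern
        L = spec.leader_len
        plen = pattern.length
        start = (L - plen) // 2 + 1  # 1-based sequence index of motif start
        peptides = []
        for i in range(spec.n_peptides_per_group):
            seq = list(random_protein(rng, L))
            # plant the motif; alternatives rotate round-robin so every
            # declared alternative occurs at its nominal ~1/|set| frequency
            off = 0
            for kind, v in pattern.elements:
                if kind == "fixed":
                    seq[start - 1 + off] = v
                    off += 1
                elif kind == "alt":
                    seq[start - 1 + off] = sorted(v)[i % len(v)]
                    off += 1
                else:
                    for _ in range(v):
                        seq[start - 1 + off] = rng.choice(list(AA20))
                        off += 1
            noisy = []
            for j, ch in enumerate(seq):
                inside = start - 1 <= j < start - 1 + plen
                if not inside and rng.random() < spec.noise_rate:
                    noisy.append(rng.choice([a for a in AA20 if a != ch]))
                else:
                    noisy.append(ch)
            peptides.append((f"{entry.name}_{i:02d}", "".join(noisy)))
        groups[entry.name] = {
            "pattern": pattern,
            "class_label": entry.class_label,
            "peptides": peptides,
            "start_index": start,
            "core_start": L + 1,
            "leader_start": start - L - 1,
        }
    return groups


def write_motif_groups(spec: FixtureSpec, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups = make_motif_groups(spec)
    truth = ["group\tpattern\tstart_index\tleader_start"]
    for name, g in groups.items():
        with open(out_dir / f"{name}.fasta", "w") as fh:
            for pid, seq in g["peptides"]:
                fh.write(f">{pid}\n{seq}\n")
        truth.append(f"{name}\t{g['pattern'].display}\t{g['start_index']}\t{g['leader_start']}")
    (out_dir / "truth.tsv").write_text("\n".join(truth) + "\n")
    return out_dir
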