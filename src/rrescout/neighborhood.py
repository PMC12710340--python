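"""Genomic-context scoring for candidate RREs.

A candidate is RiPP-associated when a marker domain of RiPP biosynthesis
occurs within seven genes (by rank, strand-agnostic) on either side of the
query, or on the query gene itself (a fusion). Short unannotated ORFs in
the same window are listed as putative precursor peptides — a heuristic,
flagged as such in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

# RiPP biosynthetic marker domains scanned for in the gene window
DEFAULT_MARKERS: dict[str, str] = {
    "PF00733": "lasso cyclase",
    "PF02222": "ATP-grasp",
    "PF04297": "PatG",
    "PF04738": "LanB",
    "PF14028": "LanC",
    "PF00881": "SagB",
    "IPR023850": "MftB",
    "IPR011842": "PqqB",
    "PF04055": "rSAM",
    "PF02624": "YcaO",
    "PF05114": "MNIO",
}


@dataclass
class GeneRecord:
    contig: str
    start: int            # nucleotide, 1-based inclusive
    end: int
    strand: str           # '+' | '-'
    locus: str
    product_length: int   # aa
    annotations: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.locus}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.locus}: strand must be + or -")


@dataclass
class MarkerMatch:
    locus: str
    offset: int
    accession: str
    label: str


@dataclass
class NeighborhoodReport:
    query_locus: str
    window: list[tuple[int, GeneRecord]]   # (signed rank offset, gene)
    markers: list[MarkerMatch]
    fusion: bool

    @property
    def is_ripp_associated(self) -> bool:
        return bool(self.markers) or self.fusion


def scan_neighborhood(genes: Sequence[GeneRecord], query: str,
                      markers: Optional[dict[str, str]] = None,
                      window: int = 7) -> NeighborhoodReport:
    """Scan the ±``window`` nearest genes (by rank along the contig) around
    the query for RiPP marker accessions. A marker on the query gene itself
    sets the fusion flag; either condition makes the candidate
    RiPP-associated."""
    markers = DEFAULT_MARKERS if markers is None else markers
    ordered = sorted(genes, key=lambda g: (g.start, g.end, g.locus))
    ranks = [i for i, g in enumerate(ordered) if g.locus == query]
    if not ranks:
        raise KeyError(f"query locus {query!r} not found on contig")
    q = ranks[0]
    qgene = ordered[q]
    window_genes = [(i - q, ordered[i])
                    for i in range(max(0, q - window), min(len(ordered), q + window + 1))
                    if i != q]
    matches = [MarkerMatch(g.locus, off, acc, markers[acc])
               for off, g in window_genes
               for acc in sorted(g.annotations & markers.keys())]
    fusion = bool(qgene.annotations & markers.keys())
    return NeighborhoodReport(query_locus=query, window=window_genes,
                              markers=matches, fusion=fusion)


def find_candidate_precursors(genes: Sequence[GeneRecord], query: str,
                              window: int = 7,
                              max_precursor_len: int = 120) -> list[GeneRecord]:
    """Window genes that look like unannotated short ORFs — candidate
    precursor peptides. Heuristic: product <= ``max_precursor_len`` aa and
    no Pfam/InterPro annotation; sorted nearest-first, downstream before
    upstream on ties."""
    report = scan_neighborhood(genes, query, markers={}, window=window)
    candidates = [(off, g) for off, g in report.window
                  if g.product_length <= max_precursor_len and not g.annotations]
    candidates.sort(key=lambda t: (abs(t[0]), 0 if t[0] > 0 else 1))
    return [g for _, g in candidates]


# ---------------------------------------------------------------------------
# annotation file readers

def _accessions_from_qualifiers(quals: dict) -> set[str]:
    accs = set()
    for ref in quals.get("db_xref", []) + quals.get("Dbxref", []):
        db, _, acc = ref.partition(":")
        if db.lower() in ("pfam", "interpro") and acc:
            accs.add(acc)
    return accs


def read_genbank(path: str | Path) -> list[GeneRecord]:
    """CDS features of the first contig in a GenBank file.

    Product length comes from the ``translation`` qualifier when present,
    otherwise from the CDS nucleotide span. Pfam/InterPro accessions are
    taken from ``db_xref`` qualifiers.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"{path}: no GenBank records")
    rec = records[0]
    genes = []
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        quals = feat.qualifiers
        locus = (quals.get("locus_tag") or quals.get("gene") or [f"cds_{len(genes)}"])[0]
        translation = quals.get("translation", [None])[0]
        if translation:
            plen = len(translation)
        else:
            plen = max(1, (int(feat.location.end) - int(feat.location.start)) // 3 - 1)
        genes.append(GeneRecord(
            contig=rec.id,
            start=int(feat.location.start) + 1,
            end=int(feat.location.end),
            strand="+" if feat.location.strand != -1 else "-",
            locus=locus,
            product_length=plen,
            annotations=_accessions_from_qualifiers(quals)))
    return genes


def read_gff3(path: str | Path,
              pfam_sidecar: Optional[str | Path] = None) -> list[GeneRecord]:
    """CDS features of the first contig in a GFF3 file.

    Accessions come from ``Dbxref`` attributes or, when absent, from a
    sidecar TSV mapping locus -> accession.
    """
    sidecar: dict[str, set[str]] = {}
    if pfam_sidecar is not None:
        from .foldseek_screen import read_pfam_tsv
        sidecar = read_pfam_tsv(pfam_sidecar)
    genes = []
    contig0 = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9 or parts[2] != "CDS":
                continue
            contig, _, _, start, end, _, strand, _, attrs = parts[:9]
            if contig0 is None:
                contig0 = contig
            if contig != contig0:
                continue
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            locus = attr.get("ID") or attr.get("locus_tag") or f"cds_{len(genes)}"
            accs = set()
            for ref in attr.get("Dbxref", "").split(","):
                db, _, acc = ref.partition(":")
                if db.lower() in ("pfam", "interpro") and acc:
                    accs.add(acc)
            accs |= sidecar.get(locus, set())
            start_i, end_i = int(start), int(end)
            genes.append(GeneRecord(
                contig=contig, start=start_i, end=end_i,
                strand="-" if strand == "-" else "+",
                locus=locus,
                product_length=max(1, (end_i - start_i + 1) // 3 - 1),
                annotations=accs))
    if not genes:
        raise ValueError(f"{path}: no CDS features")
    return genes


def write_report_tsv(report: NeighborhoodReport, path,
                     precursors: Optional[Sequence[GeneRecord]] = None) -> None:
    """Write the window report; ``path`` may be a filename or an open
    text stream."""
    import contextlib

    ctx = (contextlib.nullcontext(path) if hasattr(path, "write")
           else open(path, "w"))
    with ctx as fh:
        fh.write(f"# query={report.query_locus}\tripp_associated={report.is_ripp_associated}"
                 f"\tfusion={report.fusion}\n")
        fh.write("offset\tlocus\tlength_aa\tannotations\tmarker\n")
        marker_loci = {m.locus: m for m in report.markers}
        for off, g in report.window:
            m = marker_loci.get(g.locus)
            fh.write(f"{off:+d}\t{g.locus}\t{g.product_length}\t"
                     f"{','.join(sorted(g.annotations)) or '-'}\t"
                     f"{m.label if m else '-'}\n")
        if precursors is not None:
            fh.write("# candidate precursors (heuristic: short + unannotated)\n")
            for g in precursors:
                fh.write(f"# precursor\t{g.locus}\t{g.product_length}\n")
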