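"""Staged filtering of structural-search hit tables into candidate RREs.

Hits are reduced to one row per target protein (maximum bitscore), then
filtered in a fixed cascade: (i) bitscore >= 40, (ii) target length >= 65
residues, (iii) no Pfam annotation on the curated false-positive blocklist.
All thresholds are inclusive. Proteins without any Pfam annotation pass
stage (iii) untouched — a large fraction of genuine candidates are simply
unannotated.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

log = logging.getLogger(__name__)

PFAM_RE = re.compile(r"^PF\d{5}$")
INTERPRO_RE = re.compile(r"^IPR\d{6}$")


@dataclass
class FoldseekHit:
    query: str
    target: str
    bitscore: float
    evalue: float = 0.0
    aln_len: int = 1
    target_len: int = 1
    seq_identity: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.bitscore == self.bitscore and abs(self.bitscore) != float("inf")):
            raise ValueError("bitscore must be finite")
        if self.aln_len <= 0 or self.target_len <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class Blocklist:
    """Pfam accessions flagged as structural-search false positives."""

    accessions: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, accession: str, note: str = "") -> None:
        if not (PFAM_RE.match(accession) or INTERPRO_RE.match(accession)):
            raise ValueError(f"not a Pfam/InterPro accession: {accession!r}")
        self.accessions.add(accession)
        if note:
            self.provenance[accession] = note

    def __contains__(self, accession: str) -> bool:
        return accession in self.accessions

    def __len__(self) -> int:
        return len(self.accessions)


@dataclass
class ScreenReport:
    decisions: dict[str, str]          # protein -> "retained" | removal stage
    stage_counts: dict[str, int]       # survivors after each stage
    skipped_rows: int = 0

    @property
    def retained(self) -> list[str]:
        return sorted(p for p, d in self.decisions.items() if d == "retained")

    def removed_at(self, stage: str) -> list[str]:
        return sorted(p for p, d in self.decisions.items() if d == stage)


def screen_hits(hits: Iterable[FoldseekHit],
                annotations: Optional[Mapping[str, set[str]]] = None,
                blocklist: Optional[Blocklist] = None,
                min_bitscore: float = 40.0,
                min_len: int = 65) -> ScreenReport:
    """Apply the three-stage retention cascade to a hit table.

    Multiple hits to one target are collapsed to the best (max bitscore)
    before stage (i). Length is the target's full sequence length, not the
    alignment length. Returns per-protein decisions and stage-wise
    survivor counts.
    """
    annotations = annotations or {}
    blocklist = blocklist or Blocklist()
    best: dict[str, FoldseekHit] = {}
    for h in hits:
        prev = best.get(h.target)
        if prev is None or h.bitscore > prev.bitscore:
            best[h.target] = h
    if not best:
        raise ValueError("no hits to screen")

    decisions: dict[str, str] = {}
    survive_i = survive_ii = survive_iii = 0
    for target, h in best.items():
        if h.bitscore < min_bitscore:
            decisions[target] = "low_bitscore"
            continue
        survive_i += 1
        if h.target_len < min_len:
            decisions[target] = "too_short"
            continue
        survive_ii += 1
        if any(acc in blocklist for acc in annotations.get(target, ())):
            decisions[target] = "blocklisted_pfam"
            continue
        survive_iii += 1
        decisions[target] = "retained"
    counts = {"input": len(best), "bitscore": survive_i,
              "length": survive_ii, "blocklist": survive_iii}
    return ScreenReport(decisions=decisions, stage_counts=counts)


def build_pfam_blocklist(families: Mapping[str, list[str]],
                         classify,
                         min_family_size: int = 100,
                         sample_size: int = 100,
                         seed: int = 0) -> Blocklist:
    """Flag Pfam families in which no sampled member shows the RRE fold.

    ``families`` maps accession -> member protein ids; ``classify`` maps a
    protein id to an RREClassification (or None when the member has no
    usable structure). Families with fewer than ``min_family_size`` members
    are never evaluated; up to ``sample_size`` members are sampled with the
    given seed. A family is flagged only when zero sampled members classify
    as RRE — one positive saves the family.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    blocklist = Blocklist()
    for accession in sorted(families):
        members = families[accession]
        if len(members) < min_family_size:
            continue
        if len(members) > sample_size:
            sample = list(rng.choice(members, size=sample_size, replace=False))
        else:
            sample = list(members)
        results = [classify(m) for m in sample]
        usable = [r for r in results if r is not None]
        if not usable:
            log.warning("family %s: no classifiable structures, skipped", accession)
            continue
        if not any(r.is_rre for r in usable):
            blocklist.add(accession,
                          note=f"0/{len(usable)} sampled members show the RRE fold")
    return blocklist


# ---------------------------------------------------------------------------
# file I/O

DEFAULT_COLUMNS = ("query", "target", "fident", "alnlen", "evalue", "bits", "tlen")


def read_foldseek_tsv(path: str | Path,
                      columns: tuple[str, ...] = DEFAULT_COLUMNS) -> tuple[list[FoldseekHit], int]:
    """Read a Foldseek-style tab-separated hit table.

    Returns (hits, number of malformed rows skipped). A header row naming
    the columns is tolerated.
    """
    idx = {c: i for i, c in enumerate(columns)}
    hits: list[FoldseekHit] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == columns[0] and parts[:len(columns)] == list(columns):
                continue  # header
            try:
                hits.append(FoldseekHit(
                    query=parts[idx["query"]],
                    target=parts[idx["target"]],
                    bitscore=float(parts[idx["bits"]]),
                    evalue=float(parts[idx["evalue"]]),
                    aln_len=int(parts[idx["alnlen"]]),
                    target_len=int(parts[idx["tlen"]]),
                    seq_identity=float(parts[idx["fident"]]) if "fident" in idx else None,
                ))
            except (IndexError, ValueError):
                skipped += 1
                log.warning("skipping malformed hit row: %r", line)
    return hits, skipped


def read_pfam_tsv(path: str | Path) -> dict[str, set[str]]:
    """protein -> set of Pfam/InterPro accessions from a simple TSV
    (columns protein, accession, [envelope coords...])."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "protein":
                continue
            if len(parts) >= 2 and (PFAM_RE.match(parts[1]) or INTERPRO_RE.match(parts[1])):
                table.setdefault(parts[0], set()).add(parts[1])
    return table


def read_blocklist(path: str | Path) -> Blocklist:
    """One accession per line; '#' comments allowed."""
    bl = Blocklist()
    with open(path) as fh:
        for line in fh:
            acc = line.split("#")[0].strip()
            if acc:
                bl.add(acc)
    return bl


def write_blocklist(blocklist: Blocklist, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# Pfam families flagged as structural-search false positives\n")
        for acc in sorted(blocklist.accessions):
            note = blocklist.provenance.get(acc, "")
            fh.write(f"{acc}" + (f"  # {note}" if note else "") + "\n")
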