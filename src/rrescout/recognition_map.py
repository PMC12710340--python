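"""Recognition-sequence mapping for RRE-bound precursor peptides.

Leader regions of RiPP precursors are numbered negatively: the residue
immediately N-terminal to the core is -1. Conserved leader residues that
occupy the RRE binding cleft (alpha3/beta3) act as the recognition
sequence; groups of excised RREs with assigned precursors yield
conservation profiles, from which compact motif patterns (fixed residues,
residue alternatives, wildcard runs — e.g. Lx4F, YxxP, KPxWxxP) are
extracted, scanned against leaders, and cross-validated against
peptide-protein contacts.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structmodel import CLEFT_ELEMENTS, ContactRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}
MAX_IC = math.log2(20.0)


# ---------------------------------------------------------------------------
# motif patterns

@dataclass(frozen=True)
class MotifPattern:
    """Ordered motif elements: ('fixed', 'L'), ('alt', frozenset), ('wild', k)."""

    elements: tuple[tuple, ...]

    def __post_init__(self) -> None:
        if not any(kind != "wild" for kind, _ in self.elements):
            raise ValueError("pattern needs at least one non-wildcard element")

    @property
    def length(self) -> int:
        return sum(v if kind == "wild" else 1 for kind, v in self.elements)

    @property
    def display(self) -> str:
        out = []
        for kind, v in self.elements:
            if kind == "fixed":
                out.append(v)
            elif kind == "alt":
                out.append("[" + "".join(sorted(v)) + "]")
            else:
                out.append("x" * v if v <= 3 else f"x{v}")
        return "".join(out)

    def positions(self) -> list[tuple[int, tuple]]:
        """(0-based offset within the motif, element) for every element;
        wildcard runs contribute one entry at their first offset."""
        out = []
        off = 0
        for el in self.elements:
            out.append((off, el))
            off += el[1] if el[0] == "wild" else 1
        return out

    def matches_window(self, window: str) -> bool:
        if len(window) != self.length:
            return False
        off = 0
        for kind, v in self.elements:
            if kind == "fixed":
                if window[off] != v:
                    return False
                off += 1
            elif kind == "alt":
                if window[off] not in v:
                    return False
                off += 1
            else:
                off += v
        return True

    def example_match(self, rng: Optional[np.random.Generator] = None) -> str:
        """A concrete residue string satisfying the pattern."""
        rng = rng or np.random.default_rng(0)
        out = []
        for kind, v in self.elements:
            if kind == "fixed":
                out.append(v)
            elif kind == "alt":
                out.append(str(rng.choice(sorted(v))))
            else:
                out.extend(str(rng.choice(list(AA20))) for _ in range(v))
        return "".join(out)


_TOKEN_RE = re.compile(r"\[([A-Z]+)\]|x(\d*)|([A-WYZ])")


def parse_pattern(display: str) -> MotifPattern:
    """Parse a display string like ``Lx4F``, ``KPxWxxP`` or ``[WYL]xxP``.

    Uppercase letters are fixed residues ('x' is reserved for wildcards;
    bracketed groups are residue alternatives; ``x`` optionally followed by
    a count is a wildcard run, and consecutive wildcards merge.
    """
    elements: list[tuple] = []
    pos = 0
    while pos < len(display):
        m = _TOKEN_RE.match(display, pos)
        if not m:
            raise ValueError(f"cannot parse motif {display!r} at position {pos}")
        alt, count, fixed = m.groups()
        if alt is not None:
            elements.append(("alt", frozenset(alt)))
        elif fixed is not None:
            elements.append(("fixed", fixed))
        else:
            k = int(count) if count else 1
            if elements and elements[-1][0] == "wild":
                elements[-1] = ("wild", elements[-1][1] + k)
            else:
                elements.append(("wild", k))
        pos = m.end()
    return MotifPattern(tuple(elements))


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    class_label: str
    pattern: MotifPattern


def motif_catalog() -> list[CatalogEntry]:
    """Built-in catalog of characterized recognition-sequence motifs with
    their RiPP class labels; extensible by appending entries."""
    named = [
        ("YxxP", "lasso"),
        ("Lx4F", "thiopeptide"),
        ("HIxxI", "sactipeptide"),
        ("FxLD", "lanthipeptide"),
        ("KPxWxxP", "sactipeptide-StsA"),
        ("[WYL]xx[PLI]", "unassigned-degenerate"),
    ]
    return [CatalogEntry(d, label, parse_pattern(d)) for d, label in named]


# ---------------------------------------------------------------------------
# leader numbering

@dataclass
class LeaderNumbering:
    peptide: str
    coordinates: list[int]  # leader coordinate of each residue, parallel to peptide

    def coordinate_of(self, seq_index: int) -> int:
        """Leader coordinate for a 1-based sequence index."""
        return self.coordinates[seq_index - 1]


def leader_number(peptide: str, core_start: Optional[int] = None,
                  cterm_coordinate: Optional[int] = None) -> LeaderNumbering:
    """Negative leader numbering for a peptide.

    Under ``core_start`` (1-based index of the first core residue), the
    residue immediately before the core is -1. Under ``cterm_coordinate``,
    the last residue takes the given coordinate and the rest follow
    contiguously (used for isolated leader fragments, e.g. a 13-mer ending
    at -21 starts at -33).
    """
    if not peptide:
        raise ValueError("empty peptide")
    if (core_start is None) == (cterm_coordinate is None):
        raise ValueError("specify exactly one of core_start / cterm_coordinate")
    n = len(peptide)
    if core_start is not None:
        if not (1 <= core_start <= n + 1):
            raise ValueError(f"core_start {core_start} out of range for length {n}")
        coords = [i - core_start for i in range(1, n + 1)]
    else:
        coords = [cterm_coordinate - (n - i) for i in range(1, n + 1)]
    return LeaderNumbering(peptide=peptide, coordinates=coords)


# ---------------------------------------------------------------------------
# scanning

@dataclass
class MotifMatch:
    start: int                      # 1-based sequence index, inclusive
    end: int
    matched: str                    # residues under the whole pattern window
    anchor_coordinates: dict[int, str]  # leader coordinate -> residue, non-wildcard positions
    anchor_indices: dict[int, str]      # 1-based sequence index -> residue


def scan_motif(pattern: MotifPattern, peptide: str,
               numbering: Optional[LeaderNumbering] = None) -> list[MotifMatch]:
    """All (possibly overlapping) placements of the pattern in the peptide,
    with leader coordinates attached to every non-wildcard position."""
    if not peptide:
        raise ValueError("empty peptide")
    plen = pattern.length
    matches = []
    for start0 in range(0, len(peptide) - plen + 1):
        window = peptide[start0:start0 + plen]
        if not pattern.matches_window(window):
            continue
        anchors_i: dict[int, str] = {}
        anchors_c: dict[int, str] = {}
        for off, (kind, _) in pattern.positions():
            if kind == "wild":
                continue
            seq_idx = start0 + off + 1
            anchors_i[seq_idx] = peptide[seq_idx - 1]
            if numbering is not None:
                anchors_c[numbering.coordinate_of(seq_idx)] = peptide[seq_idx - 1]
        matches.append(MotifMatch(start=start0 + 1, end=start0 + plen,
                                  matched=window,
                                  anchor_coordinates=anchors_c,
                                  anchor_indices=anchors_i))
    return matches


# ---------------------------------------------------------------------------
# conservation profiles

@dataclass
class ConservationProfile:
    frequencies: np.ndarray      # (n_columns, 20), rows sum to 1 (gap-free part)
    gap_fraction: np.ndarray     # (n_columns,)
    information: np.ndarray      # bits per column

    @property
    def n_columns(self) -> int:
        return self.frequencies.shape[0]


def build_profile(aligned: Sequence[str]) -> ConservationProfile:
    """Per-column residue frequencies and information content (log2, against
    a uniform 20-letter background). Gaps ('-') are excluded from the
    frequency denominator; all-gap columns get zero information and are
    flagged by gap_fraction = 1."""
    if len(aligned) < 2:
        raise ValueError("need at least 2 sequences")
    ncol = len(aligned[0])
    if any(len(s) != ncol for s in aligned):
        raise ValueError("sequences must be pre-aligned to equal length")
    freqs = np.zeros((ncol, 20))
    gaps = np.zeros(ncol)
    for seq in aligned:
        for j, ch in enumerate(seq.upper()):
            if ch == "-":
                gaps[j] += 1
            elif ch in _AA_INDEX:
                freqs[j, _AA_INDEX[ch]] += 1
    info = np.zeros(ncol)
    for j in range(ncol):
        total = freqs[j].sum()
        if total == 0:
            continue
        freqs[j] /= total
        nz = freqs[j][freqs[j] > 0]
        info[j] = MAX_IC + float((nz * np.log2(nz)).sum())
    return ConservationProfile(frequencies=freqs,
                               gap_fraction=gaps / len(aligned),
                               information=np.clip(info, 0.0, MAX_IC))


@dataclass
class ExtractedMotif:
    pattern: Optional[MotifPattern]   # None = empty-pattern signal
    start_column: Optional[int]       # 0-based column of the first element

    @property
    def is_empty(self) -> bool:
        return self.pattern is None


def extract_motif(profile: ConservationProfile, ic_threshold: float = 2.0,
                  alt_fraction: float = 0.2,
                  max_wildcard_run: int = 4) -> ExtractedMotif:
    """Compact motif from a conservation profile.

    Columns with information >= ``ic_threshold`` bits become fixed residues
    (or residue-alternative sets: all residues at frequency >=
    ``alt_fraction``); columns below threshold are wildcards. The pattern
    is the window containing the most conserved columns whose internal
    wildcard runs never exceed ``max_wildcard_run``; leading and trailing
    wildcards are dropped. When no column clears the threshold an empty
    pattern is returned — the signal for groups without a specific motif
    (e.g. signal-peptide-led precursors).
    """
    conserved = [j for j in range(profile.n_columns)
                 if profile.information[j] >= ic_threshold]
    if not conserved:
        return ExtractedMotif(pattern=None, start_column=None)
    # split conserved columns into windows with bounded internal gaps
    windows: list[list[int]] = [[conserved[0]]]
    for j in conserved[1:]:
        if j - windows[-1][-1] - 1 <= max_wildcard_run:
            windows[-1].append(j)
        else:
            windows.append([j])
    best = max(windows, key=lambda w: (len(w), -w[0]))
    elements: list[tuple] = []
    prev = None
    for j in best:
        if prev is not None and j - prev - 1 > 0:
            elements.append(("wild", j - prev - 1))
        residues = frozenset(AA20[k] for k in np.flatnonzero(
            profile.frequencies[j] >= alt_fraction))
        if not residues:  # conserved but diffuse below alt_fraction: keep top residue
            residues = frozenset({AA20[int(np.argmax(profile.frequencies[j]))]})
        if len(residues) == 1:
            elements.append(("fixed", next(iter(residues))))
        else:
            elements.append(("alt", residues))
        prev = j
    return ExtractedMotif(pattern=MotifPattern(tuple(elements)), start_column=best[0])


# ---------------------------------------------------------------------------
# group retention and validation

@dataclass
class RREGroup:
    group_id: str
    members: list[str]
    precursors: dict[str, tuple[str, str]] = field(default_factory=dict)
    # member id -> (precursor sequence, provenance 'automated'|'manual')

    @property
    def coverage(self) -> float:
        return len(self.precursors) / len(self.members) if self.members else 0.0


def retain_groups(groups: Sequence[RREGroup], min_nodes: int = 10,
                  min_coverage: float = 0.5) -> tuple[list[RREGroup], dict[str, str]]:
    """Keep groups with >= ``min_nodes`` members and precursor coverage >=
    ``min_coverage`` (both inclusive); returns (retained, exclusion reasons)."""
    retained = []
    reasons: dict[str, str] = {}
    for g in groups:
        if len(g.members) < min_nodes:
            reasons[g.group_id] = "fewer_than_min_nodes"
        elif g.coverage < min_coverage:
            reasons[g.group_id] = "insufficient_precursor_coverage"
        else:
            retained.append(g)
    return retained, reasons


def validate_candidate(pattern: MotifPattern, match: MotifMatch,
                       contacts: Sequence[ContactRecord]) -> str:
    """Cross-validate a motif placement against binding-cleft contacts.

    'validated' iff at least one non-wildcard matched residue contacts an
    alpha3/beta3 protein residue; 'no_contacts' for an empty contact list;
    'not_in_cleft' otherwise. Requires the contact peptide indexing to
    match the match's sequence indexing.
    """
    if not contacts:
        return "no_contacts"
    by_index: dict[int, list[ContactRecord]] = {}
    for c in contacts:
        by_index.setdefault(c.peptide_index, []).append(c)
    for seq_idx in match.anchor_indices:
        for c in by_index.get(seq_idx, []):
            if c.protein_element in CLEFT_ELEMENTS:
                return "validated"
    return "not_in_cleft"


# ---------------------------------------------------------------------------
# alignment helper

def star_align(seqs: dict[str, str]) -> dict[str, str]:
    """Crude star alignment against the longest member: every sequence is
    projected onto the reference's columns via pairwise global alignment
    (insertions relative to the reference are dropped, deletions padded
    with '-'). Adequate for near-equal-length precursor groups."""
    from .ssn import _aligner

    ref_id = max(seqs, key=lambda k: (len(seqs[k]), k))
    ref = seqs[ref_id]
    out = {ref_id: ref}
    for sid, seq in seqs.items():
        if sid == ref_id:
            continue
        aln = _aligner().align(ref, seq)[0]
        row_ref, row_seq = str(aln[0]), str(aln[1])
        projected = [row_seq[k] for k in range(len(row_ref)) if row_ref[k] != "-"]
        out[sid] = "".join(projected)
    return out
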