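"""Structure parsing, secondary structure, and strict RRE fold classification.

The RiPP recognition element (RRE) is defined here by a strict N-to-C order
of secondary-structure elements forming a winged helix-turn-helix:
three beta strands followed by three alpha helices (beta1-beta2-beta3-
alpha1-alpha2-alpha3). Functionally related domains with the reversed
element order (alpha-alpha-alpha-beta-beta-beta), or proteins too small to
adopt the fold (<65 aa), are rejected. The binding cleft that engages the
precursor peptide's recognition sequence is formed by alpha3 and beta3;
peptide-protein contacts are mapped against those elements at a 4 A
heavy-atom cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Atom", "Residue", "Chain", "ProteinStructure",
    "SecondaryStructureString", "SSElement", "RREClassification",
    "FailureReason", "ContactRecord",
    "parse_structure", "assign_secondary_structure", "detect_rre_fold",
    "map_recognition_contacts", "peptide_engages_cleft", "kabsch_rmsd",
    "model_confidence_filter",
]

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Kabsch-Sander electrostatic H-bond model constants
_KS_Q1Q2_F = 0.084 * 332.0  # kcal/mol when distances are in Angstrom
DEFAULT_HBOND_ENERGY = -0.5  # kcal/mol

# Backbone-dihedral box for extended (beta) conformation, used to label
# strands that lack a ladder partner (e.g. edge strands of a meander
# modelled in isolation). See docs/methods.md.
_EXT_PHI = (-170.0, -70.0)
_EXT_PSI = (90.0, 180.0)


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite floats")


@dataclass
class Residue:
    index: int          # author numbering, preserved
    name: str           # 3-letter code
    atoms: list[Atom] = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name, "X")

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms if a.element != "H"])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"chain {self.chain_id}: residue indices must strictly increase")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class ProteinStructure:
    """Polymer chains with heavy atoms; ligands/waters kept separately.

    ``ptm``/``iptm`` are optional predicted-model confidence scores
    (unitless fractions in [0, 1]).
    """

    chains: list[Chain]
    ligands: list[Residue] = field(default_factory=list)
    ptm: Optional[float] = None
    iptm: Optional[float] = None
    name: str = ""

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not present (have {[c.chain_id for c in self.chains]})")

    def ca_coords(self, chain_id: str) -> np.ndarray:
        ch = self.chain(chain_id)
        return np.array([r.atom("CA").coord for r in ch.residues if r.atom("CA") is not None])


@dataclass
class SecondaryStructureString:
    chain_id: str
    labels: str  # per-residue H/E/C

    def __post_init__(self) -> None:
        if set(self.labels) - set("HEC"):
            raise ValueError("labels must be drawn from {H, E, C}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SSElement:
    kind: str          # 'helix' | 'strand'
    start: int         # 1-based sequential index, inclusive
    end: int
    ordinal: Optional[str] = None  # beta1..beta3 / alpha1..alpha3 when matched

    def __post_init__(self) -> None:
        if self.kind not in ("helix", "strand"):
            raise ValueError("kind must be 'helix' or 'strand'")
        if self.start > self.end:
            raise ValueError("element start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class FailureReason(str, Enum):
    NONE = "none"
    TOO_SHORT = "too_short"
    WRONG_ORDER = "wrong_order"
    MISSING_ELEMENTS = "missing_elements"
    SPAN_EXCEEDED = "span_exceeded"


@dataclass
class RREClassification:
    is_rre: bool
    failure_reason: FailureReason
    matched_elements: list[SSElement] = field(default_factory=list)
    domain_span: Optional[tuple[int, int]] = None
    extra_elements: list[SSElement] = field(default_factory=list)
    elements: list[SSElement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.is_rre:
            assert self.failure_reason is FailureReason.NONE
            if self.matched_elements:
                kinds = [e.kind for e in self.matched_elements]
                assert kinds == ["strand"] * 3 + ["helix"] * 3

    def element_for_residue(self, seq_index: int) -> Optional[str]:
        """Ordinal (beta1..alpha3) of the matched element covering a residue."""
        for e in self.matched_elements:
            if e.start <= seq_index <= e.end:
                return e.ordinal
        return None


@dataclass
class ContactRecord:
    peptide_chain: str
    peptide_index: int
    peptide_name: str
    protein_chain: str
    protein_index: int
    protein_name: str
    distance: float
    protein_element: Optional[str]  # alpha1..alpha3 / beta1..beta3 / None


# ---------------------------------------------------------------------------
# parsing

def parse_structure(path: str | Path, ptm: Optional[float] = None,
                    iptm: Optional[float] = None) -> ProteinStructure:
    """Read a PDB or mmCIF file into a :class:`ProteinStructure`.

    Alternate locations are resolved to the highest-occupancy conformer;
    waters and hetero ligands are excluded from polymer chains but kept in
    ``ligands``. ``REMARK 250 PTM x.xx`` / ``IPTM`` lines (as written by the
    synthetic-model generator) populate the confidence metadata unless
    overridden by the keyword arguments.
    """
    from Bio.PDB import PDBParser, MMCIFParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if suffix in (".cif", ".mmcif"):
            parser = MMCIFParser(QUIET=True)
        else:
            parser = PDBParser(QUIET=True)
        try:
            model = next(parser.get_structure(path.stem, str(path)).get_models())
        except StopIteration:
            raise ValueError(f"{path}: no polymer chain found")

    file_ptm, file_iptm = _scan_remarks(path) if suffix not in (".cif", ".mmcif") else (None, None)

    chains: list[Chain] = []
    ligands: list[Residue] = []
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            het, resseq, _ = bio_res.id
            atoms = []
            for bio_atom in bio_res:
                # DisorderedAtom: keep the highest-occupancy conformer
                if bio_atom.is_disordered():
                    bio_atom = max(bio_atom, key=lambda a: a.get_occupancy() or 0.0)
                element = (bio_atom.element or "").strip() or bio_atom.get_name()[0]
                if element == "H":
                    continue
                atoms.append(Atom(bio_atom.get_name(), element, bio_atom.get_coord()))
            rec = Residue(int(resseq), bio_res.get_resname().strip(), atoms)
            if het.strip():  # water or hetero ligand
                ligands.append(rec)
            else:
                residues.append(rec)
        if residues:
            chains.append(Chain(bio_chain.id, residues))
    if not chains:
        raise ValueError(f"{path}: no polymer chain found")
    return ProteinStructure(chains=chains, ligands=ligands,
                            ptm=ptm if ptm is not None else file_ptm,
                            iptm=iptm if iptm is not None else file_iptm,
                            name=path.stem)


def _scan_remarks(path: Path) -> tuple[Optional[float], Optional[float]]:
    ptm = iptm = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("REMARK"):
                continue
            tok = line.split()
            if len(tok) >= 4 and tok[2] in ("PTM", "IPTM"):
                try:
                    val = float(tok[3])
                except ValueError:
                    continue
                if tok[2] == "PTM":
                    ptm = val
                else:
                    iptm = val
    return ptm, iptm


# ---------------------------------------------------------------------------
# secondary structure

def _ks_hbond_energy(acc_c: np.ndarray, acc_o: np.ndarray,
                     don_n: np.ndarray, don_h: np.ndarray) -> float:
    """Kabsch-Sander electrostatic energy (kcal/mol) for one C=O...H-N pair."""
    d = np.linalg.norm
    r_on = d(acc_o - don_n)
    r_ch = d(acc_c - don_h)
    r_oh = d(acc_o - don_h)
    r_cn = d(acc_c - don_n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # overlapping atoms: no bond
        return 0.0
    return _KS_Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _backbone_frames(chain: Chain) -> list[Optional[dict[str, np.ndarray]]]:
    """Per-residue backbone coordinates (N/CA/C/O) or None when incomplete."""
    frames: list[Optional[dict[str, np.ndarray]]] = []
    for res in chain.residues:
        names = {}
        ok = True
        for n in ("N", "CA", "C", "O"):
            a = res.atom(n)
            if a is None:
                ok = False
                break
            names[n] = a.coord
        frames.append(names if ok else None)
    return frames


def _amide_h(frames, i: int) -> Optional[np.ndarray]:
    """Approximate amide-H position: 1 A from N along the previous C->O
    direction reversed (the standard DSSP construction)."""
    if i == 0 or frames[i] is None or frames[i - 1] is None:
        return None
    co = frames[i - 1]["C"] - frames[i - 1]["O"]
    n = np.linalg.norm(co)
    if n == 0:
        return None
    return frames[i]["N"] + co / n


def _hbond_set(frames_by_chain: dict[str, list], chains: dict[str, Chain],
               energy_cutoff: float) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """All (acceptor, donor) pairs with KS energy below the cutoff.

    Keys are (chain_id, residue position within chain, 0-based). Proline has
    no amide H and never donates.
    """
    bonds: set[tuple[tuple[str, int], tuple[str, int]]] = set()
    donors = []
    acceptors = []
    for cid, frames in frames_by_chain.items():
        for i, fr in enumerate(frames):
            if fr is None:
                continue
            acceptors.append((cid, i, fr["C"], fr["O"]))
            if chains[cid].residues[i].name != "PRO":
                h = _amide_h(frames, i)
                if h is not None:
                    donors.append((cid, i, fr["N"], h))
    for (ac, ai, c, o) in acceptors:
        for (dc, di, n, h) in donors:
            if ac == dc and abs(ai - di) < 2:
                continue
            if np.linalg.norm(o - n) > 5.2:  # cheap distance gate
                continue
            if _ks_hbond_energy(c, o, n, h) < energy_cutoff:
                bonds.add(((ac, ai), (dc, di)))
    return bonds


def _phi_psi(frames) -> list[tuple[Optional[float], Optional[float]]]:
    def dihedral(p0, p1, p2, p3) -> float:
        b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
        b1 = b1 / np.linalg.norm(b1)
        v = b0 - np.dot(b0, b1) * b1
        w = b2 - np.dot(b2, b1) * b1
        x = np.dot(v, w)
        y = np.dot(np.cross(b1, v), w)
        return math.degrees(math.atan2(y, x))

    out = []
    n = len(frames)
    for i in range(n):
        phi = psi = None
        if frames[i] is not None:
            if i > 0 and frames[i - 1] is not None:
                phi = dihedral(frames[i - 1]["C"], frames[i]["N"], frames[i]["CA"], frames[i]["C"])
            if i < n - 1 and frames[i + 1] is not None:
                psi = dihedral(frames[i]["N"], frames[i]["CA"], frames[i]["C"], frames[i + 1]["N"])
        out.append((phi, psi))
    return out


def assign_secondary_structure(structure: ProteinStructure, chain_id: str,
                               energy_cutoff: float = DEFAULT_HBOND_ENERGY,
                               ) -> SecondaryStructureString:
    """Three-state secondary structure (H/E/C) for one chain.

    Helices come from runs of n->n+4 backbone hydrogen bonds and strands
    from bridge/ladder pairings, both under the Kabsch-Sander electrostatic
    criterion (energy below ``energy_cutoff`` kcal/mol). Extended runs of
    three or more residues with beta-region backbone dihedrals are also
    labeled E, so that isolated strands (no ladder partner in the model)
    are not lost. Residues with incomplete backbone are labeled C. Other
    chains in the structure participate as H-bond partners (inter-chain
    sheets), but labels are returned for ``chain_id`` only.
    """
    chain = structure.chain(chain_id)
    frames_by_chain = {c.chain_id: _backbone_frames(c) for c in structure.chains}
    chains = {c.chain_id: c for c in structure.chains}
    frames = frames_by_chain[chain_id]
    n = len(frames)
    analyzable = sum(fr is not None for fr in frames)
    if analyzable < 5:
        raise ValueError(f"chain {chain_id}: fewer than 5 residues with complete backbone")

    bonds = _hbond_set(frames_by_chain, chains, energy_cutoff)

    def hb(acc: tuple[str, int], don: tuple[str, int]) -> bool:
        return (acc, don) in bonds

    labels = ["C"] * n
    me = chain_id

    # alpha helix: two consecutive n->n+4 turns cover residues i+1..i+4
    turn4 = [hb((me, i), (me, i + 4)) for i in range(n - 4)] + [False] * min(4, n)
    for i in range(n - 5):
        if turn4[i] and turn4[i + 1]:
            for j in range(i + 1, i + 5):
                labels[j] = "H"

    # beta bridges (parallel and antiparallel), within or across chains
    bridged = set()
    partners = [(cid, i) for cid, fr in frames_by_chain.items()
                for i in range(len(fr)) if fr[i] is not None]
    for i in range(n):
        if frames[i] is None:
            continue
        a = (me, i)
        for b in partners:
            if b[0] == me and abs(b[1] - i) < 3:
                continue
            j = b[1]
            cb = b[0]
            para = ((hb((me, i - 1), (cb, j)) and hb((cb, j), (me, i + 1))) if i > 0 else False) or \
                   ((hb((cb, j - 1), (me, i)) and hb((me, i), (cb, j + 1))) if j > 0 else False)
            anti = (hb((me, i), (cb, j)) and hb((cb, j), (me, i))) or \
                   ((hb((me, i - 1), (cb, j + 1)) and hb((cb, j - 1), (me, i + 1))) if (i > 0 and j > 0) else False)
            if para or anti:
                bridged.add(i)
                break
    for i in bridged:
        if labels[i] != "H":
            labels[i] = "E"

    # extended-dihedral fallback: beta-region runs of >=3 unlabeled residues
    pp = _phi_psi(frames)
    ext = [phi is not None and psi is not None and
           _EXT_PHI[0] <= phi <= _EXT_PHI[1] and _EXT_PSI[0] <= psi <= _EXT_PSI[1]
           for phi, psi in pp]
    run_start = None
    for i in range(n + 1):
        if i < n and ext[i] and labels[i] != "H":
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= 3:
                for j in range(run_start, i):
                    labels[j] = "E"
            run_start = None

    return SecondaryStructureString(chain_id=chain_id, labels="".join(labels))


# ---------------------------------------------------------------------------
# fold grammar

def segment_elements(ss: SecondaryStructureString, min_element_len: int = 3) -> list[SSElement]:
    """Maximal H/E runs of at least ``min_element_len`` residues, in order."""
    elements: list[SSElement] = []
    labels = ss.labels
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        if labels[i] in "HE" and j - i >= min_element_len:
            kind = "helix" if labels[i] == "H" else "strand"
            elements.append(SSElement(kind=kind, start=i + 1, end=j))
        i = j
    return elements


_RRE_PATTERN = ["strand", "strand", "strand", "helix", "helix", "helix"]
_ORDINALS = ["beta1", "beta2", "beta3", "alpha1", "alpha2", "alpha3"]


def detect_rre_fold(ss: SecondaryStructureString, min_len: int = 65,
                    min_element_len: int = 3,
                    max_domain_span: int = 130) -> RREClassification:
    """Strict RRE fold-order grammar on a 3-state secondary-structure string.

    Positive iff the chain is at least ``min_len`` residues long and the
    element list contains an N-to-C ordered subsequence
    strand,strand,strand,helix,helix,helix whose first-to-last span does
    not exceed ``max_domain_span`` residues. The most N-terminal qualifying
    match is reported; extra elements inside the matched span are allowed
    and recorded.
    """
    elements = segment_elements(ss, min_element_len=min_element_len)

    if len(ss) < min_len:
        return RREClassification(False, FailureReason.TOO_SHORT, elements=elements)

    n_strand = sum(e.kind == "strand" for e in elements)
    n_helix = sum(e.kind == "helix" for e in elements)
    if n_strand < 3 or n_helix < 3:
        return RREClassification(False, FailureReason.MISSING_ELEMENTS, elements=elements)

    ordered_exists = False
    for s0 in range(len(elements)):
        if elements[s0].kind != "strand":
            continue
        # greedy earliest pick for each remaining slot minimizes the span end
        picked = [s0]
        pos = s0
        for want in _RRE_PATTERN[1:]:
            nxt = next((k for k in range(pos + 1, len(elements))
                        if elements[k].kind == want), None)
            if nxt is None:
                break
            picked.append(nxt)
            pos = nxt
        if len(picked) < 6:
            continue
        ordered_exists = True
        span = (elements[picked[0]].start, elements[picked[-1]].end)
        if span[1] - span[0] + 1 <= max_domain_span:
            matched = []
            for ordinal, k in zip(_ORDINALS, picked):
                e = elements[k]
                matched.append(SSElement(e.kind, e.start, e.end, ordinal=ordinal))
            extras = [elements[k] for k in range(picked[0], picked[-1] + 1)
                      if k not in picked]
            return RREClassification(True, FailureReason.NONE, matched_elements=matched,
                                     domain_span=span, extra_elements=extras,
                                     elements=elements)
    reason = FailureReason.SPAN_EXCEEDED if ordered_exists else FailureReason.WRONG_ORDER
    return RREClassification(False, reason, elements=elements)


# ---------------------------------------------------------------------------
# contacts & superposition

def map_recognition_contacts(complex_structure: ProteinStructure, peptide_chain: str,
                             rre_chain: str, rre_class: RREClassification,
                             cutoff: float = 4.0) -> list[ContactRecord]:
    """Peptide-protein residue pairs within ``cutoff`` A (minimum heavy-atom
    distance), each annotated with the RRE element ordinal of the protein
    residue (or None outside the matched elements)."""
    pep = complex_structure.chain(peptide_chain)
    rre = complex_structure.chain(rre_chain)
    if len(pep) == 0:
        raise ValueError(f"peptide chain {peptide_chain} is empty")
    contacts: list[ContactRecord] = []
    rre_coords = [(pos + 1, res, res.heavy_coords()) for pos, res in enumerate(rre.residues)]
    for pres in pep.residues:
        pc = pres.heavy_coords()
        if pc.size == 0:
            continue
        for seq_idx, rres, rc in rre_coords:
            if rc.size == 0:
                continue
            dmin = float(cdist(pc, rc).min())
            if dmin <= cutoff:
                contacts.append(ContactRecord(
                    peptide_chain=peptide_chain, peptide_index=pres.index,
                    peptide_name=pres.name,
                    protein_chain=rre_chain, protein_index=rres.index,
                    protein_name=rres.name, distance=dmin,
                    protein_element=rre_class.element_for_residue(seq_idx)))
    return contacts


CLEFT_ELEMENTS = frozenset({"alpha3", "beta3"})


def peptide_engages_cleft(contacts: Sequence[ContactRecord]) -> bool:
    """True iff at least one contact touches the binding cleft (alpha3/beta3)."""
    return any(c.protein_element in CLEFT_ELEMENTS for c in contacts)


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Least-squares RMSD after optimal proper rigid superposition (Kabsch).

    Both inputs are (n, 3) arrays of paired coordinates, n >= 3.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be equal-shape (n, 3) arrays")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("coordinates must be finite")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    H = ac.T @ bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = ac @ R.T - bc
    return float(np.sqrt((diff ** 2).sum() / a.shape[0]))


def model_confidence_filter(models: Iterable[ProteinStructure], min_ptm: float = 0.60,
                            ) -> dict[str, list[ProteinStructure]]:
    """Partition predicted models by pTM confidence.

    Models with pTM >= ``min_ptm`` are retained (boundary inclusive), models
    below are removed, and models lacking a pTM score go to ``needs_review``
    rather than being silently retained.
    """
    out: dict[str, list[ProteinStructure]] = {"retained": [], "removed": [], "needs_review": []}
    for m in models:
        if m.ptm is None:
            out["needs_review"].append(m)
        elif m.ptm >= min_ptm:
            out["retained"].append(m)
        else:
            out["removed"].append(m)
    return out
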