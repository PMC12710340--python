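"""Domain excision and per-model bitscore threshold calibration.

Profile-HMM searches report domain envelopes on full-length proteins; the
RRE domain is excised on those envelope coordinates for downstream network
analysis. Each model gets a recommended bitscore threshold chosen by
sweeping the observed scores and maximizing F1 over a labeled validation
set, with precision = TP/(TP+FP), recall = TP/(TP+FN) and F1 their harmonic
mean. Predictions are inclusive: score >= threshold counts as positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence


@dataclass
class DomainHit:
    """One profile-HMM domain hit (1-based inclusive coordinates)."""

    protein_id: str
    model_id: str
    full_bitscore: float
    domain_bitscore: float
    env_start: int
    env_end: int
    aln_start: Optional[int] = None
    aln_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.env_start > self.env_end:
            raise ValueError(f"{self.protein_id}: envelope start > end")
        if self.env_start < 1:
            raise ValueError(f"{self.protein_id}: envelope coordinates are 1-based")

    def score(self, use_domain: bool = True) -> float:
        return self.domain_bitscore if use_domain else self.full_bitscore


@dataclass
class LabeledHit:
    hit: DomainHit
    is_rre: bool


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ThresholdPoint:
    threshold: float
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts


@dataclass
class ThresholdCurve:
    points: list[ThresholdPoint] = field(default_factory=list)

    @property
    def recommended_threshold(self) -> float:
        return recommend_threshold(self)


def excise_domain(sequence: str, hit: DomainHit, padding: int = 0) -> str:
    """Subsequence under the hit envelope, optionally padded, clipped at the
    sequence boundaries. Coordinates are 1-based inclusive."""
    n = len(sequence)
    if hit.env_end > n:
        raise ValueError(
            f"{hit.protein_id}: envelope {hit.env_start}-{hit.env_end} outside sequence of length {n}")
    start = max(1, hit.env_start - padding)
    end = min(n, hit.env_end + padding)
    return sequence[start - 1:end]


def excised_fasta_header(hit: DomainHit, padding: int = 0, seq_len: Optional[int] = None) -> str:
    """FASTA header carrying coordinate provenance, e.g. ``prot1|env:10-80``."""
    start = hit.env_start - padding
    end = hit.env_end + padding
    if seq_len is not None:
        start = max(1, start)
        end = min(seq_len, end)
    return f"{hit.protein_id}|env:{start}-{end}"


def parse_excised_header(header: str) -> tuple[str, int, int]:
    """Inverse of :func:`excised_fasta_header`."""
    pid, _, coords = header.rpartition("|env:")
    start_s, _, end_s = coords.partition("-")
    return pid, int(start_s), int(end_s)


def confusion_at_threshold(labeled: Sequence[LabeledHit], threshold: float,
                           use_domain_score: bool = True) -> ConfusionCounts:
    tp = fp = fn = tn = 0
    for item in labeled:
        predicted = item.hit.score(use_domain_score) >= threshold
        if predicted and item.is_rre:
            tp += 1
        elif predicted:
            fp += 1
        elif item.is_rre:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def precision_recall_f1(labeled: Sequence[LabeledHit],
                        use_domain_score: bool = True) -> ThresholdCurve:
    """Precision/recall/F1 swept over every distinct observed bitscore.

    Precision at zero predictions is defined as 0 so the curve stays total;
    F1 is 0 whenever precision or recall is 0. Requires at least one
    positive label (recall is undefined otherwise).
    """
    labeled = list(labeled)
    if not any(item.is_rre for item in labeled):
        raise ValueError("no positive labels: recall undefined")
    thresholds = sorted({item.hit.score(use_domain_score) for item in labeled})
    points = []
    for t in thresholds:
        c = confusion_at_threshold(labeled, t, use_domain_score)
        precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
        recall = c.tp / (c.tp + c.fn)
        f1 = (2 * precision * recall / (precision + recall)
              if (precision + recall) > 0 else 0.0)
        points.append(ThresholdPoint(t, precision, recall, f1, c))
    return ThresholdCurve(points=points)


def recommend_threshold(curve: ThresholdCurve, policy: str = "max_f1") -> float:
    """Threshold maximizing F1; ties go to the lower threshold (higher recall)."""
    if policy != "max_f1":
        raise ValueError(f"unknown policy {policy!r}")
    if not curve.points:
        raise ValueError("empty threshold curve")
    best = curve.points[0]
    for p in curve.points[1:]:
        if p.f1 > best.f1:
            best = p
    return best.threshold


def expand_seed_set(current_members: set[str], candidates: Sequence[LabeledHit],
                    fold_checks: dict, existing_model_hits: set[str],
                    threshold: float, use_domain_score: bool = True) -> list[str]:
    """Iterative seed expansion: candidates scoring below the current
    recommended threshold whose structure nonetheless shows the RRE fold,
    and that no existing model already retrieves. Deterministic order."""
    additions = []
    for item in candidates:
        pid = item.hit.protein_id
        if pid in current_members or pid in existing_model_hits:
            continue
        if item.hit.score(use_domain_score) >= threshold:
            continue
        check = fold_checks.get(pid)
        if check is not None and check.is_rre:
            additions.append(pid)
    return sorted(set(additions))


def classify_discrete(sequence_length: int, annotations: set[str],
                      discrete_max_len: int = 110,
                      rre_accessions: frozenset[str] = frozenset({"PF05402"})) -> str:
    """Discrete vs fused RRE protein by length and annotation content.

    <= ``discrete_max_len`` residues: a standalone (discrete) RRE. Longer
    proteins with a second, non-RRE annotation are fused; longer proteins
    with no extra annotation are ambiguous — over the discrete size cutoff
    but with nothing to pin the fusion partner on.
    """
    if sequence_length <= 0:
        raise ValueError("sequence length must be positive")
    if sequence_length <= discrete_max_len:
        return "discrete"
    extra = {a for a in annotations if a not in rre_accessions}
    return "fused" if extra else "ambiguous"


# ---------------------------------------------------------------------------
# file I/O

def read_domain_table(path: str | Path,
                      columns: tuple[str, ...] = ("target", "query", "full_bitscore",
                                                  "domain_bitscore", "env_from", "env_to"),
                      ) -> list[DomainHit]:
    """Read a simple tab-separated per-domain hit table (HMMER-style content,
    configurable column order; '#' comments and a header row tolerated)."""
    idx = {c: i for i, c in enumerate(columns)}
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == columns[0]:
                continue
            hits.append(DomainHit(
                protein_id=parts[idx["target"]],
                model_id=parts[idx["query"]],
                full_bitscore=float(parts[idx["full_bitscore"]]),
                domain_bitscore=float(parts[idx["domain_bitscore"]]),
                env_start=int(parts[idx["env_from"]]),
                env_end=int(parts[idx["env_to"]])))
    return hits


def write_curve_tsv(curve: ThresholdCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tprecision\trecall\tf1\ttp\tfp\tfn\ttn\n")
        for p in curve.points:
            c = p.counts
            fh.write(f"{p.threshold:.4g}\t{p.precision:.6f}\t{p.recall:.6f}\t{p.f1:.6f}"
                     f"\t{c.tp}\t{c.fp}\t{c.fn}\t{c.tn}\n")


def write_excised_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")
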