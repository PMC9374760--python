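"""In-silico tryptic digestion and quantotypic candidate filtering.

Candidate peptides come from a full tryptic digest (cleave after K/R unless
followed by P).  Each candidate is scored against a rule set split into
hard requirements (fully tryptic with no internal slow-cleaving KP/RP
sites; unique to the target protein, with Ile/Leu treated as
indistinguishable) and soft preferences (no ragged cleavage neighborhood,
one copy per protein, length 5-20, no oxidation/deamidation-prone or
terminal residues, no variant or PTM overlap, ortholog and isoform
compatibility, prior spectral evidence).  The score is a weighted count of
soft failures — weights are configuration, one point each by default — and
ranking is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DigestPeptide",
    "FilterReport",
    "PeptideAnnotations",
    "SelectionConfig",
    "UniquenessIndex",
    "digest_tryptic",
    "evaluate_criteria",
    "build_uniqueness_index",
    "rank_candidates",
    "select_peptides",
    "collapse_il",
]

TERMINUS = "-"
_STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

CRITERIA = (
    "tryptic",          # hard: no internal KP/RP
    "neighbor_sites",   # soft: ragged cleavage neighborhood
    "single_copy",      # soft: one copy per protein copy
    "length",           # soft: 5-20 residues
    "residues",         # soft: C/M/N/Q, N-term Q, protein termini, PTM overlap
    "variant",          # soft: overlaps an annotated variant
    "ortholog",         # soft: not usable for the declared ortholog
    "unique",           # hard: shared with unrelated proteins
    "isoform",          # soft: absent from the dominant splice isoform
    "proteotypic",      # soft: no/weak prior spectral evidence
)

PASS = "pass"
SOFT_FAIL = "soft_fail"
HARD_FAIL = "hard_fail"


def collapse_il(sequence: str) -> str:
    """Ile and Leu are isobaric and chromatographically near-identical."""
    return sequence.replace("I", "L")


@dataclass(frozen=True)
class DigestPeptide:
    sequence: str
    start: int  # 0-based, half-open [start, end) into the parent
    end: int
    prev_aa: str = TERMINUS
    next_aa: str = TERMINUS
    missed_cleavages: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FilterReport:
    peptide: DigestPeptide
    criterion_flags: dict[str, str]
    score: float

    @property
    def hard_pass(self) -> bool:
        return HARD_FAIL not in self.criterion_flags.values()


@dataclass
class PeptideAnnotations:
    """Optional evidence consulted by the soft criteria; all fields may be empty.

    Site positions are 0-based indices into the parent protein sequence.
    """

    parent_sequence: str = ""
    ptm_sites: frozenset[int] = frozenset()
    variant_sites: frozenset[int] = frozenset()
    ortholog_supported: frozenset[str] | None = None  # peptide sequences
    isoform_supported: frozenset[str] | None = None
    evidence_scores: Mapping[str, float] | None = None
    uniqueness: str | None = None  # "unique" | "shared_homologues" | "non_unique"


@dataclass
class SelectionConfig:
    weights: dict[str, float] = field(default_factory=dict)
    length_range: tuple[int, int] = (5, 20)
    min_evidence: float = 0.5

    def weight(self, criterion: str) -> float:
        return self.weights.get(criterion, 1.0)


def digest_tryptic(sequence: str) -> list[DigestPeptide]:
    """Full tryptic digest: cleave after K or R except before P (Keil rule).

    The peptides tile the input exactly.  Peptides containing internal KP/RP
    (possible because of the proline exception) are produced; flagging them
    is the filter's job.  Non-standard residues are tolerated here and
    flagged downstream.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    boundaries = [0]
    for i, residue in enumerate(sequence[:-1]):
        if residue in "KR" and sequence[i + 1] != "P":
            boundaries.append(i + 1)
    boundaries.append(len(sequence))
    peptides = []
    for start, end in zip(boundaries[:-1], boundaries[1:]):
        peptides.append(
            DigestPeptide(
                sequence=sequence[start:end],
                start=start,
                end=end,
                prev_aa=sequence[start - 1] if start > 0 else TERMINUS,
                next_aa=sequence[end] if end < len(sequence) else TERMINUS,
                missed_cleavages=0,
            )
        )
    return peptides


def _has_internal_cleavage_issue(seq: str) -> bool:
    # internal K/R not at the C-terminus: either a KP/RP site (slow) or a
    # missed cleavage -- both disqualify
    return any(residue in "KR" for residue in seq[:-1])


def evaluate_criteria(
    peptide: DigestPeptide,
    annotations: PeptideAnnotations | None = None,
    config: SelectionConfig | None = None,
) -> FilterReport:
    """Apply the ten-rule candidate filter to one digest peptide."""
    ann = annotations or PeptideAnnotations()
    cfg = config or SelectionConfig()
    seq = peptide.sequence
    parent = ann.parent_sequence
    flags: dict[str, str] = {c: PASS for c in CRITERIA}

    if _has_internal_cleavage_issue(seq) or not set(seq) <= _STANDARD_RESIDUES:
        flags["tryptic"] = HARD_FAIL

    neighbor = peptide.next_aa in "KR"
    if not neighbor and peptide.start >= 2 and parent:
        neighbor = parent[peptide.start - 2] in "KR"
    if neighbor:
        flags["neighbor_sites"] = SOFT_FAIL

    if parent and collapse_il(parent).count(collapse_il(seq)) > 1:
        flags["single_copy"] = SOFT_FAIL

    lo, hi = cfg.length_range
    if not lo <= len(seq) <= hi:
        flags["length"] = SOFT_FAIL

    residue_issue = (
        any(r in seq for r in "CMNQ")
        or seq.startswith("Q")
        or peptide.start == 0
        or (parent and peptide.end == len(parent))
    )
    touched = set(range(peptide.start - 1, peptide.end + 1))
    if ann.ptm_sites & touched:
        residue_issue = True
    if residue_issue:
        flags["residues"] = SOFT_FAIL

    if ann.variant_sites & touched:
        flags["variant"] = SOFT_FAIL

    if ann.ortholog_supported is not None and seq not in ann.ortholog_supported:
        flags["ortholog"] = SOFT_FAIL

    if ann.uniqueness == "non_unique":
        flags["unique"] = HARD_FAIL
    elif ann.uniqueness == "shared_homologues":
        flags["unique"] = SOFT_FAIL

    if ann.isoform_supported is not None and seq not in ann.isoform_supported:
        flags["isoform"] = SOFT_FAIL

    if ann.evidence_scores is not None:
        if ann.evidence_scores.get(seq, 0.0) < cfg.min_evidence:
            flags["proteotypic"] = SOFT_FAIL

    score = sum(cfg.weight(c) for c, f in flags.items() if f == SOFT_FAIL)
    return FilterReport(peptide=peptide, criterion_flags=flags, score=score)


class UniquenessIndex:
    """Answers: is a peptide unique to its target within a proteome?

    Matching is by I/L-collapsed substring containment, so peptides hiding
    inside other proteins in non-tryptic contexts still count as shared.
    """

    def __init__(
        self,
        proteome: Mapping[str, str],
        homologue_groups: Sequence[frozenset[str] | set[str]] = (),
    ) -> None:
        self._collapsed = {acc: collapse_il(seq.upper()) for acc, seq in proteome.items()}
        self._groups = [frozenset(g) for g in homologue_groups]
        self._cache: dict[str, frozenset[str]] = {}

    def parents(self, peptide_sequence: str) -> frozenset[str]:
        key = collapse_il(peptide_sequence.upper())
        if key not in self._cache:
            self._cache[key] = frozenset(
                acc for acc, seq in self._collapsed.items() if key in seq
            )
        return self._cache[key]

    def classify(self, peptide_sequence: str, target: str) -> str:
        parents = self.parents(peptide_sequence)
        others = parents - {target}
        if not others:
            return "unique"
        for group in self._groups:
            if target in group and parents <= group:
                return "shared_homologues"
        return "non_unique"


def build_uniqueness_index(
    proteome: Mapping[str, str],
    homologue_groups: Sequence[frozenset[str] | set[str]] = (),
) -> UniquenessIndex:
    """Index a proteome (accession -> sequence) for uniqueness lookups."""
    return UniquenessIndex(proteome, homologue_groups)


def rank_candidates(reports: Iterable[FilterReport]) -> list[FilterReport]:
    """Deterministic total order: hard-pass first, then ascending score, then
    length closest to the midpoint of the preferred range, then sequence."""
    midpoint = 12.5

    def sort_key(report: FilterReport):
        return (
            not report.hard_pass,
            report.score,
            abs(len(report.peptide) - midpoint),
            report.peptide.sequence,
        )

    return sorted(reports, key=sort_key)


def select_peptides(
    proteome: Mapping[str, str],
    annotations: Mapping[str, PeptideAnnotations] | None = None,
    config: SelectionConfig | None = None,
    homologue_groups: Sequence[frozenset[str] | set[str]] = (),
    n_per_protein: int = 2,
) -> pd.DataFrame:
    """Digest, filter and rank candidates for every protein in a proteome.

    Returns one row per candidate with per-criterion flags, the score, the
    within-protein rank, and whether the candidate made the top
    ``n_per_protein`` hard-pass cut.
    """
    cfg = config or SelectionConfig()
    annotations = annotations or {}
    index = build_uniqueness_index(proteome, homologue_groups)
    rows = []
    for accession in sorted(proteome):
        sequence = proteome[accession].upper()
        base = annotations.get(accession) or PeptideAnnotations()
        reports = []
        for peptide in digest_tryptic(sequence):
            ann = PeptideAnnotations(
                parent_sequence=sequence,
                ptm_sites=base.ptm_sites,
                variant_sites=base.variant_sites,
                ortholog_supported=base.ortholog_supported,
                isoform_supported=base.isoform_supported,
                evidence_scores=base.evidence_scores,
                uniqueness=index.classify(peptide.sequence, accession),
            )
            reports.append(evaluate_criteria(peptide, ann, cfg))
        ranked = rank_candidates(reports)
        n_selected = 0
        for rank, report in enumerate(ranked, start=1):
            selected = report.hard_pass and n_selected < n_per_protein
            if selected:
                n_selected += 1
            rows.append(
                {
                    "protein": accession,
                    "peptide": report.peptide.sequence,
                    "start": report.peptide.start,
                    "end": report.peptide.end,
                    "hard_pass": report.hard_pass,
                    "score": report.score,
                    "rank": rank,
                    "selected": selected,
                    **{f"flag_{c}": report.criterion_flags[c] for c in CRITERIA},
                }
            )
    return pd.DataFrame(rows)
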