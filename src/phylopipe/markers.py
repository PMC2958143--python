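"""Single-copy marker mining on a protein set.

An all-vs-all local alignment search stands in for a translated BLAST of a
genome against itself: each significant hit carries similarity S (percent
identity over the aligned region) and coverage C (percent of the *query*
covered by the aligned region). A gene is kept as single-copy only when every
non-self hit it is involved in has S below `s_max` AND C below `c_max`
(strict reading: any sufficiently similar or sufficiently covering duplicate
disqualifies). Orthology of a marker against a reference set is confirmed by
requiring exactly one significant non-self hit.

Significance is a raw alignment-score cutoff (BLOSUM62, affine gaps), not a
database-size-dependent e-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["Hit", "HitTable", "all_vs_all_search", "filter_single_copy",
           "confirm_single_hit", "bin_by_exon_length"]

DEFAULT_SCORE_CUTOFF = 80.0


@dataclass
class Hit:
    query: str
    subject: str
    similarity: float   # percent identity over aligned columns, [0,100]
    coverage: float     # percent of query length covered, [0,100]
    score: float

    def __post_init__(self):
        if not (0 <= self.similarity <= 100) or not (0 <= self.coverage <= 100):
            raise ValueError("similarity/coverage out of [0,100]")

    @property
    def is_self(self) -> bool:
        return self.query == self.subject


@dataclass
class HitTable:
    hits: list[Hit]
    score_cutoff: float = DEFAULT_SCORE_CUTOFF
    scoring: str = "blosum62/open-11/ext-1"

    def __post_init__(self):
        queries = {h.query for h in self.hits}
        selfs = {h.query for h in self.hits if h.is_self}
        if queries - selfs:
            raise ValueError("every query must carry its self-hit")

    def queries(self) -> set[str]:
        return {h.query for h in self.hits}

    def hits_for(self, gene: str, include_self: bool = False) -> list[Hit]:
        return [h for h in self.hits
                if h.query == gene and (include_self or not h.is_self)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(h.query, h.subject, h.similarity, h.coverage, h.score)
             for h in self.hits],
            columns=["query", "subject", "similarity", "coverage", "score"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _alignment_stats(aln) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """(percent identity over aligned columns, query span, subject span)."""
    matches = 0
    columns = 0
    for (ts, te), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
        seg_t = str(aln.target[ts:te])
        seg_q = str(aln.query[qs:qe])
        matches += sum(a == b for a, b in zip(seg_t, seg_q))
        columns += te - ts
    # count gap columns inside the local region
    t_span = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
    q_span = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
    gap_cols = (t_span[1] - t_span[0] - columns) + (q_span[1] - q_span[0] - columns)
    total_cols = columns + gap_cols
    identity = 100.0 * matches / total_cols if total_cols else 0.0
    return identity, t_span, q_span


def all_vs_all_search(records: Sequence[tuple[str, str]],
                      score_cutoff: float = DEFAULT_SCORE_CUTOFF) -> HitTable:
    """All-vs-all local protein alignment; reports every ordered pair whose
    best local alignment scores at or above the cutoff, plus all self-hits."""
    records = list(records)
    if not records:
        raise ValueError("empty record set")
    if score_cutoff <= 0:
        raise ValueError("cutoff must be positive")
    aligner = _make_aligner()
    hits: list[Hit] = []
    for gid, seq in records:
        hits.append(Hit(gid, gid, 100.0, 100.0,
                        float(aligner.score(seq, seq))))
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            (qi, si), (qj, sj) = records[i], records[j]
            score = float(aligner.score(si, sj))
            if score < score_cutoff:
                continue
            aln = aligner.align(si, sj)[0]
            identity, span_i, span_j = _alignment_stats(aln)
            cov_i = 100.0 * (span_i[1] - span_i[0]) / len(si)
            cov_j = 100.0 * (span_j[1] - span_j[0]) / len(sj)
            hits.append(Hit(qi, qj, identity, min(cov_i, 100.0), score))
            hits.append(Hit(qj, qi, identity, min(cov_j, 100.0), score))
    return HitTable(hits=hits, score_cutoff=score_cutoff)


def filter_single_copy(table: HitTable, s_max: float = 30.0,
                       c_max: float = 30.0) -> tuple[set[str], dict[str, Optional[Hit]]]:
    """Retain genes whose every non-self hit has S < s_max AND C < c_max.

    Returns (retained ids, per-gene worst-offender hit or None). The filter
    is monotone: raising either threshold can only grow the retained set.
    """
    if not (0 < s_max <= 100) or not (0 < c_max <= 100):
        raise ValueError("thresholds must be in (0,100]")
    retained: set[str] = set()
    diagnostics: dict[str, Optional[Hit]] = {}
    for gene in sorted(table.queries()):
        offenders = [h for h in table.hits_for(gene)
                     if not (h.similarity < s_max and h.coverage < c_max)]
        if offenders:
            diagnostics[gene] = max(offenders,
                                    key=lambda h: (h.similarity, h.coverage))
        else:
            retained.add(gene)
            diagnostics[gene] = None
    return retained, diagnostics


def confirm_single_hit(query: str, database_table: HitTable) -> bool:
    """True iff exactly one distinct non-self subject is hit significantly."""
    if query not in database_table.queries():
        raise KeyError(f"query {query!r} absent from table")
    subjects = {h.subject for h in database_table.hits_for(query)}
    return len(subjects) == 1


def bin_by_exon_length(exon_lengths: dict[str, float] | Sequence[float],
                       boundaries: Sequence[float] = (500, 600, 700, 800)) -> dict:
    """Histogram of exon lengths over (b0,b1], ..., (b_last, inf); lengths at
    or below the first boundary are reported separately under 'below'."""
    bl = list(boundaries)
    if bl != sorted(bl) or len(set(bl)) != len(bl):
        raise ValueError("boundaries must be strictly increasing")
    if isinstance(exon_lengths, dict):
        values = list(exon_lengths.values())
    else:
        values = list(exon_lengths)
    if any(v < 0 for v in values):
        raise ValueError("exon lengths must be >= 0")
    labels = [f"({bl[i]:g},{bl[i+1]:g}]" for i in range(len(bl) - 1)]
    labels.append(f"({bl[-1]:g},inf)")
    counts = {"below": 0, **{lab: 0 for lab in labels}}
    for v in values:
        if v <= bl[0]:
            counts["below"] += 1
            continue
        placed = False
        for i in range(len(bl) - 1):
            if bl[i] < v <= bl[i + 1]:
                counts[labels[i]] += 1
                placed = True
                break
        if not placed:
            counts[labels[-1]] += 1
    return counts
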