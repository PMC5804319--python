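"""Minbit-weighted homology graph construction.

The homology layer scores every amino-acid sequence against every other one
(either with the built-in Smith–Waterman backend or from an imported BLAST
outfmt-6 table), normalizes each hit's bitscore by the smaller of the two
genes' self-alignment bitscores (the *minbit* heuristic), and keeps pairs at
or above the minbit threshold as undirected edges for MCL.

minbit(q, s) = bitscore(q, s) / min(selfscore(q), selfscore(s))

A self-hit therefore has minbit exactly 1, and minbit is length-normalized:
a short perfect alignment between two long genes scores low.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

from .model import AnalysisParams, GeneCall, HitRecord, MetapanError, MinbitEdge

__all__ = [
    "HitRecord",
    "MinbitEdge",
    "ScoringParams",
    "raw_score_to_bits",
    "compute_self_scores",
    "minbit",
    "build_minbit_graph",
    "all_vs_all_search",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringParams:
    """Built-in aligner settings, chosen for comparability with blastp output.

    BLOSUM62 with affine gaps costing ``gap_open + k * gap_extend`` for a
    gap of length k, and the standard gapped Karlin–Altschul constants for
    those penalties; bitscore = (lambda * S - ln K) / ln 2.
    ``kmer_prefilter_k > 0`` skips pairs sharing no k-mer (such pairs cannot
    reach the minbit threshold at the divergence levels of interest); 0
    disables the prefilter.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    kmer_prefilter_k: int = 5

    def bits(self, raw_score: float) -> float:
        return (self.karlin_lambda * raw_score - math.log(self.karlin_k)) / math.log(2)


def raw_score_to_bits(raw_score: float, scoring: ScoringParams | None = None) -> float:
    """Convert a raw alignment score to bits with Karlin–Altschul statistics."""
    return (scoring or ScoringParams()).bits(raw_score)


@lru_cache(maxsize=4)
def _substitution_matrix(name: str):
    from Bio.Align import substitution_matrices

    return substitution_matrices.load(name)


def _self_raw_score(aa_seq: str, matrix) -> float:
    # ungapped full-length self-alignment: sum of diagonal substitution scores
    return float(sum(matrix[c, c] for c in aa_seq))


def compute_self_scores(
    genes: list[GeneCall], scoring: ScoringParams | None = None
) -> dict[str, float]:
    """Self-alignment bitscore per gene (the minbit normalizer).

    Computed as the ungapped full-length self-alignment under the scoring
    matrix, converted to bits; strictly positive for any non-empty sequence.
    """
    scoring = scoring or ScoringParams()
    matrix = _substitution_matrix(scoring.matrix)
    scores: dict[str, float] = {}
    for g in genes:
        if not g.aa_seq:
            raise MetapanError(f"gene {g.gene_id!r}: empty amino-acid sequence")
        scores[g.gene_id] = scoring.bits(_self_raw_score(g.aa_seq, matrix))
    return scores


def minbit(hit: HitRecord, self_q: float, self_s: float) -> float:
    """Bitscore of the hit divided by the smaller of the two self-scores."""
    if self_q <= 0 or self_s <= 0:
        raise MetapanError(
            f"hit {hit.query_id}->{hit.subject_id}: non-positive self-score"
        )
    return hit.bitscore / min(self_q, self_s)


def build_minbit_graph(
    hits: list[HitRecord],
    self_scores: dict[str, float],
    params: AnalysisParams | None = None,
) -> list[MinbitEdge]:
    """Filter hits by minbit and collapse reciprocals into undirected edges.

    Self-hits are dropped. Pairs with minbit >= ``minbit_threshold`` are
    kept; when the two directions of a pair disagree, the edge takes the
    maximum minbit. The edge weight passed to MCL is the minbit value.
    """
    params = (params or AnalysisParams()).validate()
    best: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        for gid in (h.query_id, h.subject_id):
            if gid not in self_scores:
                raise MetapanError(f"hit references gene {gid!r} without a self-score")
        mb = minbit(h, self_scores[h.query_id], self_scores[h.subject_id])
        key = (min(h.query_id, h.subject_id), max(h.query_id, h.subject_id))
        if mb > best.get(key, -1.0):
            best[key] = mb
    return [
        MinbitEdge(gene_a=a, gene_b=b, minbit=mb, weight=mb)
        for (a, b), mb in sorted(best.items())
        if mb >= params.minbit_threshold
    ]


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def all_vs_all_search(
    genes: list[GeneCall], scoring: ScoringParams | None = None
) -> list[HitRecord]:
    """All-vs-all local alignment of amino-acid sequences.

    Smith–Waterman with the configured matrix and affine gaps, bitscores on
    the same scale as imported BLAST tables. Each unordered pair is emitted
    once in canonical order (query_id <= subject_id) and every gene gets its
    self-hit. Pairs with no positive-scoring local alignment are omitted.
    """
    from Bio.Align import PairwiseAligner

    scoring = scoring or ScoringParams()
    if not genes:
        raise MetapanError("all_vs_all_search needs at least one gene")
    matrix = _substitution_matrix(scoring.matrix)
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend

    ordered = sorted(genes, key=lambda g: g.gene_id)
    seen = set()
    for g in ordered:
        if g.gene_id in seen:
            raise MetapanError(f"duplicate gene id {g.gene_id!r}")
        seen.add(g.gene_id)
        if not g.aa_seq:
            raise MetapanError(f"gene {g.gene_id!r}: empty amino-acid sequence")

    k = scoring.kmer_prefilter_k
    kmers = {g.gene_id: _kmer_set(g.aa_seq, k) for g in ordered} if k > 0 else None

    hits: list[HitRecord] = []
    for i, gq in enumerate(ordered):
        # self-hit: full-length ungapped diagonal, identical to compute_self_scores
        self_raw = _self_raw_score(gq.aa_seq, matrix)
        hits.append(
            HitRecord(
                query_id=gq.gene_id,
                subject_id=gq.gene_id,
                percent_identity=100.0,
                align_length=len(gq.aa_seq),
                bitscore=scoring.bits(self_raw),
            )
        )
        for gs in ordered[i + 1 :]:
            if kmers is not None and kmers[gq.gene_id].isdisjoint(kmers[gs.gene_id]):
                continue
            aln = aligner.align(gq.aa_seq, gs.aa_seq)
            if aln.score <= 0:
                continue
            top = aln[0]
            counts = top.counts()
            length = counts.identities + counts.mismatches + counts.gaps
            hits.append(
                HitRecord(
                    query_id=gq.gene_id,
                    subject_id=gs.gene_id,
                    percent_identity=100.0 * counts.identities / max(length, 1),
                    align_length=max(length, 1),
                    bitscore=scoring.bits(aln.score),
                )
            )
    return hits
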