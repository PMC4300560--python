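"""Read-recruitment consensus assembly of ribosomal genes.

The procedure mirrors how highly repeated rRNA genes are recovered when an
assembly fails to represent them: seed with a reference gene sequence,
recruit shotgun reads similar to it, column-vote a consensus, use that
consensus as the next query, and iterate until the consensus stops
changing.  Gene boundaries are then delineated by the position at which
sliding-window similarity to a reference gene drops, and the Pol III
terminator of 5S-type genes is located as the first CTTTT motif downstream
of the gene.

Recruitment uses overlap (free-end-gap) pairwise alignment with unit
match/mismatch scores via Biopython's C aligner; a read is recruited when
its best alignment to the query, on either strand, reaches the identity
and overlap thresholds.  The procedure is deliberately query-biased, like
the BLAST-seeded manual assembly it reconstructs: reads diverging beyond
``min_identity`` from the current query are never seen.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

from Bio import Align

from ._util import revcomp


@dataclasses.dataclass
class ReadHit:
    """One recruited read placed on the current consensus coordinate system."""

    read_id: str
    offset: int  # consensus coordinate of read position 0 (may be negative)
    strand: str
    columns: dict[int, str]  # consensus column -> base contributed
    identity: float
    aligned_length: int


@dataclasses.dataclass
class ConsensusSequence:
    """Per-column base calls with coverage and allele counts.

    ``start`` is the coordinate of the first column relative to the query
    that anchored recruitment (negative when reads extended 5' of it).
    A column is called N when coverage is below ``min_coverage``, when no
    base reaches the majority fraction, or on a tie.
    """

    sequence: str
    start: int
    coverage: list[int]
    allele_counts: list[dict[str, int]]

    def __len__(self) -> int:
        return len(self.sequence)

    def slice_on_query(self, qstart: int, qend: int) -> str:
        """The called bases over query coordinates [qstart, qend)."""
        out = []
        for q in range(qstart, qend):
            i = q - self.start
            out.append(self.sequence[i] if 0 <= i < len(self.sequence) else "N")
        return "".join(out)


def _make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    # -2.1 rather than -2: an integer gap penalty makes one gap score-equal
    # to two mismatches, leaving co-optimal alignments with different
    # identities; the 0.1 offset breaks that tie class deterministically
    a.open_gap_score = -2.1
    a.extend_gap_score = -2.1
    # free end gaps on both sequences -> overlap alignment
    a.end_gap_score = 0
    return a


def _align_one(aligner, query: str, read: str):
    """Best overlap alignment of read vs query: (matches, pairs, offset, columns)."""
    aln = aligner.align(query, read)[0]
    tblocks, rblocks = aln.aligned
    matches = 0
    pairs = 0
    columns: dict[int, str] = {}
    first_t = first_r = None
    last_t = last_r = None
    for (t0, t1), (r0, r1) in zip(tblocks, rblocks):
        if first_t is None:
            first_t, first_r = t0, r0
        last_t, last_r = t1, r1
        for i in range(t1 - t0):
            qb, rb = query[t0 + i], read[r0 + i]
            pairs += 1
            if qb == rb:
                matches += 1
            columns[t0 + i] = rb
    if pairs == 0:
        return 0, 0, 0, {}
    # overhangs: place unaligned read ends ungapped beyond the query
    offset = first_t - first_r
    for r in range(first_r):
        columns[first_t - (first_r - r)] = read[r]
    for k, r in enumerate(range(last_r, len(read))):
        columns[last_t + k] = read[r]
    return matches, pairs, offset, columns


def recruit_reads(
    reads: dict[str, str],
    query: str,
    min_identity: float = 0.85,
    min_overlap: int = 50,
) -> list[ReadHit]:
    """Recruit reads whose best overlap alignment to `query` (either strand)
    has identity >= min_identity over >= min_overlap aligned base pairs.

    Hits are reported on the query strand: a read recruited via its reverse
    complement contributes reverse-complemented bases.
    """
    if not query:
        raise ValueError("empty query")
    aligner = _make_aligner()
    hits: list[ReadHit] = []
    for rid, seq in reads.items():
        best = None
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            matches, pairs, offset, columns = _align_one(aligner, query, oriented)
            if pairs < min_overlap:
                continue
            ident = matches / pairs
            if ident < min_identity:
                continue
            key = (matches, strand == "+")  # deterministic strand preference
            if best is None or key > best[0]:
                best = (key, ReadHit(rid, offset, strand, columns, ident, pairs))
        if best is not None:
            hits.append(best[1])
    return hits


def call_consensus(
    hits: list[ReadHit],
    min_coverage: int = 2,
    majority_fraction: float = 0.5,
) -> ConsensusSequence:
    """Column-wise majority vote over placed reads.

    The call is the most frequent base when its fraction reaches
    ``majority_fraction`` and coverage reaches ``min_coverage``; ties and
    thin columns give N.  No hits give a zero-length consensus.
    """
    if not hits:
        return ConsensusSequence("", 0, [], [])
    counters: dict[int, Counter] = {}
    for h in hits:
        for col, base in h.columns.items():
            counters.setdefault(col, Counter())[base] += 1
    lo = min(counters)
    hi = max(counters)
    seq = []
    coverage = []
    alleles = []
    for col in range(lo, hi + 1):
        c = counters.get(col, Counter())
        cov = sum(c.values())
        coverage.append(cov)
        alleles.append(dict(c))
        if cov < min_coverage:
            seq.append("N")
            continue
        (top_base, top_n), *rest = c.most_common()
        if rest and rest[0][1] == top_n:  # tie
            seq.append("N")
        elif top_n / cov >= majority_fraction:
            seq.append(top_base)
        else:
            seq.append("N")
    return ConsensusSequence("".join(seq), lo, coverage, alleles)


@dataclasses.dataclass
class IterationResult:
    consensus: ConsensusSequence
    rounds: int
    converged: bool


def iterate_to_convergence(
    reads: dict[str, str],
    query: str,
    rounds_max: int = 5,
    min_identity: float = 0.85,
    min_overlap: int = 50,
    min_coverage: int = 2,
    majority_fraction: float = 0.5,
) -> IterationResult:
    """Re-query with the previous round's consensus until it stops changing.

    Stops early when two successive consensi are identical; otherwise runs
    ``rounds_max`` rounds and reports ``converged=False`` (oscillation).
    Zero recruited reads yield an empty consensus, flagged converged.
    """
    if rounds_max < 1:
        raise ValueError("rounds_max must be >= 1")
    current = query
    origin = 0  # coordinate of current query's first base in original-query space
    cons = ConsensusSequence("", 0, [], [])
    for rnd in range(1, rounds_max + 1):
        hits = recruit_reads(reads, current, min_identity, min_overlap)
        cons = call_consensus(hits, min_coverage, majority_fraction)
        nxt = cons.sequence.strip("N")
        cons.start += origin  # report in original-query coordinates
        if not nxt:
            return IterationResult(cons, rnd, True)
        if nxt == current:
            return IterationResult(cons, rnd, True)
        lead_n = len(cons.sequence) - len(cons.sequence.lstrip("N"))
        origin = cons.start + lead_n
        current = nxt
    return IterationResult(cons, rounds_max, False)


def delineate_boundary(
    candidate: str,
    reference: str,
    window: int = 20,
    identity_floor: float = 0.8,
) -> int:
    """Last 1-based position up to which all sliding windows stay similar.

    Both sequences are taken as aligned and anchored at their 5' ends; for
    every window of ``window`` columns ending at position p (1-based), the
    identity must be >= ``identity_floor``.  The boundary is the largest p
    such that every window ending at or before p passes; similarity to a
    reference gene "drops" just past the boundary.
    """
    n = min(len(candidate), len(reference))
    if n < window:
        raise ValueError("alignment shorter than window")
    match = [candidate[i] == reference[i] for i in range(n)]
    running = sum(match[:window])
    boundary = n
    for end in range(window, n + 1):  # window covers [end-window, end)
        if end > window:
            running += match[end - 1] - match[end - window - 1]
        if running / window < identity_floor:
            boundary = end - 1
            break
    return boundary


def find_pol3_terminator(
    sequence: str,
    gene_end: int,
    motif: str = "CTTTT",
    search_span: int = 100,
) -> int | None:
    """Offset of the first CTTTT motif downstream of a Pol III gene.

    ``gene_end`` is the 0-based half-open end of the gene (the index of the
    first downstream base).  The returned offset is the 1-based position of
    the motif's first base within the downstream sequence; a motif starting
    before the gene end is never reported.  None when absent within
    ``search_span`` bases.
    """
    if not 0 <= gene_end <= len(sequence):
        raise ValueError("gene_end outside sequence")
    stop = min(len(sequence), gene_end + search_span)
    idx = sequence.find(motif, gene_end, stop + len(motif) - 1)
    if idx < 0:
        return None
    return idx - gene_end + 1
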