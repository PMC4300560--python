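"""Concatenated-alignment statistics and Neighbor-Joining trees.

Per-gene alignments (partitions) are concatenated over a shared taxon set,
taxa missing from a partition being filled with '?'.  Site classification
follows the standard definitions: a column is constant when it shows one
nucleotide state, variable with two or more, and parsimony-informative
when at least two states are each present in at least two taxa; gaps, '?'
and other ambiguity symbols carry no state.  Trees come from the classic
Neighbor-Joining agglomeration on p-distances or Jukes-Cantor distances,
with a deterministic lowest-index tie-break so a given input always yields
the same newick string.
"""

from __future__ import annotations

import dataclasses

import numpy as np

BASES = set("ACGT")
MISSING = "?"


@dataclasses.dataclass
class Partition:
    name: str
    sequences: dict[str, str]  # taxon -> aligned row

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"partition {self.name!r}: rows differ in length")
        # duplicate taxa within a partition are caught upstream by read_fasta,
        # which rejects duplicate FASTA ids

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


@dataclasses.dataclass
class SiteClassCounts:
    columns: int
    constant: int
    variable: int
    parsimony_informative: int


@dataclasses.dataclass
class ConcatenatedAlignment:
    taxa: list[str]
    sequences: dict[str, str]
    boundaries: dict[str, tuple[int, int]]  # partition -> (start, end), 0-based half-open

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


def concatenate(partitions: list[Partition], taxon_order: list[str] | None = None) -> ConcatenatedAlignment:
    """Join partitions over the union of taxa; absent taxa are '?'-filled.

    Total length equals the sum of partition lengths and the partition map
    is preserved; permuting partition order permutes columns only, leaving
    all site-class counts unchanged.
    """
    if taxon_order is None:
        taxon_order = sorted({t for p in partitions for t in p.sequences})
    rows = {t: [] for t in taxon_order}
    boundaries = {}
    pos = 0
    for p in partitions:
        if p.name in boundaries:
            raise ValueError(f"duplicate partition name {p.name!r}")
        L = p.length
        for t in taxon_order:
            rows[t].append(p.sequences.get(t, MISSING * L).upper())
        boundaries[p.name] = (pos, pos + L)
        pos += L
    return ConcatenatedAlignment(
        taxa=list(taxon_order),
        sequences={t: "".join(chunks) for t, chunks in rows.items()},
        boundaries=boundaries,
    )


def classify_sites(
    aln: ConcatenatedAlignment | dict[str, str], taxa: list[str] | None = None
) -> SiteClassCounts:
    """Constant / variable / parsimony-informative counts over chosen taxa.

    Only A/C/G/T carry state; columns with no state count toward none of
    the classes.  PI requires >= 2 states each in >= 2 taxa, hence PI <=
    variable always.
    """
    seqs = aln.sequences if isinstance(aln, ConcatenatedAlignment) else aln
    if taxa is None:
        taxa = sorted(seqs)
    rows = [seqs[t].upper() for t in taxa]
    if len(rows) < 2:
        raise ValueError("need at least two taxa")
    ncol = len(rows[0])
    constant = variable = pi = 0
    for j in range(ncol):
        counts: dict[str, int] = {}
        for r in rows:
            b = r[j]
            if b in BASES:
                counts[b] = counts.get(b, 0) + 1
        if not counts:
            continue
        if len(counts) == 1:
            constant += 1
        else:
            variable += 1
            if sum(1 for n in counts.values() if n >= 2) >= 2:
                pi += 1
    return SiteClassCounts(ncol, constant, variable, pi)


# ------------------------------------------------------------- distances/NJ


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites over columns where both carry a base."""
    diff = shared = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in BASES and y in BASES:
            shared += 1
            if x != y:
                diff += 1
    return diff / shared if shared else 0.0


def jc69_distance(a: str, b: str, max_distance: float = 5.0) -> float:
    """Jukes-Cantor distance -3/4 ln(1 - 4p/3); saturated pairs are capped."""
    p = p_distance(a, b)
    if p >= 0.75:
        return max_distance
    d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    return float(min(d, max_distance))


def distance_matrix(
    seqs: dict[str, str], model: str = "p-distance", max_distance: float = 5.0
) -> tuple[list[str], np.ndarray]:
    taxa = list(seqs)
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if model == "p-distance":
                d = p_distance(seqs[taxa[i]], seqs[taxa[j]])
            elif model == "JC69":
                d = jc69_distance(seqs[taxa[i]], seqs[taxa[j]], max_distance)
            else:
                raise ValueError(f"unknown distance model {model!r}")
            D[i, j] = D[j, i] = d
    return taxa, D


def nj_tree(
    seqs: dict[str, str],
    model: str = "p-distance",
    clamp_negative: bool = True,
) -> str:
    """Neighbor-Joining newick tree from an alignment.

    Standard Saitou-Nei agglomeration on the chosen distance model.  Ties
    in the Q criterion break to the lexicographically lowest index pair, so
    the output is deterministic for a given taxon order.  Negative branch
    lengths are clamped to zero by default.  Identical sequences for all
    taxa yield a star tree with zero-length branches.
    """
    if len(seqs) < 3:
        raise ValueError("need at least three taxa")
    taxa, D = distance_matrix(seqs, model)
    if np.allclose(D, 0.0):
        return "(" + ",".join(f"{t}:0" for t in taxa) + ");"
    return nj_from_matrix(taxa, D, clamp_negative)


def nj_from_matrix(taxa: list[str], D: np.ndarray, clamp_negative: bool = True) -> str:
    """NJ agglomeration from an explicit distance matrix (see nj_tree)."""
    labels = list(taxa)
    D = D.astype(float).copy()

    def _fmt(x: float) -> str:
        if clamp_negative:
            x = max(x, 0.0)
        return f"{x:.6f}"

    while len(labels) > 3:
        n = len(labels)
        row_sums = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - row_sums[i] - row_sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        d_ij = D[i, j]
        li = 0.5 * d_ij + (row_sums[i] - row_sums[j]) / (2 * (n - 2))
        lj = d_ij - li
        merged = f"({labels[i]}:{_fmt(li)},{labels[j]}:{_fmt(lj)})"
        new_d = 0.5 * (D[i] + D[j] - d_ij)
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[: len(keep), : len(keep)] = D[np.ix_(keep, keep)]
        D2[-1, : len(keep)] = D2[: len(keep), -1] = new_d[keep]
        D = D2
        labels = [labels[k] for k in keep] + [merged]
    if len(labels) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        l0 = 0.5 * (d01 + d02 - d12)
        l1 = 0.5 * (d01 + d12 - d02)
        l2 = 0.5 * (d02 + d12 - d01)
        return (
            f"({labels[0]}:{_fmt(l0)},{labels[1]}:{_fmt(l1)},{labels[2]}:{_fmt(l2)});"
        )
    # two labels: a single edge split across the root
    d = D[0, 1]
    return f"({labels[0]}:{_fmt(d / 2)},{labels[1]}:{_fmt(d / 2)});"
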