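"""Five-evidence miRNA gene calling.

The caller integrates hit tables from five prediction lines (two ab initio
predictors, BLAST-style homology, zero-mismatch mature mapping and a
comparative structure screen): per-source confidence filtering, strand-aware
single-linkage clustering of hits that overlap or start within 40 bp of one
another, and acceptance of clusters supported by at least two distinct
sources with at least one member hit longer than 70 bp.  Opposite-strand
hits never merge, even at identical coordinates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from ._util import revcomp
from .io import Feature

#: window chopping used by the ab initio predictors: 521 bp windows
#: overlapping by 176 bp (i.e. stepping 345 bp)
CHOP_WINDOW = 521
CHOP_OVERLAP = 176

DEFAULT_THRESHOLDS = {
    "ab_initio_hmm": 0.80,
    "ab_initio_svm": 0.80,
    "blast_homology": 0.0,
    "mature_map": 0.0,
    "comparative_struct": 0.90,
}


@dataclasses.dataclass(frozen=True)
class EvidenceHit:
    source: str
    scaffold: str
    start: int  # 0-based half-open
    end: int
    strand: str
    confidence: float
    name: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("hit start must precede end")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence out of [0,1]")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class MiRNACandidate:
    scaffold: str
    strand: str
    start: int
    end: int
    hits: list[EvidenceHit]
    accepted: bool = False

    @property
    def n_sources(self) -> int:
        return len({h.source for h in self.hits})

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        for h in self.hits:
            if h.name:
                return h.name
        return "anonymous"

    def check(self, min_hit_length: int = 70, span_semantics: bool = False) -> None:
        assert all(h.scaffold == self.scaffold and h.strand == self.strand for h in self.hits)
        if self.accepted:
            assert self.n_sources >= 2
            length = self.span if span_semantics else max(h.length for h in self.hits)
            assert length > min_hit_length


def chop_scaffold(sequence: str, window: int = CHOP_WINDOW, overlap: int = CHOP_OVERLAP) -> list[tuple[int, int]]:
    """Tile a scaffold into predictor windows: 521 bp stepping 345 bp.

    Consecutive windows overlap exactly ``overlap`` bp; the last window may
    be shorter; together the windows cover every base.
    """
    if not sequence:
        raise ValueError("empty sequence")
    step = window - overlap
    out = []
    pos = 0
    L = len(sequence)
    while True:
        end = min(pos + window, L)
        out.append((pos, end))
        if end == L:
            break
        pos += step
    return out


def filter_confidence(hits: list[EvidenceHit], thresholds: dict[str, float]) -> list[EvidenceHit]:
    """Keep hits whose confidence reaches their source's threshold."""
    for h in hits:
        if h.source not in thresholds:
            raise ValueError(f"no confidence threshold for source {h.source!r}")
    return [h for h in hits if h.confidence >= thresholds[h.source]]


def cluster_hits(hits: list[EvidenceHit], start_window: int = 40) -> list[MiRNACandidate]:
    """Single-linkage clustering of same-scaffold, same-strand hits.

    Two hits join when they overlap or their starts lie within
    ``start_window`` bp (strict <), with transitive closure; opposite
    strands never join.  The cluster span is the union of member spans.
    Output ordering (scaffold, strand, start) is independent of input
    order.
    """
    groups: dict[tuple[str, str], list[EvidenceHit]] = {}
    for h in hits:
        groups.setdefault((h.scaffold, h.strand), []).append(h)
    clusters: list[MiRNACandidate] = []
    for (scaf, strand), members in sorted(groups.items()):
        members.sort(key=lambda h: (h.start, h.end, h.source))
        current: list[EvidenceHit] = []
        max_end = -1
        prev_start = None
        for h in members:
            linked = current and (
                h.start < max_end or (prev_start is not None and h.start - prev_start < start_window)
            )
            if not linked and current:
                clusters.append(_make_cluster(scaf, strand, current))
                current = []
                max_end = -1
            current.append(h)
            max_end = max(max_end, h.end)
            prev_start = h.start
        if current:
            clusters.append(_make_cluster(scaf, strand, current))
    return clusters


def _make_cluster(scaf: str, strand: str, members: list[EvidenceHit]) -> MiRNACandidate:
    return MiRNACandidate(
        scaffold=scaf,
        strand=strand,
        start=min(h.start for h in members),
        end=max(h.end for h in members),
        hits=list(members),
    )


def call_genes(
    clusters: list[MiRNACandidate],
    min_sources: int = 2,
    min_hit_length: int = 70,
    span_semantics: bool = False,
) -> list[MiRNACandidate]:
    """Accept clusters supported by >= min_sources distinct evidence lines
    with a member hit (or, with ``span_semantics``, a merged span) longer
    than ``min_hit_length`` bp.  Accepted candidates are flagged and
    returned; every candidate is invariant-checked."""
    accepted = []
    for c in clusters:
        length_ok = (
            c.span > min_hit_length
            if span_semantics
            else max(h.length for h in c.hits) > min_hit_length
        )
        c.accepted = c.n_sources >= min_sources and length_ok
        c.check(min_hit_length, span_semantics)
        if c.accepted:
            accepted.append(c)
    return accepted


def map_matures(
    scaffolds: dict[str, str], matures: dict[str, str], source: str = "mature_map"
) -> list[EvidenceHit]:
    """Exact (zero-mismatch) occurrences of mature miRNAs on either strand.

    Mature sequences must be 18-30 nt; reverse-strand hits are found via
    the reverse complement and reported in plus-strand coordinates with
    strand '-'; confidence is fixed at 1.0.
    """
    hits = []
    for name, mat in matures.items():
        mat = mat.upper().replace("U", "T")
        if not 18 <= len(mat) <= 30:
            raise ValueError(f"mature {name!r} length {len(mat)} outside 18-30 nt")
        rc = revcomp(mat)
        for scaf, seq in scaffolds.items():
            for query, strand in ((mat, "+"), (rc, "-")):
                idx = seq.find(query)
                while idx >= 0:
                    hits.append(
                        EvidenceHit(source, scaf, idx, idx + len(query), strand, 1.0, name)
                    )
                    idx = seq.find(query, idx + 1)
    hits.sort(key=lambda h: (h.scaffold, h.start, h.strand, h.name))
    return hits


@dataclasses.dataclass
class CatalogComparison:
    n_this: int
    n_other: int
    common: int
    pct_common: float  # 100 * common / n_this, one decimal


def compare_catalogs(
    set_this: list[MiRNACandidate], set_other: list[MiRNACandidate]
) -> CatalogComparison:
    """Count genes of `set_this` whose span overlaps a gene of `set_other`
    on the same scaffold and strand; percent common to one decimal."""
    from ._util import round_half_up

    def _overlaps(a: MiRNACandidate, b: MiRNACandidate) -> bool:
        return (
            a.scaffold == b.scaffold
            and a.strand == b.strand
            and a.start < b.end
            and b.start < a.end
        )

    common = sum(1 for a in set_this if any(_overlaps(a, b) for b in set_other))
    pct = round_half_up(100.0 * common / len(set_this), 1) if set_this else 0.0
    return CatalogComparison(len(set_this), len(set_other), common, pct)


# ---------------------------------------------------------------- IO helpers

BED_COLUMNS = ["scaffold", "start", "end", "source", "confidence", "strand", "name"]


def read_hits_tsv(path: str | Path) -> list[EvidenceHit]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        EvidenceHit(
            source=row["source"],
            scaffold=row["scaffold"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            confidence=float(row["confidence"]),
            name=str(row.get("name", "") or ""),
        )
        for _, row in df.iterrows()
    ]


def write_hits_tsv(hits: list[EvidenceHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "scaffold": h.scaffold,
                "start": h.start,
                "end": h.end,
                "source": h.source,
                "confidence": h.confidence,
                "strand": h.strand,
                "name": h.name,
            }
            for h in hits
        ],
        columns=BED_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def hits_from_frame(df: pd.DataFrame) -> list[EvidenceHit]:
    """EvidenceHit list from a simulator evidence table."""
    return [
        EvidenceHit(
            source=row.source,
            scaffold=row.scaffold,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            confidence=float(row.confidence),
            name=str(getattr(row, "name_", "") or getattr(row, "name", "") or ""),
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def candidates_to_features(cands: list[MiRNACandidate]) -> list[Feature]:
    return [
        Feature(
            seqid=c.scaffold,
            start=c.start,
            end=c.end,
            strand=c.strand,
            type="miRNA",
            attributes=(("Name", c.name), ("sources", str(c.n_sources))),
        )
        for c in cands
    ]
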