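"""Multi-species alignment statistics for ribosomal genes.

Operates on per-species aligned sequences over the alphabet {A,C,G,T,-,.}:
'-' is a true gap (introduced to improve the alignment, participating as a
mismatch), '.' marks sequence that was never identified for that species
and is excluded from consensus voting and polymorphism calls.  Positions
in all reports are 1-based on the consensus, and printed percentages round
half away from zero (so a 7/42 share prints as 17 and 13/42 as 31).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path

import pandas as pd

from ._util import round_half_up

ALPHABET = set("ACGT-.")
BASES = set("ACGT")

SpeciesAlignment = dict[str, str]


def _validate(aln: SpeciesAlignment) -> int:
    if not aln:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    bad = set("".join(aln.values())) - ALPHABET
    if bad:
        raise ValueError(f"unexpected symbols in alignment: {sorted(bad)}")
    return lengths.pop()


@dataclasses.dataclass
class ConsensusResult:
    sequence: str
    tie_positions: list[int]  # 1-based columns where the top count was tied


def overall_consensus(aln: SpeciesAlignment) -> ConsensusResult:
    """Column-wise most frequent non-'.' symbol across species.

    Rows with '.' at a column do not vote there; an all-dot column gives
    '.'.  Ties resolve to the alphabetically first symbol and the column is
    recorded as tied.
    """
    if len(aln) < 2:
        raise ValueError("need at least two species")
    ncol = _validate(aln)
    out = []
    ties = []
    rows = list(aln.values())
    for j in range(ncol):
        counts = Counter(r[j] for r in rows if r[j] != ".")
        if not counts:
            out.append(".")
            continue
        top = max(counts.values())
        winners = sorted(sym for sym, n in counts.items() if n == top)
        out.append(winners[0])
        if len(winners) > 1:
            ties.append(j + 1)
    return ConsensusResult("".join(out), ties)


@dataclasses.dataclass
class PolymorphismReport:
    total: int
    window: int
    window_counts: list[int]
    window_percentages: list[int]  # round-half-up integer share of total
    positions: list[int]  # 1-based polymorphic columns

    def __post_init__(self):
        assert sum(self.window_counts) == self.total


def polymorphic_sites(
    aln: SpeciesAlignment, consensus: str, window: int = 60
) -> PolymorphismReport:
    """Count columns where any species' base differs from the consensus.

    A column is polymorphic iff at least one species carries an A/C/G/T
    there (gaps and undetermined '.' do not trigger) that differs from the
    consensus symbol.  Columns partition into successive windows of
    ``window`` positions ([1..60], [61..120], remainder at the default).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    ncol = _validate(aln)
    if len(consensus) != ncol:
        raise ValueError("consensus length does not match alignment")
    positions = []
    for j in range(ncol):
        for row in aln.values():
            b = row[j]
            if b in BASES and b != consensus[j]:
                positions.append(j + 1)
                break
    nwin = (ncol + window - 1) // window
    counts = [0] * nwin
    for p in positions:
        counts[(p - 1) // window] += 1
    total = len(positions)
    percentages = [
        int(round_half_up(100.0 * c / total)) if total else 0 for c in counts
    ]
    return PolymorphismReport(total, window, counts, percentages, positions)


def pairwise_identity(seq_a: str, seq_b: str, first_n: int) -> int:
    """Percent identity over the first ``first_n`` alignment columns.

    Gaps count as mismatches; the result is 100*matches/first_n rounded to
    the nearest integer (half away from zero).  Symmetric in its arguments.
    """
    if first_n <= 0:
        raise ValueError("first_n must be positive")
    if len(seq_a) < first_n or len(seq_b) < first_n:
        raise ValueError("first_n exceeds a sequence length")
    matches = sum(
        1
        for a, b in zip(seq_a[:first_n], seq_b[:first_n])
        if a == b and a in BASES
    )
    return int(round_half_up(100.0 * matches / first_n))


def divergence_from_consensus(
    aln: SpeciesAlignment, consensus: str, first_n: int
) -> dict[str, tuple[int, list[int]]]:
    """Per-species count (and 1-based positions) of differences from the
    consensus within the first ``first_n`` columns; '.' columns are skipped.
    A column differing in several species contributes to each of them."""
    ncol = _validate(aln)
    if len(consensus) != ncol or first_n > ncol:
        raise ValueError("consensus/first_n inconsistent with alignment")
    out: dict[str, tuple[int, list[int]]] = {}
    for sp, row in aln.items():
        positions = [
            j + 1
            for j in range(first_n)
            if row[j] != "." and row[j] != consensus[j]
        ]
        out[sp] = (len(positions), positions)
    return out


SEGMENTS = ("ETS", "18S", "ITS1", "5.8S", "ITS2", "28S", "NTS", "5S")
COMPLETENESS = ("Full", "Part", "none")


@dataclasses.dataclass(frozen=True)
class SegmentRecord:
    species: str
    segment: str
    length: int
    source: str
    completeness: str

    def __post_init__(self):
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment {self.segment!r}")
        if self.completeness not in COMPLETENESS:
            raise ValueError(f"bad completeness {self.completeness!r}")
        if self.length < 0:
            raise ValueError("negative length")
        if (self.length == 0) != (self.completeness == "none"):
            raise ValueError("completeness 'none' iff length 0")


def completeness_table(records: list[SegmentRecord]) -> pd.DataFrame:
    """Per-species x per-segment report of assembled length, source and
    completeness (columns '<segment>_L/_S/_C'); missing cells are 0/none."""
    seen = set()
    for r in records:
        key = (r.species, r.segment)
        if key in seen:
            raise ValueError(f"duplicate record for {key}")
        seen.add(key)
    species = sorted({r.species for r in records})
    cols: dict[str, list] = {}
    by_key = {(r.species, r.segment): r for r in records}
    for seg in SEGMENTS:
        cols[f"{seg}_L"] = [
            by_key[(sp, seg)].length if (sp, seg) in by_key else 0 for sp in species
        ]
        cols[f"{seg}_S"] = [
            by_key[(sp, seg)].source if (sp, seg) in by_key else "" for sp in species
        ]
        cols[f"{seg}_C"] = [
            by_key[(sp, seg)].completeness if (sp, seg) in by_key else "none"
            for sp in species
        ]
    return pd.DataFrame(cols, index=pd.Index(species, name="species"))


def write_completeness_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_completeness_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="species", keep_default_na=False)
    for seg in SEGMENTS:
        df[f"{seg}_L"] = df[f"{seg}_L"].astype(int)
    return df
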