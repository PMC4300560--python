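"""tRNA isoacceptor censuses from tRNAscan-SE-style predictions.

Consumes the classic tabular output (sequence name, tRNA number, begin,
end, isotype, anticodon, intron bounds, score, optional note) and builds
per-species summaries: isoacceptor counts with percent-of-total,
pseudogene counts, totals, gene density per Mb of assembly, cross-species
averages and statistically outlying (species, isotype) cells.

Pseudogenes are excluded from isotype totals and reported separately (an
``include_pseudogenes`` flag folds them back in).  Outlier flagging uses a
two-sided exact binomial test of each species' isotype count against the
pooled proportion of the remaining species, Bonferroni-corrected over all
tested cells.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from ._util import revcomp, round_half_up

_AA3: dict[str, str] | None = None


def _codon_to_aa3() -> dict[str, str]:
    global _AA3
    if _AA3 is None:
        from Bio.Data import CodonTable, IUPACData

        table = CodonTable.unambiguous_dna_by_id[1]
        _AA3 = {c: IUPACData.protein_letters_1to3[aa] for c, aa in table.forward_table.items()}
        _AA3["TGA"] = "Sec"  # selenocysteine: anticodon TCA
    return _AA3


ISOTYPES = tuple(sorted(set(_codon_to_aa3().values())))


@dataclasses.dataclass(frozen=True)
class TRNAGeneRecord:
    species: str
    scaffold: str
    start: int  # 0-based half-open
    end: int
    strand: str
    isotype: str
    anticodon: str
    pseudogene: bool
    score: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("invalid coordinates")
        codon = revcomp(self.anticodon)
        expected = _codon_to_aa3().get(codon)
        if expected is None:
            raise ValueError(f"anticodon {self.anticodon!r} decodes to a stop codon")
        iso = "Sec" if self.isotype.lower() == "sec" else self.isotype
        if iso != expected:
            raise ValueError(
                f"isotype {self.isotype!r} inconsistent with anticodon {self.anticodon!r}"
                f" (expected {expected})"
            )


def read_trnascan(path: str | Path, species: str) -> list[TRNAGeneRecord]:
    """Parse a tRNAscan-SE tabular file into validated gene records.

    Header lines (column titles and the dashed rule) are skipped; a 'pseudo'
    annotation in the note column sets the pseudogene flag; malformed rows
    raise with their line number.
    """
    records: list[TRNAGeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            low = line.lower()
            if low.startswith(("sequence", "name", "--")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: expected >=9 columns, got {len(cols)}")
            try:
                scaffold = cols[0].strip()
                begin, end = int(cols[2]), int(cols[3])
                isotype = cols[4].strip()
                anticodon = cols[5].strip().upper().replace("U", "T")
                score = float(cols[8])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            note = " ".join(cols[9:]).lower()
            strand = "+" if begin <= end else "-"
            lo, hi = (begin, end) if begin <= end else (end, begin)
            try:
                rec = TRNAGeneRecord(
                    species=species,
                    scaffold=scaffold,
                    start=lo - 1,  # tRNAscan-SE coordinates are 1-based inclusive
                    end=hi,
                    strand=strand,
                    isotype=isotype,
                    anticodon=anticodon,
                    pseudogene="pseudo" in note,
                    score=score,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    return records


@dataclasses.dataclass
class TRNACensus:
    species: str
    isotype_counts: dict[str, int]  # functional genes only (pseudogenes separate)
    isotype_percent: dict[str, float]  # 100*count/total, one decimal
    pseudogenes: int
    total: int
    genome_size_mb: float
    genes_per_mb: float  # one decimal


def build_census(
    records: list[TRNAGeneRecord],
    genome_size_mb: float,
    species: str | None = None,
    include_pseudogenes: bool = False,
) -> TRNACensus:
    """Isoacceptor census of one species with densities.

    Percentages are 100*count/total rounded half-up to one decimal;
    genes/Mb likewise.  Zero records give a census of total 0.
    """
    if genome_size_mb <= 0:
        raise ValueError("genome_size_mb must be positive")
    if species is None:
        species = records[0].species if records else "unknown"
    counts = {iso: 0 for iso in ISOTYPES}
    pseudo = 0
    for r in records:
        if r.pseudogene:
            pseudo += 1
            if not include_pseudogenes:
                continue
        counts[r.isotype] += 1
    total = sum(counts.values())
    percent = {
        iso: (round_half_up(100.0 * n / total, 1) if total else 0.0)
        for iso, n in counts.items()
    }
    return TRNACensus(
        species=species,
        isotype_counts=counts,
        isotype_percent=percent,
        pseudogenes=pseudo,
        total=total,
        genome_size_mb=genome_size_mb,
        genes_per_mb=round_half_up(total / genome_size_mb, 1) if total else 0.0,
    )


def census_from_frame(df: pd.DataFrame, genome_size_mb: float, species: str) -> TRNACensus:
    """Census from a simulator tRNA truth table (one species' rows)."""
    recs = [
        TRNAGeneRecord(
            species=species,
            scaffold=row.scaffold,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            isotype=row.isotype,
            anticodon=row.anticodon,
            pseudogene=bool(row.pseudo),
            score=float(row.score),
        )
        for row in df.itertuples(index=False)
    ]
    return build_census(recs, genome_size_mb, species=species)


@dataclasses.dataclass
class CrossSpeciesSummary:
    mean_total: float
    mean_density: float
    percent_of_average: dict[str, float]  # 100*total/mean_total, one decimal
    pairwise_percent_difference: dict[tuple[str, str], float]  # (a-b)/b*100


def cross_species_summary(censuses: list[TRNACensus]) -> CrossSpeciesSummary:
    """Arithmetic means of totals and densities plus the derived shares:
    percent-of-average per species and pairwise percent differences
    ((a-b)/b*100, one decimal)."""
    if len(censuses) < 2:
        raise ValueError("need at least two censuses")
    totals = {c.species: c.total for c in censuses}
    mean_total = sum(totals.values()) / len(totals)
    mean_density = sum(c.genes_per_mb for c in censuses) / len(censuses)
    pct_avg = {
        sp: round_half_up(100.0 * t / mean_total, 1) if mean_total else 0.0
        for sp, t in totals.items()
    }
    pairwise = {}
    names = list(totals)
    for a in names:
        for b in names:
            if a != b and totals[b]:
                pairwise[(a, b)] = round_half_up(
                    100.0 * (totals[a] - totals[b]) / totals[b], 1
                )
    return CrossSpeciesSummary(mean_total, mean_density, pct_avg, pairwise)


def percent_difference(a: int | float, b: int | float) -> float:
    """(a-b)/b*100, one decimal, half-up — the 'a is x% higher than b' figure."""
    return round_half_up(100.0 * (a - b) / b, 1)


def percent_of_average(value: float, totals: list[float]) -> float:
    """100*value/mean(totals), one decimal."""
    mean = sum(totals) / len(totals)
    return round_half_up(100.0 * value / mean, 1)


def flag_outliers(
    censuses: list[TRNACensus], alpha: float = 0.05
) -> list[tuple[str, str, float]]:
    """(species, isotype, corrected p) cells whose isotype count deviates
    significantly from the remaining species pooled together.

    Each cell is tested with a two-sided Fisher exact test on the 2x2
    table (k, n-k) vs (k_other, n_other-k_other); a plain binomial test of
    k against the pooled proportion would ignore that the proportion is
    itself estimated and inflates the false-flag rate.  Cells are flagged
    when p < alpha after Bonferroni correction over every tested cell, so
    the familywise error under the null stays below alpha.
    """
    from scipy.stats import fisher_exact

    if len(censuses) < 3:
        raise ValueError("need at least three censuses")
    cells = []
    for c in censuses:
        others = [o for o in censuses if o is not c]
        n_other = sum(o.total for o in others)
        if c.total == 0 or n_other == 0:
            continue
        for iso in ISOTYPES:
            k_other = sum(o.isotype_counts.get(iso, 0) for o in others)
            cells.append(
                (c.species, iso, c.isotype_counts.get(iso, 0), c.total, k_other, n_other)
            )
    tested = len(cells)
    flagged = []
    for sp, iso, k, n, k_other, n_other in cells:
        table = [[k, n - k], [k_other, n_other - k_other]]
        pval = fisher_exact(table, alternative="two-sided")[1]
        if pval * tested < alpha:
            flagged.append((sp, iso, min(1.0, pval * tested)))
    return flagged


def census_to_frame(censuses: list[TRNACensus]) -> pd.DataFrame:
    """Table-style layout: one row per species, isotype count/percent column
    pairs, then pseudogenes, total, genome Mb and genes/Mb."""
    rows = []
    for c in censuses:
        row: dict = {"species": c.species}
        for iso in ISOTYPES:
            row[iso] = c.isotype_counts.get(iso, 0)
            row[f"{iso}_pct"] = c.isotype_percent.get(iso, 0.0)
        row.update(
            PG=c.pseudogenes,
            total=c.total,
            genome_mb=c.genome_size_mb,
            genes_per_mb=c.genes_per_mb,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_census_tsv(censuses: list[TRNACensus], path: str | Path) -> None:
    census_to_frame(censuses).to_csv(path, sep="\t", index=False)
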