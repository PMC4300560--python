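"""tRNAscan-SE parsing, censuses, cross-species summaries, outlier flags."""

import numpy as np
import pytest

from ncrnakit import trna
from ncrnakit.trna import (
    ISOTYPES,
    TRNACensus,
    TRNAGeneRecord,
    build_census,
    cross_species_summary,
    flag_outliers,
    percent_difference,
    percent_of_average,
    read_trnascan,
)

HEADER = (
    "Sequence\t\ttRNA\tBounds\t\ttRNA\tAnti\tIntron Bounds\tCove\n"
    "Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\n"
    "--------\t------\t-----\t---\t----\t-----\t-----\t---\t-----\n"
)


def write_scan(tmp_path, rows):
    path = tmp_path / "scan.txt"
    path.write_text(HEADER + "".join(rows))
    return path


class TestReadTrnascan:
    def test_empty_file(self, tmp_path):
        assert read_trnascan(write_scan(tmp_path, []), "sp") == []

    def test_valid_row_parsed(self, tmp_path):
        path = write_scan(tmp_path, ["scaf1\t1\t1001\t1072\tVal\tTAC\t0\t0\t55.2\n"])
        (rec,) = read_trnascan(path, "sp")
        assert rec.isotype == "Val"
        assert rec.anticodon == "TAC"
        assert (rec.start, rec.end, rec.strand) == (1000, 1072, "+")
        assert not rec.pseudogene

    def test_minus_strand_coordinates(self, tmp_path):
        path = write_scan(tmp_path, ["scaf1\t1\t1072\t1001\tVal\tTAC\t0\t0\t55.2\n"])
        (rec,) = read_trnascan(path, "sp")
        assert (rec.start, rec.end, rec.strand) == (1000, 1072, "-")

    def test_pseudo_note_sets_flag(self, tmp_path):
        path = write_scan(
            tmp_path, ["scaf1\t1\t10\t82\tGly\tGCC\t0\t0\t21.0\tpseudo\n"]
        )
        assert read_trnascan(path, "sp")[0].pseudogene

    def test_inconsistent_isotype_anticodon_errors_with_line(self, tmp_path):
        path = write_scan(tmp_path, ["scaf1\t1\t10\t82\tGly\tTAC\t0\t0\t21.0\n"])
        with pytest.raises(ValueError, match=":4.*inconsistent"):
            read_trnascan(path, "sp")

    def test_selenocysteine_anticodon(self, tmp_path):
        path = write_scan(tmp_path, ["scaf1\t1\t10\t96\tSec\tTCA\t0\t0\t80.0\n"])
        assert read_trnascan(path, "sp")[0].isotype == "Sec"

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = write_scan(tmp_path, ["scaf1\tonly-three\tcols\n"])
        with pytest.raises(ValueError, match=":4"):
            read_trnascan(path, "sp")


def make_census(species, counts, genome_mb=100.0, pseudo=0):
    full = {iso: 0 for iso in ISOTYPES}
    full.update(counts)
    total = sum(full.values())
    from ncrnakit._util import round_half_up

    pct = {
        iso: round_half_up(100.0 * n / total, 1) if total else 0.0
        for iso, n in full.items()
    }
    return TRNACensus(
        species, full, pct, pseudo, total, genome_mb,
        round_half_up(total / genome_mb, 1) if total else 0.0,
    )


class TestBuildCensus:
    def _records(self, layout):
        recs = []
        anticodons = {"Gly": "GCC", "Val": "TAC", "Ala": "AGC", "Leu": "AAG"}
        i = 0
        for iso, n, pseudo in layout:
            for _ in range(n):
                recs.append(
                    TRNAGeneRecord(
                        "sp", "sc", i * 100, i * 100 + 72, "+",
                        iso, anticodons[iso], pseudo, 50.0,
                    )
                )
                i += 1
        return recs

    def test_printed_percent_and_density(self):
        # 17 Gly of 306 genes -> 5.6%; 306 genes over 170.5 Mb -> 1.8 per Mb
        recs = self._records([("Gly", 17, False), ("Val", 150, False), ("Ala", 139, False)])
        census = build_census(recs, genome_size_mb=170.5)
        assert census.total == 306
        assert census.isotype_percent["Gly"] == 5.6
        assert census.genes_per_mb == 1.8

    def test_pseudogenes_counted_separately(self):
        recs = self._records([("Gly", 5, False), ("Val", 3, True)])
        census = build_census(recs, 10.0)
        assert census.total == 5
        assert census.pseudogenes == 3
        census_incl = build_census(recs, 10.0, include_pseudogenes=True)
        assert census_incl.total == 8

    def test_single_record_hundred_percent(self):
        census = build_census(self._records([("Leu", 1, False)]), 1.0)
        assert census.isotype_percent["Leu"] == 100.0

    def test_zero_records(self):
        census = build_census([], 5.0, species="empty")
        assert census.total == 0 and census.genes_per_mb == 0.0

    def test_percent_columns_sum_to_100(self):
        rng = np.random.default_rng(8)
        iso = list(ISOTYPES)
        for _ in range(20):
            # a prime total avoids exact .x5 rounding ties, which would
            # otherwise bias every odd count upward by 0.05
            counts = dict(zip(iso, rng.multinomial(397, [1 / len(iso)] * len(iso))))
            census = make_census("x", {k: int(v) for k, v in counts.items()})
            assert abs(sum(census.isotype_percent.values()) - 100.0) <= 0.5


class TestCrossSpeciesSummary:
    def test_printed_pairwise_increase(self):
        # 464 vs 389 genes -> 19.3% higher
        a = make_census("pest", {"Gly": 464})
        b = make_census("sform", {"Gly": 389})
        c = make_census("other", {"Gly": 300})
        summary = cross_species_summary([a, b, c])
        assert summary.pairwise_percent_difference[("pest", "sform")] == 19.3
        assert percent_difference(464, 389) == 19.3

    def test_printed_percent_of_average(self):
        # 125 genes against an average of 331.4 -> 37.7%
        assert percent_of_average(125, [331.4]) == 37.7

    def test_all_equal_totals_are_100_percent(self):
        cs = [make_census(f"s{i}", {"Gly": 250}) for i in range(4)]
        summary = cross_species_summary(cs)
        assert all(v == 100.0 for v in summary.percent_of_average.values())

    def test_mean_matches_bruteforce(self):
        totals = [306, 359, 337]
        cs = [make_census(f"s{i}", {"Gly": t}) for i, t in enumerate(totals)]
        summary = cross_species_summary(cs)
        assert summary.mean_total == pytest.approx(sum(totals) / 3)


class TestFlagOutliers:
    def _null_censuses(self, rng, n_species=5, total=300):
        iso = list(ISOTYPES)
        return [
            make_census(
                f"s{i}",
                dict(zip(iso, map(int, rng.multinomial(total, [1 / len(iso)] * len(iso))))),
            )
            for i in range(n_species)
        ]

    def test_identical_compositions_no_flags(self):
        cs = [make_census(f"s{i}", {iso: 20 for iso in ISOTYPES}) for i in range(4)]
        assert flag_outliers(cs, alpha=0.05) == []

    def test_alpha_to_zero_no_flags(self, rng):
        cs = self._null_censuses(rng)
        assert flag_outliers(cs, alpha=1e-12) == []

    def test_doubled_val_cell_flagged(self):
        # background species at a realistic ~7.4% Val share; the outlier
        # species carries double that count
        base = {iso: 28 for iso in ISOTYPES if iso != "Val"} | {"Val": 31}
        outlier = dict(base) | {"Val": 62}
        cs = [make_census("outlier", outlier)] + [
            make_census(f"s{i}", base) for i in range(10)
        ]
        flagged = {(sp, iso) for sp, iso, _ in flag_outliers(cs, alpha=0.05)}
        assert ("outlier", "Val") in flagged

    def test_needs_three_censuses(self):
        cs = [make_census("a", {"Gly": 10}), make_census("b", {"Gly": 10})]
        with pytest.raises(ValueError):
            flag_outliers(cs)


def test_census_tsv_layout(tmp_path):
    cs = [make_census("a", {"Gly": 10, "Val": 5}, genome_mb=2.0)]
    path = tmp_path / "census.tsv"
    trna.write_census_tsv(cs, path)
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    assert df.loc[0, "Gly"] == 10
    assert df.loc[0, "total"] == 15
    assert df.loc[0, "genes_per_mb"] == 7.5
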