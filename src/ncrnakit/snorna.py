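"""C/D-box snoRNA screening against a target rRNA.

C/D-box snoRNAs carry a box C (RUGAUGA) near their 5' end and a box D
(CUGA) near their 3' end, with a 10-21 nt guide immediately 5' of box D
that is antisense to the 2'-O-methylation site on the target rRNA.  The
screen detects box motifs in genomic sequence (DNA alphabet; U is written
T), requires a guide whose reverse complement matches the target allowing
a limited number of G:U wobbles, and scores candidates additively:

    score = 2 x (Watson-Crick guide pairs) + 1 x (G:U pairs)
            + 5 x (exact box C) + 5 x (exact box D)

Candidates are retained when score > 20.  This additive score is a
transparent surrogate for probabilistic log-odds snoRNA models: it is
calibrated so that a canonical gene (exact boxes, >= 10 nt perfect guide)
always clears the retention threshold, and its components are reported so
every retained candidate can be audited.  Terminal stems are classified
from the complementarity of the 6-base candidate termini into the four
classes no stem / possible stem / terminal stem / strong stem.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import pandas as pd

from ._util import revcomp, round_half_up
from .io import Feature

BOX_C_CORE = (2, 3, 4)  # positions 3-5 (1-based) of RUGAUGA must match exactly
BOX_D = "CTGA"
STEM_CLASSES = ("no stem", "possible stem", "terminal stem", "strong stem")


@dataclasses.dataclass
class SnoRNACandidate:
    scaffold: str
    strand: str
    start: int  # 0-based half-open span including 6 bp terminal flanks
    end: int
    box_c_pos: int  # plus-strand scaffold coordinate of the matched box C
    box_c_motif: str
    box_d_pos: int
    box_d_motif: str
    guide: str
    guide_target_pos: int  # 0-based position on the target rRNA
    score: float
    stem_class: str = "no stem"
    sequence: str = ""

    @property
    def guide_length(self) -> int:
        return len(self.guide)

    def check(self, retention_threshold: float = 20.0) -> None:
        assert 10 <= self.guide_length <= 21
        assert self.score > retention_threshold
        assert self.stem_class in STEM_CLASSES


@dataclasses.dataclass
class ScanParams:
    min_guide: int = 10
    max_guide: int = 21
    max_wobble: int = 2
    min_box_spacing: int = 40  # box C start to box D end, bp
    max_box_spacing: int = 200
    retention_threshold: float = 20.0
    flank: int = 6


def _box_c_matches(seq: str, i: int) -> tuple[bool, bool]:
    """(matches with <=1 peripheral mismatch, exact) for RUGAUGA at i."""
    if i + 7 > len(seq):
        return False, False
    window = seq[i : i + 7]
    # pattern R T G A T G A  (RNA RUGAUGA written in DNA)
    core_ok = window[2] == "G" and window[3] == "A" and window[4] == "T"
    if not core_ok:
        return False, False
    mismatches = 0
    if window[0] not in "AG":
        mismatches += 1
    if window[1] != "T":
        mismatches += 1
    if window[5] != "G":
        mismatches += 1
    if window[6] != "A":
        mismatches += 1
    return mismatches <= 1, mismatches == 0


def _guide_match(guide: str, target_arr, max_wobble: int) -> tuple[int, int, int] | None:
    """Best antisense placement of guide on target: (wc, gu, target_pos).

    Every guide base must pair (Watson-Crick or G:U wobble) with the
    antiparallel target base; at most ``max_wobble`` wobbles.  Returns the
    placement maximising 2*wc + gu, leftmost on ties; None when no valid
    placement exists.  ``target_arr`` is the target as a byte array
    (np.frombuffer of the uppercase sequence).
    """
    import numpy as np

    L = len(guide)
    N = len(target_arr)
    if L > N:
        return None
    grc = revcomp(guide).encode()
    npos = N - L + 1
    wc = np.zeros(npos, dtype=np.int16)
    gu = np.zeros(npos, dtype=np.int16)
    for x in range(L):
        t = target_arr[x : x + npos]
        b = grc[x]
        wc += t == b
        if b == ord("C"):  # guide G pairs target T
            gu += t == ord("T")
        elif b == ord("A"):  # guide T pairs target G
            gu += t == ord("G")
    valid = (wc + gu == L) & (gu <= max_wobble)
    if not valid.any():
        return None
    score = np.where(valid, 2 * wc + gu, -1)
    p = int(np.argmax(score))
    return int(wc[p]), int(gu[p]), p


def scan_cd_box(
    scaffolds: dict[str, str],
    target: str,
    params: ScanParams | None = None,
) -> list[SnoRNACandidate]:
    """Screen scaffolds (both strands) for C/D-box snoRNAs guided against
    ``target``; retained candidates have score > the retention threshold.

    Box C may carry one mismatch outside its GAU core; box D is exact.
    Box C start to box D end must span 40-200 bp.  For each box pair the
    best-scoring guide length/placement is kept; overlapping same-strand
    candidates are collapsed to the highest-scoring one.
    """
    params = params or ScanParams()
    target = target.upper()
    if len(target) <= 21:
        raise ValueError("target rRNA too short")
    if len(set(target)) == 1:
        warnings.warn("degenerate target (single base); scan proceeds")
    import numpy as np

    target_arr = np.frombuffer(target.encode(), dtype=np.uint8)
    out: list[SnoRNACandidate] = []
    for scaf, seq in scaffolds.items():
        seq = seq.upper()
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            out.extend(
                _scan_strand(scaf, strand, s, len(seq), target_arr, params)
            )
    out.sort(key=lambda c: (c.scaffold, c.start, c.strand))
    return out


def _scan_strand(scaf, strand, s, scaf_len, target_arr, params):
    c_hits = []
    for i in range(len(s) - 6):
        ok, exact = _box_c_matches(s, i)
        if ok:
            c_hits.append((i, exact))
    d_hits = []
    j = s.find(BOX_D)
    while j >= 0:
        d_hits.append(j)
        j = s.find(BOX_D, j + 1)

    raw: list[SnoRNACandidate] = []
    memo: dict[tuple[int, int], tuple[int, int, int] | None] = {}
    for i, exact_c in c_hits:
        for j in d_hits:
            span = j + 4 - i
            if span < params.min_box_spacing:
                continue
            if span > params.max_box_spacing:
                break  # d_hits sorted; all later ones are farther
            best = None
            for L in range(params.max_guide, params.min_guide - 1, -1):
                if j - L < i + 7:
                    continue
                guide = s[j - L : j]
                if (j, L) not in memo:
                    memo[(j, L)] = _guide_match(guide, target_arr, params.max_wobble)
                m = memo[(j, L)]
                if m is None:
                    continue
                wc, gu, tpos = m
                gscore = 2 * wc + gu
                if best is None or gscore > best[0]:
                    best = (gscore, guide, tpos)
            if best is None:
                continue
            gscore, guide, tpos = best
            score = gscore + (5 if exact_c else 0) + 5  # box D is always exact
            if score <= params.retention_threshold:
                continue
            start = max(0, i - params.flank)
            end = min(len(s), j + 4 + params.flank)
            cand_seq = s[start:end]
            if strand == "+":
                g_start, g_end = start, end
                c_pos, d_pos = i, j
            else:  # map back to plus-strand coordinates
                g_start, g_end = scaf_len - end, scaf_len - start
                c_pos, d_pos = scaf_len - (i + 7), scaf_len - (j + 4)
            raw.append(
                SnoRNACandidate(
                    scaffold=scaf,
                    strand=strand,
                    start=g_start,
                    end=g_end,
                    box_c_pos=c_pos,
                    box_c_motif=s[i : i + 7],
                    box_d_pos=d_pos,
                    box_d_motif=BOX_D,
                    guide=guide,
                    guide_target_pos=tpos,
                    score=float(score),
                    sequence=cand_seq,
                )
            )
    # collapse overlapping candidates on this strand, best score wins
    raw.sort(key=lambda c: (-c.score, c.start))
    kept: list[SnoRNACandidate] = []
    for c in raw:
        if any(k.start < c.end and c.start < k.end for k in kept):
            continue
        c.stem_class = classify_stem(c.sequence)
        kept.append(c)
    return kept


def classify_stem(candidate_seq: str, stem_len: int = 6) -> str:
    """Four-way terminal-stem class from the candidate's 6-base termini.

    The 5' terminal bases are compared with the reverse complement of the
    3' terminal bases; the longest run of contiguous Watson-Crick pairs
    maps to: >=5 strong stem, 4 terminal stem, 3 possible stem, else no
    stem.  Sequences too short for both termini are 'no stem'.
    """
    if len(candidate_seq) < 2 * stem_len:
        return "no stem"
    five = candidate_seq[:stem_len]
    three = revcomp(candidate_seq[-stem_len:])
    run = best = 0
    for a, b in zip(five, three):
        run = run + 1 if a == b else 0
        best = max(best, run)
    if best >= 5:
        return "strong stem"
    if best == 4:
        return "terminal stem"
    if best == 3:
        return "possible stem"
    return "no stem"


@dataclasses.dataclass
class DensityRow:
    species: str
    target_name: str
    target_length: int
    counts: dict[str, int]  # per stem class
    total: int
    density_per_100bp: float  # one decimal

    def __post_init__(self):
        assert sum(self.counts.values()) == self.total


def density_table(
    candidates_per_species: dict[str, list[SnoRNACandidate]],
    target_lengths: dict[str, int],
    target_name: str = "18S",
) -> list[DensityRow]:
    """Per-species candidate counts by stem class plus genes per 100 bp of
    target sequence (one decimal)."""
    rows = []
    for sp, cands in sorted(candidates_per_species.items()):
        tl = target_lengths[sp]
        if tl <= 0:
            raise ValueError(f"non-positive target length for {sp}")
        counts = {cls: 0 for cls in STEM_CLASSES}
        for c in cands:
            counts[c.stem_class] += 1
        total = len(cands)
        rows.append(
            DensityRow(
                species=sp,
                target_name=target_name,
                target_length=tl,
                counts=counts,
                total=total,
                density_per_100bp=round_half_up(100.0 * total / tl, 1),
            )
        )
    return rows


def density_to_frame(rows: list[DensityRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "target": r.target_name,
                "target_length": r.target_length,
                **{cls.replace(" ", "_"): r.counts[cls] for cls in STEM_CLASSES},
                "total": r.total,
                "genes_per_100bp": r.density_per_100bp,
            }
            for r in rows
        ]
    )


def write_density_tsv(rows: list[DensityRow], path: str | Path) -> None:
    density_to_frame(rows).to_csv(path, sep="\t", index=False)


def candidates_to_features(cands: list[SnoRNACandidate]) -> list[Feature]:
    return [
        Feature(
            seqid=c.scaffold,
            start=c.start,
            end=c.end,
            strand=c.strand,
            type="snoRNA",
            score=c.score,
            attributes=(
                ("guide", c.guide),
                ("stem_class", c.stem_class.replace(" ", "_")),
            ),
        )
        for c in cands
    ]
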