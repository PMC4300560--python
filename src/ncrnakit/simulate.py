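"""Seeded simulator of mosquito-like genomic material for the ncRNA survey.

The generator plants, per species, the three genomic contexts every
downstream stage of the survey assumes:

* a ribosomal DNA locus made of tandem repeat units laid out as
  ETS-18S-ITS1-5.8S-ITS2-28S-NTS, with species-level substitution
  polymorphism and an optional non-ribosomal insertion interrupting a
  configurable fraction of the 28S copies (the classical cause of rDNA
  assembly failure);
* a 5S locus of ~500 bp tandem repeats, each carrying the mature 5S gene
  followed closely by a CTTTT Pol III terminator motif;
* a "gene playground" scaffold with planted miRNA precursors, C/D-box
  snoRNAs whose guides are antisense to that species' 18S, and tRNA genes.

Species sequences diverge star-wise: each species' copy of a segment is
drawn independently from a common ancestral sequence with substitutions at
``per_site_polymorphism_rate`` per site.  This makes the expected number of
polymorphic alignment columns exactly binomial, which the test-suite
exploits.  Tree-correlated sequences (for phylogenetic recovery tests) are
produced separately by :func:`evolve_alignment` along the true tree that
the generator also emits.

All randomness flows from a single integer seed; identical configs give
byte-identical output.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from ._util import DNA, revcomp
from .io import Feature

RDNA_SEGMENT_ORDER = ("ETS", "18S", "ITS1", "5.8S", "ITS2", "28S", "NTS")

DEFAULT_RDNA_UNIT_LENGTHS = {
    "ETS": 860,
    "18S": 2000,
    "ITS1": 340,
    "5.8S": 160,
    "ITS2": 430,
    "28S": 4000,
    "NTS": 1500,
}

#: the five evidence lines of the miRNA survey: two ab initio predictors,
#: BLAST-style homology, zero-mismatch mature mapping and a comparative
#: structure screen. (name, sensitivity, false positives per kb, confidence range)
DEFAULT_EVIDENCE_SOURCES = (
    ("ab_initio_hmm", 0.90, 0.02, (0.80, 1.0)),
    ("ab_initio_svm", 0.90, 0.02, (0.80, 1.0)),
    ("blast_homology", 0.85, 0.01, (0.80, 1.0)),
    ("mature_map", 0.80, 0.0, (1.0, 1.0)),
    ("comparative_struct", 0.75, 0.02, (0.90, 1.0)),
)


@dataclasses.dataclass(frozen=True)
class EvidenceSource:
    name: str
    sensitivity: float
    fp_per_kb: float
    confidence_range: tuple[float, float] = (0.8, 1.0)

    def __post_init__(self):
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError(f"sensitivity out of [0,1] for {self.name}")
        if self.fp_per_kb < 0:
            raise ValueError(f"negative fp_per_kb for {self.name}")


@dataclasses.dataclass
class SimConfig:
    """Parameters of one simulated study; see module docstring for semantics."""

    seed: int = 0
    n_species: int = 3
    rdna_unit_lengths: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_RDNA_UNIT_LENGTHS)
    )
    n_rdna_units: int = 4
    n_5s_units: int = 6
    five_s_unit_length: int = 500
    five_s_gene_length: int = 120
    per_site_polymorphism_rate: float = 0.01
    indel_rate: float = 0.0
    insertion_rate_28S: float = 0.25
    insertion_element_length: int = 600
    read_length: int = 100
    read_error_rate: float = 0.005
    coverage: float = 20.0
    evidence_sources: tuple = DEFAULT_EVIDENCE_SOURCES
    n_mirnas: int = 8
    mirna_length: int = 90
    n_snornas: int = 5
    n_trnas_per_species: int = 40
    trna_pseudogene_rate: float = 0.03
    long_58S_read_fraction: float = 0.1
    gene_spacing: int = 250

    def __post_init__(self):
        for name in (
            "per_site_polymorphism_rate",
            "indel_rate",
            "insertion_rate_28S",
            "read_error_rate",
            "long_58S_read_fraction",
            "trna_pseudogene_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not a probability")
        for name in (
            "n_species",
            "n_rdna_units",
            "n_5s_units",
            "five_s_unit_length",
            "five_s_gene_length",
            "read_length",
            "n_mirnas",
            "mirna_length",
            "n_snornas",
            "n_trnas_per_species",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for seg, length in self.rdna_unit_lengths.items():
            if length <= 0:
                raise ValueError(f"rDNA segment {seg} has non-positive length")
        # the 5S repeat must hold the gene plus terminator with room to spare
        if self.five_s_unit_length < self.five_s_gene_length + 10:
            raise ValueError(
                "five_s_unit_length shorter than its planted gene plus terminator"
            )
        if self.mirna_length <= 70:
            raise ValueError("mirna_length must exceed 70 bp to be callable")

    @property
    def sources(self) -> list[EvidenceSource]:
        return [EvidenceSource(n, s, f, tuple(r)) for n, s, f, r in self.evidence_sources]


@dataclasses.dataclass(frozen=True)
class GeneInterval:
    scaffold: str
    start: int
    end: int
    strand: str
    gene_class: str  # rDNA / 5S / tRNA / miRNA / snoRNA
    name: str


@dataclasses.dataclass
class TruthSet:
    """Ground truth emitted beside the simulated scaffolds."""

    intervals: list[GeneInterval]
    segments: dict[str, dict[str, str]]  # species -> segment name -> sequence
    tree: str | None  # newick, when n_species > 2
    mature_mirnas: dict[str, str]  # name -> 22 nt mature sequence
    trna_records: pd.DataFrame  # species/scaffold/start/end/strand/isotype/anticodon/pseudo

    def intervals_for(self, gene_class: str, species: str | None = None) -> list[GeneInterval]:
        out = [iv for iv in self.intervals if iv.gene_class == gene_class]
        if species is not None:
            out = [iv for iv in out if iv.scaffold.startswith(species + "_")]
        return out

    def to_features(self) -> list[Feature]:
        return [
            Feature(
                seqid=iv.scaffold,
                start=iv.start,
                end=iv.end,
                strand=iv.strand,
                type=iv.gene_class,
                attributes=(("Name", iv.name),),
            )
            for iv in self.intervals
        ]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(DNA))[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Independent substitutions at `rate` per site (never to the same base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = [o for o in (65, 67, 71, 84) if o != arr[i]]  # A C G T
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _species_names(n: int) -> list[str]:
    return [f"sp{i + 1:02d}" for i in range(n)]


def random_tree(rng: np.random.Generator, taxa: list[str], bl_range=(0.02, 0.08)) -> str:
    """Random bifurcating newick tree over `taxa` with uniform branch lengths."""
    nodes = [(t, None) for t in taxa]  # (newick fragment, unused)
    frags = [f"{t}" for t in taxa]
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        bi = rng.uniform(*bl_range)
        bj = rng.uniform(*bl_range)
        merged = f"({frags[i]}:{bi:.5f},{frags[j]}:{bj:.5f})"
        frags = [f for k, f in enumerate(frags) if k not in (i, j)] + [merged]
    del nodes
    return frags[0] + ";"


# --- anticodon / isotype bookkeeping for planted tRNAs -----------------------

_CODON_TO_AA3 = None


def _codon_table() -> dict[str, str]:
    global _CODON_TO_AA3
    if _CODON_TO_AA3 is None:
        from Bio.Data import CodonTable, IUPACData

        table = CodonTable.unambiguous_dna_by_id[1]
        one_to_three = IUPACData.protein_letters_1to3
        _CODON_TO_AA3 = {c: one_to_three[aa] for c, aa in table.forward_table.items()}
        _CODON_TO_AA3["TGA"] = "Sec"  # selenocysteine recoding; anticodon TCA
    return _CODON_TO_AA3


def generate_genome(config: SimConfig) -> tuple[dict[str, str], TruthSet]:
    """Simulate scaffolds plus ground truth for every species.

    Returns ``(scaffolds, truth)`` where scaffolds maps
    ``"<species>_<locus>"`` to sequence and truth carries planted intervals
    (0-based half-open, plus strand unless stated), per-species true segment
    sequences, the true species tree (``n_species > 2``), the mature miRNA
    sequences and the planted tRNA gene table.
    """
    rng = np.random.default_rng(config.seed)
    species = _species_names(config.n_species)

    # ancestral truth shared by all species
    ancestral = {seg: _random_seq(rng, L) for seg, L in config.rdna_unit_lengths.items()}
    ancestral["5S"] = _random_seq(rng, config.five_s_gene_length)
    insertion_element = _random_seq(rng, config.insertion_element_length)
    tree = random_tree(rng, species) if config.n_species > 2 else None

    scaffolds: dict[str, str] = {}
    intervals: list[GeneInterval] = []
    segments: dict[str, dict[str, str]] = {}
    mature_mirnas: dict[str, str] = {}
    trna_rows: list[dict] = []

    rate = config.per_site_polymorphism_rate
    for sp in species:
        seg_seqs = {seg: _mutate(rng, seq, rate) for seg, seq in ancestral.items()}
        segments[sp] = seg_seqs

        # --- main rDNA locus: tandem ETS-18S-ITS1-5.8S-ITS2-28S-NTS units
        scaf = f"{sp}_rdna"
        parts: list[str] = []
        pos = 0
        for _unit in range(config.n_rdna_units):
            for seg in RDNA_SEGMENT_ORDER:
                seq = seg_seqs[seg]
                if seg == "28S" and rng.random() < config.insertion_rate_28S:
                    mid = len(seq) // 2
                    seq = seq[:mid] + insertion_element + seq[mid:]
                intervals.append(
                    GeneInterval(scaf, pos, pos + len(seq), "+", "rDNA", seg)
                )
                parts.append(seq)
                pos += len(seq)
        scaffolds[scaf] = "".join(parts)

        # --- 5S locus: tandem ~500 bp units, CTTTT terminator downstream of gene
        scaf = f"{sp}_5s"
        gene = seg_seqs["5S"]
        spacer_len = config.five_s_unit_length - config.five_s_gene_length
        parts = []
        pos = 0
        for _unit in range(config.n_5s_units):
            lead = _random_seq(rng, 3).replace("CTTTT", "CTTTA")
            tail = _random_seq(rng, spacer_len - 3 - 5)
            unit = gene + lead + "CTTTT" + tail
            intervals.append(
                GeneInterval(scaf, pos, pos + len(gene), "+", "5S", "5S")
            )
            parts.append(unit)
            pos += len(unit)
        scaffolds[scaf] = "".join(parts)

        # --- gene playground: miRNAs, snoRNAs (guides vs this species' 18S), tRNAs
        scaf = f"{sp}_genes"
        parts = []
        pos = 0
        target_18s = seg_seqs["18S"]

        def _spacer():
            nonlocal pos
            gap = _random_seq(rng, config.gene_spacing)
            parts.append(gap)
            pos += len(gap)

        for k in range(config.n_mirnas):
            _spacer()
            name = f"{sp}-mir-{k + 1}"
            pre = _random_seq(rng, config.mirna_length)
            mstart = int(rng.integers(5, config.mirna_length - 27))
            mature_mirnas[name] = pre[mstart : mstart + 22]
            strand = "+" if rng.random() < 0.5 else "-"
            placed = pre if strand == "+" else revcomp(pre)
            intervals.append(
                GeneInterval(scaf, pos, pos + len(pre), strand, "miRNA", name)
            )
            parts.append(placed)
            pos += len(pre)

        for k in range(config.n_snornas):
            _spacer()
            name = f"{sp}-snoRNA-{k + 1}"
            sno = _make_snorna(rng, target_18s)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = sno if strand == "+" else revcomp(sno)
            intervals.append(
                GeneInterval(scaf, pos, pos + len(sno), strand, "snoRNA", name)
            )
            parts.append(placed)
            pos += len(sno)

        codons = sorted(_codon_table())
        for k in range(config.n_trnas_per_species):
            _spacer()
            codon = codons[rng.integers(0, len(codons))]
            iso = _codon_table()[codon]
            anticodon = revcomp(codon)
            body = _random_seq(rng, 72)
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"{sp}-tRNA-{iso}-{anticodon}-{k + 1}"
            intervals.append(
                GeneInterval(scaf, pos, pos + len(body), strand, "tRNA", name)
            )
            trna_rows.append(
                {
                    "species": sp,
                    "scaffold": scaf,
                    "start": pos,
                    "end": pos + len(body),
                    "strand": strand,
                    "isotype": iso,
                    "anticodon": anticodon,
                    "pseudo": bool(rng.random() < config.trna_pseudogene_rate),
                    "score": float(np.round(rng.uniform(30, 90), 1)),
                }
            )
            parts.append(body if strand == "+" else revcomp(body))
            pos += len(body)
        _spacer()
        scaffolds[scaf] = "".join(parts)

    truth = TruthSet(
        intervals=intervals,
        segments=segments,
        tree=tree,
        mature_mirnas=mature_mirnas,
        trna_records=pd.DataFrame(trna_rows),
    )
    return scaffolds, truth


def _make_snorna(rng: np.random.Generator, target: str) -> str:
    """A canonical C/D-box snoRNA: strong terminal stem, exact boxes, WC guide."""
    stem5 = _random_seq(rng, 6)
    box_c = ("A" if rng.random() < 0.5 else "G") + "TGATGA"
    spacer = _random_seq(rng, 40)
    while "CTGA" in spacer:
        spacer = _random_seq(rng, 40)
    glen = int(rng.integers(12, 19))  # 12-18 nt, comfortably inside 10-21
    tpos = int(rng.integers(0, len(target) - glen))
    guide = revcomp(target[tpos : tpos + glen])
    box_d = "CTGA"
    return stem5 + box_c + spacer + guide + box_d + revcomp(stem5)


def simulate_reads(
    scaffolds: dict[str, str], config: SimConfig, seed: int | None = None
) -> dict[str, str]:
    """Uniform shotgun reads with per-base substitution errors.

    Read count per scaffold is ``coverage * len / read_length``; scaffolds
    shorter than one read are skipped with a warning.  Roughly half the
    reads are reverse-complemented before being reported.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    reads: dict[str, str] = {}
    idx = 0
    for name, seq in scaffolds.items():
        L = len(seq)
        if L < config.read_length:
            warnings.warn(f"scaffold {name} shorter than read length; skipped")
            continue
        n_reads = int(round(config.coverage * L / config.read_length))
        starts = rng.integers(0, L - config.read_length + 1, size=n_reads)
        flips = rng.random(n_reads) < 0.5
        for s, flip in zip(starts, flips):
            r = _mutate(rng, seq[s : s + config.read_length], config.read_error_rate)
            reads[f"read_{idx:06d}"] = revcomp(r) if flip else r
            idx += 1
    return reads


def simulate_transcript_reads(
    truth: TruthSet, species: str, config: SimConfig, n: int = 200, seed: int | None = None
) -> list[str]:
    """Transcript-length reads for the 5.8S gene of one species.

    Emulates the two RNA length classes seen in expression data: mature-length
    molecules plus a ``long_58S_read_fraction`` minority extended by 20 nt
    into the downstream spacer (a ratio of about 1:10 at the default).
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    gene = truth.segments[species]["5.8S"]
    tail = truth.segments[species]["ITS2"][:20]
    out = []
    for _ in range(n):
        long_form = rng.random() < config.long_58S_read_fraction
        out.append(gene + tail if long_form else gene)
    return out


def simulate_evidence(
    truth: TruthSet,
    config: SimConfig,
    scaffold_lengths: dict[str, int],
    seed: int | None = None,
) -> pd.DataFrame:
    """Evidence-hit tables for the five miRNA prediction lines.

    Each planted miRNA is reported by each source with the source's
    sensitivity, its start jittered uniformly within +/-20 bp and length
    preserved; false hits are placed Poisson at ``fp_per_kb`` per scaffold
    with an 80 bp span.  Confidences are uniform in the source's range.
    Columns: source, scaffold, start, end, strand, confidence, name.
    """
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    rows: list[dict] = []
    mirnas = [iv for iv in truth.intervals if iv.gene_class == "miRNA"]
    for src in config.sources:
        lo, hi = src.confidence_range
        for iv in mirnas:
            if rng.random() >= src.sensitivity:
                continue
            jitter = int(rng.integers(-20, 21))
            start = max(0, iv.start + jitter)
            rows.append(
                {
                    "source": src.name,
                    "scaffold": iv.scaffold,
                    "start": start,
                    "end": start + (iv.end - iv.start),
                    "strand": iv.strand,
                    "confidence": float(rng.uniform(lo, hi)),
                    "name": iv.name,
                }
            )
        for scaf, L in scaffold_lengths.items():
            n_fp = rng.poisson(src.fp_per_kb * L / 1000.0)
            for _ in range(n_fp):
                start = int(rng.integers(0, max(1, L - 80)))
                rows.append(
                    {
                        "source": src.name,
                        "scaffold": scaf,
                        "start": start,
                        "end": start + 80,
                        "strand": "+" if rng.random() < 0.5 else "-",
                        "confidence": float(rng.uniform(lo, hi)),
                        "name": "",
                    }
                )
    df = pd.DataFrame(
        rows, columns=["source", "scaffold", "start", "end", "strand", "confidence", "name"]
    )
    return df.sort_values(["scaffold", "start", "source"], kind="stable").reset_index(drop=True)


def evolve_alignment(
    newick: str, length: int, seed: int = 0
) -> dict[str, str]:
    """Evolve an ungapped alignment along a newick tree with branch lengths.

    Each branch substitutes every site independently with probability equal
    to its branch length (adequate at the low divergences the survey
    simulates).  Returns {taxon: sequence}.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    rng = np.random.default_rng(seed)
    root_seq = _random_seq(rng, length)
    seqs: dict[str, str] = {}

    def _descend(node, seq):
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            cseq = _mutate(rng, seq, min(1.0, bl))
            if child.is_leaf():
                seqs[child.taxon.label] = cseq
            else:
                _descend(child, cseq)

    _descend(tree.seed_node, root_seq)
    return seqs
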