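"""Sequence data model shared by all analysis stages.

Coding sequences are stored in the DNA alphabet (``T``); ``U`` is accepted on
input and converted.  Codon indices are 0-based internally and 1-based in
reports.  Trailing stop codons are stripped at load time, so every stored CDS
consists of sense codons only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STANDARD_CODE: Dict[str, str] = {}
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_BASES = "TCAG"
_AA_TABLE = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(
    (b1, b2, b3) for b1 in _BASES for b2 in _BASES for b3 in _BASES
):
    _aa = _AA_TABLE[_i]
    if _aa != "*":
        STANDARD_CODE[_b1 + _b2 + _b3] = _aa

SENSE_CODONS: List[str] = sorted(STANDARD_CODE)
assert len(SENSE_CODONS) == 61

#: Net charge carried by each amino acid side chain at physiological pH,
#: coarse-grained to {-1, 0, +1}: Arg/His/Lys positive, Asp/Glu negative.
CHARGE: Dict[str, int] = {aa: 0 for aa in set(STANDARD_CODE.values())}
CHARGE.update({"R": 1, "H": 1, "K": 1, "D": -1, "E": -1})


class SequenceError(ValueError):
    """Raised when a sequence violates a CDS invariant."""


def normalize_nt(seq: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA alphabet."""
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise SequenceError(f"invalid nucleotide characters: {sorted(bad)}")
    return s


def codon_list(cds: str) -> List[str]:
    """Partition a CDS into consecutive non-overlapping triplets."""
    if len(cds) % 3:
        raise SequenceError(f"length {len(cds)} not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def translate(cds: str) -> str:
    """Translate with the standard code; a trailing stop codon is dropped.

    Raises :class:`SequenceError` naming the (0-based) codon index of any
    internal stop codon.
    """
    codons = codon_list(normalize_nt(cds))
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    out = []
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise SequenceError(f"internal stop codon {c} at codon index {i}")
        out.append(STANDARD_CODE[c])
    return "".join(out)


@dataclass
class CodingSequence:
    """A single protein-coding gene: sense codons plus optional UTRs."""

    gene_id: str
    cds: str
    utr5: Optional[str] = None
    utr3: Optional[str] = None

    def __post_init__(self) -> None:
        self.cds = normalize_nt(self.cds)
        if len(self.cds) % 3:
            raise SequenceError(
                f"{self.gene_id}: CDS length {len(self.cds)} not divisible by 3"
            )
        codons = codon_list(self.cds)
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
            self.cds = "".join(codons)
        for i, c in enumerate(codons):
            if c in STOP_CODONS:
                raise SequenceError(
                    f"{self.gene_id}: internal stop codon at codon index {i}"
                )
        if not codons:
            raise SequenceError(f"{self.gene_id}: empty CDS")
        if self.utr5 is not None:
            self.utr5 = normalize_nt(self.utr5)
        if self.utr3 is not None:
            self.utr3 = normalize_nt(self.utr3)

    @property
    def codons(self) -> List[str]:
        return codon_list(self.cds)

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    @property
    def protein(self) -> str:
        return "".join(STANDARD_CODE[c] for c in self.codons)

    def charge_vector(self) -> List[int]:
        """Per-codon amino-acid charge: +1 Arg/His/Lys, -1 Asp/Glu, else 0."""
        return [CHARGE[STANDARD_CODE[c]] for c in self.codons]


def charge_vector(cds: str) -> List[int]:
    return CodingSequence("_", cds).charge_vector()


@dataclass
class Genome:
    """Ordered collection of coding sequences with unique gene ids."""

    genes: List[CodingSequence] = field(default_factory=list)
    organism: str = ""

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceError(f"duplicate gene ids: {dup}")
        self._index = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[CodingSequence]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> CodingSequence:
        return self._index[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    @property
    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.genes]


def filter_by_length(genome: Genome, min_length_codons: int) -> Genome:
    """Genes with at least ``min_length_codons`` sense codons.

    Profiles include all genes by default (short genes just cover fewer
    positions); this filter serves analyses restricted to genes of
    substantial length.
    """
    kept = [g for g in genome.genes if g.n_codons >= min_length_codons]
    if not kept:
        raise SequenceError("no genes pass the length filter")
    return Genome(kept, organism=genome.organism)


def load_genome(
    path, utr5_path=None, utr3_path=None, organism: str = ""
) -> Genome:
    """Load a genome from a FASTA of coding sequences.

    Records that violate CDS invariants (length not divisible by 3, internal
    stops, invalid characters) are skipped with a logged warning.  Duplicate
    ids and an empty result are fatal.
    """
    utr5 = _load_utrs(utr5_path) if utr5_path else {}
    utr3 = _load_utrs(utr3_path) if utr3_path else {}
    genes: List[CodingSequence] = []
    n_skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            genes.append(
                CodingSequence(
                    rec.id,
                    str(rec.seq),
                    utr5=utr5.get(rec.id),
                    utr3=utr3.get(rec.id),
                )
            )
        except SequenceError as e:
            n_skipped += 1
            logger.warning("skipping record %s: %s", rec.id, e)
    if not genes:
        raise SequenceError(f"no valid coding sequences in {path}")
    if n_skipped:
        logger.warning("%d records skipped while loading %s", n_skipped, path)
    return Genome(genes, organism=organism)


def write_genome(genome: Genome, path) -> None:
    """Write coding sequences to FASTA (one record per gene)."""
    records = [
        SeqRecord(Seq(g.cds), id=g.gene_id, description="") for g in genome
    ]
    SeqIO.write(records, str(path), "fasta")


def _load_utrs(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


@dataclass
class ExpressionTable:
    """Per-gene mRNA level and protein abundance (positive reals, sparse)."""

    mrna_level: Dict[str, float] = field(default_factory=dict)
    protein_abundance: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, table in (
            ("mrna_level", self.mrna_level),
            ("protein_abundance", self.protein_abundance),
        ):
            for gid, v in table.items():
                if not (v > 0) or v != v or v in (float("inf"),):
                    raise ValueError(f"{name}[{gid}] = {v!r} not finite > 0")


def load_expression(path) -> ExpressionTable:
    """Read a tab-separated expression table.

    Expected columns: ``gene_id``, ``mrna_level``, ``protein_abundance``.
    Empty cells are treated as missing.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    mrna, prot = {}, {}
    for _, row in df.iterrows():
        gid = str(row["gene_id"])
        if "mrna_level" in df.columns and pd.notna(row.get("mrna_level")):
            mrna[gid] = float(row["mrna_level"])
        if "protein_abundance" in df.columns and pd.notna(
            row.get("protein_abundance")
        ):
            prot[gid] = float(row["protein_abundance"])
    return ExpressionTable(mrna, prot)


def write_expression(table: ExpressionTable, path) -> None:
    import pandas as pd

    ids = sorted(set(table.mrna_level) | set(table.protein_abundance))
    df = pd.DataFrame(
        {
            "gene_id": ids,
            "mrna_level": [table.mrna_level.get(i) for i in ids],
            "protein_abundance": [table.protein_abundance.get(i) for i in ids],
        }
    )
    df.to_csv(path, sep="\t", index=False)
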