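"""Intron distribution patterns and splicing phases within the domain.

An intron interrupting the domain-encoding CDS is described by its phase
(0 = between codons, 1/2 = after the first/second base of a codon) and by the
domain-alignment position of the amino acid it is attributed to: the residue
whose codon it interrupts for phases 1 and 2, or the residue immediately 3'
of the junction for phase 0.  The resulting (positions, phases) vector is
canonicalised as a pattern key like ``"10:0;27:1"`` (``"-"`` for intronless),
and distinct keys across a family are labelled A, B, C ... in order of
descending frequency.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import gffutils

from .consensus import DOMAIN_LENGTH
from .domains import BHLHDomain


@dataclass(frozen=True)
class GeneModel:
    """One gene model: CDS intervals in transcript (5'->3') order.

    Intervals are 1-based inclusive genomic coordinates; for minus-strand
    genes the first interval is the rightmost one.
    """

    gene_id: str
    chrom: str
    strand: str
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if not self.cds:
            raise ValueError(f"gene {self.gene_id} has no CDS")
        if self.cds_length % 3:
            raise ValueError(f"gene {self.gene_id}: CDS length not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def segment_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.cds)


@dataclass(frozen=True)
class IntronPattern:
    positions: tuple[int, ...]  # 1-based positions on the 61-aa alignment
    phases: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.phases):
            raise ValueError("positions and phases differ in length")
        if any(p2 <= p1 for p1, p2 in zip(self.positions, self.positions[1:])):
            # same aligned residue can host phase-1 and phase-2 introns only
            # in degenerate inputs; positions must not decrease
            if any(p2 < p1 for p1, p2 in zip(self.positions, self.positions[1:])):
                raise ValueError("positions must be non-decreasing")
        if any(ph not in (0, 1, 2) for ph in self.phases):
            raise ValueError("phases must be 0, 1 or 2")

    @property
    def n_introns(self) -> int:
        return len(self.positions)

    @property
    def pattern_key(self) -> str:
        if not self.positions:
            return "-"
        return ";".join(f"{p}:{ph}" for p, ph in zip(self.positions, self.phases))

    @classmethod
    def from_key(cls, key: str) -> "IntronPattern":
        if key == "-":
            return cls((), ())
        pos, ph = [], []
        for item in key.split(";"):
            p, f = item.split(":")
            pos.append(int(p))
            ph.append(int(f))
        return cls(tuple(pos), tuple(ph))


def load_gene_models(gff3: str | Path) -> dict[str, GeneModel]:
    """Parse gene models from GFF3 (first mRNA per gene)."""
    db = gffutils.create_db(
        str(gff3), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    models = {}
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        cds = sorted(
            ((f.start, f.end) for f in db.children(parent, featuretype="CDS")),
        )
        if not cds:
            continue
        if gene.strand == "-":
            cds = cds[::-1]
        models[gene.id] = GeneModel(gene.id, gene.seqid, gene.strand, tuple(cds))
    return models


def domain_intron_pattern(model: GeneModel, domain: BHLHDomain) -> IntronPattern:
    """Introns interrupting the domain-encoding CDS of one gene.

    The domain occupies CDS bases [3*start, 3*(start+61)) in transcript
    orientation.  An intron after CDS base offset o (0-based count of coding
    bases 5' of the junction) has phase o % 3 and is attributed to amino acid
    o // 3; it is reported only when both flanking exonic bases lie within the
    domain-encoding span.
    """
    span_start = 3 * domain.start
    span_end = 3 * (domain.start + DOMAIN_LENGTH)
    if span_end > model.cds_length:
        raise ValueError(
            f"domain of {domain.protein_id or model.gene_id} extends past the CDS"
        )
    positions, phases = [], []
    offset = 0
    for seg_len in model.segment_lengths[:-1]:
        offset += seg_len
        # flanking exonic bases are offsets offset-1 and offset
        if span_start + 1 <= offset <= span_end - 1:
            aa_index = offset // 3  # 0-based protein coordinate
            positions.append(aa_index - domain.start + 1)
            phases.append(offset % 3)
    return IntronPattern(tuple(positions), tuple(phases))


def label_patterns(patterns: list[IntronPattern]) -> dict[str, str]:
    """Letter labels for distinct patterns, by descending family frequency.

    Ties are broken lexicographically on the pattern key; labels run A..Z and
    continue AA, AB, ... when a family shows more than 26 distinct patterns.
    """
    if not patterns:
        raise ValueError("no intron patterns supplied")
    freq = Counter(p.pattern_key for p in patterns)
    ordered = sorted(freq, key=lambda k: (-freq[k], k))
    return {key: _letter_label(i) for i, key in enumerate(ordered)}


def _letter_label(i: int) -> str:
    letters = ""
    i += 1  # bijective base-26
    while i:
        i, rem = divmod(i - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters
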