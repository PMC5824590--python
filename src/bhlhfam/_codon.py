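"""Codon-level utilities shared by the Ks estimator and the sequence generator.

The standard genetic code (translation table 1) is used throughout; generated
CDS never contain ambiguity codes, but analysis entry points tolerate them by
dropping the affected codon pair.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]

BASES = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODON_TO_AA = dict(_TABLE.forward_table)  # sense codons only
SENSE_CODONS = tuple(sorted(CODON_TO_AA))


def is_sense(codon: str) -> bool:
    return codon in CODON_TO_AA


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, '*' for a stop."""
    return CODON_TO_AA.get(codon, "*")


@lru_cache(maxsize=None)
def synonymous_alternatives(codon: str, position: int) -> tuple[str, ...]:
    """Alternative bases at ``position`` that leave the amino acid unchanged.

    Changes producing stop codons are never synonymous alternatives.
    """
    aa = CODON_TO_AA[codon]
    out = []
    for b in BASES:
        if b == codon[position]:
            continue
        alt = codon[:position] + b + codon[position + 1:]
        if CODON_TO_AA.get(alt) == aa:
            out.append(b)
    return tuple(out)


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Number of synonymous sites in a sense codon (Nei-Gojobori counting).

    Each position contributes the fraction of its three possible single-base
    changes that are synonymous; changes creating a stop codon count as
    nonsynonymous, so synonymous + nonsynonymous sites always total 3.
    """
    s = 0.0
    for pos in range(3):
        s += len(synonymous_alternatives(codon, pos)) / 3.0
    return s


@lru_cache(maxsize=None)
def pathway_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons.

    For codons differing at k positions all k! orderings of the single-base
    steps are enumerated; orderings passing through a stop codon are excluded
    from the average (both endpoints must be sense codons).  If every ordering
    is blocked by a stop, the average falls back to all orderings so that the
    total number of differences is conserved.
    """
    if not (is_sense(codon1) and is_sense(codon2)):
        raise ValueError(f"stop codon in pair ({codon1}, {codon2})")
    diff = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff:
        return (0.0, 0.0)

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        sd = nd = 0.0
        cur = codon1
        for step, pos in enumerate(order):
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                return None
            if translate_codon(cur) == translate_codon(nxt):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return (sd, nd)

    valid = [r for r in (walk(order) for order in permutations(diff)) if r is not None]
    if not valid:
        # all orderings pass through a stop; average over them anyway
        valid = []
        for order in permutations(diff):
            sd = nd = 0.0
            cur = codon1
            for pos in order:
                nxt = cur[:pos] + codon2[pos] + cur[pos + 1:]
                if translate_codon(cur) == translate_codon(nxt):
                    sd += 1.0
                else:
                    nd += 1.0
                cur = nxt
            valid.append((sd, nd))
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return (sd, nd)


def split_codons(cds: str) -> list[str]:
    """Split a CDS into codons, validating length and internal stops."""
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons[:-1]):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c} at codon {i}")
    return codons
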