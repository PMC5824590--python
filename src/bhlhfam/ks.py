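"""Pairwise Ka/Ks estimation and duplication-age dating.

Synonymous divergence is estimated with the Nei-Gojobori (1986) counting
method: per-codon synonymous site fractions are obtained by enumerating the
three single-base changes at each position under the standard genetic code,
observed differences between codons are averaged over all orderings of the
mutational pathway, and multiple hits are corrected with the Jukes-Cantor
formula Ks = -(3/4) ln(1 - (4/3) pS).

Ks doubles as a molecular clock: with a synonymous rate r per site per year,
a pair with divergence Ks coalesces T = Ks / (2 r) years ago.  The default
rate 2.6e-9 substitutions/site/year places Ks = 0.312 at 60 MYA (the
cotton-cacao split) and Ks = 0.520 at 100 MYA (the older paleopolyploidy),
and duplicate pairs are classed as "recent" (0.005 < Ks <= 0.312) or "old"
(0.312 < Ks <= 3.0); pairs beyond Ks 3.0 are saturated and excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from ._codon import pathway_differences, split_codons, synonymous_sites

logger = logging.getLogger(__name__)

#: synonymous substitutions per site per year; Ks 0.312 <-> 60 MYA
DEFAULT_CLOCK_RATE = 2.6e-9

#: age-class boundaries on Ks
KS_SUB_RECENT_MAX = 0.005
KS_RECENT_MAX = 0.312
KS_SATURATION = 3.0

AGE_CLASSES = ("sub_recent", "recent", "old", "excluded")

_BASES = set("ACGT")


@dataclass(frozen=True)
class CodonAlignment:
    """A gap-free codon alignment of two CDS after gap-column removal."""

    id1: str
    id2: str
    codons1: tuple[str, ...]
    codons2: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons1) != len(self.codons2):
            raise ValueError("aligned codon strings differ in length")

    @property
    def n_codons_compared(self) -> int:
        return len(self.codons1)


@dataclass(frozen=True)
class KsEstimate:
    id1: str
    id2: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    valid: bool


@dataclass(frozen=True)
class AgeClass:
    age_class: str
    mya: float


def make_protein_aligner() -> PairwiseAligner:
    """Global protein aligner: BLOSUM62, gap open 10, extend 0.5."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def codon_align(cds1: str, cds2: str, id1: str = "seq1", id2: str = "seq2") -> CodonAlignment:
    """Codon-aware pairwise alignment via global protein alignment.

    The proteins are aligned (BLOSUM62, affine gaps), the alignment is
    back-translated to codons, and gap columns are removed.  Codons containing
    non-ACGT characters are also dropped pairwise.
    """
    codons1 = split_codons(cds1)
    codons2 = split_codons(cds2)
    # trailing stop codons are tolerated and trimmed
    from ._codon import STOP_CODONS
    if codons1 and codons1[-1] in STOP_CODONS:
        codons1 = codons1[:-1]
    if codons2 and codons2[-1] in STOP_CODONS:
        codons2 = codons2[:-1]
    prot1 = str(Seq("".join(codons1)).translate())
    prot2 = str(Seq("".join(codons2)).translate())
    if "*" in prot1 or "*" in prot2:
        raise ValueError("untranslatable CDS (internal stop)")
    aligner = make_protein_aligner()
    aln = aligner.align(prot1, prot2)[0]
    a1, a2 = str(aln[0]), str(aln[1])
    kept1, kept2 = [], []
    i1 = i2 = 0
    for c1, c2 in zip(a1, a2):
        if c1 != "-" and c2 != "-":
            cod1, cod2 = codons1[i1], codons2[i2]
            if set(cod1) <= _BASES and set(cod2) <= _BASES:
                kept1.append(cod1)
                kept2.append(cod2)
        if c1 != "-":
            i1 += 1
        if c2 != "-":
            i2 += 1
    return CodonAlignment(id1, id2, tuple(kept1), tuple(kept2))


def ng86_ks(aln: CodonAlignment, min_codons: int = 10) -> KsEstimate:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    ``valid`` is False when either proportion reaches the Jukes-Cantor
    singularity (p >= 3/4), in which case the rate is reported as NaN.
    """
    n = aln.n_codons_compared
    if n < min_codons:
        raise ValueError(f"alignment has {n} codons; at least {min_codons} required")
    s1 = sum(synonymous_sites(c) for c in aln.codons1)
    s2 = sum(synonymous_sites(c) for c in aln.codons2)
    S = (s1 + s2) / 2.0
    N = 3.0 * n - S
    Sd = Nd = 0.0
    for c1, c2 in zip(aln.codons1, aln.codons2):
        sd, nd = pathway_differences(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks, ks_ok = _jukes_cantor(pS)
    Ka, ka_ok = _jukes_cantor(pN)
    return KsEstimate(
        aln.id1, aln.id2, S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        Ks=Ks, Ka=Ka, valid=ks_ok and ka_ok,
    )


def _jukes_cantor(p: float) -> tuple[float, bool]:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return (float("nan"), False)
    return (-0.75 * math.log(arg), True)


def classify_age(ks: float, rate: float = DEFAULT_CLOCK_RATE) -> AgeClass:
    """Assign a duplication age class and point age (MYA) from Ks.

    Boundaries are inclusive on the lower class: Ks <= 0.005 is sub-recent
    (post-polyploidy), 0.005 < Ks <= 0.312 recent, 0.312 < Ks <= 3.0 old,
    Ks > 3.0 saturated/excluded.
    """
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    if ks <= KS_SUB_RECENT_MAX:
        cls = "sub_recent"
    elif ks <= KS_RECENT_MAX:
        cls = "recent"
    elif ks <= KS_SATURATION:
        cls = "old"
    else:
        cls = "excluded"
    return AgeClass(cls, ks_to_mya(ks, rate))


def ks_to_mya(ks: float, rate: float = DEFAULT_CLOCK_RATE) -> float:
    """Convert synonymous divergence to an age in million years: Ks/(2r)/1e6."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    if rate <= 0:
        raise ValueError("clock rate must be positive")
    return ks / (2.0 * rate) / 1e6


def ks_histogram(estimates: list[KsEstimate], bin_width: float = 0.1) -> pd.DataFrame:
    """Frequency table of Ks over bins [0, w), [w, 2w) ... up to saturation.

    Invalid estimates and values beyond the saturation cutoff are dropped
    with a logged count; an empty retained set is an error.
    """
    if not estimates:
        raise ValueError("no Ks estimates supplied")
    values = [e.Ks for e in estimates if e.valid and e.Ks <= KS_SATURATION]
    dropped = len(estimates) - len(values)
    if dropped:
        logger.info("ks_histogram: dropped %d invalid/saturated estimates", dropped)
    if not values:
        raise ValueError("no Ks estimates retained after filtering")
    edges = np.arange(0.0, KS_SATURATION + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )


def ks_table(
    cds_fasta: str | Path,
    pairs: pd.DataFrame,
    rate: float = DEFAULT_CLOCK_RATE,
) -> pd.DataFrame:
    """Ka/Ks and age class for every pair in a two-column pair list.

    ``pairs`` must have its gene-id columns first and second; the CDS FASTA
    must contain every listed gene.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(cds_fasta), "fasta")}
    rows = []
    for g1, g2 in pairs.iloc[:, :2].itertuples(index=False):
        if g1 not in seqs:
            raise KeyError(f"gene {g1} missing from CDS FASTA")
        if g2 not in seqs:
            raise KeyError(f"gene {g2} missing from CDS FASTA")
        est = ng86_ks(codon_align(seqs[g1], seqs[g2], g1, g2))
        age = classify_age(est.Ks, rate) if est.valid else AgeClass("excluded", float("nan"))
        rows.append(
            {
                "gene1": g1, "gene2": g2,
                "S": round(est.S, 4), "N": round(est.N, 4),
                "Ka": round(est.Ka, 6) if est.valid else float("nan"),
                "Ks": round(est.Ks, 6) if est.valid else float("nan"),
                "age_class": age.age_class,
                "mya": round(age.mya, 3) if est.valid else float("nan"),
            }
        )
    return pd.DataFrame(rows)
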