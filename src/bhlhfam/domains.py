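"""bHLH domain detection and DNA-binding classification.

A protein is scanned with the 61-position consensus log-odds profile; the
basic region (alignment positions 1-17) of each hit is then read out to
predict DNA-binding behaviour, following the residue criteria established for
plant bHLH surveys:

* DNA-binding requires at least 5 basic residues (Lys/Arg/His) among the 17
  basic-region positions; fewer makes the protein a non-DNA-binding HLH.
* E-box (CANNTG) recognition requires Glu at alignment position 9 and Arg at
  position 12.
* G-box (CACGTG) recognition additionally requires His at position 5 and Arg
  at position 13.
* Proteins with the E-box residues but lacking Arg at position 16 are flagged
  SREBP-like: animal SREBP proteins miss this arginine yet still bind E-boxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .consensus import (
    AA_INDEX,
    ALPHABET,
    BASIC_REGION_LENGTH,
    DOMAIN_LENGTH,
    KEY_POSITIONS,
    ConsensusModel,
    default_model,
)

BASIC_RESIDUES = frozenset("KRH")

#: The four predicted DNA-binding activity categories.
CATEGORIES = ("G-box", "E-box-non-G-box", "non-E-box", "non-DNA")

#: Minimum basic residues in the basic region for DNA binding.
DNA_BINDING_MIN_BASIC = 5


@dataclass(frozen=True)
class BHLHDomain:
    """A located domain hit.

    ``start``/``end`` are 0-based half-open protein coordinates; ``aligned``
    is the 61-character residue string on the model's alignment, so alignment
    position ``i`` (1-based) maps to protein position ``start + i - 1``.
    """

    protein_id: str
    start: int
    end: int
    aligned: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned) != DOMAIN_LENGTH:
            raise ValueError("aligned string must have 61 positions")
        if self.end - self.start > DOMAIN_LENGTH:
            raise ValueError("domain span exceeds alignment length")

    @property
    def basic_region(self) -> str:
        return self.aligned[:BASIC_REGION_LENGTH]

    def protein_position(self, aligned_pos: int) -> int:
        """Protein coordinate (0-based) of a 1-based alignment position."""
        if not 1 <= aligned_pos <= DOMAIN_LENGTH:
            raise ValueError("alignment position out of range")
        return self.start + aligned_pos - 1

    def residue_at(self, aligned_pos: int) -> str:
        return self.aligned[aligned_pos - 1]


@dataclass(frozen=True)
class BindingCall:
    category: str
    basic_residue_count: int
    srebp_like: bool

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def scan_for_bhlh(protein: str, model: ConsensusModel | None = None) -> list[BHLHDomain]:
    """Scan a protein for bHLH domains with an ungapped log-odds window scan.

    Returns non-overlapping hits (greedy by score) sorted by position, each
    scoring at least the model threshold.  'X' is tolerated and scores as
    background; any other non-standard residue is an input error.
    """
    if model is None:
        model = default_model()
    protein = protein.upper()
    if not protein:
        return []
    for aa in set(protein):
        if aa not in AA_INDEX and aa != "X":
            raise ValueError(f"illegal amino-acid character {aa!r}")
    n = len(protein)
    if n < DOMAIN_LENGTH:
        return []
    # vectorized window scoring: encode, gather per-position log-odds
    codes = np.array([AA_INDEX.get(a, -1) for a in protein], dtype=np.int64)
    lo = np.concatenate([model.log_odds, np.zeros((DOMAIN_LENGTH, 1))], axis=1)  # X column
    n_win = n - DOMAIN_LENGTH + 1
    idx = codes[np.arange(n_win)[:, None] + np.arange(DOMAIN_LENGTH)[None, :]]
    scores = lo[np.arange(DOMAIN_LENGTH)[None, :], idx].sum(axis=1)

    order = np.argsort(-scores, kind="stable")
    taken: list[tuple[int, float]] = []
    for i in order:
        if scores[i] < model.threshold:
            break
        if all(abs(int(i) - s) >= DOMAIN_LENGTH for s, _ in taken):
            taken.append((int(i), float(scores[i])))
    hits = [
        BHLHDomain(
            protein_id="",
            start=s,
            end=s + DOMAIN_LENGTH,
            aligned=protein[s:s + DOMAIN_LENGTH],
            score=sc,
        )
        for s, sc in sorted(taken)
    ]
    return hits


def best_hit(protein_id: str, protein: str, model: ConsensusModel | None = None) -> BHLHDomain | None:
    """Best-scoring domain of a protein (one domain per protein for family
    statistics), or None when nothing reaches the threshold."""
    hits = scan_for_bhlh(protein, model)
    if not hits:
        return None
    top = max(hits, key=lambda h: h.score)
    return BHLHDomain(protein_id, top.start, top.end, top.aligned, top.score)


def count_basic_residues(basic_region: str) -> int:
    """Number of Lys/Arg/His residues in the 17-position basic region.

    Gap characters ('-') are allowed and not counted.
    """
    if len(basic_region) != BASIC_REGION_LENGTH:
        raise ValueError(f"basic region must have {BASIC_REGION_LENGTH} positions")
    return sum(1 for aa in basic_region.upper() if aa in BASIC_RESIDUES)


def classify_binding(domain: BHLHDomain) -> BindingCall:
    """Assign the four-way DNA-binding category from basic-region residues."""
    region = domain.basic_region
    n_basic = count_basic_residues(region)
    ebox = (
        domain.residue_at(KEY_POSITIONS["glu9"]) == "E"
        and domain.residue_at(KEY_POSITIONS["arg12"]) == "R"
    )
    gbox = ebox and (
        domain.residue_at(KEY_POSITIONS["his5"]) == "H"
        and domain.residue_at(KEY_POSITIONS["arg13"]) == "R"
    )
    srebp = ebox and domain.residue_at(KEY_POSITIONS["arg16"]) != "R"
    if n_basic < DNA_BINDING_MIN_BASIC:
        return BindingCall("non-DNA", n_basic, False)
    if gbox:
        return BindingCall("G-box", n_basic, srebp)
    if ebox:
        return BindingCall("E-box-non-G-box", n_basic, srebp)
    return BindingCall("non-E-box", n_basic, False)


def mean_basic_residues(calls: list[BindingCall]) -> float:
    """Mean basic-residue count over a family, reported to 2 decimals."""
    if not calls:
        raise ValueError("empty list of binding calls")
    return round(sum(c.basic_residue_count for c in calls) / len(calls), 2)


def scan_fasta(path: str | Path, model: ConsensusModel | None = None) -> pd.DataFrame:
    """Scan a protein FASTA and classify every best hit.

    Returns a table with columns protein_id, start, end, score,
    aligned_domain, basic_count, category, srebp_like (one row per protein
    with a detected domain).
    """
    if model is None:
        model = default_model()
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        hit = best_hit(rec.id, str(rec.seq), model)
        if hit is None:
            continue
        call = classify_binding(hit)
        rows.append(
            {
                "protein_id": rec.id,
                "start": hit.start,
                "end": hit.end,
                "score": round(hit.score, 4),
                "aligned_domain": hit.aligned,
                "basic_count": call.basic_residue_count,
                "category": call.category,
                "srebp_like": call.srebp_like,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "start", "end", "score", "aligned_domain",
            "basic_count", "category", "srebp_like",
        ],
    )
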