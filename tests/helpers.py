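"""Independent brute-force oracles used to check the implementation."""

from __future__ import annotations

import math

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)


def aa_of(codon: str) -> str:
    return _AA.get(codon, "*")


def ng86_pathway_oracle(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) by recursive enumeration of substitution
    orders, excluding orders that pass through a stop codon (falling back to
    all orders when every one is blocked)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return (0.0, 0.0)

    def recurse(cur: str, remaining: list[int], allow_stops: bool):
        if not remaining:
            return [(0.0, 0.0)]
        out = []
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS and not allow_stops:
                continue
            step = (1.0, 0.0) if aa_of(cur) == aa_of(nxt) else (0.0, 1.0)
            for sd, nd in recurse(nxt, [p for p in remaining if p != pos], allow_stops):
                out.append((step[0] + sd, step[1] + nd))
        return out

    paths = recurse(c1, diff, allow_stops=False)
    if not paths:
        paths = recurse(c1, diff, allow_stops=True)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return (sd, nd)


def syn_sites_oracle(codon: str) -> float:
    """Fraction-of-synonymous-changes site count, computed directly."""
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in _STOPS and aa_of(alt) == aa_of(codon):
                syn += 1
        total += syn / 3.0
    return total


def fisher_family_oracle(r1: int, r2: int, c1: int) -> dict[int, float]:
    """Exact two-sided Fisher p for every table with margins (r1, r2, c1).

    Returns {a: p}.  Integer arithmetic throughout: p is the sum of
    hypergeometric numerators no larger than the observed one, over the
    common denominator C(n, c1).
    """
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = {a: math.comb(r1, a) * math.comb(r2, c1 - a) for a in range(lo, hi + 1)}
    denom = math.comb(n, c1)
    out = {}
    for a, obs in nums.items():
        out[a] = sum(v for v in nums.values() if v <= obs) / denom
    return out


def window_scores_oracle(protein: str, model) -> list[float]:
    """Per-window log-odds scores computed position by position in Python."""
    L = model.length
    return [
        model.score_sequence(protein[i:i + L])
        for i in range(len(protein) - L + 1)
    ]
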