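"""Position-specific scoring model for the ~60-aa bHLH domain.

The domain is represented on a fixed 61-position alignment: positions 1-17
form the basic region that contacts DNA, followed by helix 1, the loop and
helix 2.  Detection uses an ungapped log-odds scan of this profile rather
than a profile HMM; the profile is strongly conserved over the helix-loop-
helix core and deliberately soft over the basic region, whose composition is
what the downstream DNA-binding classifier reads out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

DOMAIN_LENGTH = 61
BASIC_REGION_LENGTH = 17
#: 1-based alignment positions whose residues determine DNA-motif recognition
KEY_POSITIONS = {"his5": 5, "glu9": 9, "arg12": 12, "arg13": 13, "arg16": 16}

# Fixed 61-position consensus: 17-aa basic region (His5/Glu9/Arg12/Arg13/Arg16
# at the recognition positions), 15-aa helix 1, 6-aa loop, 23-aa helix 2.
CONSENSUS = (
    "KRRAHNEAERERRRRIN"   # basic region, positions 1-17
    "NERERNRVKQVNNGF"     # helix 1
    "AVKMDK"              # loop
    "ASILGDAIEYLKELLQRINDLHN"  # helix 2
)
assert len(CONSENSUS) == DOMAIN_LENGTH

# Residue pool the basic region draws on besides the consensus residue.
_BASIC_REGION_POOL = {
    "R": 0.13, "K": 0.10, "H": 0.05, "Q": 0.09, "E": 0.09, "N": 0.09,
    "S": 0.09, "A": 0.09, "D": 0.05, "T": 0.05, "G": 0.05, "L": 0.04,
    "M": 0.03, "V": 0.03, "I": 0.02,
}


@dataclass
class ConsensusModel:
    """61-position residue-frequency profile with a log-odds score threshold.

    Parameters
    ----------
    profile : (61, 20) array of per-position residue frequencies, rows sum to 1.
    background : length-20 background residue frequencies.
    threshold : minimum window log-odds score (nats) to report a hit.
    """

    profile: np.ndarray
    background: np.ndarray
    threshold: float
    consensus: str = CONSENSUS
    log_odds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.profile.shape != (DOMAIN_LENGTH, len(ALPHABET)):
            raise ValueError(f"profile must be ({DOMAIN_LENGTH}, {len(ALPHABET)})")
        if not np.allclose(self.profile.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile rows must sum to 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        self.log_odds = np.log(self.profile / self.background[None, :])

    @property
    def length(self) -> int:
        return DOMAIN_LENGTH

    def max_score(self) -> float:
        """Score of the per-position argmax (consensus) sequence."""
        return float(self.log_odds.max(axis=1).sum())

    def score_sequence(self, window: str) -> float:
        """Log-odds score of one 61-aa window; X scores 0 (background)."""
        if len(window) != DOMAIN_LENGTH:
            raise ValueError("window length must equal the model length")
        total = 0.0
        for p, aa in enumerate(window):
            if aa == "X":
                continue
            total += self.log_odds[p, AA_INDEX[aa]]
        return total


def _position_distribution(pos: int) -> np.ndarray:
    """Frequency vector for one alignment position (0-based)."""
    cons = CONSENSUS[pos]
    freq = np.zeros(len(ALPHABET))
    if pos < BASIC_REGION_LENGTH:
        w = 0.50 if (pos + 1) in KEY_POSITIONS.values() else 0.25
        pool = np.zeros(len(ALPHABET))
        for aa, p in _BASIC_REGION_POOL.items():
            pool[AA_INDEX[aa]] = p
        pool /= pool.sum()
        freq = w * _one_hot(cons) + (1.0 - w) * pool
    else:
        w = 0.70
        rest = np.full(len(ALPHABET), (1.0 - w) / (len(ALPHABET) - 1))
        rest[AA_INDEX[cons]] = 0.0
        freq = w * _one_hot(cons) + rest
    # floor every residue so log-odds stay finite for any input sequence
    freq = 0.99 * freq + 0.01 / len(ALPHABET)
    return freq / freq.sum()


def _one_hot(aa: str) -> np.ndarray:
    v = np.zeros(len(ALPHABET))
    v[AA_INDEX[aa]] = 1.0
    return v


def default_model(threshold_sigma: float = 4.0) -> ConsensusModel:
    """Build the package's default bHLH consensus model.

    The score threshold is set analytically at ``mean - threshold_sigma * sd``
    of the window score distribution for sequences sampled from the profile
    itself, so that profile-conforming domains are retained with high
    probability while random background windows (whose expected score is
    strongly negative) never reach it.
    """
    profile = np.vstack([_position_distribution(p) for p in range(DOMAIN_LENGTH)])
    background = np.full(len(ALPHABET), 1.0 / len(ALPHABET))
    log_odds = np.log(profile / background[None, :])
    mean = float((profile * log_odds).sum())
    ex2 = float((profile * log_odds**2).sum(axis=1).sum())
    per_pos_mean = (profile * log_odds).sum(axis=1)
    var = float(((profile * log_odds**2).sum(axis=1) - per_pos_mean**2).sum())
    threshold = mean - threshold_sigma * np.sqrt(var)
    if threshold <= 0:
        raise ValueError("degenerate profile: threshold not positive")
    return ConsensusModel(profile=profile, background=background, threshold=threshold)
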