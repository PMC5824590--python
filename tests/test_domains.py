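"""Domain scanning and DNA-binding classification."""

import numpy as np
import pytest

import bhlhfam as bf
from bhlhfam.consensus import ALPHABET, CONSENSUS, KEY_POSITIONS
from bhlhfam.domains import BHLHDomain, best_hit

from helpers import window_scores_oracle


def _domain_with(basic_region: str, rest: str | None = None) -> BHLHDomain:
    rest = rest or "L" * 44
    return BHLHDomain("p", 0, 61, basic_region + rest, 50.0)


class TestScan:
    def test_homopolymer_has_no_motif(self, model):
        assert bf.scan_for_bhlh("A" * 200, model) == []

    def test_empty_sequence_yields_empty_list(self, model):
        assert bf.scan_for_bhlh("", model) == []

    def test_illegal_residue_is_named(self, model):
        with pytest.raises(ValueError, match="B"):
            bf.scan_for_bhlh("ACDB" + "A" * 100, model)

    def test_x_is_tolerated(self, model):
        assert bf.scan_for_bhlh("AXA" * 40, model) == []

    def test_embedded_consensus_found_at_offset_with_max_score(self, model):
        rng = np.random.default_rng(7)
        bg = "".join(rng.choice(list(ALPHABET), size=239))
        protein = bg[:100] + CONSENSUS + bg[100:]
        hits = bf.scan_for_bhlh(protein, model)
        assert [h.start for h in hits] == [100]
        assert hits[0].score == pytest.approx(model.max_score())
        assert hits[0].aligned == CONSENSUS

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_scanner_matches_exhaustive_window_scoring(self, model, seed):
        """Vectorised scan equals a per-window Python scorer on short input."""
        rng = np.random.default_rng(seed)
        bg = "".join(rng.choice(list(ALPHABET), size=300 - 61))
        protein = bg[:90] + CONSENSUS + bg[90:]
        oracle = window_scores_oracle(protein, model)
        hits = bf.scan_for_bhlh(protein, model)
        assert hits, "planted consensus must be detected"
        top = max(hits, key=lambda h: h.score)
        assert top.start == int(np.argmax(oracle))
        for h in hits:
            assert h.score == pytest.approx(oracle[h.start], abs=1e-9)
            assert h.score >= model.threshold

    def test_synthetic_planted_domain_recovered(self, model, small_family):
        genes = small_family.genes
        row = genes.iloc[0]
        hit = best_hit(row.name, row.protein, model)
        assert hit is not None
        assert hit.start == row.domain_start
        assert hit.aligned == row.protein[row.domain_start:row.domain_start + 61]


class TestBasicResidues:
    @pytest.mark.parametrize(
        "region, expected",
        [
            ("A" * 17, 0),
            ("KRKRKRKRKRKRKRKRK", 17),
            ("MKRAHEQRNRSTAAKLE", 6),  # K,R,H,R,R,K counted by hand
            ("K-GA-EQGNRSTAAKLE", 3),  # K, R, K; gaps tolerated, not counted
        ],
    )
    def test_counts(self, region, expected):
        assert bf.count_basic_residues(region) == expected

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            bf.count_basic_residues("KKK")

    @pytest.mark.parametrize(
        "calls, expected",
        [([5], 5.0), ([4, 6], 5.0), ([5, 6, 7], 6.0)],
    )
    def test_mean_basic(self, calls, expected):
        made = [bf.BindingCall("G-box", c, False) for c in calls]
        assert bf.mean_basic_residues(made) == expected

    def test_mean_basic_empty_rejected(self):
        with pytest.raises(ValueError):
            bf.mean_basic_residues([])


def _rule_oracle(region: str) -> str:
    """Independent statement of the category decision rules."""
    n_basic = sum(1 for a in region if a in "KRH")
    if n_basic < 5:
        return "non-DNA"
    ebox = region[8] == "E" and region[11] == "R"
    gbox = ebox and region[4] == "H" and region[12] == "R"
    if gbox:
        return "G-box"
    if ebox:
        return "E-box-non-G-box"
    return "non-E-box"


class TestClassification:
    def test_all_gly_region_is_non_dna(self):
        call = bf.classify_binding(_domain_with("G" * 17))
        assert call.category == "non-DNA"
        assert call.basic_residue_count == 0

    def test_gbox_from_key_residues(self):
        # K/R count 6 with His5, Glu9, Arg12, Arg13, Arg16
        region = "AKKA" + "H" + "AAA" + "E" + "AA" + "RR" + "AA" + "R" + "A"
        assert len(region) == 17
        call = bf.classify_binding(_domain_with(region))
        assert call.category == "G-box"
        assert not call.srebp_like

    def test_ebox_non_gbox_when_his5_absent(self):
        region = "AKKK" + "A" + "AAA" + "E" + "AA" + "RR" + "AA" + "R" + "A"
        call = bf.classify_binding(_domain_with(region))
        assert call.category == "E-box-non-G-box"

    def test_srebp_flag_requires_ebox_without_arg16(self):
        region = "AKKA" + "H" + "AAA" + "E" + "AA" + "RRK" + "A" + "Q" + "A"
        call = bf.classify_binding(_domain_with(region))
        assert call.srebp_like
        assert call.category == "G-box"

    def test_truth_table_over_key_positions(self):
        """All 32 on/off combinations of the five key residues agree with an
        independently written rule oracle."""
        for mask in range(32):
            keys = {
                5: "H" if mask & 1 else "A",
                9: "E" if mask & 2 else "A",
                12: "R" if mask & 4 else "A",
                13: "R" if mask & 8 else "A",
                16: "R" if mask & 16 else "A",
            }
            region = list("KKKAAAKAAKAAAAAAA")  # 6 basics at non-key slots
            for pos, aa in keys.items():
                region[pos - 1] = aa
            region = "".join(region)
            call = bf.classify_binding(_domain_with(region))
            assert call.category == _rule_oracle(region), region

    def test_category_partition(self, small_family, model):
        """Every protein gets exactly one category; counts sum to the total."""
        from bhlhfam.domains import classify_binding
        cats = []
        for _, row in small_family.genes.iterrows():
            hit = best_hit(row.name, row.protein, model)
            cats.append(classify_binding(hit).category)
        from collections import Counter

        from bhlhfam.domains import CATEGORIES

        counts = Counter(cats)
        assert sum(counts.values()) == len(small_family.genes)
        assert set(counts) <= set(CATEGORIES)
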