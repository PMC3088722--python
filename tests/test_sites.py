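"""Seed extraction, pattern compilation, scanning and target annotation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mirshift.io import MiRNARecord, UTRRecord
from mirshift.sites import (
    SITE_TYPES,
    FamilyRule,
    build_target_annotations,
    compile_patterns,
    extract_seed,
    reverse_complement,
    scan_utr,
    select_conserved,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def naive_scan(sequence, patterns):
    """Independent all-offsets oracle with the same priority/advance rules."""
    ordered = sorted(patterns, key=lambda p: SITE_TYPES.index(p.site_type))
    out = []
    i = 0
    while i < len(sequence):
        hit = None
        for pat in ordered:
            if sequence.startswith(pat.match_string, i):
                hit = pat
                break
        if hit is None:
            i += 1
            continue
        out.append((i, i + len(hit.match_string), hit.site_type))
        i += 6 + (1 if hit.site_type in ("8mer", "7mer-m8") else 0)
    return out


def random_mirna(rng):
    return MiRNARecord(f"m", "".join(rng.choice(list("ACGU"), size=22)))


class TestExtractSeed:
    @pytest.mark.parametrize(
        "sequence,seed",
        [
            ("UAAGUGCUUCCAUGUU", "AAGUGC"),
            ("AAAAGUGCUUAC", "AAAGUG"),
            ("ACGUACGU", "CGUACG"),
        ],
    )
    def test_positions_2_to_7(self, sequence, seed):
        assert extract_seed(sequence) == seed

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            extract_seed("ACGUACG")


class TestCompilePatterns:
    def test_without_position8_only_a1_and_6mer(self):
        pats = {p.site_type: p.match_string for p in compile_patterns("AAGUGC")}
        assert pats == {"6mer": "GCACTT", "7mer-A1": "GCACTTA"}

    def test_with_position8_all_four(self):
        pats = {p.site_type: p.match_string
                for p in compile_patterns("AAGUGC", "U")}
        assert pats == {
            "6mer": "GCACTT",
            "7mer-A1": "GCACTTA",
            "7mer-m8": "AGCACTT",
            "8mer": "AGCACTTA",
        }

    def test_homopolymer_seed(self):
        pats = {p.site_type: p.match_string for p in compile_patterns("AAAAAA")}
        assert pats["6mer"] == "TTTTTT"

    @given(dna)
    def test_reverse_complement_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestScanUtr:
    PATTERNS = compile_patterns("AAGUGC", "U")

    def test_exact_core_yields_one_6mer(self):
        sites = scan_utr(UTRRecord("g", "GCACTT"), self.PATTERNS, "AAGUGC")
        assert [(s.start, s.end, s.site_type) for s in sites] == [(0, 6, "6mer")]

    def test_8mer_not_also_counted_as_lower_types(self):
        sites = scan_utr(UTRRecord("g", "AGCACTTA"), self.PATTERNS, "AAGUGC")
        assert [(s.start, s.end, s.site_type) for s in sites] == [(0, 8, "8mer")]

    def test_a1_site_beats_6mer_at_same_offset(self):
        sites = scan_utr(UTRRecord("g", "GCACTTAG"), self.PATTERNS, "AAGUGC")
        assert [(s.start, s.end, s.site_type) for s in sites] == [(0, 7, "7mer-A1")]

    def test_adjacent_cores_both_counted(self):
        sites = scan_utr(UTRRecord("g", "GCACTTGCACTTG"), self.PATTERNS, "AAGUGC")
        assert [(s.start, s.site_type) for s in sites] == [(0, "6mer"), (6, "6mer")]

    def test_emitted_substring_equals_pattern(self):
        rng = np.random.default_rng(7)
        by_type = {p.site_type: p.match_string for p in self.PATTERNS}
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            for site in scan_utr(UTRRecord("g", seq), self.PATTERNS, "AAGUGC"):
                assert seq[site.start:site.end] == by_type[site.site_type]

    def test_matches_naive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            mirna = random_mirna(rng)
            patterns = compile_patterns(mirna.seed, mirna.position8)
            seq = "".join(rng.choice(list("ACGT"), size=200))
            got = [(s.start, s.end, s.site_type)
                   for s in scan_utr(UTRRecord("g", seq), patterns)]
            assert got == naive_scan(seq, patterns)


class TestTargetAnnotations:
    MIRNA = MiRNARecord("miR-295-3p", "AAAGUGCUACUACUUUUGAGUCU")

    def test_single_6mer_makes_target(self):
        ann = build_target_annotations([UTRRecord("g1", "CCCGCACTTCAA")],
                                       [self.MIRNA])
        assert bool(ann.loc["g1", "is_target"])
        assert ann.loc["g1", "n_6mer"] == 1

    def test_exclude_family_drops_all_sites(self):
        utrs = [UTRRecord("g1", "AAAGCACTTCAA")]
        rule = FamilyRule("miR-295-3p", "exclude_family")
        ann = build_target_annotations(utrs, [self.MIRNA], [rule])
        assert not bool(ann.loc["g1", "is_target"])

    def test_exclude_site_types_drops_only_those_types(self):
        # g1 has only a 7mer-A1; g2 has an 8mer (which survives)
        utrs = [UTRRecord("g1", "CCGCACTTACC"), UTRRecord("g2", "CCAGCACTTACC")]
        rule = FamilyRule("miR-295-3p", "exclude_site_types",
                          frozenset({"7mer-A1"}))
        ann = build_target_annotations(utrs, [self.MIRNA], [rule])
        assert not bool(ann.loc["g1", "is_target"])
        assert bool(ann.loc["g2", "is_target"])

    def test_excluded_type_not_reclassified_to_lower_type(self):
        # the excluded 7mer-A1 contains a 6mer core but must not resurface as one
        utrs = [UTRRecord("g1", "CCGCACTTACC")]
        rule = FamilyRule("miR-295-3p", "exclude_site_types",
                          frozenset({"7mer-A1"}))
        ann = build_target_annotations(utrs, [self.MIRNA], [rule])
        assert ann.loc["g1", "n_sites"] == 0

    def test_shared_family_sites_counted_once(self):
        sibling = MiRNARecord("miR-294-3p", "AAAGUGCUUCCCUUUUGUGUGU")
        utrs = [UTRRecord("g1", "CCAGCACTTACC")]
        ann = build_target_annotations(utrs, [self.MIRNA, sibling])
        assert ann.loc["g1", "n_sites"] == 1

    def test_unknown_rule_warns(self):
        with pytest.warns(UserWarning, match="no miRNA"):
            build_target_annotations([UTRRecord("g1", "ACGTACGT")],
                                     [self.MIRNA],
                                     [FamilyRule("miR-999", "exclude_family")])


class TestSelectConserved:
    def _ann(self, scores, targets=None):
        import pandas as pd

        genes = [f"g{i}" for i in range(len(scores))]
        targets = [True] * len(scores) if targets is None else targets
        return pd.DataFrame(
            {"is_target": targets, "n_sites": [int(t) for t in targets],
             "conservation_score": scores},
            index=pd.Index(genes, name="gene_id"),
        )

    def test_top_decile_of_ten(self):
        ann = self._ann(list(range(1, 11)))
        assert select_conserved(ann, 0.1) == {"g9"}

    def test_fraction_one_returns_all_scored_targets(self):
        ann = self._ann(list(range(1, 11)))
        assert select_conserved(ann, 1.0) == {f"g{i}" for i in range(10)}

    def test_ceiling_rule_on_seven_targets(self):
        ann = self._ann([1, 2, 3, 4, 5, 6, 7])
        assert len(select_conserved(ann, 0.1)) == 1

    def test_ties_broken_lexicographically(self):
        ann = self._ann([5.0, 5.0, 5.0, 1.0])
        assert select_conserved(ann, 0.25) == {"g0"}

    def test_unscored_targets_excluded_and_subset_of_targets(self):
        ann = self._ann([1.0, float("nan"), 3.0, 2.0],
                        targets=[True, True, True, False])
        out = select_conserved(ann, 1.0)
        assert out == {"g0", "g2"}
        assert out <= set(ann.index[ann["is_target"]])

    def test_no_scored_targets_is_error(self):
        ann = self._ann([float("nan")])
        with pytest.raises(ValueError):
            select_conserved(ann, 0.5)
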