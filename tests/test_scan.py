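"""Repeat-profile construction, sliding-window scanning and family
classification."""

import numpy as np
import pytest

from mybfam.profiles import (
    AMINO_ACIDS,
    R2_CONSENSUS,
    R3_CONSENSUS,
    build_profile,
    landmark_rules_for_span,
    sample_background_sequence,
)
from mybfam.scan import (
    ProteinRecord,
    classify_protein,
    classify_repeat_kind,
    extract_domain,
    global_identity,
    scan_protein,
    scan_repeats,
)


def brute_force_scan(protein, profile):
    """Independent oracle: score every window by plain iteration, apply
    threshold + landmark rules, then the same greedy overlap resolution."""
    seq = protein.seq
    candidates = []
    for offset in range(len(seq) - profile.length + 1):
        window = seq[offset: offset + profile.length]
        score = 0.0
        for i, ch in enumerate(window):
            if ch in AMINO_ACIDS:
                score += profile.log_odds[i, AMINO_ACIDS.index(ch)]
        if score < profile.threshold:
            continue
        if not all(
            window[pos - 1] in allowed
            for pos, allowed in profile.landmark_rules.items()
        ):
            continue
        candidates.append((offset + 1, offset + profile.length, score))
    chosen = []
    for start, end, score in sorted(candidates, key=lambda c: (-c[2], c[0])):
        if all(end < s or start > e for s, e, _ in chosen):
            chosen.append((start, end, score))
    return sorted(chosen)


class TestBuildProfile:
    def test_identical_seed_gives_consensus_with_maximal_scores(self):
        prof = build_profile([R2_CONSENSUS] * 5, pseudocount=0.5)
        assert prof.consensus == R2_CONSENSUS
        for i, ch in enumerate(R2_CONSENSUS):
            assert prof.log_odds[i].argmax() == AMINO_ACIDS.index(ch)

    def test_single_difference_scores_equally_before_pseudocounts(self):
        a = R2_CONSENSUS
        b = R2_CONSENSUS[:10] + "Q" + R2_CONSENSUS[11:]
        prof = build_profile([a, b], pseudocount=1.0)
        s_orig = prof.log_odds[10, AMINO_ACIDS.index(a[10])]
        s_alt = prof.log_odds[10, AMINO_ACIDS.index("Q")]
        # equal raw counts -> scores differ only through the background term
        bg_orig = prof.background[AMINO_ACIDS.index(a[10])]
        bg_alt = prof.background[AMINO_ACIDS.index("Q")]
        expected_gap = np.log(1 + bg_orig) - np.log(bg_orig) - (
            np.log(1 + bg_alt) - np.log(bg_alt)
        )
        assert s_orig - s_alt == pytest.approx(expected_gap)

    def test_background_expected_score_nonpositive_per_position(self, profile_r2):
        expected = (profile_r2.log_odds * profile_r2.background).sum(axis=1)
        assert (expected <= 1e-12).all()

    def test_ragged_or_empty_seed_rejected(self):
        with pytest.raises(ValueError):
            build_profile(["AAA", "AA"])
        with pytest.raises(ValueError):
            build_profile([])
        with pytest.raises(ValueError):
            build_profile(["AAAA"])  # single sequence


class TestScanProtein:
    def test_exact_consensus_pair_yields_two_hits_at_planted_offsets(
        self, profile_r2, profile_r3
    ):
        flank = "AGSTNQ" * 5
        protein = ProteinRecord("p", flank + R2_CONSENSUS + R3_CONSENSUS + flank)
        hits = scan_repeats(protein, profile_r2, profile_r3)
        assert [(h.start, h.end) for h in hits] == [
            (31, 83),
            (84, 134),
        ]
        assert [h.repeat_kind for h in hits] == ["R2", "R3"]

    def test_background_decoy_has_no_hits(self, profile_r2, profile_r3):
        rng = np.random.default_rng(42)
        for _ in range(20):
            seq = sample_background_sequence(rng, 300, profile_r2.background)
            protein = ProteinRecord("decoy", seq)
            assert scan_repeats(protein, profile_r2, profile_r3) == []

    def test_w98c_substitution_still_detected_and_recorded(self, profile_r3):
        # canonical 98 is window position 45 of the R3 repeat
        mutated = R3_CONSENSUS[:44] + "C" + R3_CONSENSUS[45:]
        protein = ProteinRecord("p", "GSTA" * 5 + mutated + "GSTA" * 5)
        hits = scan_protein(protein, profile_r3)
        assert len(hits) == 1
        residue, used_substitution = hits[0].landmark_evidence[98]
        assert residue == "C" and used_substitution

    def test_shorter_than_profile_returns_empty(self, profile_r2):
        assert scan_protein(ProteinRecord("p", "MKV"), profile_r2) == []

    def test_matches_brute_force_oracle(self, profile_r2, profile_r3):
        from mybfam.synthetic import generate_proteome

        proteins, _ = generate_proteome(
            n_r2r3=10, n_myb3r=2, n_decoy=10, sub_rate=0.1, seed=3
        )
        for protein in proteins:
            for prof in (profile_r2, profile_r3):
                got = [(h.start, h.end, h.score) for h in scan_protein(protein, prof)]
                expected = brute_force_scan(protein, prof)
                assert [(s, e) for s, e, _ in got] == [(s, e) for s, e, _ in expected]
                for (_, _, g), (_, _, x) in zip(got, expected):
                    assert g == pytest.approx(x)

    def test_raising_threshold_never_adds_hits(self, profile_r2):
        from dataclasses import replace

        protein = ProteinRecord("p", "AGST" * 8 + R2_CONSENSUS + "AGST" * 8)
        prev = None
        base = profile_r2.threshold
        for bump in (0.0, 10.0, 50.0, 100.0, 200.0):
            prof = replace(profile_r2, threshold=base + bump)
            hits = {(h.start, h.end) for h in scan_protein(protein, prof)}
            if prev is not None:
                assert hits <= prev
            prev = hits


class TestClassify:
    def test_consensus_windows_classify_as_their_kind(self, profile_r2, profile_r3):
        protein = ProteinRecord("p", R2_CONSENSUS + R3_CONSENSUS)
        hits = scan_repeats(protein, profile_r2, profile_r3)
        assert [h.repeat_kind for h in hits] == ["R2", "R3"]

    def test_chimeric_window_is_unclassified_within_tolerance(
        self, profile_r2, profile_r3
    ):
        # alternate per-position picks between the two consensus repeats
        chimera = "".join(
            R2_CONSENSUS[i] if i % 2 else R3_CONSENSUS[i]
            for i in range(len(R3_CONSENSUS))
        )
        protein = ProteinRecord("p", chimera + "A" * 10)
        # direct summation under both profiles bounds the margin
        m2 = profile_r2.score_window(chimera) / profile_r2.length
        m3 = profile_r3.score_window(chimera[: profile_r3.length]) / profile_r3.length
        margin = abs(m2 - m3)
        from mybfam.scan import RepeatHit

        hit = RepeatHit("p", 1, len(chimera), 0.0)
        assert (
            classify_repeat_kind(hit, protein, profile_r2, profile_r3,
                                 tie_tolerance=margin + 0.01)
            == "unclassified"
        )

    @pytest.mark.parametrize(
        "n_hits,expected",
        [(0, "non-MYB"), (1, "single-repeat"), (2, "R2R3"), (3, "MYB3R"), (4, "MYB4R")],
    )
    def test_family_class_follows_repeat_count(self, n_hits, expected):
        from mybfam.scan import RepeatHit

        hits = [
            RepeatHit("p", 1 + 60 * i, 53 + 60 * i, 50.0, "R2") for i in range(n_hits)
        ]
        protein = ProteinRecord("p", "A" * 400)
        c = classify_protein(hits, protein)
        assert c.family_class == expected
        assert c.is_family_member == (n_hits >= 2)

    def test_classification_is_pure(self, profile_r2, profile_r3):
        protein = ProteinRecord("p", R2_CONSENSUS + R3_CONSENSUS)
        hits = scan_repeats(protein, profile_r2, profile_r3)
        a = classify_protein(hits, protein)
        b = classify_protein(hits, protein)
        assert a == b

    def test_cdc5_similarity_overrides_count_class(self, profile_r2, profile_r3):
        from mybfam import datasets

        landmark = datasets.load_cdc5_landmark()
        # a close homolog of the landmark: every 25th residue mutated
        seq = list(landmark.seq)
        for i in range(0, len(seq), 25):
            seq[i] = "A" if seq[i] != "A" else "G"
        query = ProteinRecord("q", "".join(seq))
        hits = scan_repeats(query, profile_r2, profile_r3)
        assert len(hits) >= 2
        c = classify_protein(hits, query, cdc5_landmark=landmark)
        assert c.family_class == "CDC5-like"
        # an unrelated two-repeat protein keeps its count class
        other = ProteinRecord("r", "AGST" * 10 + R2_CONSENSUS + R3_CONSENSUS)
        c2 = classify_protein(
            scan_repeats(other, profile_r2, profile_r3), other, cdc5_landmark=landmark
        )
        assert c2.family_class == "R2R3"

    def test_three_repeat_protein_relabels_first_repeat_r1_like(
        self, profile_r2, profile_r3
    ):
        protein = ProteinRecord("p", R2_CONSENSUS + R2_CONSENSUS + R3_CONSENSUS)
        hits = scan_repeats(protein, profile_r2, profile_r3)
        assert [h.repeat_kind for h in hits] == ["R1-like", "R2", "R3"]

    def test_global_identity_of_identical_sequences(self):
        assert global_identity("MKVLAG", "MKVLAG") == 1.0


class TestExtractDomain:
    def test_canonical_positions_read_the_planted_residues(
        self, profile_r2, profile_r3
    ):
        offset = 17
        protein = ProteinRecord(
            "p", "G" * offset + R2_CONSENSUS + R3_CONSENSUS + "G" * 9
        )
        hits = scan_repeats(protein, profile_r2, profile_r3)
        c = classify_protein(hits, protein)
        domain = extract_domain(c, protein)
        assert domain.residue_at(11) == "D"
        assert domain.residue_at(43) == "C"
        assert domain.residue_at(46) == "R"
        assert domain.residue_at(98) == "W"
        assert domain.mapping[1] == offset + 1
        assert len(domain.sequence) == 104

    def test_non_r2r3_input_rejected(self, profile_r2, profile_r3):
        protein = ProteinRecord("p", R2_CONSENSUS + "A" * 40)
        c = classify_protein(scan_repeats(protein, profile_r2, profile_r3), protein)
        with pytest.raises(ValueError):
            extract_domain(c, protein)
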