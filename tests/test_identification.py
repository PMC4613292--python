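import numpy as np
import pytest

from barcodegap.distance import pairwise_matrix
from barcodegap.identification import (
    IdentificationError,
    ScoringScheme,
    evaluate_loo,
    identify_best_hit,
    identify_nearest,
    local_alignment_score,
    write_outcomes_tsv,
)
from barcodegap.seqio import LabeledAlignment, LabeledRecord
from barcodegap.simulate import GenusSimConfig, simulate_genus

from conftest import make_dm

NEG = float("-inf")


def gotoh_local_score(a, b, match, mismatch, gap_open, gap_extend):
    """Independent O(n*m) affine-gap Smith-Waterman oracle.

    ``gap_open`` is the score of the first gapped position, ``gap_extend``
    of each subsequent one.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestLocalAlignmentScore:
    def test_identical_sequences(self):
        s = local_alignment_score("ACGTACGTAC", "ACGTACGTAC",
                                  ScoringScheme(match=1, mismatch=-1))
        assert s == 10.0

    def test_disjoint_alphabets_empty_alignment(self):
        s = local_alignment_score("AAAA", "GGGG", ScoringScheme(match=1, mismatch=-1))
        assert s == 0.0

    def test_empty_sequence_error(self):
        with pytest.raises(IdentificationError):
            local_alignment_score("", "ACGT")

    @pytest.mark.parametrize("a,b", [
        ("ACGTACGT", "ACGACGT"),
        ("ACGTACGTACGT", "TACGGGT"),
        ("AAAATTTT", "AAATTT"),
        ("GATTACA", "GCATGCT"),
    ])
    def test_matches_brute_force_dp_oracle(self, a, b):
        scheme = ScoringScheme(match=1, mismatch=-1, gap_open=-2, gap_extend=-1)
        expected = gotoh_local_score(a, b, 1, -1, -2, -1)
        assert local_alignment_score(a, b, scheme) == expected

    def test_random_sequences_match_oracle(self):
        rng = np.random.default_rng(9)
        scheme = ScoringScheme()  # BLASTN-style 2/-3/-5/-2
        for _ in range(15):
            a = "".join(rng.choice(list("ACGT"), rng.integers(5, 40)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(5, 40)))
            expected = gotoh_local_score(a, b, 2, -3, -5, -2)
            assert local_alignment_score(a, b, scheme) == expected

    def test_ambiguous_residues_neutral(self):
        scheme = ScoringScheme(match=1, mismatch=-1, ambiguous_score=0)
        # N contributes 0 wherever it lands
        assert local_alignment_score("ANA", "AAA", scheme) == 2.0


class TestIdentifyNearest:
    def test_unique_nearest_correct(self):
        dm = make_dm(["q", "a1", "b1"],
                     [[0, 0.01, 0.05], [0.01, 0, 0.06], [0.05, 0.06, 0]])
        labels = {"q": "A", "a1": "A", "b1": "B"}
        out = identify_nearest("q", dm, labels)
        assert out.verdict == "correct"
        assert out.predicted_species == {"A"}
        assert out.criterion_value == pytest.approx(0.01)

    def test_tied_min_distance_ambiguous(self):
        dm = make_dm(["q", "a1", "b1"],
                     [[0, 0.02, 0.02], [0.02, 0, 0.06], [0.02, 0.06, 0]])
        labels = {"q": "A", "a1": "A", "b1": "B"}
        out = identify_nearest("q", dm, labels)
        assert out.verdict == "ambiguous"
        assert out.predicted_species == {"A", "B"}

    def test_nearest_heterospecific_incorrect(self):
        dm = make_dm(["q", "a1", "b1"],
                     [[0, 0.05, 0.01], [0.05, 0, 0.06], [0.01, 0.06, 0]])
        out = identify_nearest("q", dm, {"q": "A", "a1": "A", "b1": "B"})
        assert out.verdict == "incorrect"

    def test_empty_reference_unidentifiable(self):
        dm = make_dm(["q", "x"], [[0, 0.1], [0.1, 0]])
        out = identify_nearest("q", dm, {"q": "A", "x": "B"}, exclude=["x"])
        assert out.verdict == "unidentifiable"

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        n = 8
        vals = rng.uniform(0.01, 0.4, (n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        ids = [f"s{i}" for i in range(n)]
        labels = {f"s{i}": f"sp{i % 3}" for i in range(n)}
        dm1 = make_dm(ids, vals)
        dm2 = make_dm(ids, np.sqrt(vals))  # strictly monotone
        for q in ids:
            o1 = identify_nearest(q, dm1, labels)
            o2 = identify_nearest(q, dm2, labels)
            assert o1.predicted_species == o2.predicted_species
            assert o1.verdict == o2.verdict


class TestIdentifyBestHit:
    def _aln(self):
        return LabeledAlignment([
            LabeledRecord("q", "A", "ACGTACGTACGTACGT"),
            LabeledRecord("a1", "A", "ACGTACGTACGTACGT"),
            LabeledRecord("b1", "B", "TTTTCCCCGGGGAAAA"),
        ])

    def test_identical_reference_correct(self):
        aln = self._aln()
        out = identify_best_hit("q", aln, aln.labels)
        assert out.verdict == "correct"

    def test_tied_scores_ambiguous(self):
        aln = LabeledAlignment([
            LabeledRecord("q", "A", "ACGTACGT"),
            LabeledRecord("a1", "A", "ACGTACGT"),
            LabeledRecord("b1", "B", "ACGTACGT"),
        ])
        out = identify_best_hit("q", aln, aln.labels)
        assert out.verdict == "ambiguous"
        assert out.predicted_species == {"A", "B"}

    def test_concordant_with_nearest_on_separated_data(self, small_genus):
        aln, _, _ = small_genus
        sub = aln.subset([r.id for r in aln.records if r.id.endswith("_1")])
        dm = pairwise_matrix(sub)
        for q in sub.ids[:4]:
            near = identify_nearest(q, dm, sub.labels)
            best = identify_best_hit(q, sub, sub.labels)
            assert near.verdict == best.verdict


class TestEvaluateLoo:
    def test_well_separated_all_correct(self):
        aln = LabeledAlignment([
            LabeledRecord("a1", "A", "A" * 20),
            LabeledRecord("a2", "A", "A" * 19 + "G"),
            LabeledRecord("b1", "B", "GGGG" + "A" * 16),
            LabeledRecord("b2", "B", "GGG" + "A" * 17),
        ], aligned=True)
        dm = pairwise_matrix(aln)
        for method in ("nearest", "best_hit"):
            rates, _ = evaluate_loo(aln, dm, aln.labels, method)
            assert rates.pct_correct == 100.0
            assert rates.pct_incorrect == 0.0

    def test_shared_haplotype_species_ambiguous_never_incorrect(self):
        # two species whose samples are all one identical haplotype:
        # every query ties between both species -> ambiguous
        aln = LabeledAlignment([
            LabeledRecord("a1", "A", "AAAAAAAAAA"),
            LabeledRecord("a2", "A", "AAAAAAAAAA"),
            LabeledRecord("b1", "B", "AAAAAAAAAA"),
            LabeledRecord("b2", "B", "AAAAAAAAAA"),
            LabeledRecord("c1", "C", "GGGAAAAAAA"),
            LabeledRecord("c2", "C", "GGGAAAAAAA"),
        ], aligned=True)
        dm = pairwise_matrix(aln)
        for method in ("nearest", "best_hit"):
            rates, outcomes = evaluate_loo(aln, dm, aln.labels, method)
            by_q = {o.query_id: o for o in outcomes}
            for q in ("a1", "a2", "b1", "b2"):
                assert by_q[q].verdict == "ambiguous"
            assert by_q["c1"].verdict == "correct"
            assert rates.pct_incorrect == 0.0

    def test_percentages_sum_to_100(self, small_genus):
        aln, _, _ = small_genus
        dm = pairwise_matrix(aln)
        rates, outcomes = evaluate_loo(aln, dm, aln.labels, "nearest")
        assert rates.pct_correct + rates.pct_ambiguous + rates.pct_incorrect \
            == pytest.approx(100.0)
        assert rates.n_samples == len(outcomes) == len(aln)

    def test_positive_gap_theorem(self, small_genus):
        """No incorrect verdict is possible when every species' minimum
        heterospecific distance exceeds its maximum conspecific distance
        and every species has >= 2 samples."""
        aln, _, _ = small_genus
        dm = pairwise_matrix(aln)
        from barcodegap.divergence import per_species_stats

        stats = per_species_stats(dm, aln.labels)
        assert all(s["hetero_min"] > s["intra_max"] for s in stats.values())
        for method in ("nearest", "best_hit"):
            rates, _ = evaluate_loo(aln, dm, aln.labels, method)
            assert rates.pct_incorrect == 0.0
            assert rates.pct_correct == 100.0

    def test_unknown_method_error(self, small_genus):
        aln, _, _ = small_genus
        with pytest.raises(IdentificationError, match="unknown method"):
            evaluate_loo(aln, None, aln.labels, "blast")

    def test_outcomes_tsv_flags_singletons(self, tmp_path):
        aln = LabeledAlignment([
            LabeledRecord("a1", "A", "AAAAAAAAAA"),
            LabeledRecord("a2", "A", "AAAAAAAAAG"),
            LabeledRecord("b1", "B", "GGGAAAAAAA"),
        ], aligned=True)
        dm = pairwise_matrix(aln)
        _, outcomes = evaluate_loo(aln, dm, aln.labels, "nearest")
        write_outcomes_tsv(outcomes, aln.labels, tmp_path / "o.tsv")
        lines = (tmp_path / "o.tsv").read_text().splitlines()
        assert lines[0].split("\t")[-1] == "singleton_species"
        b1 = [l for l in lines if l.startswith("b1")][0]
        assert b1.split("\t")[-1] == "yes"


def test_planted_pairs_drive_ambiguity(planted_genus):
    aln, truth, cfg = planted_genus
    dm = pairwise_matrix(aln)
    affected = {sp for pair in truth.planted_pairs for sp in pair}
    for method in ("nearest", "best_hit"):
        _, outcomes = evaluate_loo(aln, dm, aln.labels, method)
        for o in outcomes:
            if o.true_species in affected:
                assert o.verdict == "ambiguous"
            else:
                assert o.verdict == "correct"
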