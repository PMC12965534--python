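"""Perturbation operations, cosine shifts, significance and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rankshift import (
    GeneVocabulary,
    compute_goal_state,
    delete_gene,
    expressed_in_both_conditions,
    overexpress_gene,
    perturb_corpus,
    rank_candidates,
    shift_to_goal,
)
from rankshift.encoding import RankEncoding
from rankshift.perturb import SKIP, GoalState, PerturbationRecord, bh_adjust
from rankshift.simulate import DISEASE


def _enc(tokens, L=8):
    return RankEncoding(cell_id="c", tokens=tuple(tokens), context_length=L)


# token map: A=2, B=3, C=4, D=5 (fixture abc_vocabulary)


class TestDelete:
    def test_removal_preserves_order(self, abc_vocabulary):
        out = delete_gene(_enc([3, 2, 4]), "A", abc_vocabulary)
        assert out.tokens == (3, 4)

    def test_absent_gene_is_skip_not_error(self, abc_vocabulary):
        assert delete_gene(_enc([3, 2, 4]), "D", abc_vocabulary) is SKIP

    def test_unknown_gene_is_error(self, abc_vocabulary):
        with pytest.raises(ValueError, match="vocabulary"):
            delete_gene(_enc([3, 2, 4]), "Z", abc_vocabulary)


class TestOverexpress:
    def test_move_to_front(self, abc_vocabulary):
        assert overexpress_gene(_enc([3, 2, 4]), "C", abc_vocabulary).tokens == (4, 3, 2)

    def test_insert_then_truncate(self, abc_vocabulary):
        out = overexpress_gene(_enc([3, 2], L=2), "D", abc_vocabulary)
        assert out.tokens == (5, 3)

    def test_already_at_front_unchanged(self, abc_vocabulary):
        assert overexpress_gene(_enc([3, 2, 4]), "B", abc_vocabulary).tokens == (3, 2, 4)


@st.composite
def random_encoding(draw):
    L = draw(st.integers(2, 12))
    n = draw(st.integers(1, L))
    tokens = draw(
        st.lists(st.integers(2, 30), min_size=n, max_size=n, unique=True)
    )
    return RankEncoding(cell_id="r", tokens=tuple(tokens), context_length=L)


_WIDE_VOCAB = GeneVocabulary([f"g{i:02d}" for i in range(29)], np.ones(29))


@given(random_encoding(), st.integers(0, 28))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_perturbations_never_duplicate_or_overflow(encoding, gene_idx):
    gene = _WIDE_VOCAB.gene_ids[gene_idx]
    token = _WIDE_VOCAB.token_of[gene]
    deleted = delete_gene(encoding, gene, _WIDE_VOCAB)
    if deleted is not SKIP:
        # inverse operation: re-insert at the recorded original index
        pos = encoding.tokens.index(token)
        restored = deleted.tokens[:pos] + (token,) + deleted.tokens[pos:]
        assert restored == encoding.tokens
        assert len(deleted) == len(encoding) - 1
    over = overexpress_gene(encoding, gene, _WIDE_VOCAB)
    assert over.tokens[0] == token
    assert len(set(over.tokens)) == len(over.tokens)
    assert len(over) <= encoding.context_length
    # relative order of untouched tokens preserved
    others = [t for t in encoding.tokens if t != token]
    kept = [t for t in over.tokens if t != token]
    assert kept == others[: len(kept)]


class TestGoalState:
    def test_single_cell_centroid_is_embedding(self):
        goal = compute_goal_state(np.array([[1.0, 2.0, 3.0]]), DISEASE)
        np.testing.assert_array_equal(goal.centroid, [1.0, 2.0, 3.0])
        assert goal.n_cells == 1

    def test_mean_of_two_cells(self):
        goal = compute_goal_state(np.array([[1.0, 0.0], [0.0, 1.0]]), DISEASE)
        np.testing.assert_array_equal(goal.centroid, [0.5, 0.5])

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(10, 4))
        a = compute_goal_state(emb, DISEASE).centroid
        b = compute_goal_state(emb[::-1], DISEASE).centroid
        np.testing.assert_allclose(a, b)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            compute_goal_state(np.empty((0, 3)), DISEASE)


class TestShiftToGoal:
    def test_identity_perturbation_is_zero(self):
        goal = GoalState(DISEASE, np.array([1.0, 1.0]), 1)
        v = np.array([0.3, 0.7])
        assert shift_to_goal(v, v, goal) == 0.0

    def test_hand_cosine_example(self):
        goal = GoalState(DISEASE, np.array([0.0, 1.0]), 1)
        s = shift_to_goal(np.array([1.0, 0.0]), np.array([0.0, 1.0]), goal)
        assert s == pytest.approx(1.0)

    def test_antisymmetry_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        goal = GoalState(DISEASE, rng.normal(size=5), 3)
        a, b = rng.normal(size=5), rng.normal(size=5)
        s = shift_to_goal(a, b, goal)
        assert shift_to_goal(b, a, goal) == pytest.approx(-s)
        assert shift_to_goal(3.0 * a, 0.5 * b, goal) == pytest.approx(s)
        assert -2.0 <= s <= 2.0

    def test_zero_norm_vector_rejected(self):
        goal = GoalState(DISEASE, np.array([1.0, 0.0]), 1)
        with pytest.raises(ValueError, match="zero-norm"):
            shift_to_goal(np.zeros(2), np.array([1.0, 0.0]), goal)


class _ConstantModel:
    """Embeds every encoding to the same vector."""

    def embed(self, encodings):
        return np.tile(np.array([1.0, 2.0, 2.0]), (len(encodings), 1))


class TestPerturbCorpus:
    def test_constant_model_gives_exactly_zero_shifts_and_no_candidates(
        self, abc_vocabulary
    ):
        encs = [_enc([3, 2, 4]), _enc([2, 4, 3]), _enc([4, 2])] * 3
        goal = GoalState(DISEASE, np.array([0.5, 0.1, 0.9]), 2)
        records = perturb_corpus(
            _ConstantModel(), encs, ["A", "B", "C"], "delete", goal,
            abc_vocabulary, direction="control->disease",
        )
        for r in records:
            assert r.n_cells > 0
            assert (r.cell_shifts == 0.0).all()
            assert r.shift_to_goal_end == 0.0
        table = rank_candidates(records, min_cells=1)
        assert table.table.empty

    def test_gene_expressed_nowhere_reported_excluded(self, abc_vocabulary):
        encs = [_enc([3, 2]), _enc([2, 3])]
        goal = GoalState(DISEASE, np.array([1.0, 0.0, 0.0]), 1)
        records = perturb_corpus(
            _ConstantModel(), encs, ["A", "B", "D"], "delete", goal, abc_vocabulary
        )
        by_gene = {r.gene_id: r for r in records}
        assert by_gene["D"].n_cells == 0
        table = rank_candidates(records, min_cells=1)
        assert list(table.excluded.gene_id) == ["D"]

    def test_deletion_counts_only_expressing_cells(self, abc_vocabulary):
        encs = [_enc([3, 2]), _enc([3, 4]), _enc([3, 2, 4])]
        goal = GoalState(DISEASE, np.array([1.0, 0.0, 0.0]), 1)
        records = perturb_corpus(
            _ConstantModel(), encs, ["A", "C"], "delete", goal, abc_vocabulary
        )
        by_gene = {r.gene_id: r for r in records}
        assert by_gene["A"].n_cells == 2
        assert by_gene["C"].n_cells == 2

    def test_overexpression_covers_all_cells(self, abc_vocabulary):
        encs = [_enc([3, 2]), _enc([3, 4])]
        goal = GoalState(DISEASE, np.array([1.0, 0.0, 0.0]), 1)
        records = perturb_corpus(
            _ConstantModel(), encs, ["D"], "overexpress", goal, abc_vocabulary
        )
        assert records[0].n_cells == 2

    def test_empty_gene_list_rejected(self, abc_vocabulary):
        with pytest.raises(ValueError, match="gene list"):
            perturb_corpus(
                _ConstantModel(), [_enc([2])], [], "delete",
                GoalState(DISEASE, np.array([1.0, 0, 0]), 1), abc_vocabulary,
            )

    def test_planted_drivers_shift_more_than_non_drivers(self, small_setup):
        """Deleting drivers from control cells moves embeddings toward the
        disease centroid more than deleting random non-drivers."""
        su = small_setup
        test_ctrl = [
            e for e, c in zip(su.enc_test, su.test.condition) if c == "control"
        ]
        test_dis = [
            e for e, c in zip(su.enc_test, su.test.condition) if c == "disease"
        ]
        goal = compute_goal_state(su.model.embed(test_dis), DISEASE)
        drivers = sorted(su.corpus.ground_truth)
        rng = np.random.default_rng(4)
        non = [g for g in expressed_in_both_conditions(su.corpus)
               if g not in su.corpus.ground_truth]
        non_sample = list(rng.choice(non, size=20, replace=False))
        records = perturb_corpus(
            su.model, test_ctrl[:60], drivers + non_sample, "delete", goal,
            su.vocabulary, direction="control->disease",
        )
        by_gene = {r.gene_id: r for r in records}
        mean_driver = np.mean([by_gene[g].shift_to_goal_end for g in drivers])
        mean_non = np.mean([by_gene[g].shift_to_goal_end for g in non_sample])
        assert mean_driver > mean_non


def _bh_oracle(pvals):
    """Brute-force BH step-up: sort, scale by m/rank, cumulative min from the
    largest, cap at 1."""
    m = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


class TestRanking:
    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.04])), [0.03, 0.03, 0.04]
        )

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bh_matches_step_up_oracle(self, pvals):
        pvals = np.array(pvals)
        np.testing.assert_allclose(bh_adjust(pvals), _bh_oracle(pvals), atol=1e-12)

    def _records(self, shift_arrays):
        return [
            PerturbationRecord(
                gene_id=f"g{i}", mode="delete", direction="control->disease",
                n_cells=len(s), shift_to_goal_end=float(np.mean(s)),
                cell_shifts=np.asarray(s, dtype=float),
            )
            for i, s in enumerate(shift_arrays)
        ]

    def test_strong_positive_gene_ranks_first_among_nulls(self):
        rng = np.random.default_rng(8)
        arrays = [rng.normal(0, 0.01, 30) for _ in range(50)]
        arrays.append(rng.normal(0.5, 0.01, 30))  # g50: large positive shifts
        table = rank_candidates(self._records(arrays), min_cells=5)
        assert table.table.iloc[0].gene_id == "g50"
        assert table.table.iloc[0].fdr < 0.05

    def test_null_gene_matching_pooled_distribution_excluded(self):
        values = np.linspace(-1, 1, 30)
        arrays = [values.copy() for _ in range(10)]
        table = rank_candidates(self._records(arrays), min_cells=5)
        assert (table.all_records.fdr > 0.9).all()
        assert table.table.empty

    def test_ordering_keys_shift_desc_then_fdr_asc(self):
        rng = np.random.default_rng(3)
        arrays = [rng.normal(0, 0.01, 40) for _ in range(30)]
        arrays += [rng.normal(0.3, 0.01, 40), rng.normal(0.6, 0.01, 40)]
        table = rank_candidates(self._records(arrays), min_cells=5)
        shifts = table.table.shift_to_goal_end.to_numpy()
        assert (np.diff(shifts) <= 1e-12).all()

    def test_fdr_at_least_p_value(self):
        rng = np.random.default_rng(9)
        arrays = [rng.normal(0, 1, 25) for _ in range(12)]
        table = rank_candidates(self._records(arrays), min_cells=5)
        assert (table.all_records.fdr >= table.all_records.p_value - 1e-12).all()

    def test_fewer_than_two_tested_genes_rejected(self):
        with pytest.raises(ValueError, match="aggregate null"):
            rank_candidates(self._records([np.ones(10)]), min_cells=5)
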