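import numpy as np
import pytest

from pdnet import fixtures as fx
from pdnet.evaluation import (
    confusion_probability_matrix,
    contact_rank_coverage,
    overall_accuracy,
    profile_rmse,
    recall_precision,
    sequence_identity,
    top_k_accuracy,
)
from pdnet.structure_io import AA_ALPHABET


def _one_hot_profiles(pred_labels, natives, peak=1.0):
    probs = np.full((len(pred_labels), 20), (1 - peak) / 19)
    probs[np.arange(len(pred_labels)), pred_labels] = peak
    return probs, np.asarray(natives)


def test_overall_accuracy_direct_count():
    rng = np.random.default_rng(0)
    natives = rng.integers(0, 20, size=10)
    preds = natives.copy()
    preds[:6] = (preds[:6] + 1) % 20  # 4 correct out of 10
    probs, natives = _one_hot_profiles(preds, natives, peak=0.9)
    assert overall_accuracy((probs, natives)) == pytest.approx(0.4)
    perfect, _ = _one_hot_profiles(natives, natives, peak=0.9)
    assert overall_accuracy((perfect, natives)) == 1.0


def test_uniform_rows_resolve_to_alphabetical_first():
    probs = np.full((6, 20), 0.05)
    natives = np.array([0, 0, 1, 2, 3, 0])
    # tie rule: argmax = class 0 (Ala) everywhere
    assert overall_accuracy((probs, natives)) == pytest.approx(3 / 6)


def test_empty_profile_errors():
    with pytest.raises(ValueError):
        overall_accuracy((np.zeros((0, 20)), np.zeros(0, dtype=int)))


def test_top_k_limits_and_equivalence():
    rng = np.random.default_rng(1)
    probs = rng.dirichlet(np.ones(20), size=30)
    natives = rng.integers(0, 20, size=30)
    assert top_k_accuracy((probs, natives), 20) == 1.0
    assert top_k_accuracy((probs, natives), 1) == overall_accuracy((probs, natives))
    with pytest.raises(ValueError):
        top_k_accuracy((probs, natives), 0)
    with pytest.raises(ValueError):
        top_k_accuracy((probs, natives), 21)


def test_top_k_matches_brute_force_membership():
    probs = np.array([
        [0.5, 0.3, 0.2] + [0.0] * 17,
        [0.1, 0.15, 0.05, 0.7] + [0.0] * 16,
        [0.25, 0.25, 0.25, 0.25] + [0.0] * 16,
    ])
    natives = np.array([1, 0, 3])
    for k in range(1, 21):
        brute = np.mean([
            n in sorted(range(20), key=lambda c: (-p[c], c))[:k]
            for p, n in zip(probs, natives)])
        assert top_k_accuracy((probs, natives), k) == pytest.approx(brute)


def test_top_k_monotone_in_k():
    rng = np.random.default_rng(2)
    probs = rng.dirichlet(np.ones(20) * 0.3, size=50)
    natives = rng.integers(0, 20, size=50)
    accs = [top_k_accuracy((probs, natives), k) for k in range(1, 21)]
    assert all(a <= b for a, b in zip(accs, accs[1:]))
    assert accs[-1] == 1.0


def test_recall_precision_hand_count():
    # native A x4 -> predicted A,A,A,G ; native G x1 -> predicted A
    A, G = AA_ALPHABET.index("A"), AA_ALPHABET.index("G")
    preds = [A, A, A, G, A]
    natives = [A, A, A, A, G]
    probs, natives = _one_hot_profiles(preds, natives, peak=0.8)
    rp = recall_precision((probs, natives))
    rec_a, prec_a, sup_a = rp["A"]
    assert rec_a == pytest.approx(0.75) and prec_a == pytest.approx(0.75)
    assert sup_a == 4
    rec_g, prec_g, _ = rp["G"]
    assert rec_g == 0.0
    assert prec_g == pytest.approx(0.0)  # G was predicted once, incorrectly
    # class never seen nor predicted: both missing
    assert rp["W"] == (None, None, 0)


def test_perfect_predictions_give_unit_recall_precision():
    natives = np.array([0, 3, 3, 7, 12])
    probs, natives = _one_hot_profiles(natives, natives, peak=0.9)
    for aa, (rec, prec, sup) in recall_precision((probs, natives)).items():
        if sup:
            assert rec == 1.0 and prec == 1.0


def test_micro_recall_equals_overall_accuracy():
    rng = np.random.default_rng(3)
    probs = rng.dirichlet(np.ones(20), size=200)
    natives = rng.integers(0, 20, size=200)
    rp = recall_precision((probs, natives))
    correct = sum(rec * sup for rec, _, sup in rp.values() if rec is not None)
    assert correct / 200 == pytest.approx(overall_accuracy((probs, natives)))


def test_confusion_matrix_hand_count_and_normalization():
    A, G = AA_ALPHABET.index("A"), AA_ALPHABET.index("G")
    preds = [A, A, A, G, A]
    natives = [A, A, A, A, G]
    probs, natives = _one_hot_profiles(preds, natives, peak=0.8)
    cm = confusion_probability_matrix((probs, natives))
    assert cm.matrix[A, A] == pytest.approx(0.75)
    assert cm.matrix[A, G] == pytest.approx(0.25)
    assert cm.matrix[G, A] == pytest.approx(1.0)
    rows = cm.support > 0
    np.testing.assert_allclose(cm.matrix[rows].sum(axis=1), 1.0, atol=1e-9)


def test_sequence_identity_examples():
    assert sequence_identity("ACDE", "ACDE") == 1.0
    assert sequence_identity("ACDE", "ACDG") == 0.75
    with pytest.raises(ValueError):
        sequence_identity("ACD", "ACDE")
    with pytest.raises(ValueError):
        sequence_identity("", "")


def test_profile_rmse_closed_form_and_symmetry():
    a = np.zeros((1, 20))
    a[0, 0] = 1.0
    b = np.zeros((1, 20))
    b[0, 1] = 1.0
    assert profile_rmse(a, a) == 0.0
    assert profile_rmse(a, b) == pytest.approx(np.sqrt(2 / 20))
    rng = np.random.default_rng(4)
    x, y = rng.dirichlet(np.ones(20), size=5), rng.dirichlet(np.ones(20), size=5)
    assert profile_rmse(x, y) == pytest.approx(profile_rmse(y, x))
    with pytest.raises(ValueError):
        profile_rmse(x, y[:3])


def test_contact_coverage_compact_helix(helix12):
    # all contacts in a short helix are among the nearest neighbors
    assert contact_rank_coverage(helix12, 11) == 1.0


def test_contact_coverage_constructed_rank():
    from conftest import rigid_copy

    # A compact 8-residue helix plus one distant residue that contacts the
    # target through a long "reach" atom: its Ca-distance rank exceeds 5.
    chain = fx.make_ideal_helix(8)
    # place a faraway residue whose O atom reaches near residue 0's N
    far = rigid_copy(fx.make_ideal_helix(2, chain_id="B"), np.eye(3),
                     np.array([25.0, 0.0, 0.0]))
    target_n = chain[0].coord("N")
    far[0].atom("O").coord = target_n + np.array([3.0, 0.0, 0.0])
    residues = chain + far
    cas = np.array([r.coord("CA") for r in residues])
    d = np.linalg.norm(cas - cas[0], axis=1)
    rank_of_far = int(np.argsort(d).tolist().index(8))
    assert rank_of_far > 5
    low = contact_rank_coverage(residues, 5)
    full = contact_rank_coverage(residues, rank_of_far)
    assert low < 1.0
    assert full == 1.0


def test_contact_coverage_monotone_in_rank(helix12):
    vals = [contact_rank_coverage(helix12, n) for n in range(1, 12)]
    assert all(a <= b for a, b in zip(vals, vals[1:]))


def test_no_contacts_returns_missing():
    from conftest import rigid_copy

    a = fx.make_ideal_helix(2)
    b = rigid_copy(fx.make_ideal_helix(2, chain_id="B", start_index=5),
                   np.eye(3), np.array([100.0, 0, 0]))
    # residues within one helix always contact; separate the two residues too
    a[1] = rigid_copy([a[1]], np.eye(3), np.array([0.0, 100.0, 0]))[0]
    b[1] = rigid_copy([b[1]], np.eye(3), np.array([0.0, 100.0, 0]))[0]
    assert contact_rank_coverage(a + b, 3) is None
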