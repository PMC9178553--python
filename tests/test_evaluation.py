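"""Similarity metrics, top-k accuracies, m/z calculation and the PSM test.

Every metric is checked against an independent brute-force computation on
randomized or simulated inputs.
"""

import numpy as np
import pytest

from yfrag.encoding import N_SLOTS, encode_targets, slot_index
from yfrag.evaluation import (
    highest_peak_accuracy,
    pcc,
    pcc_with_zero,
    pcc_without_zero,
    precursor_mz,
    psm_grouping,
    psm_match_accuracy,
    y_ion_mz,
)
from yfrag.simulate import confusable_library, make_fixture
from .conftest import make_peak, make_spectrum

# monoisotopic residue masses, independent of the implementation's mass source
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.01056
PROTON = 1.00728


def oracle_y_mz(seq, k, z):
    return (sum(RESIDUE_MASS[a] for a in seq[-k:]) + WATER + z * PROTON) / z


class TestPcc:
    def test_identity_and_sign_flip(self, rng):
        x = rng.normal(size=20)
        assert pcc(x, x) == pytest.approx(1.0)
        assert pcc(x, -x) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        expected = cov / (x.std() * y.std())
        assert pcc(x, y) == pytest.approx(expected, abs=1e-12)

    def test_undefined_cases_flagged(self):
        assert np.isnan(pcc([1.0, 1.0], [0.5, 0.7]))
        assert np.isnan(pcc([1.0], [2.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pcc([1, 2], [1, 2, 3])


class TestPccVariants:
    def _worked_spectrum(self):
        peaks = tuple(
            make_peak("y", k, 1, intensity=i)
            for k, i in zip((8, 7, 6, 5), (100.0, 75.0, 50.0, 25.0))
        )
        return make_spectrum(sequence="ACDEFGHIK", charge=2, peaks=peaks)

    def test_without_zero_uses_exactly_database_slots(self, rng):
        spec = self._worked_spectrum()
        pred = rng.random(N_SLOTS)
        target, _ = encode_targets(spec)
        slots = [slot_index(k, 1) for k in (5, 6, 7, 8)]
        expected = pcc(pred[slots], target[slots])
        assert pcc_without_zero(pred, spec) == pytest.approx(expected)

    def test_without_zero_perfect_on_database_slots(self):
        spec = self._worked_spectrum()
        target, _ = encode_targets(spec)
        assert pcc_without_zero(target, spec) == pytest.approx(1.0)

    def test_with_zero_spans_feasible_slots(self, rng):
        spec = self._worked_spectrum()
        pred = rng.random(N_SLOTS)
        target, mask = encode_targets(spec)
        assert mask.sum() == 16  # length 9, charge 2
        assert pcc_with_zero(pred, spec) == pytest.approx(
            pcc(pred[mask], target[mask])
        )

    def test_with_zero_slots_superset_of_without_zero(self, paperlike_library):
        library, _ = paperlike_library
        for spec in library[:50]:
            _, mask = encode_targets(spec)
            assert mask.sum() >= len(spec.peaks)

    def test_variants_agree_when_every_feasible_slot_filled(self, rng):
        peaks = tuple(
            make_peak("y", k, 1, intensity=float(rng.random() + 0.1))
            for k in range(1, 6)
        )
        spec = make_spectrum(sequence="ACDEFG", charge=1, peaks=peaks)
        pred = rng.random(N_SLOTS)
        assert pcc_with_zero(pred, spec) == pytest.approx(pcc_without_zero(pred, spec))

    def test_too_few_peaks_flagged(self, rng):
        spec = make_spectrum(peaks=(make_peak(),))
        assert np.isnan(pcc_without_zero(rng.random(N_SLOTS), spec))


class TestHighestPeakAccuracy:
    def test_perfect_predictions(self, paperlike_library):
        library, _ = paperlike_library
        lib = list(library[:50])
        preds = [encode_targets(s)[0] for s in lib]
        assert highest_peak_accuracy(preds, lib) == (1.0, 1.0, 1.0)

    def test_second_highest_counts_for_top1of3_only(self):
        peaks = (
            make_peak("y", 5, 1, intensity=100.0),
            make_peak("y", 4, 1, intensity=80.0),
            make_peak("y", 3, 1, intensity=60.0),
        )
        spec = make_spectrum(sequence="ACDEFGHIK", charge=2, peaks=peaks)
        pred = np.zeros(N_SLOTS)
        pred[slot_index(4, 1)] = 1.0  # argmax at the database 2nd-highest
        pred[slot_index(5, 1)] = 0.9
        high, top1, top2 = highest_peak_accuracy([pred], [spec])
        assert (high, top1, top2) == (0.0, 1.0, 1.0)

    def test_matches_bruteforce_on_panel(self, rng):
        library, _ = make_fixture("paperlike", n_peptides=50, seed=17)
        lib = list(library)
        preds = [rng.random(N_SLOTS) for _ in lib]
        high, top1, top2 = highest_peak_accuracy(preds, lib)
        n_h = n_1 = n_2 = 0
        for pred, spec in zip(preds, lib):
            target, mask = encode_targets(spec)
            feas = np.flatnonzero(mask)
            db_sorted = feas[np.lexsort((feas, -target[feas]))]
            pr_sorted = feas[np.lexsort((feas, -pred[feas]))]
            top3 = set(db_sorted[:3].tolist())
            n_h += pr_sorted[0] == db_sorted[0]
            n_1 += pr_sorted[0] in top3
            n_2 += set(pr_sorted[:2].tolist()) <= top3
        assert (high, top1, top2) == (n_h / 50, n_1 / 50, n_2 / 50)

    def test_highest_never_exceeds_top1of3(self, rng):
        library, _ = make_fixture("paperlike", n_peptides=100, seed=23)
        preds = [rng.random(N_SLOTS) for _ in library]
        high, top1, _ = highest_peak_accuracy(preds, list(library))
        assert high <= top1

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            highest_peak_accuracy([], [])


class TestMz:
    def test_y1_of_lysine(self):
        assert y_ion_mz("ACDEFGHIK", 1, 1) == pytest.approx(147.1128, abs=1e-3)

    def test_y2_glycine_lysine(self):
        assert y_ion_mz("ACDEFGHGK", 2, 1) == pytest.approx(204.1343, abs=1e-3)

    def test_charge_identity(self):
        seq = "ACDEFGHIK"
        for k in range(1, 9):
            single = y_ion_mz(seq, k, 1)
            assert y_ion_mz(seq, k, 2) == pytest.approx(
                (single + PROTON) / 2, abs=1e-3
            )

    def test_precursor_gg(self):
        assert precursor_mz("GG", 1) == pytest.approx(133.0608, abs=1e-3)

    def test_precursor_monotone_in_charge(self):
        assert precursor_mz("ACDEFGHIK", 2) < precursor_mz("ACDEFGHIK", 1)

    def test_matches_residue_table_oracle(self, rng):
        letters = list(RESIDUE_MASS)
        for _ in range(100):
            seq = "".join(rng.choice(letters, size=rng.integers(6, 16)))
            k = int(rng.integers(1, len(seq)))
            z = int(rng.integers(1, 4))
            assert y_ion_mz(seq, k, z) == pytest.approx(
                oracle_y_mz(seq, k, z), abs=1e-3
            )

    def test_invalid_ordinal_rejected(self):
        with pytest.raises(ValueError):
            y_ion_mz("ACDEFG", 6, 1)


class TestPsmGrouping:
    def test_close_pair_grouped(self, paperlike_library):
        library, _ = paperlike_library
        # construct two spectra guaranteed to pair: same sequence & charge
        a = library[0]
        b = make_spectrum(
            sequence=a.sequence, charge=a.precursor_charge, peaks=a.peaks
        )
        groups = psm_grouping([a, b])
        assert groups == [[0, 1]]

    def test_distant_precursors_never_grouped(self):
        a = make_spectrum(sequence="ACDEFGHIK", charge=2,
                          peaks=tuple(make_peak("y", k, 1, mz=oracle_y_mz("ACDEFGHIK", k, 1)) for k in (3, 4, 5)))
        b = make_spectrum(sequence="WWWWWWWWW", charge=2,
                          peaks=tuple(make_peak("y", k, 1, mz=oracle_y_mz("WWWWWWWWW", k, 1)) for k in (3, 4, 5)))
        assert psm_grouping([a, b]) == []

    def test_matches_bruteforce_all_pairs(self):
        library, _ = make_fixture("paperlike", n_peptides=150, seed=31)
        lib = list(library)
        groups = psm_grouping(lib)

        # O(n^2) oracle with union-find over explicit pair predicate
        prec = [precursor_mz(s.sequence, s.precursor_charge) for s in lib]
        frag = [np.array([p.mz for p in s.peaks]) for s in lib]
        parent = list(range(len(lib)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(len(lib)):
            for j in range(i + 1, len(lib)):
                if abs(prec[i] - prec[j]) > 0.5:
                    continue
                d = np.abs(frag[i][:, None] - frag[j][None, :]) <= 0.5
                if min(d.any(1).sum(), d.any(0).sum()) >= 3:
                    parent[find(i)] = find(j)
        oracle = {}
        for i in range(len(lib)):
            oracle.setdefault(find(i), []).append(i)
        oracle_groups = sorted(
            [sorted(g) for g in oracle.values() if len(g) >= 2]
        )
        assert sorted(groups) == oracle_groups

    def test_partition_invariant_under_order(self):
        library, _ = make_fixture("paperlike", n_peptides=80, seed=37)
        lib = list(library)
        groups = psm_grouping(lib)
        perm = np.random.default_rng(1).permutation(len(lib))
        permuted = [lib[i] for i in perm]
        groups_p = psm_grouping(permuted)
        as_sets = lambda gs, names: {
            frozenset(names[i] for i in g) for g in gs
        }
        names = [s.key for s in lib]
        names_p = [s.key for s in permuted]
        assert as_sets(groups, names) == as_sets(groups_p, names_p)


class TestPsmMatchAccuracy:
    def test_perfect_predictions_match_themselves(self):
        lib = confusable_library(20, seed=41)
        groups = psm_grouping(lib)
        assert groups, "fixture must produce at least one group"
        preds = [encode_targets(s)[0].clip(min=0) for s in lib]
        assert psm_match_accuracy(preds, groups, lib) == 1.0

    def test_swapped_prediction_scores_zero(self):
        a = make_spectrum(sequence="ACDEFGHIK", charge=2,
                          peaks=(make_peak("y", 3, 1, intensity=10.0),
                                 make_peak("y", 4, 1, intensity=5.0),
                                 make_peak("y", 5, 1, intensity=1.0)))
        b = make_spectrum(sequence="ACDEGFHIK", charge=2,
                          peaks=(make_peak("y", 6, 1, intensity=10.0),
                                 make_peak("y", 7, 1, intensity=5.0),
                                 make_peak("y", 8, 1, intensity=1.0)))
        ta, _ = encode_targets(a)
        tb, _ = encode_targets(b)
        # each prediction equals the groupmate's spectrum
        acc = psm_match_accuracy([tb.clip(min=0), ta.clip(min=0)], [[0, 1]], [a, b])
        assert acc == 0.0

    def test_matches_exhaustive_scoring(self, rng):
        lib = confusable_library(20, seed=43)
        groups = psm_grouping(lib)
        preds = [np.abs(rng.normal(size=N_SLOTS)) for _ in lib]
        acc = psm_match_accuracy(preds, groups, lib)

        n_ok = n = 0
        for g in groups:
            for i in g:
                best, best_key = None, None
                for j in g:
                    t = encode_targets(lib[j])[0]
                    t = np.where(t > 0, t, 0.0)
                    r = pcc(preds[i], t)
                    mse = float(np.mean((preds[i] - t) ** 2))
                    key = (-(r if not np.isnan(r) else -1e18), mse, j)
                    if best is None or key < best:
                        best, best_key = key, j
                n_ok += best_key == i
                n += 1
        assert acc == pytest.approx(n_ok / n)
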