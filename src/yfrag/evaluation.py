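"""Spectral-similarity statistics for predicted versus library spectra.

Two Pearson-correlation conventions are provided.  The "without-zero" PCC
compares predictions only at slots where the library spectrum actually has
a peak; the "with-zero" PCC compares over every feasible slot, treating
absent library peaks as zero intensity.  On top of these come the
highest-peak accuracies used to judge SRM/MRM transition selection, and a
simplified peptide-spectrum-match (PSM) test in which near-isobaric
peptides sharing fragment m/z values are grouped and each prediction must
pick out its own library spectrum within the group.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .encoding import N_SLOTS, encode_targets, feasibility_mask, slot_index
from .masses import precursor_mz, y_ion_mz  # re-exported module surface
from .speclib import LibrarySpectrum

__all__ = [
    "pcc",
    "pcc_without_zero",
    "pcc_with_zero",
    "highest_peak_accuracy",
    "y_ion_mz",
    "precursor_mz",
    "psm_grouping",
    "psm_match_accuracy",
    "EvalReport",
    "evaluate_predictions",
]


def pcc(x, y) -> float:
    """Pearson correlation; NaN (flagged missing) when undefined.

    Undefined cases — fewer than two points or a constant vector — return
    NaN so they can be excluded from medians.  A length mismatch is an
    error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # near-constant-input advisories
        return float(stats.pearsonr(x, y)[0])


def _check_prediction(prediction) -> np.ndarray:
    prediction = np.asarray(prediction, dtype=float)
    if prediction.shape != (N_SLOTS,):
        raise ValueError(f"prediction must have shape ({N_SLOTS},), got {prediction.shape}")
    return prediction


def pcc_without_zero(prediction, spectrum: LibrarySpectrum) -> float:
    """PCC restricted to the slots holding a library peak."""
    prediction = _check_prediction(prediction)
    target, _ = encode_targets(spectrum)
    slots = sorted(slot_index(p.ordinal, p.fragment_charge) for p in spectrum.peaks)
    if len(slots) < 2:
        return float("nan")
    return pcc(prediction[slots], target[slots])


def pcc_with_zero(prediction, spectrum: LibrarySpectrum) -> float:
    """PCC over all feasible slots, absent library peaks counted as zero."""
    prediction = _check_prediction(prediction)
    target, mask = encode_targets(spectrum)
    return pcc(prediction[mask], target[mask])


def _top_slots(values: np.ndarray, mask: np.ndarray, k: int) -> list[int]:
    """Indices of the k largest feasible values, ties to the smaller slot."""
    order = sorted(
        (s for s in range(N_SLOTS) if mask[s]), key=lambda s: (-values[s], s)
    )
    return order[:k]


def highest_peak_accuracy(
    predictions: list[np.ndarray], library: list[LibrarySpectrum]
) -> tuple[float, float, float]:
    """Fractions (highest, top-1-of-3, top-2-of-3) over the library.

    highest: the predicted argmax slot equals the library argmax slot;
    top-1-of-3: the predicted argmax is among the library's three most
    intense slots; top-2-of-3: both predicted top-two slots are among the
    library top three.  Library ties are broken by slot order.
    """
    if not library:
        raise ValueError("empty library")
    if len(predictions) != len(library):
        raise ValueError("predictions and library must align")
    n_high = n_top1 = n_top2 = 0
    for pred, spec in zip(predictions, library):
        pred = _check_prediction(pred)
        target, mask = encode_targets(spec)
        db_top3 = set(_top_slots(target, mask, 3))
        db_argmax = _top_slots(target, mask, 1)[0]
        pred_top2 = _top_slots(pred, mask, 2)
        n_high += pred_top2[0] == db_argmax
        n_top1 += pred_top2[0] in db_top3
        n_top2 += set(pred_top2) <= db_top3
    n = len(library)
    return n_high / n, n_top1 / n, n_top2 / n


# --------------------------------------------------------------------------
# Simplified PSM grouping test
# --------------------------------------------------------------------------

def _shared_fragments(mzs_a: np.ndarray, mzs_b: np.ndarray, tol: float) -> int:
    """Symmetric count of fragments with a partner within tolerance."""
    if mzs_a.size == 0 or mzs_b.size == 0:
        return 0
    d = np.abs(mzs_a[:, None] - mzs_b[None, :]) <= tol
    return int(min(d.any(axis=1).sum(), d.any(axis=0).sum()))


def psm_grouping(
    library: list[LibrarySpectrum],
    precursor_tol: float = 0.5,
    fragment_tol: float = 0.5,
    min_shared: int = 3,
) -> list[list[int]]:
    """Group near-confusable peptides by precursor and fragment m/z.

    Two peptides are linked when their precursor m/z differ by at most
    ``precursor_tol`` and they share at least ``min_shared`` product ions
    within ``fragment_tol``.  Groups are connected components of the link
    graph; singletons are omitted.  Returns lists of library indices,
    each sorted, in order of their smallest member.
    """
    n = len(library)
    prec = np.array(
        [precursor_mz(s.sequence, s.precursor_charge) for s in library]
    )
    frags = [np.array([p.mz for p in s.peaks]) for s in library]

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = np.argsort(prec, kind="stable")
    for a_pos in range(n):
        i = int(order[a_pos])
        for b_pos in range(a_pos + 1, n):
            j = int(order[b_pos])
            if prec[j] - prec[i] > precursor_tol:
                break
            if _shared_fragments(frags[i], frags[j], fragment_tol) >= min_shared:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = [sorted(g) for g in groups.values() if len(g) >= 2]
    out.sort(key=lambda g: g[0])
    return out


def _zero_filled(spectrum: LibrarySpectrum) -> np.ndarray:
    target, _ = encode_targets(spectrum)
    return np.where(target > 0, target, 0.0)


def psm_match_accuracy(
    predictions: list[np.ndarray],
    groups: list[list[int]],
    library: list[LibrarySpectrum],
) -> float:
    """Fraction of grouped peptides whose prediction best matches themselves.

    Within each group, every member's predicted 42-slot spectrum is scored
    against every member's library spectrum (both zero-filled over the 42
    slots); the best match is the library spectrum with the highest PCC,
    ties broken by the lowest MSE.  Groups of size < 2 are skipped.
    """
    if len(predictions) != len(library):
        raise ValueError("predictions and library must align")
    preds = [np.maximum(_check_prediction(p), 0.0) for p in predictions]
    targets = [_zero_filled(s) for s in library]
    n_correct = n_total = 0
    for group in groups:
        if len(group) < 2:
            continue
        for i in group:
            scored = []
            for j in group:
                r = pcc(preds[i], targets[j])
                mse = float(np.mean((preds[i] - targets[j]) ** 2))
                scored.append((-(-1e18 if np.isnan(r) else r), mse, j))
            best = min(scored)[2]
            n_correct += best == i
            n_total += 1
    return n_correct / n_total if n_total else float("nan")


# --------------------------------------------------------------------------
# Report
# --------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Bundle of evaluation statistics for one prediction set."""

    pcc_without_zero: list[float] = field(default_factory=list)
    pcc_with_zero: list[float] = field(default_factory=list)
    median_pcc_without_zero: float = float("nan")
    median_pcc_with_zero: float = float("nan")
    accuracy_highest: float = float("nan")
    accuracy_top1of3: float = float("nan")
    accuracy_top2of3: float = float("nan")
    psm_groups: int = 0
    psm_mean_group_size: float = float("nan")
    psm_match_accuracy: float = float("nan")

    def to_json(self, **kwargs) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        return json.dumps(d, **kwargs)


def _nanmedian(values: list[float]) -> float:
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    return float(np.median(arr)) if arr.size else float("nan")


def evaluate_predictions(
    predictions: list[np.ndarray],
    library: list[LibrarySpectrum],
    run_psm_test: bool = True,
) -> EvalReport:
    """Compute the full report for aligned predictions and library spectra."""
    report = EvalReport()
    report.pcc_without_zero = [
        pcc_without_zero(p, s) for p, s in zip(predictions, library)
    ]
    report.pcc_with_zero = [pcc_with_zero(p, s) for p, s in zip(predictions, library)]
    report.median_pcc_without_zero = _nanmedian(report.pcc_without_zero)
    report.median_pcc_with_zero = _nanmedian(report.pcc_with_zero)
    (
        report.accuracy_highest,
        report.accuracy_top1of3,
        report.accuracy_top2of3,
    ) = highest_peak_accuracy(predictions, library)
    if run_psm_test:
        groups = psm_grouping(library)
        report.psm_groups = len(groups)
        report.psm_mean_group_size = (
            float(np.mean([len(g) for g in groups])) if groups else float("nan")
        )
        report.psm_match_accuracy = psm_match_accuracy(predictions, groups, library)
    return report
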