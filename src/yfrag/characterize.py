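"""Exploratory highest-peak statistics of a cleaned y-ion library.

These are the descriptive analyses that motivate the predictor's feature
set: which residues flank the cleavage producing the most intense y ion,
how the highest-fragment length tracks precursor length, which residues
dominate charge-retaining fragments, and how large the intensity gap to
the second peak is when proline sits at the fragment +1 site.

Site convention: for the y ion of length k from a length-L peptide, the
cleavage falls between residues L-k-1 and L-k (0-based).  Offset +1 is the
fragment's N-terminal residue (index L-k), -1 the residue immediately
N-terminal to the cleavage (index L-k-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import slot_index
from .speclib import CANONICAL_AA, LibrarySpectrum

AA_LIST = list(CANONICAL_AA)


@dataclass(frozen=True)
class HighestPeak:
    """The most intense y ion of one spectrum and its sequence context."""

    sequence: str
    precursor_charge: int
    fragment_length: int
    fragment_charge: int
    site_minus2: str | None
    site_minus1: str
    site_plus1: str
    site_plus2: str | None
    retained_charge: bool
    gap: float  # highest minus second-highest intensity; 0 for single peaks


def site_residue(sequence: str, fragment_length: int, offset: int) -> str | None:
    """Residue at a signed offset from the cleavage, or None if outside."""
    if offset == 0:
        raise ValueError("offset 0 is undefined; the cleavage falls between residues")
    cut = len(sequence) - fragment_length  # index of the +1 residue
    idx = cut + offset - 1 if offset > 0 else cut + offset
    return sequence[idx] if 0 <= idx < len(sequence) else None


def highest_peak(spectrum: LibrarySpectrum) -> HighestPeak:
    """Locate the max-intensity peak; ties go to the smaller target slot."""
    if not spectrum.peaks:
        raise ValueError(f"spectrum {spectrum.key} has no peaks")
    best = max(
        spectrum.peaks,
        key=lambda p: (p.intensity, -slot_index(p.ordinal, p.fragment_charge)),
    )
    intensities = sorted((p.intensity for p in spectrum.peaks), reverse=True)
    gap = intensities[0] - intensities[1] if len(intensities) > 1 else 0.0
    k = best.ordinal
    return HighestPeak(
        sequence=spectrum.sequence,
        precursor_charge=spectrum.precursor_charge,
        fragment_length=k,
        fragment_charge=best.fragment_charge,
        site_minus2=site_residue(spectrum.sequence, k, -2),
        site_minus1=site_residue(spectrum.sequence, k, -1),
        site_plus1=site_residue(spectrum.sequence, k, +1),
        site_plus2=site_residue(spectrum.sequence, k, +2),
        retained_charge=best.fragment_charge == spectrum.precursor_charge,
        gap=gap,
    )


def flanking_matrix(library: list[LibrarySpectrum]) -> pd.DataFrame:
    """20x20 count matrix of (+1 residue, -1 residue) over highest peaks.

    Terminal highest peaks (fragment length = L-1, which have no -2 residue)
    are excluded, so every counted cleavage has a full interior context.
    """
    counts = pd.DataFrame(0, index=AA_LIST, columns=AA_LIST, dtype=int)
    for spec in library:
        if not spec.peaks:
            continue
        hp = highest_peak(spec)
        if hp.site_minus2 is None:
            continue
        counts.loc[hp.site_plus1, hp.site_minus1] += 1
    return counts


def charge_retention_profile(
    library: list[LibrarySpectrum], window: tuple[int, int] = (-4, 4)
) -> pd.DataFrame:
    """Per-position residue probabilities around charge-retaining cleavages.

    Restricted to highest peaks whose fragment charge equals the precursor
    charge.  Columns are signed offsets (no offset 0); each column sums to 1
    over the residues observed at that offset.  Empty result if no ion
    retained its charge.
    """
    offsets = [o for o in range(window[0], window[1] + 1) if o != 0]
    counts = pd.DataFrame(0, index=AA_LIST, columns=offsets, dtype=int)
    n_retaining = 0
    for spec in library:
        if not spec.peaks:
            continue
        hp = highest_peak(spec)
        if not hp.retained_charge:
            continue
        n_retaining += 1
        for off in offsets:
            res = site_residue(spec.sequence, hp.fragment_length, off)
            if res is not None:
                counts.loc[res, off] += 1
    if n_retaining == 0:
        return counts.astype(float)
    totals = counts.sum(axis=0)
    return counts / totals.replace(0, np.nan)


def length_cooccurrence(library: list[LibrarySpectrum]) -> pd.DataFrame:
    """Counts of (precursor length, highest-fragment length).

    Row sums equal the number of spectra per precursor length.
    """
    lengths = sorted({len(s.sequence) for s in library if s.peaks})
    frag_lengths = list(range(1, (max(lengths) if lengths else 2)))
    counts = pd.DataFrame(0, index=lengths, columns=frag_lengths, dtype=int)
    for spec in library:
        if not spec.peaks:
            continue
        hp = highest_peak(spec)
        counts.loc[len(spec.sequence), hp.fragment_length] += 1
    return counts


def plus1_abundance_correlation(
    library: list[LibrarySpectrum], outlier_z: float = 2.0
) -> dict:
    """Compare +1-site residue counts between the length - 2 stratum and the rest.

    Highest peaks are split by whether the fragment length equals precursor
    length - 2.  Returns the 20 paired counts, their Pearson correlation,
    and the outlying residues — those whose cleavage propensity is not
    explained by background abundance.  Outliers are judged by
    leave-one-out studentized residuals (the line is refit without the
    candidate residue), so a single dominant residue cannot drag the fit
    toward itself and hide.
    """
    at_len2 = pd.Series(0, index=AA_LIST, dtype=int)
    elsewhere = pd.Series(0, index=AA_LIST, dtype=int)
    for spec in library:
        if not spec.peaks:
            continue
        hp = highest_peak(spec)
        stratum = at_len2 if hp.fragment_length == len(spec.sequence) - 2 else elsewhere
        stratum[hp.site_plus1] += 1
    x, y = elsewhere.to_numpy(float), at_len2.to_numpy(float)
    if x.sum() == 0 or y.sum() == 0 or np.all(x == x[0]) or np.all(y == y[0]):
        return {
            "counts": pd.DataFrame({"at_len2": at_len2, "elsewhere": elsewhere}),
            "pcc": float("nan"),
            "outliers": [],
            "degenerate": True,
        }
    std_resid = np.zeros(len(x))
    for i in range(len(x)):
        keep = np.arange(len(x)) != i
        fit = stats.linregress(x[keep], y[keep])
        resid_rest = y[keep] - (fit.intercept + fit.slope * x[keep])
        sd = resid_rest.std(ddof=2)
        if sd > 0:
            std_resid[i] = (y[i] - (fit.intercept + fit.slope * x[i])) / sd
    outliers = [AA_LIST[i] for i in np.flatnonzero(np.abs(std_resid) > outlier_z)]
    return {
        "counts": pd.DataFrame({"at_len2": at_len2, "elsewhere": elsewhere}),
        "pcc": float(stats.pearsonr(x, y)[0]),
        "outliers": outliers,
        "standardized_residuals": pd.Series(std_resid, index=AA_LIST),
        "degenerate": False,
    }


def gap_by_plus1(library: list[LibrarySpectrum]) -> dict:
    """Highest-vs-second intensity gaps stratified by proline at the +1 site.

    Only spectra with at least two peaks contribute.
    """
    with_p: list[float] = []
    without_p: list[float] = []
    for spec in library:
        if len(spec.peaks) < 2:
            continue
        hp = highest_peak(spec)
        (with_p if hp.site_plus1 == "P" else without_p).append(hp.gap)
    return {
        "proline_plus1": np.asarray(with_p),
        "other_plus1": np.asarray(without_p),
        "median_proline": float(np.median(with_p)) if with_p else float("nan"),
        "median_other": float(np.median(without_p)) if without_p else float("nan"),
    }
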