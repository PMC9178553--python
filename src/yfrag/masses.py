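"""Monoisotopic m/z of y ions and precursors (thin wrapper over pyteomics)."""

from __future__ import annotations

from pyteomics import mass as _pt_mass


def y_ion_mz(sequence: str, ordinal: int, fragment_charge: int) -> float:
    """m/z of the y ion containing the C-terminal ``ordinal`` residues.

    (sum of monoisotopic residue masses + water + z protons) / z.
    """
    if not 1 <= ordinal <= len(sequence) - 1:
        raise ValueError(
            f"y-ion ordinal must be in 1..{len(sequence) - 1} for {sequence!r}, "
            f"got {ordinal}"
        )
    if fragment_charge < 1:
        raise ValueError(f"fragment_charge must be >= 1, got {fragment_charge}")
    return _pt_mass.fast_mass(
        sequence[-ordinal:], ion_type="y", charge=fragment_charge
    )


def precursor_mz(sequence: str, charge: int) -> float:
    """m/z of the intact peptide: (residue masses + water + z protons) / z."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return _pt_mass.fast_mass(sequence, charge=charge)
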