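"""Model-ready encodings of cleaned spectra.

Three input channels and one target are produced per peptide:

* a one-hot sequence matrix (``max_length`` x 20, zero-padded rows),
* a 4-vector of scalar features (CE, precursor charge, length, proline count),
* a 4 x 12 sliding-window matrix of numeric 4-mer codes,
* a 42-slot target of relative y-ion intensities.

The 42 slots cover y1..y14 at fragment charges 1..3 (ordinal-major,
charge-minor).  Slots that cannot physically occur for a peptide — an
ordinal at or beyond the peptide length, or a fragment charge above the
precursor charge — are filled with -1; feasible slots with no observed
peak are filled with 0; observed peaks are base-peak normalised so the
most intense y ion equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .speclib import (
    CANONICAL_AA,
    MAX_FRAGMENT_CHARGE,
    MAX_ORDINAL,
    LibrarySpectrum,
)

N_SLOTS = MAX_ORDINAL * MAX_FRAGMENT_CHARGE  # 42
MIN_LENGTH = 6
MAX_LENGTH = 15
WINDOW = 4
MAX_WINDOWS = MAX_LENGTH - WINDOW + 1  # 12

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


def slot_index(ordinal: int, fragment_charge: int) -> int:
    """Map (y-ion ordinal k, fragment charge z) to its slot 0..41."""
    if not 1 <= ordinal <= MAX_ORDINAL:
        raise ValueError(f"ordinal must be in 1..{MAX_ORDINAL}, got {ordinal}")
    if not 1 <= fragment_charge <= MAX_FRAGMENT_CHARGE:
        raise ValueError(
            f"fragment_charge must be in 1..{MAX_FRAGMENT_CHARGE}, got {fragment_charge}"
        )
    return (ordinal - 1) * MAX_FRAGMENT_CHARGE + (fragment_charge - 1)


def slot_to_ion(slot: int) -> tuple[int, int]:
    """Inverse of :func:`slot_index`: slot 0..41 -> (ordinal, fragment charge)."""
    if not 0 <= slot < N_SLOTS:
        raise ValueError(f"slot must be in 0..{N_SLOTS - 1}, got {slot}")
    return slot // MAX_FRAGMENT_CHARGE + 1, slot % MAX_FRAGMENT_CHARGE + 1


def _validate_sequence(sequence: str, max_length: int = MAX_LENGTH) -> None:
    if not MIN_LENGTH <= len(sequence) <= max_length:
        raise ValueError(
            f"peptide length must be in [{MIN_LENGTH}, {max_length}], "
            f"got {len(sequence)} for {sequence!r}"
        )
    for ch in sequence:
        if ch not in _AA_INDEX:
            raise ValueError(f"non-canonical residue {ch!r} in {sequence!r}")


def one_hot_sequence(sequence: str, max_length: int = MAX_LENGTH) -> np.ndarray:
    """One-hot encode a peptide; rows beyond the sequence are zero padding.

    Columns follow the alphabetical order of the one-letter codes.
    """
    _validate_sequence(sequence, max_length)
    out = np.zeros((max_length, len(CANONICAL_AA)))
    for i, ch in enumerate(sequence):
        out[i, _AA_INDEX[ch]] = 1.0
    return out


def scalar_features(
    sequence: str,
    precursor_charge: int,
    collision_energy: float,
    standardize: bool = True,
) -> np.ndarray:
    """The 4-vector (CE, charge, length, proline count).

    With ``standardize`` each entry is scaled to order 1:
    CE/100, charge/3, length/15, prolines/15.
    """
    _validate_sequence(sequence)
    raw = np.array(
        [
            float(collision_energy),
            float(precursor_charge),
            float(len(sequence)),
            float(sequence.count("P")),
        ]
    )
    if standardize:
        raw = raw / np.array([100.0, 3.0, float(MAX_LENGTH), float(MAX_LENGTH)])
    return raw


def sliding_windows(
    sequence: str, window: int = WINDOW, max_windows: int = MAX_WINDOWS
) -> np.ndarray:
    """4-mer sliding-window matrix, one window per column.

    Column j holds the numeric codes of residues j..j+window-1 (alphabetical
    rank 1..20 scaled by 1/20); columns beyond len - window + 1 are zero.
    """
    _validate_sequence(sequence)
    if len(sequence) < window:
        raise ValueError(f"sequence shorter than window {window}: {sequence!r}")
    out = np.zeros((window, max_windows))
    n_windows = len(sequence) - window + 1
    for j in range(min(n_windows, max_windows)):
        for i in range(window):
            out[i, j] = (_AA_INDEX[sequence[j + i]] + 1) / 20.0
    return out


def feasibility_mask(length: int, precursor_charge: int) -> np.ndarray:
    """Boolean 42-vector: slot (k, z) is feasible iff k <= length - 1 and
    z <= precursor_charge."""
    if not MIN_LENGTH <= length <= MAX_LENGTH:
        raise ValueError(f"length must be in [{MIN_LENGTH}, {MAX_LENGTH}], got {length}")
    if not 1 <= precursor_charge <= MAX_FRAGMENT_CHARGE:
        raise ValueError(
            f"precursor_charge must be in 1..{MAX_FRAGMENT_CHARGE}, got {precursor_charge}"
        )
    mask = np.zeros(N_SLOTS, dtype=bool)
    for k in range(1, length):
        for z in range(1, precursor_charge + 1):
            mask[slot_index(k, z)] = True
    return mask


def encode_targets(spectrum: LibrarySpectrum) -> tuple[np.ndarray, np.ndarray]:
    """Place base-peak-normalised intensities into the 42-slot target.

    Feasible slots without a peak are 0; infeasible slots are -1.  A peak at
    an infeasible slot indicates inconsistent data and is an error.
    """
    if not spectrum.peaks:
        raise ValueError(f"spectrum {spectrum.key} has no peaks to encode")
    mask = feasibility_mask(len(spectrum.sequence), spectrum.precursor_charge)
    target = np.where(mask, 0.0, -1.0)
    base = max(p.intensity for p in spectrum.peaks)
    if base <= 0:
        raise ValueError(f"spectrum {spectrum.key} has no positive intensity")
    for p in spectrum.peaks:
        s = slot_index(p.ordinal, p.fragment_charge)
        if not mask[s]:
            raise ValueError(
                f"peak y{p.ordinal}^{p.fragment_charge} is infeasible for "
                f"{spectrum.key} (length {len(spectrum.sequence)}, "
                f"charge {spectrum.precursor_charge})"
            )
        target[s] = p.intensity / base
    return target, mask


def decode_targets(
    vector: np.ndarray, length: int, precursor_charge: int
) -> list[tuple[int, int, float]]:
    """Feasible slots with positive intensity as (ordinal, charge, intensity),
    sorted by descending intensity, ties by smaller slot index."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (N_SLOTS,):
        raise ValueError(f"expected a length-{N_SLOTS} vector, got shape {vector.shape}")
    mask = feasibility_mask(length, precursor_charge)
    hits = [
        (s, vector[s]) for s in range(N_SLOTS) if mask[s] and vector[s] > 0
    ]
    hits.sort(key=lambda t: (-t[1], t[0]))
    return [(*slot_to_ion(s), v) for s, v in hits]


@dataclass(frozen=True)
class EncodedSample:
    """Model-ready bundle for one peptide."""

    sequence: str
    precursor_charge: int
    collision_energy: float
    onehot: np.ndarray  # (max_length, 20)
    features: np.ndarray  # (4,)
    windows: np.ndarray  # (4, 12)
    target: np.ndarray  # (42,)
    mask: np.ndarray  # (42,) bool


DEFAULT_CE = 30.0


def encode_spectrum(
    spectrum: LibrarySpectrum, default_ce: float = DEFAULT_CE
) -> EncodedSample:
    """Encode one cleaned spectrum into all model channels plus the target."""
    ce = spectrum.collision_energy if spectrum.collision_energy is not None else default_ce
    target, mask = encode_targets(spectrum)
    return EncodedSample(
        sequence=spectrum.sequence,
        precursor_charge=spectrum.precursor_charge,
        collision_energy=ce,
        onehot=one_hot_sequence(spectrum.sequence),
        features=scalar_features(spectrum.sequence, spectrum.precursor_charge, ce),
        windows=sliding_windows(spectrum.sequence),
        target=target,
        mask=mask,
    )


def encode_library(
    library: list[LibrarySpectrum], default_ce: float = DEFAULT_CE
) -> list[EncodedSample]:
    return [encode_spectrum(s, default_ce) for s in library]


# --------------------------------------------------------------------------
# Columnar persistence
# --------------------------------------------------------------------------

def samples_to_frame(samples: list[EncodedSample]):
    """One row per peptide: sequence, charge, CE, 42 targets, 42 mask bits.

    Input channels are deterministic functions of (sequence, charge, CE) and
    are re-derived on load, so the table round-trips bit-exactly.
    """
    import pandas as pd

    rows = []
    for s in samples:
        row = {"sequence": s.sequence, "charge": s.precursor_charge, "ce": s.collision_energy}
        for i in range(N_SLOTS):
            row[f"t{i:02d}"] = s.target[i]
        for i in range(N_SLOTS):
            row[f"m{i:02d}"] = int(s.mask[i])
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_samples(frame) -> list[EncodedSample]:
    samples = []
    tcols = [f"t{i:02d}" for i in range(N_SLOTS)]
    mcols = [f"m{i:02d}" for i in range(N_SLOTS)]
    for _, row in frame.iterrows():
        seq, charge, ce = row["sequence"], int(row["charge"]), float(row["ce"])
        samples.append(
            EncodedSample(
                sequence=seq,
                precursor_charge=charge,
                collision_energy=ce,
                onehot=one_hot_sequence(seq),
                features=scalar_features(seq, charge, ce),
                windows=sliding_windows(seq),
                target=row[tcols].to_numpy(dtype=float),
                mask=row[mcols].to_numpy(dtype=float).astype(bool),
            )
        )
    return samples
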