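"""Generative y-ion fragmentation simulator.

The simulator produces MSP-compatible libraries whose spectra carry the
statistical signatures of beam-type CID fragmentation of tryptic-scale
peptides: enhanced cleavage N-terminal to proline (proline at the fragment
+1 site), enrichment of aliphatic and acidic residues at the -1 site,
preferential high-intensity fragments at precursor length - 2 (and, more
weakly, length - 4), and precursor-charge retention biased toward
proline-containing fragments.

Per cleavage site k of a length-L peptide the log-intensity score is

    s_k = b_P * 1[+1 residue is P] + b_L2 * 1[k = L-2] + b_L4 * 1[k = L-4]
        + b_ali * 1[-1 residue in {A,V,L,I}] + b_aci * 1[-1 residue in {D,E}]
        + Normal(0, noise_sd)

and intensities are exp(s_k), base-peak normalised.  The exponential link
keeps intensities positive and makes each effect a multiplicative intensity
bonus.  One y ion is emitted per cleavage; its charge equals the precursor
charge with a retention probability that increases when the fragment
contains proline, and is otherwise drawn uniformly below the precursor
charge.  Each non-base peak is finally dropped with ``dropout_prob``,
emulating detection loss of minor ions (the base peak is always detected).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .masses import y_ion_mz
from .speclib import CANONICAL_AA, LibrarySpectrum, PeakAnnotation

ALIPHATIC = set("AVLI")
ACIDIC = set("DE")


@dataclass(frozen=True)
class SimulatorParams:
    """Effect sizes and noise level of the generative fragmentation model.

    Betas are log-intensity bonuses (a beta of 2 multiplies the intensity
    by e^2 ~ 7.4).  ``charge_retention_base`` is the probability that a
    fragment keeps the precursor charge; ``charge_retention_proline`` is
    added to it when the fragment contains a proline.
    """

    n_peptides: int = 1000
    length_range: tuple[int, int] = (6, 15)
    charge_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.7, 3: 0.3}
    )
    aa_freqs: tuple[float, ...] = tuple([1.0 / 20] * 20)
    beta_proline: float = 2.0
    beta_len2: float = 1.2
    beta_len4: float = 0.5
    beta_aliphatic: float = 0.5
    beta_acidic: float = 0.7
    charge_retention_base: float = 0.15
    charge_retention_proline: float = 0.45
    noise_sd: float = 0.3
    dropout_prob: float = 0.15
    collision_energy: float = 30.0
    tryptic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (6 <= lo <= hi <= 15):
            raise ValueError(f"length_range must lie within [6, 15], got {self.length_range}")
        if abs(sum(self.aa_freqs) - 1.0) > 1e-9 or len(self.aa_freqs) != 20:
            raise ValueError("aa_freqs must be a 20-vector summing to 1")
        for p in (
            self.charge_retention_base,
            self.charge_retention_proline,
            self.dropout_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if abs(sum(self.charge_probs.values()) - 1.0) > 1e-9:
            raise ValueError("charge_probs must sum to 1")


def _random_peptide(rng: np.random.Generator, params: SimulatorParams) -> str:
    lo, hi = params.length_range
    length = int(rng.integers(lo, hi + 1))
    letters = list(CANONICAL_AA)
    seq = "".join(rng.choice(letters, size=length, p=np.asarray(params.aa_freqs)))
    if params.tryptic:
        seq = seq[:-1] + ("K" if rng.random() < 0.5 else "R")
    return seq


def cleavage_scores(
    sequence: str, params: SimulatorParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Deterministic log-intensity scores for y1..y(L-1); noise added if a
    generator is supplied."""
    L = len(sequence)
    scores = np.zeros(L - 1)
    for k in range(1, L):
        plus1 = sequence[L - k]
        minus1 = sequence[L - k - 1]
        s = 0.0
        if plus1 == "P":
            s += params.beta_proline
        if k == L - 2:
            s += params.beta_len2
        if k == L - 4:
            s += params.beta_len4
        if minus1 in ALIPHATIC:
            s += params.beta_aliphatic
        if minus1 in ACIDIC:
            s += params.beta_acidic
        scores[k - 1] = s
    if rng is not None and params.noise_sd > 0:
        scores = scores + rng.normal(0.0, params.noise_sd, size=L - 1)
    return scores


def _draw_fragment_charge(
    fragment: str, precursor_charge: int, params: SimulatorParams, rng: np.random.Generator
) -> int:
    p_retain = params.charge_retention_base
    if "P" in fragment:
        p_retain = min(1.0, p_retain + params.charge_retention_proline)
    if precursor_charge == 1 or rng.random() < p_retain:
        return precursor_charge
    return int(rng.integers(1, precursor_charge))


def simulate_spectrum(
    sequence: str, precursor_charge: int, params: SimulatorParams, rng: np.random.Generator
) -> LibrarySpectrum:
    """Simulate one spectrum for a given peptide precursor."""
    L = len(sequence)
    scores = cleavage_scores(sequence, params, rng)
    intensities = np.exp(scores)
    intensities = intensities / intensities.max()  # base peak -> 1
    base_k = int(np.argmax(intensities)) + 1

    peaks = []
    for k in range(1, L):
        inten = float(intensities[k - 1])
        if k != base_k and rng.random() < params.dropout_prob:
            continue
        z = _draw_fragment_charge(sequence[-k:], precursor_charge, params, rng)
        peaks.append(
            PeakAnnotation(
                series="y",
                ordinal=k,
                fragment_charge=z,
                mz=y_ion_mz(sequence, k, z),
                intensity=inten,
            )
        )
    return LibrarySpectrum(
        sequence=sequence,
        precursor_charge=precursor_charge,
        collision_energy=params.collision_energy,
        peaks=tuple(peaks),
        source="simulated",
    )


def simulate_library(params: SimulatorParams) -> list[LibrarySpectrum]:
    """Simulate ``params.n_peptides`` spectra; deterministic given the seed.

    Peptide (sequence, charge) keys are unique within the library.
    """
    rng = np.random.default_rng(params.seed)
    charges = sorted(params.charge_probs)
    charge_p = np.array([params.charge_probs[c] for c in charges])
    library: list[LibrarySpectrum] = []
    seen: set[tuple[str, int]] = set()
    while len(library) < params.n_peptides:
        seq = _random_peptide(rng, params)
        z = int(rng.choice(charges, p=charge_p))
        if (seq, z) in seen:
            continue
        seen.add((seq, z))
        library.append(simulate_spectrum(seq, z, params, rng))
    return library


def confusable_library(
    n_families: int,
    params: SimulatorParams | None = None,
    family_size: int = 2,
    seed: int = 0,
) -> list[LibrarySpectrum]:
    """Families of near-isobaric peptides for the PSM grouping test.

    Members of a family share their precursor charge, their C-terminal
    six residues (hence at least six y ions with identical m/z, of which
    typically three or more survive charge assignment and detection loss)
    and their full residue composition (hence an identical precursor m/z):
    each variant permutes the N-terminal part of the founder sequence.
    This emulates the confusable peptide groups that arise in complex
    samples, where co-eluting near-isobaric peptides are mutual noise.
    """
    params = params or SimulatorParams()
    if params.length_range[1] < 10:
        raise ValueError("confusable families need founders of length >= 10")
    rng = np.random.default_rng(seed)
    charges = sorted(params.charge_probs)
    charge_p = np.array([params.charge_probs[c] for c in charges])
    library: list[LibrarySpectrum] = []
    seen: set[tuple[str, int]] = set()
    while sum(1 for _ in library) < n_families * family_size:
        founder = _random_peptide(rng, params)
        if len(founder) < 10:
            continue
        z = int(rng.choice(charges, p=charge_p))
        family = [founder]
        prefix = list(founder[:-6])
        for _ in range(family_size - 1):
            for _attempt in range(20):
                rng.shuffle(prefix)
                variant = "".join(prefix) + founder[-6:]
                if variant not in family:
                    family.append(variant)
                    break
        if len(family) < family_size:
            continue  # e.g. a homopolymeric prefix cannot be permuted
        if any((seq, z) in seen for seq in family):
            continue
        for seq in family:
            seen.add((seq, z))
            library.append(simulate_spectrum(seq, z, params, rng))
    return library


PRESETS: dict[str, dict] = {
    "flat": dict(
        beta_proline=0.0,
        beta_len2=0.0,
        beta_len4=0.0,
        beta_aliphatic=0.0,
        beta_acidic=0.0,
        charge_retention_proline=0.0,
        noise_sd=0.0,
        dropout_prob=0.0,
    ),
    "paperlike": {},  # the defaults: every effect switched on
    "proline-only": dict(
        beta_len2=0.0,
        beta_len4=0.0,
        beta_aliphatic=0.0,
        beta_acidic=0.0,
    ),
    "length-only": dict(
        beta_proline=0.0,
        beta_aliphatic=0.0,
        beta_acidic=0.0,
        charge_retention_proline=0.0,
    ),
}


def make_fixture(
    name: str, n_peptides: int = 1000, seed: int = 0
) -> tuple[list[LibrarySpectrum], SimulatorParams]:
    """Reproducible named corpus plus its ground-truth parameters."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = replace(
        SimulatorParams(n_peptides=n_peptides, seed=seed), **PRESETS[name]
    )
    return simulate_library(params), params
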