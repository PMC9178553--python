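"""Reading, writing and cleaning of MSP-style y-ion spectral libraries.

The library preparation pipeline mirrors common practice for building
beam-type CID training sets: parse NIST-dialect MSP text, strip residue
modifications, keep only singly- to triply-charged y ions up to y14,
collapse duplicate (sequence, precursor charge) entries onto the
best-annotated spectrum, and drop sparsely annotated peptides.
"""

from __future__ import annotations

import io
import re
import statistics
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, TextIO

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: y-ion ordinals representable by the 42-slot target (y1..y14).
MAX_ORDINAL = 14
#: fragment charges representable by the 42-slot target (1+..3+).
MAX_FRAGMENT_CHARGE = 3


class MSPParseError(ValueError):
    """Raised when an MSP record cannot be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class PeakAnnotation:
    """A single annotated fragment peak.

    ``series`` is the ion-series label ('y' after cleaning; raw labels such
    as 'b2' or '?' are retained by the parser so cleaning can act on them).
    ``ordinal`` is the fragment length k, ``fragment_charge`` the fragment
    charge z, ``mz`` the mass-to-charge in Th, ``intensity`` the relative
    abundance as stored in the library.
    """

    series: str
    ordinal: int
    fragment_charge: int
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.ordinal < 0:
            raise ValueError(f"ordinal must be >= 0, got {self.ordinal}")
        if self.fragment_charge < 0:
            raise ValueError(
                f"fragment_charge must be >= 0, got {self.fragment_charge}"
            )
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class LibrarySpectrum:
    """One peptide precursor and its annotated peaks.

    The identity key of a spectrum is ``(sequence, precursor_charge)``:
    the same sequence at a different charge state is a distinct peptide.
    """

    sequence: str
    precursor_charge: int
    collision_energy: float | None = None
    peaks: tuple[PeakAnnotation, ...] = field(default_factory=tuple)
    source: str = ""

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError(
                f"precursor_charge must be >= 1, got {self.precursor_charge}"
            )
        object.__setattr__(self, "peaks", tuple(self.peaks))

    @property
    def key(self) -> tuple[str, int]:
        return (self.sequence, self.precursor_charge)


# --------------------------------------------------------------------------
# MSP parsing / writing
# --------------------------------------------------------------------------

_NAME_RE = re.compile(r"^Name:\s*(\S+)/(\d+)\s*$")
_ANNOT_RE = re.compile(r"^([a-zA-Z]+)(\d+)(?:\^(\d+))?$")

#: Comment: keys accepted as the collision energy, first match wins.
CE_COMMENT_KEYS = ("CE", "NCE", "Collision_energy")


def _parse_annotation(raw: str) -> tuple[str, int, int]:
    """Split a peak annotation like ``y5^2`` into (series, ordinal, charge).

    Unparseable annotations come back with the raw label as the series and
    ordinal/charge 0, so that the cleaning step can discard them.
    """
    token = raw.strip().strip('"').split("/")[0].split(",")[0]
    m = _ANNOT_RE.match(token)
    if m is None:
        return (raw.strip(), 0, 0)
    series, ordinal, charge = m.group(1), int(m.group(2)), m.group(3)
    return (series, ordinal, int(charge) if charge else 1)


def _parse_comment(line: str) -> tuple[float | None, str]:
    ce = None
    for key in CE_COMMENT_KEYS:
        m = re.search(rf"\b{key}=([0-9.]+)", line)
        if m:
            ce = float(m.group(1))
            break
    m = re.search(r"\bSource=(\S+)", line)
    return ce, (m.group(1) if m else "")


def read_msp(stream: TextIO | str) -> list[LibrarySpectrum]:
    """Parse a NIST-dialect MSP text stream into a list of spectra.

    Each record is a ``Name: SEQUENCE/charge`` line, an optional ``Comment:``
    line (collision energy read from a ``CE=`` style key), a ``Num peaks:``
    line and then one ``mz<TAB>intensity<TAB>annotation`` line per peak.
    Record order is preserved.  A peak-count mismatch produces a warning and
    keeps the peaks actually present; a malformed Name line raises
    :class:`MSPParseError` with the offending line number.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    spectra: list[LibrarySpectrum] = []
    seq: str | None = None
    charge = 0
    ce: float | None = None
    source = ""
    declared: int | None = None
    peaks: list[PeakAnnotation] = []

    def flush() -> None:
        nonlocal seq
        if seq is None:
            return
        if declared is not None and declared != len(peaks):
            warnings.warn(
                f"record '{seq}/{charge}' declares {declared} peaks "
                f"but has {len(peaks)}; keeping the actual peaks",
                stacklevel=3,
            )
        spectra.append(
            LibrarySpectrum(
                sequence=seq,
                precursor_charge=charge,
                collision_energy=ce,
                peaks=tuple(peaks),
                source=source,
            )
        )
        seq = None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("Name:"):
            flush()
            m = _NAME_RE.match(line)
            if m is None:
                raise MSPParseError(f"malformed Name line {line!r}", lineno)
            seq, charge = m.group(1), int(m.group(2))
            ce, source, declared, peaks = None, "", None, []
        elif line.startswith("Comment:"):
            ce, source = _parse_comment(line)
        elif line.startswith("Num peaks:") or line.startswith("NumPeaks:"):
            declared = int(line.split(":", 1)[1])
        else:
            if seq is None:
                raise MSPParseError(f"peak line outside a record: {line!r}", lineno)
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise MSPParseError(f"malformed peak line {line!r}", lineno)
            mz, intensity = float(fields[0]), float(fields[1])
            series, ordinal, z = (
                _parse_annotation(fields[2]) if len(fields) > 2 else ("?", 0, 0)
            )
            peaks.append(PeakAnnotation(series, ordinal, z, mz, intensity))
    flush()
    return spectra


def write_msp(library: Iterable[LibrarySpectrum], stream: TextIO) -> None:
    """Write spectra in the same MSP dialect :func:`read_msp` accepts."""
    for spec in library:
        stream.write(f"Name: {spec.sequence}/{spec.precursor_charge}\n")
        comment_parts = []
        if spec.collision_energy is not None:
            comment_parts.append(f"CE={spec.collision_energy!r}")
        if spec.source:
            comment_parts.append(f"Source={spec.source}")
        if comment_parts:
            stream.write("Comment: " + " ".join(comment_parts) + "\n")
        stream.write(f"Num peaks: {len(spec.peaks)}\n")
        for p in spec.peaks:
            label = p.series
            if p.ordinal > 0:
                label = f"{p.series}{p.ordinal}"
                if p.fragment_charge > 1:
                    label += f"^{p.fragment_charge}"
            stream.write(f"{p.mz!r}\t{p.intensity!r}\t{label}\n")
        stream.write("\n")


# --------------------------------------------------------------------------
# Cleaning pipeline
# --------------------------------------------------------------------------

_MOD_BRACKET_RE = re.compile(r"\[[^\]]*\]|\([^)]*\)")


def strip_modifications(spectrum: LibrarySpectrum) -> LibrarySpectrum:
    """Drop modification markup, leaving the plain canonical sequence.

    Bracketed mass tags (``C[+57.021]``) are removed and lowercase letters
    (a common modified-residue convention) are uppercased; modified residues
    are thereby encoded as their unmodified counterparts.  A residue that
    cannot be mapped to one of the 20 canonical letters is an error.
    """
    seq = _MOD_BRACKET_RE.sub("", spectrum.sequence).upper()
    for ch in seq:
        if ch not in CANONICAL_AA:
            raise ValueError(
                f"residue {ch!r} in {spectrum.sequence!r} is not a canonical amino acid"
            )
    if seq == spectrum.sequence:
        return spectrum
    return replace(spectrum, sequence=seq)


def drop_b_ions(spectrum: LibrarySpectrum) -> LibrarySpectrum:
    """Keep only y ions the 42-slot target can represent.

    Retains peaks with series 'y', ordinal 1..14 and fragment charge 1..3;
    b ions, a ions, neutral losses and unannotated peaks are removed, as are
    y ions outside the representable ordinal/charge range.
    """
    kept = tuple(
        p
        for p in spectrum.peaks
        if p.series == "y"
        and 1 <= p.ordinal <= MAX_ORDINAL
        and 1 <= p.fragment_charge <= MAX_FRAGMENT_CHARGE
        and p.ordinal <= len(spectrum.sequence) - 1
    )
    return replace(spectrum, peaks=kept)


def deduplicate(libraries: list[list[LibrarySpectrum]]) -> list[LibrarySpectrum]:
    """Merge several source libraries, one spectrum per (sequence, charge).

    Among duplicates the spectrum with the most peaks survives; ties are
    broken in favour of the earlier source (and the earlier record within a
    source).  Output order is first-appearance order of each key.
    """
    best: dict[tuple[str, int], LibrarySpectrum] = {}
    order: list[tuple[str, int]] = []
    for library in libraries:
        for spec in library:
            if spec.key not in best:
                best[spec.key] = spec
                order.append(spec.key)
            elif len(spec.peaks) > len(best[spec.key].peaks):
                best[spec.key] = spec
    return [best[k] for k in order]


def filter_min_peaks(
    library: list[LibrarySpectrum], min_peaks: int = 3
) -> list[LibrarySpectrum]:
    """Drop peptides annotated with fewer than ``min_peaks`` y-ion peaks."""
    if min_peaks < 1:
        raise ValueError(f"min_peaks must be >= 1, got {min_peaks}")
    return [s for s in library if len(s.peaks) >= min_peaks]


def clean_library(
    libraries: list[list[LibrarySpectrum]], min_peaks: int = 3
) -> list[LibrarySpectrum]:
    """Full preparation pipeline: strip mods, keep y ions, dedup, filter."""
    cleaned = [
        [drop_b_ions(strip_modifications(s)) for s in lib] for lib in libraries
    ]
    return filter_min_peaks(deduplicate(cleaned), min_peaks=min_peaks)


def summarize(library: list[LibrarySpectrum]) -> dict:
    """Peptide count, mean/median peaks per peptide and peak-count histogram."""
    counts = [len(s.peaks) for s in library]
    hist = dict(sorted(Counter(counts).items()))
    if not counts:
        return {
            "peptides": 0,
            "mean_peaks": None,
            "median_peaks": None,
            "histogram": {},
        }
    return {
        "peptides": len(counts),
        "mean_peaks": sum(counts) / len(counts),
        "median_peaks": statistics.median(counts),
        "histogram": hist,
    }
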