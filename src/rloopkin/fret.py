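"""FRET ratio readout of gRNA loading and dye-labelling efficiency.

The RNP-loading assay uses a doubly labelled (Cy3 donor / Cy5 acceptor)
Cas9: in the apo state the labelled residues are close and energy transfer
is high; loading a gRNA moves them apart and transfer drops.  The proxy
readout is (ratio)_A: the acceptor emission peak under donor excitation
(530 nm, sensitized emission, optionally corrected for donor
bleed-through) divided by the acceptor peak under direct acceptor
excitation (630 nm).  Peaks are quantified as the mean intensity over a
+/-10 nm window around the acceptor emission maximum, which is more robust
than a single-pixel maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmissionSpectrum",
    "RatioA",
    "ratio_a",
    "labelling_efficiency",
]

#: half-width of the acceptor quantification window (nm)
_PEAK_HALFWIDTH = 10.0
#: default acceptor search window when locating the peak (nm)
_ACCEPTOR_SEARCH = (650.0, 700.0)


@dataclass
class EmissionSpectrum:
    """Fluorescence emission spectrum under one excitation wavelength
    (530 nm excitation scanned 550-800 nm, 630 nm excitation 650-800 nm)."""

    excitation_nm: float
    emission_nm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.emission_nm = np.asarray(self.emission_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.emission_nm.size != self.intensity.size:
            raise ValueError("emission grid and intensity must have equal length")
        if np.any(np.diff(self.emission_nm) <= 0):
            raise ValueError("emission grid must be strictly increasing")
        if self.emission_nm[0] <= self.excitation_nm:
            raise ValueError("emission must start above the excitation wavelength")

    def window_mean(self, center: float, halfwidth: float = _PEAK_HALFWIDTH) -> float:
        mask = np.abs(self.emission_nm - center) <= halfwidth
        if not np.any(mask):
            raise ValueError(
                f"spectrum does not cover the window {center}+/-{halfwidth} nm"
            )
        return float(np.mean(self.intensity[mask]))

    def peak_in(self, lo: float, hi: float) -> float:
        mask = (self.emission_nm >= lo) & (self.emission_nm <= hi)
        if not np.any(mask):
            raise ValueError(f"spectrum does not cover {lo}-{hi} nm")
        idx = np.argmax(self.intensity[mask])
        return float(self.emission_nm[mask][idx])


@dataclass
class RatioA:
    """(ratio)_A = sensitized acceptor emission / direct-excitation
    acceptor emission; high in the apo (high-FRET) state, low once a gRNA
    is loaded."""

    value: float
    sensitized: float
    direct: float
    peak_window_nm: tuple


def ratio_a(
    spec530: EmissionSpectrum,
    spec630: EmissionSpectrum,
    donor_only_reference: EmissionSpectrum | None = None,
    noise_floor: float = 1e-9,
) -> RatioA:
    """(ratio)_A from a donor-excitation / acceptor-excitation spectrum pair.

    The acceptor peak position is located in the 630 nm-excitation spectrum
    (search window 650-700 nm) and both spectra are quantified as the mean
    intensity over +/-10 nm around it.  When a donor-only reference is
    supplied, its contribution in the acceptor window -- scaled by the
    donor-peak intensities of the two 530 nm spectra -- is subtracted from
    the sensitized emission (donor bleed-through correction).
    """
    center = spec630.peak_in(*_ACCEPTOR_SEARCH)
    direct = spec630.window_mean(center)
    if direct <= noise_floor:
        raise ValueError(
            "acceptor peak below the noise floor in the direct-excitation spectrum"
        )
    sensitized = spec530.window_mean(center)
    if donor_only_reference is not None:
        donor_center = donor_only_reference.peak_in(
            donor_only_reference.emission_nm[0], center - _PEAK_HALFWIDTH
        )
        ref_donor = donor_only_reference.window_mean(donor_center)
        sample_donor = spec530.window_mean(donor_center)
        if ref_donor > 0:
            scale = sample_donor / ref_donor
            sensitized -= scale * donor_only_reference.window_mean(center)
    sensitized = max(sensitized, 0.0)
    return RatioA(
        value=sensitized / direct,
        sensitized=sensitized,
        direct=direct,
        peak_window_nm=(center - _PEAK_HALFWIDTH, center + _PEAK_HALFWIDTH),
    )


def labelling_efficiency(
    a280: float,
    a552: float,
    a650: float,
    eps_protein: float,
    eps_cy3: float,
    eps_cy5: float,
    correction_280: tuple = (0.08, 0.05),
) -> dict:
    """Protein concentration and dye:protein labelling ratios from
    absorbance readings.

    Dye concentrations are A/eps at their absorption maxima (552 nm Cy3,
    650 nm Cy5); the protein A280 is corrected for each dye's fractional
    absorbance at 280 nm (``correction_280`` = (Cy3 fraction, Cy5
    fraction)) before dividing by the protein extinction coefficient.
    Returns concentrations in the units implied by the extinction
    coefficients (M for M^-1 cm^-1 and a 1 cm path).
    """
    for name, a in (("a280", a280), ("a552", a552), ("a650", a650)):
        if a < 0:
            raise ValueError(f"{name} must be >= 0")
    for name, e in (("eps_protein", eps_protein), ("eps_cy3", eps_cy3), ("eps_cy5", eps_cy5)):
        if e <= 0:
            raise ValueError(f"{name} must be > 0")
    cy3 = a552 / eps_cy3
    cy5 = a650 / eps_cy5
    a280_corrected = a280 - correction_280[0] * a552 - correction_280[1] * a650
    if a280_corrected <= 0:
        raise ValueError("corrected A280 is <= 0: dye correction exceeds the signal")
    protein = a280_corrected / eps_protein
    return {
        "protein_conc": protein,
        "cy3_per_protein": cy3 / protein,
        "cy5_per_protein": cy5 / protein,
    }
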