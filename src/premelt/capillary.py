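"""Capillary-wave analysis: Fourier spectra of interface fluctuations,
stiffness estimation, and interfacial energetics.

Capillary-wave theory for a crystal-liquid interface predicts mode
amplitudes <|dh_k|^2> = kB T / (L gamma k^2) for a flat interface of
length L (k = 2 pi m / L) and <|dR_k|^2> = kB T / (2 pi gamma k^2 R0)
for a circular interface of mean radius R0 (k = m / R0).  Comparing the
measured proportionality constant at small k with theory yields the
interfacial stiffness gamma.

DFT convention: dh(x) = sum_k dh_k exp(i k x), i.e. the forward transform
divided by the number of grid points.  +-m modes are pooled (Hermitian
redundancy for real heights) and m = 0 is excluded (the mean is
subtracted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import K_MAX_DEFAULT, KB
from .synth import HeightSample

__all__ = [
    "Spectrum", "StiffnessFit", "AssemblyEnergy",
    "flat_spectrum", "circular_spectrum", "fit_stiffness",
    "assembly_energy", "theory_spectrum",
]


@dataclass
class Spectrum:
    """Mode-resolved mean-square fluctuation amplitudes.

    k = 2 pi m / L for flat geometry, k = m / R0 for circular; amplitudes
    are in nm^2 with frame-to-frame standard errors.
    """

    m: np.ndarray
    k: np.ndarray
    amplitude: np.ndarray
    stderr: np.ndarray
    n_frames: int
    geometry: str                  # 'flat' | 'circular'
    length: float                  # L or R0 (nm)

    def __post_init__(self) -> None:
        for name in ("m", "k", "amplitude", "stderr"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be non-negative")
        if np.any(self.m == 0):
            raise ValueError("m = 0 must be excluded")


@dataclass
class StiffnessFit:
    """Interfacial stiffness from a weighted small-k capillary fit."""

    gamma: float                   # pN
    stderr: float                  # pN
    k_max: float                   # nm^-1
    temperature: float             # K
    geometry: str
    n_modes: int
    chi2_reduced: float


@dataclass
class AssemblyEnergy:
    """Interfacial free-energy change of merging two interfaces into one:
    dF = gamma (Pf - P1 - P2)."""

    P1: float
    P2: float
    Pf: float
    gamma: float
    temperature: float
    dF_pn_nm: float
    dF_kBT: float


def _mode_table(deltas: np.ndarray, n_pool: int) -> tuple[np.ndarray,
                                                          np.ndarray]:
    """Per-frame pooled mode amplitudes |c_m|^2 for m = 1..n_pool.

    deltas: (n_frames, n_grid) real fluctuations; returns (n_frames,
    n_pool) amplitudes with +-m averaged (equal for real input).
    """
    n_grid = deltas.shape[1]
    coeff = np.fft.fft(deltas, axis=1) / n_grid
    pos = np.abs(coeff[:, 1:n_pool + 1]) ** 2
    neg = np.abs(coeff[:, -1:-n_pool - 1:-1]) ** 2
    return 0.5 * (pos + neg)


def _spectrum_from_frames(values: np.ndarray, geometry: str, length: float,
                          n_modes: int | None = None) -> Spectrum:
    n_frames, n_grid = values.shape
    m_max = (n_grid - 1) // 2
    if n_modes is not None:
        m_max = min(m_max, n_modes)
    deltas = values - values.mean(axis=1, keepdims=True)
    amps = _mode_table(deltas, m_max)
    mean = amps.mean(axis=0)
    if n_frames > 1:
        se = amps.std(axis=0, ddof=1) / np.sqrt(n_frames)
    else:
        se = np.zeros(m_max)
    m = np.arange(1, m_max + 1)
    k = 2 * np.pi * m / length if geometry == "flat" else m / length
    return Spectrum(m, k, mean, se, n_frames, geometry, length)


def flat_spectrum(height_samples: Sequence[HeightSample],
                  L: float | None = None,
                  n_modes: int | None = None) -> Spectrum:
    """Frame-averaged Fourier spectrum <|dh_k|^2> of flat-interface heights.

    All samples must share a uniform grid and length; the mean height is
    subtracted per frame; +-m pooled; standard errors over frames.
    """
    if len(height_samples) < 2:
        raise ValueError("need at least 2 frames for a spectrum")
    n_grid = height_samples[0].n_grid
    L0 = float(L if L is not None else height_samples[0].length)
    for s in height_samples:
        if s.n_grid != n_grid:
            raise ValueError("all frames must share a uniform common grid")
        if abs(s.length - L0) > 1e-9 * L0:
            raise ValueError("all frames must share the interface length")
    values = np.stack([s.values for s in height_samples])
    return _spectrum_from_frames(values, "flat", L0, n_modes)


def circular_spectrum(radius_samples: Sequence[HeightSample],
                      n_modes: int | None = None) -> Spectrum:
    """Frame-averaged angular spectrum <|dR_k|^2> of closed-interface radii.

    Each frame carries its own mean radius; k is assigned as m over the
    ensemble-mean R0.  Frames whose R0 varies by more than 20% are
    rejected as non-stationary.
    """
    if len(radius_samples) < 2:
        raise ValueError("need at least 2 frames for a spectrum")
    n_grid = radius_samples[0].n_grid
    r0s = np.array([float(np.mean(s.values)) for s in radius_samples])
    if (r0s.max() - r0s.min()) > 0.2 * r0s.mean():
        raise ValueError("mean radius varies by more than 20% across "
                         "frames; ensemble not stationary")
    for s in radius_samples:
        if s.n_grid != n_grid:
            raise ValueError("all frames must share a uniform angle grid")
    values = np.stack([s.values for s in radius_samples])
    return _spectrum_from_frames(values, "circular", float(r0s.mean()),
                                 n_modes)


def fit_stiffness(spectrum: Spectrum, T: float,
                  k_max: float = K_MAX_DEFAULT,
                  xi: float | None = None) -> StiffnessFit:
    """Interfacial stiffness from the small-k capillary spectrum.

    Fits A_k k^2 (which capillary theory predicts to be the constant
    kB T/(L gamma) for flat, kB T/(2 pi R0 gamma) for circular geometry)
    by weighted least squares over modes with k < k_max, weights from
    per-mode standard errors.  ``xi`` optionally deconvolves the Gaussian
    coarse-graining used to locate the interface by multiplying amplitudes
    by exp(k^2 xi^2) before fitting (appropriate for heights extracted
    from a coarse-grained field, not for raw height samples).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    sel = spectrum.k < k_max
    if sel.sum() < 3:
        raise ValueError(
            f"need at least 3 modes with k < {k_max}; spectrum has "
            f"{int(sel.sum())}")
    k = spectrum.k[sel]
    amp = spectrum.amplitude[sel].copy()
    se = spectrum.stderr[sel].copy()
    if xi is not None:
        boost = np.exp(k ** 2 * xi ** 2)
        amp *= boost
        se *= boost
    y = amp * k ** 2
    sy = se * k ** 2
    if np.all(sy > 0):
        w = 1.0 / sy ** 2
        C = float(np.sum(w * y) / np.sum(w))
        C_se = float(np.sqrt(1.0 / np.sum(w)))
        chi2 = float(np.sum(w * (y - C) ** 2))
    else:
        C = float(np.mean(y))
        C_se = float(np.std(y, ddof=1) / np.sqrt(y.size)) if y.size > 1 \
            else 0.0
        chi2 = 0.0
    if C <= 0:
        raise ValueError("non-positive fitted spectral constant: input is "
                         "not capillary-like")
    kT = KB * T
    if spectrum.geometry == "flat":
        gamma = kT / (spectrum.length * C)
    else:
        gamma = kT / (2 * np.pi * spectrum.length * C)
    gamma_se = gamma * C_se / C
    dof = max(1, y.size - 1)
    return StiffnessFit(gamma, gamma_se, k_max, T, spectrum.geometry,
                        int(y.size), chi2 / dof)


def assembly_energy(P1: float, P2: float, Pf: float, gamma: float,
                    T: float) -> AssemblyEnergy:
    """Interfacial free-energy change when two interfaces of perimeters P1
    and P2 merge into one of perimeter Pf: dF = gamma (Pf - P1 - P2),
    reported in pN nm and in units of kB T."""
    if min(P1, P2, Pf) <= 0 or gamma <= 0 or T <= 0:
        raise ValueError("perimeters, gamma and T must be positive")
    dF = gamma * (Pf - P1 - P2)
    return AssemblyEnergy(P1, P2, Pf, gamma, T, dF, dF / (KB * T))


def theory_spectrum(gamma: float, T: float, geometry: str,
                    length: float, modes: Sequence[int]) -> Spectrum:
    """Analytic capillary-wave amplitudes for the requested modes (the
    theory overlay for measured spectra)."""
    if gamma <= 0 or T <= 0:
        raise ValueError("gamma and T must be positive")
    m = np.asarray(modes, dtype=int)
    if np.any(m == 0):
        raise ValueError("m = 0 has no capillary amplitude")
    m = np.abs(m)
    if geometry == "flat":
        k = 2 * np.pi * m / length
        amp = KB * T / (length * gamma * k ** 2)
    elif geometry == "circular":
        k = m / length
        amp = KB * T / (2 * np.pi * gamma * length * k ** 2)
    else:
        raise ValueError("geometry must be 'flat' or 'circular'")
    return Spectrum(m, k, amp, np.zeros_like(amp), 0, geometry,
                    float(length))
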