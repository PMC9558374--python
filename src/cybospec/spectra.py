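"""Spectral assembly: Gaussian broadening, averaging, shift arithmetic.

Stick transitions (wavenumber, oscillator strength) are broadened with
Gaussian line shapes of fixed half-width at half-maximum (default 600
cm⁻¹) normalised so that each band integrates to f / 4.319×10⁻⁹ on the
wavenumber axis, giving molar absorptivity ε in M⁻¹ cm⁻¹. Per-cluster
spectra are combined as weighted point-wise means using the cluster
populations, and solvatochromic shift tables are assembled with the
composition rule

    Total = λ_cf + (λ_c2qm − λ_c0qm) + (λ_vib − λ_pmm)

— the collective-frame band position corrected by the explicit-QM
solvent effect evaluated at the cluster centroid and by the vibronic
displacement — followed by population-weighted averaging over clusters
and shifts relative to a reference solvent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CybospecError
from .units import OSCILLATOR_TO_ABSORPTIVITY, nm_to_wavenumber

__all__ = [
    "Spectrum",
    "broaden",
    "average_spectra",
    "compose_total",
    "weighted_average",
    "shift_vs_reference",
    "build_shift_table",
]

_SIGMA_PER_HWHM = 1.0 / np.sqrt(2.0 * np.log(2.0))


@dataclass
class Spectrum:
    """Broadened molar-absorptivity curve on a wavelength grid (nm)."""

    grid: np.ndarray               # nm
    epsilon: np.ndarray            # M⁻¹ cm⁻¹
    hwhm: float                    # cm⁻¹

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.grid.shape != self.epsilon.shape:
            raise CybospecError("grid and epsilon must have matching shapes")

    @property
    def lambda_max(self) -> float:
        return float(self.grid[int(np.argmax(self.epsilon))])

    @property
    def epsilon_max(self) -> float:
        return float(self.epsilon.max()) if len(self.epsilon) else 0.0


def broaden(
    transitions: list[tuple[float, float]],
    hwhm: float = 600.0,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Gaussian-broaden stick transitions into an ε(λ) curve.

    ``transitions`` holds (wavenumber cm⁻¹, oscillator strength) pairs;
    ``grid`` is the output wavelength grid in nm (default 200–800 nm at
    0.1 nm). Each stick becomes a Gaussian in wavenumber with σ =
    HWHM/√(2 ln 2), scaled so its wavenumber integral is
    f / 4.319×10⁻⁹ (the standard oscillator-strength ↔ band-area
    conversion), hence ε in M⁻¹ cm⁻¹.
    """
    if hwhm <= 0:
        raise CybospecError(f"hwhm must be positive, got {hwhm}")
    if grid is None:
        grid = np.arange(200.0, 800.0 + 1e-9, 0.1)
    grid = np.asarray(grid, dtype=float)
    nu_grid = nm_to_wavenumber(grid)
    eps = np.zeros_like(nu_grid)
    if not transitions:
        warnings.warn("no transitions supplied: returning a zero spectrum")
        return Spectrum(grid=grid, epsilon=eps, hwhm=hwhm)
    sigma = hwhm * _SIGMA_PER_HWHM
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    for nu_k, f_k in transitions:
        area = f_k / OSCILLATOR_TO_ABSORPTIVITY
        eps += area * norm * np.exp(-((nu_grid - nu_k) ** 2) / (2.0 * sigma**2))
    return Spectrum(grid=grid, epsilon=eps, hwhm=hwhm)


def average_spectra(spectra: list[Spectrum], weights) -> Spectrum:
    """Point-wise weighted mean of spectra sharing one grid."""
    if not spectra:
        raise CybospecError("no spectra to average")
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(spectra):
        raise CybospecError("one weight per spectrum required")
    if abs(weights.sum() - 1.0) > 0.01:
        raise CybospecError(f"weights must sum to 1 ± 0.01, got {weights.sum()}")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid.shape != grid.shape or not np.allclose(s.grid, grid):
            raise CybospecError("spectra are not on a common grid")
    eps = np.zeros_like(grid)
    for w, s in zip(weights, spectra):
        eps += w * s.epsilon
    return Spectrum(grid=grid, epsilon=eps, hwhm=spectra[0].hwhm)


def compose_total(
    lambda_cf: float,
    lambda_c2qm: float,
    lambda_c0qm: float,
    lambda_pmm_vib: float,
    lambda_pmm: float,
) -> float:
    """Per-cluster composed band position (nm).

    Collective-frame maximum, corrected by the explicit-QM solvent
    effect at the centroid (with-QM minus without-QM) and by the
    vibronic displacement (vibronic PMM minus bare PMM):
    λ_cf + (λ_c2qm − λ_c0qm) + (λ_vib − λ_pmm). Full precision is kept;
    round only at reporting.
    """
    vals = [lambda_cf, lambda_c2qm, lambda_c0qm, lambda_pmm_vib, lambda_pmm]
    if not all(np.isfinite(vals)):
        raise CybospecError("all five band positions must be finite")
    return lambda_cf + (lambda_c2qm - lambda_c0qm) + (lambda_pmm_vib - lambda_pmm)


def weighted_average(values, weights) -> float:
    """Population-weighted mean of per-cluster band positions (nm)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise CybospecError("values and weights must have the same length")
    if abs(weights.sum() - 1.0) > 0.01:
        raise CybospecError(f"weights must sum to 1 ± 0.01, got {weights.sum()}")
    return float(values @ weights)


def shift_vs_reference(averages: dict[str, float], reference_solvent: str) -> dict[str, float]:
    """Per-solvent shift Δ_s = ⟨λ⟩_s − ⟨λ⟩_ref (nm); Δ_ref = 0."""
    if reference_solvent not in averages:
        raise CybospecError(f"reference solvent {reference_solvent!r} not in table")
    ref = averages[reference_solvent]
    return {s: v - ref for s, v in averages.items()}


def build_shift_table(
    per_solvent_rows: dict[str, dict[str, list[float]]],
    reference_solvent: str,
) -> pd.DataFrame:
    """Assemble the per-cluster composition/averaging table.

    ``per_solvent_rows[solvent]`` must provide equal-length lists under
    the keys ``cf``, ``c2qm``, ``c0qm``, ``pmm_vib``, ``pmm``, and
    ``weight`` (cluster populations summing to 1 ± 0.01). The output has
    one row per (solvent, cluster) with the composed Total, plus
    summary rows holding the weighted Average and the shift versus the
    reference solvent. Reported values are rounded to 0.1 nm; the
    Average/shift arithmetic runs at full precision.
    """
    records = []
    averages: dict[str, float] = {}
    for solvent, rows in per_solvent_rows.items():
        keys = ("cf", "c2qm", "c0qm", "pmm_vib", "pmm", "weight")
        missing = [k for k in keys if k not in rows]
        if missing:
            raise CybospecError(f"{solvent}: missing row(s) {missing}")
        n = len(rows["cf"])
        if any(len(rows[k]) != n for k in keys):
            raise CybospecError(f"{solvent}: per-cluster rows have unequal lengths")
        totals = [
            compose_total(rows["cf"][i], rows["c2qm"][i], rows["c0qm"][i],
                          rows["pmm_vib"][i], rows["pmm"][i])
            for i in range(n)
        ]
        averages[solvent] = weighted_average(totals, rows["weight"])
        for i in range(n):
            records.append(
                {
                    "solvent": solvent,
                    "cluster": i + 1,
                    "weight": rows["weight"][i],
                    "lambda_cf": rows["cf"][i],
                    "lambda_c2qm": rows["c2qm"][i],
                    "lambda_c0qm": rows["c0qm"][i],
                    "lambda_pmm_vib": rows["pmm_vib"][i],
                    "lambda_pmm": rows["pmm"][i],
                    "total": round(totals[i], 1),
                }
            )
    shifts = shift_vs_reference(averages, reference_solvent)
    table = pd.DataFrame.from_records(records)
    table["average"] = table["solvent"].map(lambda s: round(averages[s], 1))
    table["delta_vs_reference"] = table["solvent"].map(lambda s: round(shifts[s], 1))
    return table
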