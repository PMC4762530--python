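"""Mass arithmetic and the averagine isotopic-envelope model.

The averagine model predicts an intact protein's aggregate isotope
distribution from its mass alone, by scaling an "average amino acid"
elemental composition (Senko's averagine) and convolving per-element
isotope distributions.  Peaks are aggregated per neutron number; each
aggregate peak carries its abundance-weighted mean mass.
"""

from __future__ import annotations

import numpy as np
from pyteomics import mass as pmass

PROTON = 1.00727646677  # Da, mass of H+
WATER = pmass.calculate_mass(formula="H2O")

#: Senko averagine: average elemental composition per amino-acid residue
AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
AVERAGINE_MONO_MASS = sum(
    n * pmass.nist_mass[el][0][0] for el, n in AVERAGINE.items()
)


def monoisotopic_mass(
    sequence: str, modifications: list[tuple[str, float, int]] | None = None
) -> float:
    """Monoisotopic mass of a (modified) polypeptide in Da.

    Residue masses + one water + the sum of modification mass shifts.
    """
    m = pmass.calculate_mass(sequence=sequence)
    if modifications:
        m += sum(shift for _name, shift, _pos in modifications)
    return m


def _element_isotope_arrays(element: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom isotope distribution as (prob, prob*mass) arrays indexed by
    neutron offset from the lightest naturally occurring isotope."""
    isotopes = [
        (m, ab)
        for key, (m, ab) in pmass.nist_mass[element].items()
        if key != 0 and ab > 0
    ]
    isotopes.sort()
    base_nominal = round(isotopes[0][0])
    size = round(isotopes[-1][0]) - base_nominal + 1
    p = np.zeros(size)
    pm = np.zeros(size)
    for m, ab in isotopes:
        k = round(m) - base_nominal
        p[k] += ab
        pm[k] += ab * m
    return p, pm


def _convolve_pair(
    a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray], max_len: int
) -> tuple[np.ndarray, np.ndarray]:
    pa, ma = a
    pb, mb = b
    p = np.convolve(pa, pb)[:max_len]
    m = (np.convolve(ma, pb) + np.convolve(pa, mb))[:max_len]
    return p, m


def _power_distribution(
    base: tuple[np.ndarray, np.ndarray], n: int, max_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Isotope distribution of n identical atoms (convolution power),
    by exponentiation-by-squaring with tail truncation."""
    result = (np.array([1.0]), np.array([0.0]))
    sq = base
    while n > 0:
        if n & 1:
            result = _convolve_pair(result, sq, max_len)
        n >>= 1
        if n:
            sq = _convolve_pair(sq, sq, max_len)
    return result


def averagine_composition(monoisotopic: float) -> dict[str, int]:
    """Integer elemental composition of an averagine pseudo-protein with
    approximately the given monoisotopic mass."""
    if monoisotopic <= 0:
        raise ValueError("mass must be positive")
    n_units = monoisotopic / AVERAGINE_MONO_MASS
    return {el: max(int(round(r * n_units)), 0) for el, r in AVERAGINE.items()}


def averagine_isotope_pattern(
    monoisotopic: float, prune: float = 1e-5, max_len: int = 120
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate isotope pattern for an averagine model protein.

    Returns ``(masses, probs)``: absolute neutral masses of the aggregate
    isotope peaks (shifted so the first peak sits exactly at
    ``monoisotopic``) and their relative abundances (summing to 1 after
    pruning peaks below ``prune`` x the maximum).
    """
    comp = averagine_composition(monoisotopic)
    dist = (np.array([1.0]), np.array([0.0]))
    for el, n in comp.items():
        if n == 0:
            continue
        dist = _convolve_pair(
            dist, _power_distribution(_element_isotope_arrays(el), n, max_len), max_len
        )
    p, pm = dist
    keep = p > prune * p.max()
    # mean mass of each aggregate peak, re-centred on the requested mass
    masses = pm[keep] / p[keep]
    masses += monoisotopic - masses[0]
    probs = p[keep] / p[keep].sum()
    return masses, probs


def envelope_profile(
    mz_grid: np.ndarray,
    neutral_mass: float,
    charge: int,
    resolving_power: float,
    prune: float = 1e-5,
) -> np.ndarray:
    """Unit-area isotopic envelope of one proteoform sampled on ``mz_grid``.

    Gaussian peak shapes with FWHM = m/z / resolving_power; total profile
    normalised to unit sum so fitted coefficients compare abundances.
    """
    if charge <= 0:
        raise ValueError("charge must be a positive integer")
    masses, probs = averagine_isotope_pattern(neutral_mass, prune=prune)
    centers = (masses + charge * PROTON) / charge
    sigma = centers / (resolving_power * 2.0 * np.sqrt(2.0 * np.log(2.0)))
    profile = np.zeros_like(mz_grid, dtype=float)
    for c, p, s in zip(centers, probs, sigma):
        profile += p * np.exp(-0.5 * ((mz_grid - c) / s) ** 2)
    total = profile.sum()
    if total > 0:
        profile /= total
    return profile
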