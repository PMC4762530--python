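"""Core domain types shared across the pipeline.

A *proteoform* is one specific molecular form of a protein — a sequence
(possibly carrying a coding variant) plus a set of co-occurring PTMs.
Top-down (TD) MS observes proteoforms as intact neutral masses; bottom-up
(BU) MS observes tryptic peptides and infers proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: statuses used throughout the concordance layer
DE = "DE"
NOT_DE = "not_DE"
NOT_DETECTED = "not_detected"
STATUSES = (DE, NOT_DE, NOT_DETECTED)


@dataclass
class ProteoformRecord:
    """One proteoform: sequence, modifications and intact monoisotopic mass.

    ``modifications`` is a list of ``(name, mass_shift_da, position)`` with
    1-based residue positions.  ``variant`` is ``(kind, description)`` with
    kind in {"cSNP", "NSJ"} and a description like ``"E110V"``.
    ``fragment_of`` links a proteolytic fragment to its parent proteoform.
    """

    proteoform_id: str
    protein_accession: str
    sequence: str
    modifications: list[tuple[str, float, int]] = field(default_factory=list)
    monoisotopic_mass: float = 0.0
    variant: tuple[str, str] | None = None
    fragment_of: str | None = None

    def __post_init__(self) -> None:
        for name, _shift, pos in self.modifications:
            if not (1 <= pos <= len(self.sequence)):
                raise ValueError(
                    f"modification {name!r} position {pos} outside sequence "
                    f"of length {len(self.sequence)}"
                )
        if self.variant is not None:
            kind, desc = self.variant
            if kind not in ("cSNP", "NSJ"):
                raise ValueError(f"unknown variant kind {kind!r}")
            if kind == "cSNP":
                # description like "E110V": residue at that position must
                # be the alternate amino acid
                alt, pos = desc[-1], int(desc[1:-1])
                if not (1 <= pos <= len(self.sequence)) or self.sequence[pos - 1] != alt:
                    raise ValueError(
                        f"cSNP description {desc!r} inconsistent with sequence"
                    )


@dataclass
class StudyDesign:
    """Two-state factorial design: GELFrEE replicates x LC-MS replicates
    x molecular-weight fractions.

    ``mw_range`` is the overall mass window covered by the GELFrEE
    fractions (split into ``n_fractions`` equal bins).
    """

    states: tuple[str, str] = ("WHIM2", "WHIM16")
    n_gelfree_reps: int = 3
    n_lcms_reps: int = 5
    n_fractions: int = 5
    mw_range: tuple[float, float] = (0.0, 30000.0)

    def __post_init__(self) -> None:
        if len(self.states) != 2:
            raise ValueError("exactly two states are required")
        for n in (self.n_gelfree_reps, self.n_lcms_reps, self.n_fractions):
            if n < 1:
                raise ValueError("all design counts must be >= 1")
        lo, hi = self.mw_range
        if not (hi > lo >= 0):
            raise ValueError("mw_range must be a non-empty interval")

    @property
    def n_runs(self) -> int:
        """Number of LC-MS acquisitions: states x GELFrEE x LC replicates
        x fractions (each fraction is injected separately)."""
        return 2 * self.n_gelfree_reps * self.n_lcms_reps * self.n_fractions

    @property
    def n_injections_per_fraction(self) -> int:
        return 2 * self.n_gelfree_reps * self.n_lcms_reps

    def fraction_bounds(self, fraction: int) -> tuple[float, float]:
        """Mass window of a 1-based fraction index."""
        lo, hi = self.mw_range
        width = (hi - lo) / self.n_fractions
        return lo + (fraction - 1) * width, lo + fraction * width

    def fraction_for_mass(self, mass: float) -> int:
        lo, hi = self.mw_range
        width = (hi - lo) / self.n_fractions
        f = int(np.floor((mass - lo) / width)) + 1
        return min(max(f, 1), self.n_fractions)

    @classmethod
    def study3(cls) -> "StudyDesign":
        """Quantitative TD/BU comparison: 2 states x 3 GELFrEE x 5 LC-MS
        replicates x 5 fractions, 0-30 kDa (150 acquisitions)."""
        return cls(n_gelfree_reps=3, n_lcms_reps=5, n_fractions=5)

    @classmethod
    def study2(cls) -> "StudyDesign":
        """Single-fraction label-free TD quantitation: 2 x 3 x 6 x 1."""
        return cls(n_gelfree_reps=3, n_lcms_reps=6, n_fractions=1)


@dataclass
class EffectSpec:
    """Simulated ground truth for one entity (proteoform or protein).

    ``log2_fold_change`` is state2 vs state1; a nonzero value marks the
    entity as truly differentially expressed.
    """

    entity_id: str
    log2_fold_change: float = 0.0
    missing_rate: float = 0.0
    intensity_scale: float = 1e6
    intensity_cv: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.intensity_scale <= 0 or self.intensity_cv < 0:
            raise ValueError("intensity_scale must be > 0 and cv >= 0")

    @property
    def de_flag(self) -> bool:
        return self.log2_fold_change != 0.0


@dataclass
class MassGroup:
    """A cluster of MS1 neutral-mass observations sharing accurate mass and
    retention time — the TD quantitation unit."""

    group_id: int
    consensus_mass: float
    rt_center: float
    member_index: np.ndarray
    proteoform_id: str | None = None
    mass_error_da: float | None = None

    @property
    def n_members(self) -> int:
        return len(self.member_index)


@dataclass
class Spectrum:
    """A profile-mode intact-mass spectrum (m/z ascending)."""

    mz: np.ndarray
    intensity: np.ndarray
    charge: int | None = None
    resolving_power: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly increasing")


@dataclass
class AlleleCall:
    """Genotype call for one coding SNP from intact-mass evidence."""

    protein_accession: str
    csnp: str
    genotype: str  # homozygous_ref | homozygous_alt | heterozygous | not_detected
    ratio: float | None = None  # alt/ref abundance when heterozygous
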