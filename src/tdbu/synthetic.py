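"""Synthetic proteoform catalogs and paired TD/BU datasets.

The generator emulates the statistical structure of a two-state
(WHIM2-like vs WHIM16-like xenograft) label-free comparison:

* a proteoform catalog with several proteoforms per protein accession —
  PTM forms, proteolytic fragments and heterozygous cSNP pairs;
* top-down MS1 neutral-mass observation tables over a
  states x GELFrEE-replicates x LC-MS-replicates x fractions design,
  with log-normal intensities, ppm-scale mass error and a configurable
  missing-observation rate (~55% in the emulated study);
* bottom-up per-run peptide spectral-count tables with negative-binomial
  counts and a high missing-cell rate (~78.5% in the emulated study);
* intact-mass spectra of co-eluting proteoform pairs for allelic-ratio
  analysis, built on the averagine envelope model.

All operations are deterministic given a seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chem import monoisotopic_mass
from . import chem
from .types import EffectSpec, ProteoformRecord, Spectrum, StudyDesign

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: one substitution partner per reference residue, used to mint cSNP pairs
CSNP_PARTNERS = {
    "S": "I", "V": "L", "I": "V", "E": "V", "T": "S",
    "N": "S", "Y": "D", "P": "S", "A": "G", "L": "M",
}

#: common PTMs used for derived proteoforms (name, monoisotopic shift in Da)
PTMS = [
    ("Phospho", 79.96633),
    ("Acetyl", 42.01057),
    ("Hydroxylation", 15.99491),
]

# largest residue mass (Trp) — head-room needed when growing a sequence
_MAX_RESIDUE = 186.08


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _validate_distribution(spec: dict) -> tuple[np.ndarray, np.ndarray]:
    if not spec:
        raise ValueError("empty distribution spec")
    ks = np.array(sorted(spec), dtype=int)
    ps = np.array([spec[int(k)] for k in ks], dtype=float)
    if (ks < 1).any() or (ps < 0).any() or abs(ps.sum() - 1.0) > 1e-6:
        raise ValueError(f"invalid distribution spec: {spec!r}")
    return ks, ps / ps.sum()


def _random_sequence(rng: np.random.Generator, target_mass: float) -> str:
    """Random amino-acid sequence with monoisotopic mass just below target."""
    residues = []
    m = chem.WATER
    while True:
        aa = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        dm = monoisotopic_mass(aa) - chem.WATER
        if m + dm > target_mass:
            if residues:
                return "".join(residues)
            # target smaller than one residue: use glycine
            return "G"
        residues.append(aa)
        m += dm


def generate_catalog(
    n_proteins: int,
    proteoforms_per_protein: dict[int, float] | None = None,
    mass_range: tuple[float, float] = (0.0, 30000.0),
    variant_fraction: float = 0.0,
    seed=None,
) -> list[ProteoformRecord]:
    """Generate a proteoform catalog.

    Each protein gets a base proteoform plus ``k - 1`` derived forms
    (PTM additions or proteolytic fragments), with ``k`` drawn from
    ``proteoforms_per_protein``.  With probability ``variant_fraction``
    a protein additionally carries a heterozygous cSNP, represented as a
    second allele proteoform annotated e.g. ``("cSNP", "E110V")``.
    """
    if n_proteins < 0:
        raise ValueError("n_proteins must be >= 0")
    lo, hi = mass_range
    if not hi > lo:
        raise ValueError("empty mass_range")
    if not 0.0 <= variant_fraction <= 1.0:
        raise ValueError("variant_fraction must be a probability")
    if proteoforms_per_protein is None:
        # ~52% of accessions seen by a single proteoform in the emulated study
        proteoforms_per_protein = {1: 0.52, 2: 0.24, 3: 0.16, 4: 0.08}
    ks, ps = _validate_distribution(proteoforms_per_protein)

    rng = _rng(seed)
    records: list[ProteoformRecord] = []
    pf_counter = 0

    def new_id() -> str:
        nonlocal pf_counter
        pf_counter += 1
        return f"PF{pf_counter:05d}"

    # leave head-room for PTM shifts at the top of the range when possible
    draw_lo = min(lo + 2.0 * _MAX_RESIDUE, hi)
    draw_hi = max(hi - 150.0, draw_lo)

    for i in range(n_proteins):
        accession = f"NP_{i + 1:06d}"
        k = int(rng.choice(ks, p=ps))
        for _attempt in range(100):
            target = rng.uniform(draw_lo, draw_hi)
            sequence = _random_sequence(rng, target)
            base_mass = monoisotopic_mass(sequence)
            if lo <= base_mass <= hi:
                break
        else:  # pragma: no cover - degenerate mass_range
            raise ValueError(f"could not generate a sequence within {mass_range}")
        base = ProteoformRecord(new_id(), accession, sequence,
                                monoisotopic_mass=base_mass)
        records.append(base)

        for _ in range(k - 1):
            if rng.random() < 0.3 and len(sequence) >= 20:
                # proteolytic fragment: keep an N- or C-terminal stretch
                frac = rng.uniform(0.4, 0.85)
                cut = max(int(len(sequence) * frac), 5)
                frag_seq = sequence[:cut] if rng.random() < 0.5 else sequence[-cut:]
                frag_mass = monoisotopic_mass(frag_seq)
                if lo <= frag_mass <= hi:
                    records.append(
                        ProteoformRecord(new_id(), accession, frag_seq,
                                         monoisotopic_mass=frag_mass,
                                         fragment_of=base.proteoform_id)
                    )
                    continue
            name, shift = PTMS[rng.integers(len(PTMS))]
            pos = int(rng.integers(1, len(sequence) + 1))
            mods = [(name, shift, pos)]
            records.append(
                ProteoformRecord(new_id(), accession, sequence, mods,
                                 monoisotopic_mass=monoisotopic_mass(sequence, mods))
            )

        if rng.random() < variant_fraction:
            positions = [j for j, aa in enumerate(sequence) if aa in CSNP_PARTNERS]
            if positions:
                j = int(positions[rng.integers(len(positions))])
                ref_aa = sequence[j]
                alt_aa = CSNP_PARTNERS[ref_aa]
                alt_seq = sequence[:j] + alt_aa + sequence[j + 1:]
                desc = f"{ref_aa}{j + 1}{alt_aa}"
                records.append(
                    ProteoformRecord(new_id(), accession, alt_seq,
                                     monoisotopic_mass=monoisotopic_mass(alt_seq),
                                     variant=("cSNP", desc))
                )
    return records


def make_effects(
    entity_ids: list[str],
    de_fraction: float = 0.0,
    log2fc_range: tuple[float, float] = (1.0, 3.0),
    missing_rate: float = 0.0,
    intensity_scale: float = 1e6,
    intensity_cv: float = 0.25,
    seed=None,
) -> list[EffectSpec]:
    """Draw per-entity ground-truth effects.

    A ``de_fraction`` of entities receives a nonzero log2 fold change with
    magnitude uniform in ``log2fc_range`` and random sign; intensity scales
    are log-normally dispersed around ``intensity_scale``.
    """
    rng = _rng(seed)
    effects = []
    for eid in entity_ids:
        lfc = 0.0
        if rng.random() < de_fraction:
            lfc = float(rng.uniform(*log2fc_range)) * (1 if rng.random() < 0.5 else -1)
        scale = float(intensity_scale * rng.lognormal(0.0, 0.8))
        effects.append(EffectSpec(eid, lfc, missing_rate, scale, intensity_cv))
    return effects


def _effect_map(catalog_ids: set[str], effects: list[EffectSpec]) -> dict[str, EffectSpec]:
    emap = {}
    for e in effects:
        if e.entity_id not in catalog_ids:
            raise KeyError(f"effect entity {e.entity_id!r} not in catalog")
        emap[e.entity_id] = e
    return emap


def simulate_td_observations(
    catalog: list[ProteoformRecord],
    design: StudyDesign,
    effects: list[EffectSpec],
    rt_model: tuple[float, float] = (60.0, 0.5),
    ppm_error_sd: float = 2.0,
    p_span: float = 0.3,
    missing_mode: str = "mcar",
    seed=None,
) -> pd.DataFrame:
    """Simulate the TD MS1 neutral-mass observation table.

    Each proteoform elutes in its molecular-weight home fraction and, with
    probability ``p_span``, in one or two adjacent fractions as well.  Per
    theoretically possible (proteoform x state x GELFrEE x LC-MS x
    fraction) cell, the intensity is log-normal around the state mean
    (state2 mean = state1 mean x 2**log2FC) and the cell is dropped
    either completely at random (``missing_mode="mcar"``) or with a
    logistic-in-log-intensity censoring favouring low intensities
    (``missing_mode="intensity"``); the overall rate is the effect's
    ``missing_rate`` in both modes (approximately so for ``"intensity"``).
    Observed neutral masses carry Gaussian ppm-scale error.
    """
    if missing_mode not in ("mcar", "intensity"):
        raise ValueError(f"unknown missing_mode {missing_mode!r}")
    rng = _rng(seed)
    emap = _effect_map({r.proteoform_id for r in catalog}, effects)
    gradient_min, jitter_sd = rt_model

    frames = []
    state2 = design.states[1]
    for rec in catalog:
        eff = emap.get(rec.proteoform_id) or EffectSpec(rec.proteoform_id)
        home = design.fraction_for_mass(rec.monoisotopic_mass)
        fractions = [home]
        u = rng.random()
        if u < p_span:
            step = 1 if (home < design.n_fractions and (rng.random() < 0.5 or home == 1)) else -1
            fractions.append(home + step)
            if u < 0.2 * p_span:
                other = home - step
                if 1 <= other <= design.n_fractions:
                    fractions.append(other)
        fractions = sorted(set(f for f in fractions if 1 <= f <= design.n_fractions))

        rt_center = rng.uniform(0.1, 0.9) * gradient_min

        states, greps, lreps, fracs = np.meshgrid(
            np.arange(2),
            np.arange(1, design.n_gelfree_reps + 1),
            np.arange(1, design.n_lcms_reps + 1),
            np.array(fractions),
            indexing="ij",
        )
        states, greps, lreps, fracs = (a.ravel() for a in (states, greps, lreps, fracs))
        n_cells = states.size

        mean = eff.intensity_scale * np.where(
            states == 1, 2.0 ** eff.log2_fold_change, 1.0
        )
        sigma = np.sqrt(np.log1p(eff.intensity_cv**2))
        mu = np.log(mean) - sigma**2 / 2.0
        intensity = rng.lognormal(mu, sigma)

        if eff.missing_rate > 0:
            if missing_mode == "mcar":
                keep = rng.random(n_cells) >= eff.missing_rate
            else:
                # censor low-intensity cells: logistic in log-intensity with
                # the cut placed at the missing_rate quantile
                logi = np.log(intensity)
                cut = np.quantile(logi, eff.missing_rate)
                p_miss = 1.0 / (1.0 + np.exp((logi - cut) / 0.25))
                keep = rng.random(n_cells) >= p_miss
        else:
            keep = np.ones(n_cells, dtype=bool)

        obs_mass = rec.monoisotopic_mass * (
            1.0 + rng.normal(0.0, ppm_error_sd * 1e-6, n_cells)
        )
        rt = rt_center + rng.normal(0.0, jitter_sd, n_cells)

        frames.append(pd.DataFrame({
            "proteoform_id": rec.proteoform_id,
            "neutral_mass_da": obs_mass[keep],
            "rt_min": rt[keep],
            "fraction": fracs[keep],
            "state": np.where(states[keep] == 1, state2, design.states[0]),
            "gelfree_rep": greps[keep],
            "lcms_rep": lreps[keep],
            "intensity": intensity[keep],
        }))
    if not frames:
        return pd.DataFrame(columns=[
            "proteoform_id", "neutral_mass_da", "rt_min", "fraction",
            "state", "gelfree_rep", "lcms_rep", "intensity",
        ])
    return pd.concat(frames, ignore_index=True)


def _zero_truncated_nb(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float | None
) -> np.ndarray:
    """Zero-truncated negative-binomial (or Poisson) counts.

    Spectral-count tables record a detected peptide per run; a zero count
    is represented by the absence of a row, so observed counts are >= 1.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion is None:
        draw = lambda m: rng.poisson(m)
    else:
        k = float(dispersion)
        draw = lambda m: rng.negative_binomial(k, k / (k + m))
    counts = draw(mean)
    for _ in range(200):
        zero = counts == 0
        if not zero.any():
            break
        counts[zero] = draw(mean[zero])
    counts[counts == 0] = 1
    return counts


def simulate_bu_counts(
    catalog: list[ProteoformRecord],
    peptides_per_protein: dict[int, float] | None = None,
    design: StudyDesign | None = None,
    effects: list[EffectSpec] | None = None,
    base_count_mean: float = 8.0,
    dispersion: float | None = 2.0,
    seed=None,
) -> pd.DataFrame:
    """Simulate the BU peptide x run spectral-count table.

    BU runs are states x GELFrEE replicates x LC-MS replicates (fractions
    are digested and acquired together).  Per peptide and run, counts are
    zero-truncated negative-binomial around peptide abundance x the
    protein's state fold change; cells are dropped completely at random at
    the protein effect's ``missing_rate``.  Proteins whose catalog entry
    carries a cSNP/NSJ contribute one annotated variant peptide.
    Effects are keyed by protein accession.
    """
    if design is None:
        design = StudyDesign.study3()
    if peptides_per_protein is None:
        peptides_per_protein = {3: 0.3, 5: 0.3, 8: 0.25, 12: 0.15}
    ks, ps = _validate_distribution(peptides_per_protein)
    rng = _rng(seed)

    by_accession: dict[str, list[ProteoformRecord]] = {}
    for rec in catalog:
        by_accession.setdefault(rec.protein_accession, []).append(rec)
    emap = _effect_map(set(by_accession), effects or [])

    state2 = design.states[1]
    n_runs = 2 * design.n_gelfree_reps * design.n_lcms_reps
    states, greps, lreps = np.meshgrid(
        np.arange(2),
        np.arange(1, design.n_gelfree_reps + 1),
        np.arange(1, design.n_lcms_reps + 1),
        indexing="ij",
    )
    states, greps, lreps = (a.ravel() for a in (states, greps, lreps))

    frames = []
    for accession, recs in by_accession.items():
        eff = emap.get(accession) or EffectSpec(accession)
        n_pep = int(rng.choice(ks, p=ps))
        base = recs[0]
        variant_kinds = ["none"] * n_pep
        for rec in recs:
            if rec.variant is not None:
                variant_kinds.append(rec.variant[0])
                n_pep += 1
                break
        for j in range(n_pep):
            seq_len = int(rng.integers(8, 16))
            start = int(rng.integers(0, max(len(base.sequence) - seq_len, 1)))
            pep = base.sequence[start:start + seq_len] or base.sequence
            pep = f"{pep}"
            abundance = base_count_mean * rng.lognormal(0.0, 0.8)
            mean = abundance * np.where(states == 1, 2.0 ** eff.log2_fold_change, 1.0)
            keep = rng.random(n_runs) >= eff.missing_rate
            if not keep.any():
                continue
            counts = _zero_truncated_nb(rng, mean[keep], dispersion)
            frames.append(pd.DataFrame({
                "peptide_seq": f"{accession}:{pep}:{j}",
                "protein_accession": accession,
                "unique_flag": True,
                "variant_kind": variant_kinds[j],
                "state": np.where(states[keep] == 1, state2, design.states[0]),
                "gelfree_rep": greps[keep],
                "lcms_rep": lreps[keep],
                "spectral_count": counts,
            }))
    if not frames:
        return pd.DataFrame(columns=[
            "peptide_seq", "protein_accession", "unique_flag", "variant_kind",
            "state", "gelfree_rep", "lcms_rep", "spectral_count",
        ])
    return pd.concat(frames, ignore_index=True)


def synthesize_envelope_spectrum(
    proteoforms: list[ProteoformRecord] | list[float],
    abundances: list[float],
    charge: int,
    resolving_power: float = 120000.0,
    noise_sd: float = 0.01,
    seed=None,
    mz_pad: float = 1.0,
    grid_step: float | None = None,
) -> Spectrum:
    """Synthesize an intact-mass spectrum of 1-2 co-eluting proteoforms.

    Each proteoform contributes an averagine isotopic envelope centred at
    ``(mass + charge * proton) / charge``, with Gaussian peak shapes at
    the stated resolving power, scaled by its abundance.  Additive
    Gaussian noise with sd ``noise_sd`` relative to the strongest signal.
    """
    if charge <= 0:
        raise ValueError("charge must be a positive integer")
    if not 1 <= len(proteoforms) <= 2 or len(abundances) != len(proteoforms):
        raise ValueError("provide 1-2 proteoforms with matching abundances")
    if any(a <= 0 for a in abundances):
        raise ValueError("abundances must be positive")
    masses = [
        p.monoisotopic_mass if isinstance(p, ProteoformRecord) else float(p)
        for p in proteoforms
    ]
    if len(masses) == 2 and abs(masses[0] - masses[1]) < 1e-6:
        raise ValueError("the two proteoforms must differ in mass")

    rng = _rng(seed)
    patterns = [chem.averagine_isotope_pattern(m) for m in masses]
    centers = np.concatenate(
        [(mass + charge * chem.PROTON) / charge for mass, _ in patterns]
    )
    lo, hi = centers.min() - mz_pad, centers.max() + mz_pad
    if grid_step is None:
        sigma = lo / (resolving_power * 2.355)
        grid_step = sigma / 4.0
    mz = np.arange(lo, hi, grid_step)

    signal = np.zeros_like(mz)
    for m, a in zip(masses, abundances):
        signal += a * chem.envelope_profile(mz, m, charge, resolving_power)
    peak = signal.max()
    if peak > 0:
        signal /= peak
    intensity = signal + rng.normal(0.0, noise_sd, mz.size)
    return Spectrum(mz, intensity, charge=charge, resolving_power=resolving_power)
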