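"""File formats and configuration.

Catalog FASTA dialect: ``>{protein_accession}|{proteoform_id}|{mass:.4f}``
followed by optional space-separated ``key=value`` attributes:
``mods=Name@pos:shift;...``, ``variant=kind:desc``, ``fragment_of=id``.
All tables are TSV with a header row; missing values are empty fields.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .chem import monoisotopic_mass
from .types import ProteoformRecord, Spectrum, StudyDesign


def write_catalog_fasta(records: list[ProteoformRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.protein_accession}|{r.proteoform_id}|{r.monoisotopic_mass:.4f}"
            if r.modifications:
                mods = ";".join(
                    f"{name}@{pos}:{shift!r}" for name, shift, pos in r.modifications
                )
                header += f" mods={mods}"
            if r.variant is not None:
                header += f" variant={r.variant[0]}:{r.variant[1]}"
            if r.fragment_of is not None:
                header += f" fragment_of={r.fragment_of}"
            fh.write(header + "\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i:i + 60] + "\n")


def read_catalog_fasta(path) -> list[ProteoformRecord]:
    """Parse a catalog FASTA, re-validating the mass invariant.

    Raises ValueError naming the offending record on a malformed header;
    warns when the header mass disagrees with the mass recomputed from
    sequence + modifications by more than 1e-3 Da.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        parts = entry.id.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"malformed catalog header {entry.description!r}: expected "
                "'accession|proteoform_id|mass'"
            )
        accession, pf_id, mass_str = parts
        try:
            mass = float(mass_str)
        except ValueError:
            raise ValueError(
                f"malformed catalog header {entry.description!r}: bad mass field"
            ) from None
        mods: list[tuple[str, float, int]] = []
        variant = None
        fragment_of = None
        for token in entry.description.split()[1:]:
            if "=" not in token:
                raise ValueError(
                    f"malformed attribute {token!r} in header {entry.description!r}"
                )
            key, value = token.split("=", 1)
            if key == "mods":
                for item in value.split(";"):
                    name, rest = item.split("@", 1)
                    pos_str, shift_str = rest.split(":", 1)
                    mods.append((name, float(shift_str), int(pos_str)))
            elif key == "variant":
                kind, desc = value.split(":", 1)
                variant = (kind, desc)
            elif key == "fragment_of":
                fragment_of = value
            else:
                raise ValueError(
                    f"unknown attribute {key!r} in header {entry.description!r}"
                )
        sequence = str(entry.seq)
        expected = monoisotopic_mass(sequence, mods)
        if abs(expected - mass) > 1e-3:
            warnings.warn(
                f"catalog mass mismatch for {pf_id}: header {mass:.4f} Da vs "
                f"computed {expected:.4f} Da"
            )
        records.append(ProteoformRecord(pf_id, accession, sequence, mods,
                                        mass, variant, fragment_of))
    return records


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_td_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("neutral_mass_da", "rt_min", "intensity"):
        df[col] = df[col].astype(float)
    for col in ("fraction", "gelfree_rep", "lcms_rep"):
        df[col] = df[col].astype(int)
    return df


def read_bu_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["spectral_count"] = df["spectral_count"].astype(int)
    df["unique_flag"] = df["unique_flag"].astype(bool)
    df["variant_kind"] = df["variant_kind"].fillna("none")
    return df


def write_spectrum(spectrum: Spectrum, path) -> None:
    pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensity}).to_csv(
        path, sep="\t", index=False
    )


def read_spectrum(path, charge=None, resolving_power=None) -> Spectrum:
    df = pd.read_csv(path, sep="\t")
    return Spectrum(df["mz"].to_numpy(), df["intensity"].to_numpy(),
                    charge=charge, resolving_power=resolving_power)


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end run configuration with the study's thresholds as defaults.

    TD testing at alpha 0.05 with BH FDR; BU testing at alpha 0.01;
    intact-mass linkage within 2.2 Da; mass grouping at 10 ppm / 5 min;
    variant peptides require a spectral count of 3 within one run.
    """

    # synthetic study conditions
    n_proteins: int = 150
    variant_fraction: float = 0.05
    de_fraction: float = 0.25
    log2fc_low: float = 1.0
    log2fc_high: float = 3.0
    intensity_cv: float = 0.25
    td_missing_rate: float = 0.546
    bu_missing_rate: float = 0.785
    design_preset: str = "study3"  # or "study2"
    # plant this many proteins observed in state1 only (present/absent truth)
    n_present_absent: int = 0
    # TD quantitation
    mass_tol_ppm: float = 10.0
    rt_tol_min: float = 5.0
    precursor_tol_da: float = 2.2
    td_alpha: float = 0.05
    log_before_standardize: bool = False
    # BU quantitation
    bu_alpha: float = 0.01
    pseudocount: float = 0.5
    equal_variance: bool = True
    min_unique_peptides: int = 2
    variant_min_count_per_run: int = 3
    # concordance
    rollup_convention: str = "de_priority"
    seed: int = 0

    def __post_init__(self) -> None:
        for tol in (self.mass_tol_ppm, self.rt_tol_min, self.precursor_tol_da):
            if tol <= 0:
                raise ValueError("all tolerances must be > 0")
        for a in (self.td_alpha, self.bu_alpha):
            if not 0 < a < 1:
                raise ValueError("alphas must lie in (0, 1)")

    def design(self) -> StudyDesign:
        if self.design_preset == "study3":
            return StudyDesign.study3()
        if self.design_preset == "study2":
            return StudyDesign.study2()
        raise ValueError(f"unknown design preset {self.design_preset!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
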