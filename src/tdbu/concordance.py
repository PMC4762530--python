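"""TD/BU concordance: proteoform-to-protein rollup, 3x3 cross-
classification of detection and differential-expression status, and the
summary statistics derived from it.

TD quantifies proteoforms; BU quantifies proteins.  Rolling TD up to
protein accessions, each protein falls into one of three TD statuses
(DE, not DE, not detected) and one of three BU statuses, giving the 3x3
grid (with the doubly-undetected cell empty by construction).  A protein
with several proteoforms of mixed status legitimately occupies two TD
rows; for disjoint protein totals the DE row takes precedence by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import DE, NOT_DE, NOT_DETECTED, STATUSES

log = logging.getLogger(__name__)

#: the (TD not_detected, BU not_detected) cell is empty by construction
VALID_CELLS = [
    (td, bu) for td in STATUSES for bu in STATUSES
    if not (td == NOT_DETECTED and bu == NOT_DETECTED)
]


def rollup_proteoforms(td_results: pd.DataFrame) -> pd.DataFrame:
    """Protein-level TD status from proteoform results.

    ``td_results`` needs columns ``entity_id``, ``protein_accession`` and
    ``de_flag``.  Each accession is reported once with its proteoform
    counts per status; a protein contributes to the DE row if >= 1
    proteoform is DE and to the not-DE row if >= 1 proteoform is not —
    both are possible.
    """
    if td_results.empty:
        return pd.DataFrame(columns=["protein_accession", "n_de_proteoforms",
                                     "n_not_de_proteoforms"])
    grp = td_results.groupby("protein_accession")["de_flag"]
    out = pd.DataFrame({
        "n_de_proteoforms": grp.sum().astype(int),
        "n_not_de_proteoforms": (grp.count() - grp.sum()).astype(int),
    })
    return out.reset_index()


@dataclass
class ConcordanceTable:
    """3x3 protein/proteoform counts over TD status x BU status.

    ``protein_counts``/``proteoform_counts`` map (td_status, bu_status)
    cells to counts; proteoform counts are undefined (absent) for TD
    not-detected cells.  When built from per-protein status tables the
    accession sets per cell are kept for exact marginal accounting.
    """

    protein_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    proteoform_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    protein_sets: dict[tuple[str, str], set] | None = None

    @classmethod
    def from_counts(
        cls,
        protein_counts: dict[tuple[str, str], int],
        proteoform_counts: dict[tuple[str, str], int] | None = None,
    ) -> "ConcordanceTable":
        """Build from pre-tabulated (printed) cell counts, treated as
        disjoint protein sets."""
        bad = set(protein_counts) - set(VALID_CELLS)
        if bad:
            raise ValueError(f"invalid cells: {sorted(bad)}")
        return cls(dict(protein_counts), dict(proteoform_counts or {}))

    def protein_count(self, td: str, bu: str) -> int:
        return int(self.protein_counts.get((td, bu), 0))

    def to_frame(self) -> pd.DataFrame:
        """Long-form cell table (one row per valid cell)."""
        rows = []
        for cell in VALID_CELLS:
            pf = self.proteoform_counts.get(cell)
            rows.append({
                "td_status": cell[0], "bu_status": cell[1],
                "protein_count": self.protein_count(*cell),
                "proteoform_count": pf if cell[0] != NOT_DETECTED else None,
            })
        return pd.DataFrame(rows)


def classify(
    td_protein_status: pd.DataFrame,
    bu_protein_status: dict[str, str] | pd.DataFrame,
    convention: str = "de_priority",
) -> ConcordanceTable:
    """Cross-classify proteins by (TD status, BU status).

    ``td_protein_status`` is the rollup output; ``bu_protein_status`` maps
    accession -> "DE"/"not_DE" for BU-detected proteins (a DataFrame with
    ``protein_accession``/``de_flag`` columns is also accepted).

    ``convention`` controls protein counting for accessions whose
    proteoforms have mixed TD status: ``"de_priority"`` (default) assigns
    the protein to the DE row only, keeping cells disjoint so totals add
    up; ``"both"`` counts it once in each occupied row.  Proteoform
    counts always split across rows by proteoform status.
    """
    if convention not in ("de_priority", "both"):
        raise ValueError(f"unknown convention {convention!r}")
    if isinstance(bu_protein_status, pd.DataFrame):
        bu_map = {
            r.protein_accession: (DE if r.de_flag else NOT_DE)
            for r in bu_protein_status.itertuples()
            if getattr(r, "call", "tested") == "tested"
        }
    else:
        bu_map = dict(bu_protein_status)

    td_map: dict[str, tuple[int, int]] = {
        r.protein_accession: (r.n_de_proteoforms, r.n_not_de_proteoforms)
        for r in td_protein_status.itertuples()
    }

    protein_sets: dict[tuple[str, str], set] = {c: set() for c in VALID_CELLS}
    proteoform_counts: dict[tuple[str, str], int] = {}
    for acc in set(td_map) | set(bu_map):
        n_de, n_nde = td_map.get(acc, (0, 0))
        bu_status = bu_map.get(acc, NOT_DETECTED)
        td_rows = []
        if n_de > 0:
            td_rows.append(DE)
        if n_nde > 0:
            td_rows.append(NOT_DE)
        if not td_rows:
            td_rows = [NOT_DETECTED]
            if bu_status == NOT_DETECTED:
                log.warning("accession %s has neither TD nor BU status", acc)
                continue
        for td_status in td_rows:
            n_pf = n_de if td_status == DE else (n_nde if td_status == NOT_DE else 0)
            if td_status != NOT_DETECTED:
                cell = (td_status, bu_status)
                proteoform_counts[cell] = proteoform_counts.get(cell, 0) + n_pf
        if convention == "de_priority":
            protein_sets[(td_rows[0], bu_status)].add(acc)
        else:
            for td_status in td_rows:
                protein_sets[(td_status, bu_status)].add(acc)

    protein_counts = {c: len(s) for c, s in protein_sets.items() if s}
    return ConcordanceTable(protein_counts, proteoform_counts, protein_sets)


def summarize(table: ConcordanceTable) -> dict:
    """The headline concordance statistics.

    Percent DE agreement = 100 x (both-DE + both-not-DE) / co-detected
    proteins, rounded to the nearest integer; detection ratio =
    BU total / TD total to one decimal.  Agreement is None when no
    protein is co-detected.
    """
    co_detected = sum(
        table.protein_count(td, bu)
        for td in (DE, NOT_DE) for bu in (DE, NOT_DE)
    )
    agree = table.protein_count(DE, DE) + table.protein_count(NOT_DE, NOT_DE)
    bu_only = (table.protein_count(NOT_DETECTED, DE)
               + table.protein_count(NOT_DETECTED, NOT_DE))
    td_only = (table.protein_count(DE, NOT_DETECTED)
               + table.protein_count(NOT_DE, NOT_DETECTED))
    bu_total = co_detected + bu_only
    td_total = co_detected + td_only
    return {
        "percent_DE_agreement_among_codetected": (
            round(100.0 * agree / co_detected) if co_detected else None
        ),
        "bu_only_proteins": bu_only,
        "td_only_proteins": td_only,
        "bu_total_proteins": bu_total,
        "td_total_proteins": td_total,
        "detection_ratio_bu_over_td": (
            round(bu_total / td_total, 1) if td_total else None
        ),
    }


def foldchange_agreement(
    td_results: pd.DataFrame,
    bu_results: pd.DataFrame,
    min_pairs: int = 3,
) -> tuple[float | None, float | None, pd.DataFrame]:
    """Fold-change agreement between platforms on co-DE proteins.

    The TD protein-level log2FC is the median over its DE proteoforms
    (``td_results`` needs ``protein_accession``, ``de_flag``,
    ``log2_fold_change``).  Returns (Pearson r, r^2, paired table);
    r is None with fewer than ``min_pairs`` co-DE proteins.
    """
    td_de = td_results[td_results["de_flag"]]
    td_fc = td_de.groupby("protein_accession")["log2_fold_change"].median()
    bu_de = bu_results[bu_results["de_flag"].fillna(False).astype(bool)]
    bu_fc = bu_de.set_index("protein_accession")["log2_fold_change"]
    common = sorted(set(td_fc.index) & set(bu_fc.index))
    paired = pd.DataFrame({
        "protein_accession": common,
        "td_log2fc": td_fc.loc[common].to_numpy(),
        "bu_log2fc": bu_fc.loc[common].to_numpy(),
    })
    if len(paired) < min_pairs:
        return None, None, paired
    r = float(stats.pearsonr(paired["td_log2fc"], paired["bu_log2fc"]).statistic)
    return r, r * r, paired
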