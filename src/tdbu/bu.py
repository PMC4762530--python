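"""Bottom-up spectral-count quantitation.

Identification filtering (>= 2 unique peptides per protein, pre-computed
FDR pass flags), the per-run count threshold for variant peptides,
protein-level count summaries, and differential expression by two-sided
t-tests on log2 spectral counts per GELFrEE replicate with
Benjamini-Hochberg FDR calling at alpha = 0.01.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .td import bh_fdr
from .types import StudyDesign

log = logging.getLogger(__name__)

COUNT_COLUMNS = [
    "peptide_seq", "protein_accession", "unique_flag", "variant_kind",
    "state", "gelfree_rep", "lcms_rep", "spectral_count",
]

_RUN_KEY = ["state", "gelfree_rep", "lcms_rep"]


def apply_identification_filters(
    table: pd.DataFrame, min_unique_peptides: int = 2
) -> pd.DataFrame:
    """Enforce the identification quality filters.

    Rows whose ``fdr_pass`` flag (if present) is False are dropped —
    PSM/protein FDR estimation happens upstream and arrives as flags.
    Proteins observed with fewer than ``min_unique_peptides`` distinct
    unique peptides are removed entirely.  Removal counts are logged and
    attached as ``table.attrs['filter_stats']``.
    """
    n_input = len(table)
    if "fdr_pass" in table.columns:
        table = table[table["fdr_pass"].astype(bool)]
    n_fdr_removed = n_input - len(table)

    if table.empty:
        out = table.copy()
        out.attrs["filter_stats"] = {
            "n_input": n_input, "n_removed_fdr": n_fdr_removed,
            "n_removed_protein": 0, "n_retained": 0,
        }
        return out

    uniq = (
        table[table["unique_flag"].astype(bool)]
        .groupby("protein_accession")["peptide_seq"]
        .nunique()
    )
    keep_proteins = set(uniq[uniq >= min_unique_peptides].index)
    out = table[table["protein_accession"].isin(keep_proteins)].copy()
    stats_ = {
        "n_input": n_input,
        "n_removed_fdr": n_fdr_removed,
        "n_removed_protein": len(table) - len(out),
        "n_retained": len(out),
    }
    log.info("identification filters: %s", stats_)
    out.attrs["filter_stats"] = stats_
    return out


def filter_variant_peptides(
    table: pd.DataFrame, min_count_per_run: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the per-run count threshold to SNP/splice-variant peptides.

    A variant peptide is retained iff it reaches ``min_count_per_run``
    spectral counts within at least one single LC-MS run; non-variant
    peptides are unaffected.  Returns ``(filtered_table, variant_report)``.
    """
    if table.empty:
        report = pd.DataFrame(columns=["peptide_seq", "variant_kind",
                                       "max_run_count", "retained"])
        return table.copy(), report
    is_variant = table["variant_kind"].fillna("none") != "none"
    variants = table[is_variant]
    max_run = variants.groupby("peptide_seq")["spectral_count"].max()
    retained = max_run[max_run >= min_count_per_run].index
    report = pd.DataFrame({
        "peptide_seq": max_run.index,
        "variant_kind": variants.groupby("peptide_seq")["variant_kind"].first().values,
        "max_run_count": max_run.values,
        "retained": max_run.values >= min_count_per_run,
    }).reset_index(drop=True)
    keep = ~is_variant | table["peptide_seq"].isin(retained)
    return table[keep].copy(), report


def summarize_protein_counts(
    table: pd.DataFrame, states: tuple[str, str] | None = None
) -> pd.DataFrame:
    """Per-protein spectral-count summary.

    One row per protein accession: per-state total counts, the number of
    distinct unique peptides, and the state2/state1 count ratio reported
    to two decimals (None when state1 has no counts).
    """
    if states is None:
        states = tuple(sorted(table["state"].unique()))
    rows = []
    for acc, sub in table.groupby("protein_accession", sort=True):
        t1 = int(sub.loc[sub["state"] == states[0], "spectral_count"].sum())
        t2 = int(sub.loc[sub["state"] == states[1], "spectral_count"].sum())
        n_uniq = sub.loc[sub["unique_flag"].astype(bool), "peptide_seq"].nunique()
        ratio = round(t2 / t1, 2) if t1 > 0 else None
        rows.append((acc, t1, t2, ratio, n_uniq))
    return pd.DataFrame(
        rows,
        columns=["protein_accession", "state1_total", "state2_total",
                 "count_ratio", "n_unique_peptides"],
    )


def replicate_totals(
    table: pd.DataFrame, design: StudyDesign
) -> pd.DataFrame:
    """Protein x (state, GELFrEE replicate) total spectral counts.

    LC-MS runs within a GELFrEE replicate are summed; replicates with no
    observed peptide for a protein contribute zero.  The GELFrEE replicate
    is the biological replicate unit for BU testing.
    """
    cols = pd.MultiIndex.from_product(
        [design.states, range(1, design.n_gelfree_reps + 1)],
        names=["state", "gelfree_rep"],
    )
    if table.empty:
        return pd.DataFrame(columns=cols)
    pivot = table.pivot_table(
        index="protein_accession",
        columns=["state", "gelfree_rep"],
        values="spectral_count",
        aggfunc="sum",
        fill_value=0,
    )
    return pivot.reindex(columns=cols, fill_value=0)


def protein_de_test(
    table: pd.DataFrame,
    design: StudyDesign,
    equal_variance: bool = True,
    alpha: float = 0.01,
    pseudocount: float = 0.5,
    present_absent_min_run_count: int = 3,
    normalize_per_run: bool = False,
) -> pd.DataFrame:
    """Protein differential expression from spectral counts.

    Two-sided t-test on log2(replicate total + pseudocount) between the
    two states' GELFrEE replicates — pooled equal-variance by default,
    Welch otherwise (the call for borderline proteins can flip between
    the two).  DE calling uses Benjamini-Hochberg critical values at
    ``alpha`` across all tested proteins.  A protein with all-zero counts
    in one state is not t-tested: it is called "present_absent" when the
    other state reaches ``present_absent_min_run_count`` in some single
    run, else "insufficient_evidence" (low stray counts are weak evidence
    given the high missing-value rate of spectral counting).
    """
    if normalize_per_run and not table.empty:
        run_tot = table.groupby(_RUN_KEY)["spectral_count"].transform("sum")
        table = table.copy()
        table["spectral_count"] = (
            table["spectral_count"] / run_tot * run_tot.mean()
        )
    totals = replicate_totals(table, design)
    s1, s2 = design.states

    max_run = (
        table.groupby(["protein_accession"] + _RUN_KEY)["spectral_count"]
        .sum()
        .groupby(["protein_accession", "state"])
        .max()
    )

    rows = []
    tested_p = []
    for acc in totals.index:
        x1 = totals.loc[acc, s1].to_numpy(dtype=float)
        x2 = totals.loc[acc, s2].to_numpy(dtype=float)
        if x1.sum() == 0 or x2.sum() == 0:
            present_state = s1 if x1.sum() > 0 else s2
            peak = max_run.get((acc, present_state), 0)
            call = (
                "present_absent"
                if peak >= present_absent_min_run_count
                else "insufficient_evidence"
            )
            rows.append({
                "protein_accession": acc, "level": "protein",
                "log2_fold_change": np.nan, "p_value": np.nan,
                "call": call, "present_in": present_state,
            })
            continue
        l1 = np.log2(x1 + pseudocount)
        l2 = np.log2(x2 + pseudocount)
        lfc = float(l2.mean() - l1.mean())
        if l1.std(ddof=1) == 0 and l2.std(ddof=1) == 0:
            p = 1.0 if lfc == 0 else 0.0
        else:
            p = float(stats.ttest_ind(l2, l1, equal_var=equal_variance).pvalue)
        rows.append({
            "protein_accession": acc, "level": "protein",
            "log2_fold_change": lfc, "p_value": p,
            "call": "tested", "present_in": "",
        })
        tested_p.append(p)

    results = pd.DataFrame(rows)
    results["q_value"] = np.nan
    results["de_flag"] = False
    tested = results["call"] == "tested"
    if tested.any():
        q, flags = bh_fdr(results.loc[tested, "p_value"].to_numpy(), alpha=alpha)
        results.loc[tested, "q_value"] = q
        results.loc[tested, "de_flag"] = flags
    return results[[
        "protein_accession", "level", "log2_fold_change", "p_value",
        "q_value", "de_flag", "call", "present_in",
    ]]


def report_missingness(table: pd.DataFrame, design: StudyDesign) -> float:
    """Fraction of (identified peptide x run) cells with no spectral count.

    BU runs are states x GELFrEE x LC-MS replicates.  A peptide counts as
    identified if it appears in at least one run.
    """
    n_runs = 2 * design.n_gelfree_reps * design.n_lcms_reps
    n_peptides = table["peptide_seq"].nunique()
    if n_peptides == 0:
        return 0.0
    observed = len(table.drop_duplicates(subset=["peptide_seq"] + _RUN_KEY))
    return 1.0 - observed / (n_peptides * n_runs)
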