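"""Label-free top-down proteoform quantitation.

Pipeline: MS1 neutral-mass observations are clustered into mass groups by
accurate mass and retention time, linked to catalog proteoforms by intact
mass, standardized within each (proteoform, GELFrEE fraction) cell, and
tested per proteoform with a fixed-effects two-way ANOVA (state +
fraction, each fraction treated as a separate measure of the proteoform's
differential expression).  Benjamini-Hochberg FDR correction at
alpha = 0.05 yields q-values and DE flags; effect sizes are log2 fold
changes of raw state mean intensities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import MassGroup, ProteoformRecord

OBS_COLUMNS = [
    "proteoform_id", "neutral_mass_da", "rt_min", "fraction",
    "state", "gelfree_rep", "lcms_rep", "intensity",
]


def group_masses(
    observations: pd.DataFrame, mass_tol_ppm: float = 10.0, rt_tol_min: float = 5.0
) -> list[MassGroup]:
    """Cluster observations into mass groups by accurate mass and RT.

    Greedy agglomeration seeded in descending intensity order (ties broken
    by ascending mass): each unassigned seed collects all unassigned
    observations within ``mass_tol_ppm`` and ``rt_tol_min``; the
    intensity-weighted consensus is then refined until every member lies
    within tolerance of the consensus.  Deterministic for a given table.
    """
    if mass_tol_ppm <= 0 or rt_tol_min <= 0:
        raise ValueError("tolerances must be > 0")
    if observations.empty:
        return []
    mass = observations["neutral_mass_da"].to_numpy(dtype=float)
    rt = observations["rt_min"].to_numpy(dtype=float)
    inten = observations["intensity"].to_numpy(dtype=float)
    index = observations.index.to_numpy()
    n = mass.size

    seed_order = np.lexsort((mass, -inten))
    mass_order = np.argsort(mass, kind="stable")
    mass_sorted = mass[mass_order]
    assigned = np.zeros(n, dtype=bool)

    groups: list[MassGroup] = []
    for pos in seed_order:
        if assigned[pos]:
            continue
        tol = mass_tol_ppm * 1e-6 * mass[pos]
        lo = np.searchsorted(mass_sorted, mass[pos] - tol, side="left")
        hi = np.searchsorted(mass_sorted, mass[pos] + tol, side="right")
        cand = mass_order[lo:hi]
        cand = cand[~assigned[cand] & (np.abs(rt[cand] - rt[pos]) <= rt_tol_min)]
        members = cand
        for _ in range(5):
            w = inten[members]
            cm = float(np.average(mass[members], weights=w))
            rc = float(np.average(rt[members], weights=w))
            tol_c = mass_tol_ppm * 1e-6 * cm
            keep = (np.abs(mass[members] - cm) <= tol_c) & (
                np.abs(rt[members] - rc) <= rt_tol_min
            )
            if keep.all():
                break
            members = members[keep]
            if members.size == 0:
                members = np.array([pos])
        assigned[members] = True
        groups.append(
            MassGroup(len(groups) + 1, cm, rc, member_index=index[members])
        )
    return groups


def link_groups_to_proteoforms(
    groups: list[MassGroup],
    catalog: list[ProteoformRecord],
    precursor_tol_da: float = 2.2,
) -> list[MassGroup]:
    """Link each mass group to the nearest catalog proteoform by intact mass.

    The default 2.2 Da precursor tolerance is the conventional intact-mass
    window for isotopologue ambiguity.  Ties break by smaller absolute
    mass error, then lexicographic proteoform id; groups with no catalog
    mass within tolerance stay unlinked (and are excluded from
    quantitation downstream).
    """
    if precursor_tol_da < 0:
        raise ValueError("precursor_tol_da must be >= 0")
    if not catalog:
        raise ValueError("catalog is empty")
    cat = sorted(catalog, key=lambda r: (r.monoisotopic_mass, r.proteoform_id))
    cat_mass = np.array([r.monoisotopic_mass for r in cat])
    for g in groups:
        i = int(np.searchsorted(cat_mass, g.consensus_mass))
        best = None
        for j in range(max(i - 2, 0), min(i + 2, len(cat))):
            err = abs(cat_mass[j] - g.consensus_mass)
            if err <= precursor_tol_da:
                key = (err, cat[j].proteoform_id)
                if best is None or key < best[0]:
                    best = (key, cat[j])
        if best is not None:
            g.proteoform_id = best[1].proteoform_id
            g.mass_error_da = float(best[0][0])
        else:
            g.proteoform_id = None
            g.mass_error_da = None
    return groups


def linked_observation_table(
    groups: list[MassGroup], observations: pd.DataFrame
) -> pd.DataFrame:
    """Observation table restricted to linked groups, with ``proteoform_id``
    set from the linkage (the quantitation input)."""
    frames = []
    for g in groups:
        if g.proteoform_id is None:
            continue
        sub = observations.loc[g.member_index].copy()
        sub["proteoform_id"] = g.proteoform_id
        frames.append(sub)
    if not frames:
        return observations.iloc[0:0].copy()
    return pd.concat(frames).sort_index()


def standardize_within_fraction(
    observations: pd.DataFrame,
    value_col: str = "intensity",
    log_before: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize intensities within each (proteoform, fraction) cell.

    Subtracts the mean of all measurements of the proteoform within the
    fraction and divides by their sample standard deviation, so each cell
    is centred on zero with unit sd.  Cells with fewer than two
    measurements or zero variance are untestable and reported separately.

    Returns ``(standardized, untestable)``: the standardized table gains a
    ``z`` column; ``untestable`` lists (proteoform_id, fraction, reason).
    """
    df = observations.copy()
    x = np.log(df[value_col].to_numpy(dtype=float)) if log_before else df[
        value_col
    ].to_numpy(dtype=float)
    df["_x"] = x
    grp = df.groupby(["proteoform_id", "fraction"], sort=False)["_x"]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1
    count = grp.transform("count")
    ok = (count >= 2) & (sd > 0)
    out = df[ok].copy()
    out["z"] = (out["_x"] - mean[ok]) / sd[ok]
    out = out.drop(columns="_x")

    bad = df[~ok]
    reasons = np.where(count[~ok] < 2, "too_few_obs", "zero_variance")
    untestable = (
        pd.DataFrame({
            "proteoform_id": bad["proteoform_id"],
            "fraction": bad["fraction"],
            "reason": reasons,
        })
        .drop_duplicates()
        .reset_index(drop=True)
    )
    return out, untestable


def _anova_state_f(
    y: np.ndarray,
    state: np.ndarray,
    fraction: np.ndarray,
    gelfree: np.ndarray | None = None,
) -> tuple[float, float, float, int]:
    """F-test for the state term in y ~ state + fraction (+ gelfree).

    Fixed-effects two-way layout with fraction (and optionally GELFrEE
    replicate) as blocking factors.  Returns (p, state_effect, F, df_den).
    With a single fraction and balanced groups, F equals the square of the
    equal-variance two-sample t statistic.
    """
    n = y.size
    cols = [np.ones(n), (state == state.max()).astype(float)]
    for factor in ([fraction] if gelfree is None else [fraction, gelfree]):
        levels = np.unique(factor)
        for lev in levels[1:]:
            cols.append((factor == lev).astype(float))
    X = np.column_stack(cols)
    Xr = np.delete(X, 1, axis=1)

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = float(np.sum((y - X @ beta) ** 2))
    beta_r, *_ = np.linalg.lstsq(Xr, y, rcond=None)
    rss_red = float(np.sum((y - Xr @ beta_r) ** 2))

    df_den = n - int(np.linalg.matrix_rank(X))
    if df_den <= 0:
        return float("nan"), float(beta[1]), float("nan"), df_den
    if rss_full <= 0:
        p = 0.0 if rss_red > rss_full else 1.0
        return p, float(beta[1]), float("inf"), df_den
    F = (rss_red - rss_full) / (rss_full / df_den)
    p = float(stats.f.sf(F, 1, df_den))
    return p, float(beta[1]), float(F), df_den


def fit_hierarchical_anova(
    standardized: pd.DataFrame,
    include_gelfree: bool = False,
) -> tuple[float, float]:
    """State-term ANOVA p-value and effect direction for one proteoform.

    ``standardized`` holds that proteoform's testable rows with columns
    ``z``, ``state``, ``fraction`` (and ``gelfree_rep`` if blocking on
    GELFrEE replicate is requested).  Requires >= 2 observations per state.
    """
    states = standardized["state"].to_numpy()
    labels = np.unique(states)
    if labels.size < 2 or min((states == s).sum() for s in labels) < 2:
        raise ValueError("need >= 2 observations in each state")
    state_codes = (states == labels.max()).astype(int)
    p, eff, _f, _df = _anova_state_f(
        standardized["z"].to_numpy(dtype=float),
        state_codes,
        standardized["fraction"].to_numpy(),
        standardized["gelfree_rep"].to_numpy() if include_gelfree else None,
    )
    return p, eff


def estimate_log2fc(
    state1_intensities: np.ndarray, state2_intensities: np.ndarray
) -> float | None:
    """log2 of the ratio of raw state mean intensities (state2 / state1).

    Standardized values are z-scores and carry no scale, so the effect
    size is estimated from the raw intensities.  Returns None when either
    state has no observations (a present/absent situation, not a fold
    change).
    """
    a = np.asarray(state1_intensities, dtype=float)
    b = np.asarray(state2_intensities, dtype=float)
    if a.size == 0 or b.size == 0:
        return None
    return float(np.log2(b.mean() / a.mean()))


def bh_fdr(
    p_values, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: monotone adjusted q-values and DE flags.

    Rejects H(i) for all i <= k where k = max{i : p(i) <= i*alpha/m};
    equivalently flags entities with q <= alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def quantify_td(
    observations: pd.DataFrame,
    alpha: float = 0.05,
    log_before_standardize: bool = False,
    include_gelfree: bool = False,
    min_obs_per_state: int = 2,
    states: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-proteoform differential expression from linked TD observations.

    ``states`` fixes the (state1, state2) order used for the fold-change
    sign; by default the two labels are taken in sorted order.

    Returns ``(results, side)``.  ``results`` has one row per tested
    proteoform: entity_id, level, log2_fold_change, p_value, q_value,
    de_flag, n_obs_state1, n_obs_state2, n_fractions.  ``side`` lists
    untestable and present/absent entities with a reason, never silently
    dropped.
    """
    obs = observations[observations["proteoform_id"].notna()]
    if states is None:
        states = sorted(obs["state"].unique()) if not obs.empty else []
    else:
        states = list(states)
    std, untestable_cells = standardize_within_fraction(
        obs, log_before=log_before_standardize
    )

    std_groups = dict(tuple(std.groupby("proteoform_id", sort=False))) if not std.empty else {}

    rows = []
    side = []
    for pid, raw in obs.groupby("proteoform_id", sort=True):
        by_state = {s: raw.loc[raw["state"] == s, "intensity"].to_numpy() for s in states}
        n1 = by_state.get(states[0], np.array([])).size if states else 0
        n2 = by_state.get(states[1], np.array([])).size if len(states) > 1 else 0
        if n1 == 0 or n2 == 0:
            side.append((pid, "present_absent",
                         states[0] if n1 > 0 else (states[1] if n2 > 0 else "")))
            continue
        sub = std_groups.get(pid)
        counts = sub["state"].value_counts() if sub is not None else pd.Series(dtype=int)
        if (
            sub is None
            or counts.size < 2
            or counts.min() < min_obs_per_state
        ):
            side.append((pid, "insufficient_replication", ""))
            continue
        p, eff = fit_hierarchical_anova(sub, include_gelfree=include_gelfree)
        if not np.isfinite(p):
            side.append((pid, "insufficient_replication", ""))
            continue
        lfc = estimate_log2fc(by_state[states[0]], by_state[states[1]])
        rows.append({
            "entity_id": pid,
            "level": "proteoform",
            "log2_fold_change": lfc,
            "p_value": p,
            "n_obs_state1": n1,
            "n_obs_state2": n2,
            "n_fractions": sub["fraction"].nunique(),
        })

    results = pd.DataFrame(rows)
    if not results.empty:
        q, flags = bh_fdr(results["p_value"].to_numpy(), alpha=alpha)
        results["q_value"] = q
        results["de_flag"] = flags
        results = results[[
            "entity_id", "level", "log2_fold_change", "p_value", "q_value",
            "de_flag", "n_obs_state1", "n_obs_state2", "n_fractions",
        ]]
    else:
        results = pd.DataFrame(columns=[
            "entity_id", "level", "log2_fold_change", "p_value", "q_value",
            "de_flag", "n_obs_state1", "n_obs_state2", "n_fractions",
        ])
    side_df = pd.DataFrame(side, columns=["entity_id", "reason", "present_in"])
    return results, side_df


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano coordinates per tested proteoform, sorted by q ascending."""
    if results.empty:
        return pd.DataFrame(columns=["entity_id", "log2_fold_change",
                                     "neg_log10_q", "de_flag"])
    out = results[["entity_id", "log2_fold_change", "q_value", "de_flag"]].copy()
    out["neg_log10_q"] = -np.log10(np.clip(out["q_value"], 1e-300, None))
    out = out.sort_values(["q_value", "entity_id"]).reset_index(drop=True)
    return out[["entity_id", "log2_fold_change", "neg_log10_q", "de_flag"]]
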