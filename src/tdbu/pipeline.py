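"""Top-level orchestration: simulate -> TD quant + BU quant -> concordance.

All stage outputs are computed in memory and written together at the end,
so a failing stage leaves no partial result files.  The run log records
the config, seed and per-stage record counts; identical seeds give
byte-identical output bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bu, concordance, io, synthetic, td
from .types import EffectSpec


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent per-stage integer seeds derived from one master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_pipeline(config: io.PipelineConfig, out_dir, seed: int | None = None) -> dict:
    """Execute the full synthetic study and write the report bundle.

    Returns a dict with the in-memory stage outputs (catalog, tables,
    results, concordance summary) alongside writing TSV/JSON files plus a
    plain-text report to ``out_dir``.
    """
    if seed is None:
        seed = config.seed
    s_catalog, s_effects, s_td, s_bu = _spawn_seeds(seed, 4)
    design = config.design()
    stage = "generate_catalog"
    try:
        catalog = synthetic.generate_catalog(
            config.n_proteins,
            mass_range=design.mw_range,
            variant_fraction=config.variant_fraction,
            seed=s_catalog,
        )
        pf_to_protein = {r.proteoform_id: r.protein_accession for r in catalog}

        stage = "plant_effects"
        rng = np.random.default_rng(s_effects)
        accessions = sorted({r.protein_accession for r in catalog})
        protein_effects = synthetic.make_effects(
            accessions,
            de_fraction=config.de_fraction,
            log2fc_range=(config.log2fc_low, config.log2fc_high),
            missing_rate=config.bu_missing_rate,
            intensity_cv=config.intensity_cv,
            seed=rng,
        )
        protein_lfc = {e.entity_id: e.log2_fold_change for e in protein_effects}
        td_effects = [
            EffectSpec(
                r.proteoform_id,
                protein_lfc[r.protein_accession],
                missing_rate=config.td_missing_rate,
                intensity_scale=float(1e6 * rng.lognormal(0.0, 0.8)),
                intensity_cv=config.intensity_cv,
            )
            for r in catalog
        ]

        stage = "simulate_td_observations"
        td_obs = synthetic.simulate_td_observations(
            catalog, design, td_effects, seed=s_td
        )
        stage = "simulate_bu_counts"
        bu_counts = synthetic.simulate_bu_counts(
            catalog, design=design, effects=protein_effects, seed=s_bu
        )

        stage = "plant_present_absent"
        planted_pa = accessions[: config.n_present_absent]
        if planted_pa:
            pa_set = set(planted_pa)
            pa_pfs = {r.proteoform_id for r in catalog
                      if r.protein_accession in pa_set}
            s2 = design.states[1]
            td_obs = td_obs[
                ~(td_obs["proteoform_id"].isin(pa_pfs) & (td_obs["state"] == s2))
            ].reset_index(drop=True)
            bu_counts = bu_counts[
                ~(bu_counts["protein_accession"].isin(pa_set)
                  & (bu_counts["state"] == s2))
            ].reset_index(drop=True)

        stage = "td_quantitation"
        # the generated proteoform ids are ground truth; quantitation
        # re-derives linkage from mass and RT alone
        groups = td.group_masses(
            td_obs,
            mass_tol_ppm=config.mass_tol_ppm,
            rt_tol_min=config.rt_tol_min,
        )
        groups = td.link_groups_to_proteoforms(
            groups, catalog, precursor_tol_da=config.precursor_tol_da
        )
        linked = td.linked_observation_table(groups, td_obs)
        td_results, td_side = td.quantify_td(
            linked,
            alpha=config.td_alpha,
            log_before_standardize=config.log_before_standardize,
            states=design.states,
        )
        td_results["protein_accession"] = td_results["entity_id"].map(pf_to_protein)
        td_side["protein_accession"] = td_side["entity_id"].map(pf_to_protein)
        volcano = td.volcano_table(td_results)

        stage = "bu_quantitation"
        filtered = bu.apply_identification_filters(
            bu_counts, min_unique_peptides=config.min_unique_peptides
        )
        filtered, variant_report = bu.filter_variant_peptides(
            filtered, min_count_per_run=config.variant_min_count_per_run
        )
        bu_results = bu.protein_de_test(
            filtered, design,
            equal_variance=config.equal_variance,
            alpha=config.bu_alpha,
            pseudocount=config.pseudocount,
        )
        bu_missing = bu.report_missingness(filtered, design)

        stage = "concordance"
        rollup = concordance.rollup_proteoforms(td_results)
        table = concordance.classify(
            rollup, bu_results, convention=config.rollup_convention
        )
        summary = concordance.summarize(table)
        r, r2, paired_fc = concordance.foldchange_agreement(td_results, bu_results)
        summary["foldchange_pearson_r"] = r
        summary["foldchange_r_squared"] = r2
        summary["bu_missing_fraction"] = round(bu_missing, 4)
        summary["n_present_absent_td"] = int((td_side["reason"] == "present_absent").sum())
        summary["n_present_absent_bu"] = int((bu_results["call"] == "present_absent").sum())
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_catalog_fasta(catalog, out / "catalog.fasta")
    io.write_table(td_obs, out / "td_observations.tsv")
    io.write_table(bu_counts, out / "bu_counts.tsv")
    io.write_table(td_results, out / "td_results.tsv")
    io.write_table(td_side, out / "td_untestable.tsv")
    io.write_table(volcano, out / "td_volcano.tsv")
    io.write_table(bu_results, out / "bu_results.tsv")
    io.write_table(variant_report, out / "bu_variant_report.tsv")
    io.write_table(table.to_frame(), out / "concordance.tsv")
    io.write_table(paired_fc, out / "paired_foldchange.tsv")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    config.to_yaml(out / "config.yaml")

    config_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    present_absent = td_side[td_side["reason"] == "present_absent"]
    report_lines = [
        "tdbu pipeline report",
        f"seed: {seed}",
        f"config_hash: {config_hash}",
        f"design: {config.design_preset} "
        f"({design.n_gelfree_reps} GELFrEE x {design.n_lcms_reps} LC-MS x "
        f"{design.n_fractions} fractions)",
        f"catalog: {len(catalog)} proteoforms / {len(accessions)} proteins",
        f"td_observations: {len(td_obs)} rows",
        f"td mass groups: {len(groups)} "
        f"({sum(g.proteoform_id is not None for g in groups)} linked)",
        f"td tested proteoforms: {len(td_results)} "
        f"({int(td_results['de_flag'].sum()) if not td_results.empty else 0} DE)",
        f"td untestable/present-absent: {len(td_side)}",
        "td present/absent proteoforms: "
        + (", ".join(present_absent["entity_id"]) if len(present_absent) else "none"),
        f"bu_counts: {len(bu_counts)} rows "
        f"({bu_missing:.1%} peptide x run cells missing after filters)",
        f"bu tested proteins: {int((bu_results['call'] == 'tested').sum())} "
        f"({int(bu_results['de_flag'].sum())} DE)",
        "bu present/absent proteins: "
        + (", ".join(
            bu_results.loc[bu_results["call"] == "present_absent",
                           "protein_accession"])
           or "none"),
        f"concordance summary: {json.dumps(summary, sort_keys=True)}",
    ]
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")

    return {
        "catalog": catalog,
        "td_observations": td_obs,
        "bu_counts": bu_counts,
        "td_results": td_results,
        "td_side": td_side,
        "bu_results": bu_results,
        "concordance": table,
        "summary": summary,
    }
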