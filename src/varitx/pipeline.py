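"""End-to-end synthetic pipeline: simulate -> variability -> decode ->
enrich -> macroscale, with a JSON provenance record.

All tabular outputs are TSV and deterministic under fixed seeds, so a
rerun from the same configuration reproduces them byte for byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets, enrichment, io, macroscale
from .decoding import PLSModel, predictive_validation
from .spatial import build_weight_matrix, moran_eigenbasis
from .variability import VariabilityModel

DEFAULTS = {
    "seed": 0,
    "cohort": {},             # CohortConfig keyword overrides
    "expression": {},         # ExpressionConfig keyword overrides
    "n_boot": 500,
    "n_perm": 2000,
    "n_surr": 500,
    "gene_sets": {"n_sets": 7,
                  "overlap_fracs": [0.0, 0.1, 0.2, 0.3, 0.5, 0.8, 1.0],
                  "set_sizes": 20},
    "n_terms": 10,
    "manifest": None,
}


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the full synthetic analysis and write outputs plus provenance.

    ``config`` is a dict or a YAML/JSON path with the keys of
    ``pipeline.DEFAULTS`` (all optional).  Returns a report dict with the
    headline numbers; writes TSV tables and ``provenance.json`` under
    ``outdir``.
    """
    if not isinstance(config, dict):
        config = io.read_config(config)
    cfg = {**DEFAULTS, **(config or {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    qc_excluded = 0
    if cfg["manifest"] is not None:
        manifest = io.read_manifest(cfg["manifest"])
        qc_excluded = int((~manifest["qc_pass"]).sum())

    # --- simulate -------------------------------------------------------
    ccfg = datasets.CohortConfig(seed=seed, **cfg["cohort"])
    cohort = datasets.simulate_cohort(ccfg)
    ecfg = datasets.ExpressionConfig(seed=seed + 1, **cfg["expression"])
    expr, signal_mask = datasets.simulate_expression(cohort.gradient, ecfg)
    signal_genes = list(expr.columns[signal_mask])
    sets = datasets.simulate_gene_sets(
        signal_genes, list(expr.columns), seed=seed + 2,
        **cfg["gene_sets"])
    truth = pd.DataFrame({"voxel_id": np.arange(cohort.truth.size),
                          "inter_sd": cohort.truth,
                          "gradient": cohort.gradient,
                          "network": cohort.network_labels})
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    io.write_gmt(sets, outdir / "gene_sets.gmt")

    # --- variability ----------------------------------------------------
    vres = VariabilityModel(cohort.stack).fit()
    vres.to_frame().to_csv(outdir / "variability_maps.tsv", sep="\t")
    vres.network_table(cohort.network_labels).to_csv(
        outdir / "network_variability.tsv", sep="\t")

    # --- decode ---------------------------------------------------------
    pres = PLSModel(expr, vres.V_mean).fit(n_boot=int(cfg["n_boot"]),
                                           seed=seed + 3)
    pres.gene_table().to_csv(outdir / "pls_genes.tsv", sep="\t", index=False)
    w = build_weight_matrix(cohort.coords, k=8)
    basis = moran_eigenbasis(w)
    folds = predictive_validation(vres.V, expr, basis=basis,
                                  n_surr=int(cfg["n_surr"]), seed=seed + 4)
    folds.to_csv(outdir / "predictive_validation.tsv", sep="\t", index=False)

    # --- enrich ---------------------------------------------------------
    gene_list = pres.plus_list + pres.minus_list
    if not gene_list:                      # fall back to top |Z| decile
        gene_list = pres.gene_table()["gene"].head(
            max(1, len(expr.columns) // 10)).tolist()
    perm = enrichment.celltype_permutation(gene_list, sets,
                                           n_perm=int(cfg["n_perm"]),
                                           seed=seed + 5)
    perm.to_csv(outdir / "celltype_enrichment.tsv", sep="\t", index=False)
    ora = enrichment.ora_hypergeometric(gene_list, sets)
    ora.to_csv(outdir / "disease_ora.tsv", sep="\t", index=False)

    # --- macroscale -----------------------------------------------------
    index_stack = datasets.simulate_index_stack(
        mean_map=cohort.gradient, sd_field=0.2 + 0.3 * cohort.truth,
        n_subjects=cohort.stack.n_subjects, seed=seed + 6)
    index_var = macroscale.index_variability(index_stack)
    coupling = macroscale.map_correlation(
        vres.V_mean, index_var, coords=cohort.coords, weights=w,
        n_surr=int(cfg["n_surr"]), seed=seed + 7)
    coupling.to_csv(outdir / "macroscale_coupling.tsv", sep="\t", index=False)
    terms = datasets.simulate_term_maps(vres.V_mean, int(cfg["n_terms"]),
                                        seed=seed + 8)
    decoded = macroscale.behavior_decode(vres.V_mean, terms)
    decoded.to_csv(outdir / "behavior_terms.tsv", sep="\t", index=False)

    report = {
        "seed": seed,
        "n_voxels": int(cohort.truth.size),
        "n_subjects": int(cohort.stack.n_subjects),
        "n_sessions": int(cohort.stack.n_sessions),
        "qc_excluded_runs": qc_excluded,
        "pls_r_scores_map": pres.r_scores_y,
        "n_pls_plus": len(pres.plus_list),
        "n_pls_minus": len(pres.minus_list),
        "predictive_r_mean": float(folds["r"].mean()),
        "coupling_rho_whole": float(coupling["rho"].iloc[0]),
        "n_terms_selected": int(len(decoded)),
        "parameters": {k: v for k, v in cfg.items() if k != "manifest"},
        "stage_seeds": {"cohort": seed, "expression": seed + 1,
                        "gene_sets": seed + 2, "bootstrap": seed + 3,
                        "validation": seed + 4, "permutation": seed + 5,
                        "index_stack": seed + 6, "coupling": seed + 7,
                        "terms": seed + 8},
    }
    io.write_provenance(report, outdir / "provenance.json")
    return report
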