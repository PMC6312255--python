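"""End-to-end orchestration of the integrative dose-response analysis.

Stage order: (optional) simulation -> per-feature QC -> dose/age
deconvolution -> group-wise dose-response with shape filtration ->
transcript differential expression -> Fisher p-value integration with the
restrictive comparator -> gene-set enrichment of both feature lists ->
exploratory correlation and clustering. The run emits a machine-readable
summary (category counts, per-group deregulation counts, restrictive vs
integrative pair counts, term-set comparison) plus per-feature report
tables.
"""

from __future__ import annotations

import hashlib
import json
import platform
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .deconvolution import deconvolve_matrix
from .dose_response import dose_response_table, summarize_dose_sets
from .enrichment import compare_term_sets, fisher_enrich
from .explore import hierarchical_cluster, spearman_correlation, spearman_distance_matrix
from .integration import (
    coherence_report,
    integrate,
    map_features,
    protein_high_vs_control_p,
    restrictive_intersection,
)
from .io import (
    RunConfig,
    StudyBundle,
    ValidationError,
    read_study,
    write_feature_report,
)
from .preprocess import dixon_outlier_test
from .simulate import CohortDesign, simulate_study
from .transcript_de import replicate_correlation, run_de

__all__ = ["stage_seed", "run_all"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage child seed by stable hashing of the stage name."""
    return (zlib.crc32(stage.encode("utf-8")) ^ (global_seed * 2654435761)) % (2**31)


def _qc_outliers(bundle: StudyBundle, alpha: float) -> dict:
    """Count Dixon-flagged abundance values per sample (flagging only; the
    cohort this emulates showed no sample with a significant pile-up)."""
    flags_per_sample = {sid: 0 for sid in bundle.abundance.sample_ids}
    vals = bundle.abundance.values
    for _, row in vals.iterrows():
        x = row.to_numpy(float)
        mask = np.isfinite(x)
        if mask.sum() < 3 or np.ptp(x[mask]) == 0:
            continue
        flags = dixon_outlier_test(x[mask], alpha)
        for sid in row.index[mask][flags]:
            flags_per_sample[sid] += 1
    return flags_per_sample


def run_all(
    out_dir: str | Path,
    config: RunConfig | None = None,
    bundle: StudyBundle | None = None,
    design: CohortDesign | None = None,
    simulate: bool = False,
    input_paths: dict | None = None,
    qc_outlier_scan: bool = False,
) -> dict:
    """Run the complete pipeline and write reports + summary.json.

    Exactly one input source is used: ``bundle`` (in-memory), ``simulate``
    (synthetic study from ``design``), or ``input_paths`` (a dict with keys
    abundance, counts, metadata, map, genesets). Returns the summary dict;
    all randomness derives from ``config.seed`` through per-stage child
    seeds. The per-protein Dixon scan is off by default (it is a reporting
    aid, not an analysis dependency).
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    truth = None
    if bundle is None:
        if simulate:
            bundle, truth = simulate_study(design or CohortDesign(), stage_seed(config.seed, "simulate"))
        elif input_paths:
            required = {"abundance", "counts", "metadata", "map", "genesets"}
            missing = {k for k in required if input_paths.get(k) is None}
            if missing:
                raise ValidationError(f"missing input paths: {sorted(missing)}")
            for key in sorted(required):
                if not Path(input_paths[key]).exists():
                    raise ValidationError(f"input file not found: {input_paths[key]}")
            bundle = read_study(
                input_paths["abundance"],
                input_paths["counts"],
                input_paths["metadata"],
                input_paths["map"],
                input_paths["genesets"],
                config.dose_boundaries,
            )
        else:
            raise ValidationError("provide a bundle, input paths, or simulate=True")

    summary: dict = {
        "config": config.to_dict(),
        "versions": {"domix": __version__, "python": platform.python_version()},
    }

    # --- explore: dose-age confounding ------------------------------------
    rho, rho_p = spearman_correlation(bundle.metadata.dose, bundle.metadata.age)
    summary["dose_age_spearman"] = {"rho": rho, "p": rho_p}

    # --- QC ----------------------------------------------------------------
    if qc_outlier_scan:
        summary["dixon_flags_per_sample"] = _qc_outliers(bundle, config.posthoc_alpha)

    # --- deconvolution ------------------------------------------------------
    deconv, category_counts = deconvolve_matrix(bundle.abundance, bundle.metadata, config)
    write_feature_report(deconv, out_dir / "deconvolution.tsv")
    summary["category_counts"] = category_counts

    # --- dose-response on the dose-responsive features ----------------------
    dr = dose_response_table(bundle.abundance, bundle.metadata, config)
    write_feature_report(dr, out_dir / "dose_response.tsv")
    dose_only_ids = set(deconv.loc[deconv["category"] == "dose_only", "feature_id"])
    dr_dose_only = dr[dr["feature_id"].isin(dose_only_ids)]
    summary["dose_response"] = {
        "n_kw_significant": int((dr["q_value"] <= config.fdr_level).sum()),
        "pi0_hat": dr.attrs.get("pi0_hat"),
        "dose_only_sets": summarize_dose_sets(
            dr_dose_only, config.posthoc_alpha, config.fdr_level
        ),
        "all_sets": summarize_dose_sets(dr, config.posthoc_alpha, config.fdr_level),
    }

    # --- transcript DE ------------------------------------------------------
    rna_meta = bundle.metadata.subset(bundle.counts.sample_ids)
    groups = rna_meta.dose_group.to_numpy()
    de_table, removed = run_de(bundle.counts, groups, config.min_total_counts, reference="control")
    write_feature_report(de_table, out_dir / "transcript_de.tsv", id_column="gene_id")
    tested = de_table[~de_table["filtered"]]
    sig = tested[tested["bh_adjusted_p"] <= config.fdr_level]
    rep_corr = {
        g: replicate_correlation(bundle.counts, rna_meta.group_samples(g))["correlation"].mean()
        for g in ("control", "high")
        if len(rna_meta.group_samples(g)) >= 2
    }
    summary["transcript_de"] = {
        "n_genes_input": len(de_table),
        "n_filtered_low_counts": len(removed),
        "n_tested": int(len(tested)),
        "n_up": int((sig["log2_fold_change"] > 0).sum()),
        "n_down": int((sig["log2_fold_change"] < 0).sum()),
        "replicate_correlation": rep_corr,
    }

    # --- integration --------------------------------------------------------
    prot_p = protein_high_vs_control_p(bundle.abundance, bundle.metadata)
    if config.integration_protein_p == "dunnett":
        dn = dr.set_index("feature_id")
        prot_p = prot_p.merge(
            dn[["dunnett_p_high", "direction_high"]], left_on="protein_id", right_index=True
        )
        prot_p["protein_p"] = prot_p.pop("dunnett_p_high")
        prot_p["protein_direction"] = prot_p.pop("direction_high").astype(int)
    matched, unmapped = map_features(prot_p, de_table, bundle.feature_map)
    records = integrate(matched)
    if not records.empty:
        write_feature_report(records, out_dir / "integration.tsv", id_column="protein_id")
    restrictive = restrictive_intersection(matched, config.posthoc_alpha)
    integ_sig = records[records["bh_adjusted_combined_p"] <= config.fdr_level] if not records.empty else records
    summary["integration"] = {
        "n_pairs": int(len(records)),
        "n_unmapped_proteins": len(unmapped),
        "restrictive": {k: int(len(v)) for k, v in restrictive.items()},
        "n_integrative_significant": int(len(integ_sig)),
        "coherent_fraction": coherence_report(records, config.fdr_level) if not records.empty else None,
    }

    # --- enrichment: restrictive vs integrative gene lists ------------------
    # universe = genes that actually entered the pairing stage (one per
    # tested protein), not the whole transcriptome
    universe = sorted(set(matched["chosen_gene_id"])) if len(matched) else []
    restrictive_genes = sorted(
        set(pd.concat([restrictive["up"], restrictive["down"]])["chosen_gene_id"])
        if len(matched)
        else set()
    )
    integrative_genes = sorted(set(integ_sig["chosen_gene_id"])) if len(integ_sig) else []
    if universe:
        enr_r = fisher_enrich(set(restrictive_genes) & set(universe), universe, bundle.gene_sets)
        enr_i = fisher_enrich(set(integrative_genes) & set(universe), universe, bundle.gene_sets)
    else:
        enr_r = enr_i = pd.DataFrame()
    for name, tab in (("enrichment_restrictive.tsv", enr_r), ("enrichment_integrative.tsv", enr_i)):
        if not tab.empty:
            write_feature_report(tab, out_dir / name, id_column="set_name")
    terms_r = enr_r.loc[enr_r["bh_adjusted_p"] <= config.enrichment_alpha, "set_name"] if not enr_r.empty else []
    terms_i = enr_i.loc[enr_i["bh_adjusted_p"] <= config.enrichment_alpha, "set_name"] if not enr_i.empty else []
    summary["enrichment"] = compare_term_sets(terms_r, terms_i)

    # --- explore: clustering on dose-responsive significant proteins --------
    cluster_ids = sorted(
        dose_only_ids & set(dr.loc[dr["q_value"] <= config.fdr_level, "feature_id"])
    )
    if len(cluster_ids) >= 2:
        sub = bundle.abundance.values.loc[cluster_ids]
        from .io import AbundanceMatrix

        dist = spearman_distance_matrix(AbundanceMatrix(sub))
        clust = hierarchical_cluster(dist)
        labels = clust.cut(2)
        ctrl = bundle.metadata.group_samples("control")
        high = bundle.metadata.group_samples("high")
        ctrl_lab = set(labels[ctrl]) if ctrl else set()
        high_lab = set(labels[high]) if high else set()
        summary["clustering"] = {
            "n_features": len(cluster_ids),
            "leaf_order": clust.leaf_order,
            "control_high_separated": bool(
                len(ctrl_lab) == 1 and len(high_lab) == 1 and ctrl_lab != high_lab
            ),
        }

    if truth is not None:
        write_feature_report(truth, out_dir / "truth.tsv")

    payload = json.dumps(summary, indent=2, sort_keys=True, default=_jsonify)
    summary["config_hash"] = hashlib.sha256(payload.encode()).hexdigest()[:16]
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_jsonify) + "\n", encoding="utf-8"
    )
    return summary


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
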