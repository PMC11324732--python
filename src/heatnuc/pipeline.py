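"""End-to-end orchestration: simulate/load -> quantify -> test -> classify
-> cluster -> correlate, with PCA QC and a reproducibility manifest."""

from __future__ import annotations

import datetime
import json
import os
import sys
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import (
    ContrastThresholds,
    contrast_summary,
    dap_set,
    run_contrasts,
)
from .kinetic_classifier import (
    DEFAULT_RULES,
    classify_all,
    group_summary,
    load_rules,
    rules_hash,
)
from .omics_correlation import (
    category_proportions,
    correlate,
    match_condition_profiles,
)
from .profile_clustering import condition_profiles, cluster_unassigned, log2fc_profiles
from .quant_io import (
    AbundanceMatrix,
    SampleDesign,
    aggregate_peptides,
    impute_left_censored,
    log2_transform,
    median_center,
    presence_filter,
    read_abundance,
    read_design,
    read_peptides,
    read_transcript_counts,
    rpm_normalize,
    write_abundance,
)
from .synthetic_data import (
    SimulationConfig,
    simulate_proteome,
    simulate_transcripts,
)

__all__ = ["pca_scores", "run_all"]


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def pca_scores(
    m: AbundanceMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores and explained-variance fractions via SVD (QC only).

    Missing values are mean-imputed per protein before centering; rows
    that are entirely missing are dropped.
    """
    if m.scale != "log2":
        raise ValueError("PCA expects a log2 matrix")
    if m.data.shape[1] < 2:
        raise ValueError("need at least 2 samples for PCA")
    x = m.data.to_numpy(dtype=float)
    x = x[~np.all(np.isnan(x), axis=1)]
    row_mean = np.nanmean(x, axis=1, keepdims=True)
    x = np.where(np.isnan(x), row_mean, x)
    xt = x.T  # samples x proteins
    xt = xt - xt.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xt, full_matrices=False)
    total = float((s**2).sum())
    n_components = min(n_components, len(s))
    scores = u[:, :n_components] * s[:n_components]
    frac = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    out = pd.DataFrame(
        scores,
        index=m.data.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    out.index.name = "sample"
    return out, frac


def _atomic_write_json(obj: dict, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
    os.replace(tmp, path)


def run_all(config: dict, out_dir: str | Path) -> dict:
    """Run every stage described by ``config``; returns the manifest.

    Config keys (all optional unless noted): ``simulate`` (a
    SimulationConfig field mapping) or ``inputs`` (paths: design +
    proteins or peptides, optionally counts/totals/rna_design);
    ``quant``, ``diff``, ``classify``, ``cluster``, ``correlate``
    stage-parameter mappings.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "started": datetime.datetime.now().isoformat(),
        "config": config,
        "stages": {},
    }

    # --- stage: acquire -------------------------------------------------
    truth = None
    rna = None
    rna_design = None
    if "simulate" in config:
        sim_cfg = SimulationConfig(**config["simulate"])
        raw, truth = simulate_proteome(sim_cfg)
        design = sim_cfg.design()
        tc, rna_design, coupling = simulate_transcripts(truth, sim_cfg)
        rna = rpm_normalize(tc)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        design.to_frame().to_csv(out / "design.tsv", sep="\t", index=False)
        _log("simulate", f"{len(raw.data)} proteins, seed {sim_cfg.seed}")
    elif "inputs" in config:
        paths = config["inputs"]
        design = read_design(paths["design"])
        if "peptides" in paths:
            raw = aggregate_peptides(read_peptides(paths["peptides"]), design)
        else:
            raw = read_abundance(paths["proteins"], scale="raw")
        if "counts" in paths:
            tc = read_transcript_counts(paths["counts"], paths["totals"])
            rna = rpm_normalize(tc)
            rna_design = read_design(paths["rna_design"])
        _log("acquire", f"{len(raw.data)} proteins, {len(design)} samples")
    else:
        raise ValueError("config needs a 'simulate' or 'inputs' block")

    # --- stage: quantify ------------------------------------------------
    q = config.get("quant", {})
    m = log2_transform(raw)
    m = presence_filter(m, design, int(q.get("min_per_condition", 2)))
    if q.get("impute", False):
        m = impute_left_censored(
            m, design, quantile=float(q.get("impute_quantile", 0.01)),
            seed=int(q.get("impute_seed", 0)),
        )
    if q.get("median_center", False):
        m = median_center(m)
    write_abundance(m, out / "proteins_log2.tsv")
    manifest["stages"]["quantify"] = {"proteins_in": int(len(raw.data)),
                                      "proteins_kept": int(len(m.data))}
    _log("quantify", f"{len(m.data)} proteins retained")

    scores, frac = pca_scores(m)
    scores.assign(variance_fraction=np.resize(frac, len(scores))).to_csv(
        out / "pca_scores.tsv", sep="\t"
    )

    # --- stage: differential -------------------------------------------
    d = config.get("diff", {})
    th = ContrastThresholds(
        alpha=d.get("alpha", ContrastThresholds().alpha),
        mode=d.get("mode", "raw_p"),
    )
    ct = run_contrasts(m, design, th, adjust_method=d.get("adjust_method", "storey_lambda"))
    ct.to_csv(out / "contrasts.tsv", sep="\t", index=False, float_format="%.12g")
    summary = contrast_summary(ct)
    summary.to_csv(out / "contrast_summary.tsv", sep="\t", index=False)
    daps = dap_set(ct)
    pd.Series(daps, name="accession").to_csv(out / "daps.tsv", sep="\t", index=False)
    manifest["stages"]["differential"] = {
        "daps": len(daps),
        "per_contrast": summary.to_dict("records"),
    }
    _log("diff", f"{len(daps)} DAPs across 6 contrasts")

    # --- stage: classify ------------------------------------------------
    c = config.get("classify", {})
    rules = load_rules(c["rules"]) if "rules" in c else DEFAULT_RULES
    groups = classify_all(ct, rules)
    groups.to_csv(out / "groups.tsv", sep="\t", index=False)
    gsum = group_summary(groups)
    gsum.to_csv(out / "group_summary.tsv", sep="\t", index=False)
    n_classified = int((groups["group"] != "UNASSIGNED").sum())
    n_unassigned = int((groups["group"] == "UNASSIGNED").sum())
    assert n_classified + n_unassigned == len(daps), "partition identity violated"
    manifest["stages"]["classify"] = {
        "classified": n_classified,
        "unassigned": n_unassigned,
        "rules_hash": rules_hash(rules),
    }
    _log("classify", f"{n_classified} classified + {n_unassigned} unassigned "
                     f"= {len(daps)} DAPs")

    # --- stage: cluster -------------------------------------------------
    cl = config.get("cluster", {})
    unassigned = groups.loc[groups["group"] == "UNASSIGNED", "accession"]
    if len(unassigned) >= 3:
        space = cl.get("space", "abundance")
        if space == "abundance":
            profiles = condition_profiles(
                AbundanceMatrix(m.data.loc[unassigned], scale="log2"), design
            )
        elif space == "log2fc":
            profiles = log2fc_profiles(ct[ct["accession"].isin(set(unassigned))])
        else:
            raise ValueError(f"unknown clustering space {space!r}")
        members, like, gap_res = cluster_unassigned(
            profiles,
            k=cl.get("k"),
            kmax=int(cl.get("kmax", 12)),
            B=int(cl.get("B", 100)),
            seed=int(cl.get("seed", 0)),
            tau=float(cl.get("tau", 0.8)),
        )
        members.to_csv(out / "clusters.tsv", sep="\t", index=False)
        like.to_csv(out / "like_groups.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["stages"]["cluster"] = {
            "clustered": int(len(members)),
            "k": int(like["cluster"].max()),
            "chosen_by_gap": gap_res is not None,
            "space": space,
        }
        _log("cluster", f"{len(members)} proteins in {like['cluster'].max()} clusters")
    else:
        manifest["stages"]["cluster"] = {"skipped": "fewer than 3 unassigned DAPs"}
        _log("cluster", "skipped (fewer than 3 unassigned DAPs)")

    # --- stage: correlate -----------------------------------------------
    if rna is not None:
        co = config.get("correlate", {})
        dap_matrix = AbundanceMatrix(
            m.data.loc[m.data.index.intersection(daps)], scale="log2"
        )
        pairs = match_condition_profiles(
            dap_matrix, design, rna, rna_design,
            rna_pseudocount=float(co.get("pseudocount", 1.0)),
        )
        records = correlate(pairs)
        records.to_csv(out / "correlations.tsv", sep="\t", index=False,
                       float_format="%.6g")
        props, density = category_proportions(records)
        props.to_csv(out / "correlation_proportions.tsv", sep="\t", index=False)
        density.to_csv(out / "correlation_density.tsv", sep="\t", index=False)
        manifest["stages"]["correlate"] = {
            "genes": int(len(records)),
            "proportions": props.set_index("category")["fraction"].to_dict(),
        }
        _log("correlate", f"{len(records)} matched genes")
    else:
        manifest["stages"]["correlate"] = {"skipped": "no RNA inputs"}
        _log("correlate", "skipped (no RNA inputs)")

    manifest["finished"] = datetime.datetime.now().isoformat()
    _atomic_write_json(manifest, out / "manifest.json")
    return manifest
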