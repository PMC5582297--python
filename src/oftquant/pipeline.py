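"""End-to-end orchestration of the morphometry and proteomics stages.

Each run writes per-sample JSON reports, group-comparison JSON, TSV result
tables, and a manifest echoing the configuration and the record count at
every filter stage (counts are non-increasing along the pipeline, which
makes the filters auditable).  Outputs contain no timestamps: a rerun with
the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__, io
from .config import RunConfig, SampleSpec
from .fibril_metrics import (
    compute_orientation,
    mean_bundle_thickness,
    summarize_orientation,
    two_sample_t,
)
from .mito_metrics import analyze_mitochondria
from .pathway_scoring import analysis_input_filter, score_pathways
from .proteomics_quant import run_quantification
from .volumetrics import compute_volume_fractions

logger = logging.getLogger("oftquant")


def analyze_sample(sample: SampleSpec, thresholds) -> dict:
    """All morphometry reports for one labeled volume + annotation pair."""
    vol = io.read_labeled_volume(sample.volume_tiff, sample.volume_yaml)
    annotations = io.read_annotations(sample.annotations_tsv)
    fractions = compute_volume_fractions(vol)
    phis = [
        o.phi for o in (compute_orientation(a.axis_vector) for a in annotations)
        if o.phi is not None
    ]
    thetas = [
        o.theta for o in (compute_orientation(a.axis_vector) for a in annotations)
        if o.theta is not None
    ]
    report: dict = {
        "sample_id": sample.sample_id,
        "group": sample.group,
        "volume_fractions": fractions,
        "clusters": analyze_mitochondria(
            vol, gap_nm=thresholds.gap_nm, top_k=thresholds.top_k
        ),
    }
    if annotations:
        report["orientation_phi"] = summarize_orientation(
            phis, window_width=thresholds.window_width_deg
        )
        report["orientation_theta"] = summarize_orientation(
            thetas, window_width=thresholds.window_width_deg
        )
        report["thickness"] = mean_bundle_thickness(annotations)
    return report


def _metric_values(reports: list[dict], group: str) -> dict[str, list[float]]:
    vals: dict[str, list[float]] = {
        "myo_fraction": [], "mito_fraction": [], "thickness_mean": [],
        "phi_concentration": [], "theta_concentration": [],
    }
    for r in reports:
        if r["group"] != group:
            continue
        vals["myo_fraction"].append(r["volume_fractions"].myo_fraction_of_cytoplasm)
        vals["mito_fraction"].append(r["volume_fractions"].mito_fraction_of_cytoplasm)
        if "thickness" in r:
            vals["thickness_mean"].append(r["thickness"].mean)
            vals["phi_concentration"].append(r["orientation_phi"].max_window_fraction)
            vals["theta_concentration"].append(r["orientation_theta"].max_window_fraction)
    return vals


def run_morphometry(config: RunConfig) -> dict:
    """Per-sample morphometry + control-vs-banded comparisons, written to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports = [analyze_sample(s, config.thresholds) for s in config.samples]
    for r in reports:
        io.write_json(r, out / f"morphometry_{r['sample_id']}.json")

    comparisons: dict[str, object] = {}
    ctrl = _metric_values(reports, "control")
    band = _metric_values(reports, "banded")
    for metric in ctrl:
        if len(ctrl[metric]) >= 2 and len(band[metric]) >= 2:
            comparisons[metric] = two_sample_t(ctrl[metric], band[metric])
    io.write_json(comparisons, out / "group_comparisons.json")
    logger.info("morphometry: %d samples, %d comparisons", len(reports), len(comparisons))
    return {"reports": reports, "comparisons": comparisons}


def run_proteomics(config: RunConfig) -> dict:
    """PSM table -> differential abundance -> pathway scoring, written to disk."""
    if config.psm_tsv is None:
        raise ValueError("config.psm_tsv is required for the proteomics stage")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds

    psms = io.read_psm_table(config.psm_tsv)
    if len(psms) == 0:
        logger.warning("empty PSM table: writing empty outputs")
    table, results, counts = run_quantification(
        psms,
        normalize=config.normalize_channels,
        reporter_floor=th.reporter_floor,
    )
    diff = results.reset_index()
    diff.to_csv(out / "differential_abundance.tsv", sep="\t", index=False)
    counts[f"significant_q_lt_{th.q_cutoff}"] = int((results["q"] < th.q_cutoff).sum())

    pathway_rows = []
    if config.pathways_tsv is not None and len(table) > 0:
        definitions = io.read_pathways(config.pathways_tsv)
        selected = analysis_input_filter(
            table,
            results,
            intensity_floor=th.intensity_floor,
            p_max=th.input_p_max,
        )
        counts["pathway_input_proteins"] = int(len(selected))
        fold_signs = {
            str(p): (1 if f >= 1 else -1) for p, f in selected["fold"].items()
        }
        universe = set(map(str, table.index))
        scored = score_pathways(
            fold_signs,
            definitions,
            universe,
            z_threshold=th.z_threshold,
            p_threshold=th.pathway_p_max,
        )
        pathway_rows = [
            {
                "pathway_id": r.pathway_id,
                "p": r.p,
                "z": r.z,
                "ratio": r.ratio,
                "call": r.call,
            }
            for r in scored
        ]
    pd.DataFrame(
        pathway_rows, columns=["pathway_id", "p", "z", "ratio", "call"]
    ).to_csv(out / "pathway_results.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": asdict(config.thresholds),
        "normalize_channels": config.normalize_channels,
        "stage_counts": counts,
    }
    io.write_json(manifest, out / "manifest.json")
    logger.info("proteomics stage counts: %s", counts)
    return {"table": table, "results": results, "counts": counts, "pathways": pathway_rows}


def run_all(config: RunConfig) -> dict:
    """Morphometry (if samples listed) then proteomics (if PSM input given)."""
    out: dict = {}
    if config.samples:
        out["morphometry"] = run_morphometry(config)
    if config.psm_tsv is not None:
        out["proteomics"] = run_proteomics(config)
    return out
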