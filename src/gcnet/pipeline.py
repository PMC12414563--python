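"""End-to-end orchestration: simulate -> connectivity -> sparsify -> graph
metrics -> directional indices -> group statistics.

Every stage is importable on its own; ``run_pipeline`` sequences them with a
single seed, writes standard text outputs (TSV matrices, tidy CSVs, JSON
report) into a run directory and returns the in-memory results.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dirindex, graphmetrics, sparsify, specgc, stats
from .synthcohort import Cohort, CohortConfig, generate_cohort, read_cohort

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "cohort_band_adjacency"]


@dataclass
class RunConfig:
    """Pipeline settings; defaults mirror the reference analysis (500 Hz
    sampling, AR order 30, 0.1 Hz spectral resolution, four canonical bands,
    5000 permutations, uncorrected edge alpha .05)."""

    fs: float = 500.0
    ar_order: int = 30
    freq_resolution: float = 0.1
    bands: dict = field(default_factory=lambda: {
        k: list(v) for k, v in specgc.DEFAULT_BANDS.items()})
    n_perm: int = 5000
    edge_alpha: float = 0.05
    sparsify: bool = True
    seed: int = 0
    contrast_family_global: int = 4  # bands, for GE/LE
    contrast_family_directional: int = 8  # band x direction
    omnibus: bool = True  # fit the mixed-model omnibus (skippable in sweeps)

    def bands_tuples(self) -> dict[str, tuple[float, float]]:
        return {k: (float(v[0]), float(v[1])) for k, v in self.bands.items()}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class PipelineResult:
    config: RunConfig
    band_adjacency: dict[str, np.ndarray]  # band -> (n_subjects, R, R)
    groups: list[str]
    subject_ids: list[str]
    roi_labels: list[str]
    edge_stats: dict[str, sparsify.EdgeStats]
    sparse: dict[str, sparsify.SparseBandConnectivity]
    metrics: pd.DataFrame  # subject_id, group, band, GE, LE
    centralities: pd.DataFrame
    node_significance: dict[tuple[str, str], graphmetrics.NodeSignificance]
    indices: pd.DataFrame
    contrasts: pd.DataFrame
    omnibus: dict[str, pd.DataFrame]
    report: dict


def cohort_band_adjacency(
    cohort: Cohort,
    config: RunConfig,
) -> tuple[dict[str, np.ndarray], dict]:
    """Band adjacency stacks (band -> (n_subjects, R, R)) for every subject,
    with a completeness report (fit failures, clamp counts)."""
    bands = config.bands_tuples()
    stacks: dict[str, list[np.ndarray]] = {b: [] for b in bands}
    n_failed = 0
    n_clamped = 0
    for ts in cohort.subjects:
        conn = specgc.connectivity_matrices(ts, p=config.ar_order,
                                            freq_resolution=config.freq_resolution)
        n_failed += len(conn.failed_pairs)
        n_clamped += conn.n_clamped
        bc = specgc.band_average(conn, bands)
        for b in bands:
            stacks[b].append(bc.adjacency[b])
    report = {"n_failed_pairs": n_failed, "n_clamped": n_clamped}
    return {b: np.asarray(v) for b, v in stacks.items()}, report


def run_pipeline(
    config: RunConfig,
    cohort: Cohort | CohortConfig | str | Path,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on a cohort (an in-memory Cohort, a CohortConfig
    to simulate, or a directory containing manifest.csv)."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if isinstance(cohort, CohortConfig):
        cohort = generate_cohort(cohort)
    elif isinstance(cohort, (str, Path)):
        cohort = read_cohort(cohort)
    timings["cohort"] = time.perf_counter() - t0

    labels = cohort.roi_labels
    groups = list(cohort.groups)
    subject_ids = [s.subject_id for s in cohort.subjects]
    low_idx = [i for i, g in enumerate(groups) if g == "low"]
    high_idx = [i for i, g in enumerate(groups) if g == "high"]
    rng = np.random.default_rng(config.seed)
    stage_seeds = rng.integers(0, 2 ** 31 - 1, size=64)
    seed_iter = iter(int(s) for s in stage_seeds)

    t0 = time.perf_counter()
    band_adj, conn_report = cohort_band_adjacency(cohort, config)
    timings["connectivity"] = time.perf_counter() - t0

    # sparsification by group-contrast permutation test
    t0 = time.perf_counter()
    edge_stats: dict[str, sparsify.EdgeStats] = {}
    sparse: dict[str, sparsify.SparseBandConnectivity] = {}
    for band, stack in band_adj.items():
        st = sparsify.edge_permutation_test(
            stack[low_idx], stack[high_idx], n_perm=config.n_perm,
            seed=next(seed_iter), band=band)
        edge_stats[band] = st
        sparse[band] = sparsify.apply_sparsity_mask(
            stack, st, alpha=config.edge_alpha, bypass=not config.sparsify)
    timings["sparsify"] = time.perf_counter() - t0

    # graph metrics
    t0 = time.perf_counter()
    metric_rows = []
    cent_rows = []
    centralities: dict[str, list[graphmetrics.NodeCentrality]] = {}
    for band, sp in sparse.items():
        cents = []
        for k, sid in enumerate(subject_ids):
            A = sp.matrices[k]
            ge = graphmetrics.global_efficiency(A)
            le = graphmetrics.local_efficiency(A)
            metric_rows.append({"subject_id": sid, "group": groups[k],
                                "band": band, "GE": ge, "LE": le})
            nc = graphmetrics.degree_centralities(A, subject_id=sid, band=band)
            cents.append(nc)
            for r, lab in enumerate(labels):
                cent_rows.append({"subject_id": sid, "group": groups[k],
                                  "band": band, "roi": lab,
                                  "outdegree": nc.outdegree[r],
                                  "indegree": nc.indegree[r]})
        centralities[band] = cents
    metrics = pd.DataFrame(metric_rows)
    cent_df = pd.DataFrame(cent_rows)
    timings["graph"] = time.perf_counter() - t0

    # node significance and directional indices
    t0 = time.perf_counter()
    part = dirindex.partition_rois(cohort.partition) if cohort.partition is not None \
        else None
    node_sig: dict[tuple[str, str], graphmetrics.NodeSignificance] = {}
    idx_rows = []
    for band, cents in centralities.items():
        sig_by_metric = {}
        for metric in ("outdegree", "indegree"):
            sig = graphmetrics.node_significance(
                [cents[i] for i in low_idx], [cents[i] for i in high_idx],
                metric, n_perm=config.n_perm, seed=next(seed_iter),
                labels=labels, band=band)
            node_sig[(band, metric)] = sig
            sig_by_metric[metric] = sig
        if part is None:
            continue
        for k, sid in enumerate(subject_ids):
            di = dirindex.compute_directional_indices(
                sparse[band].matrices[k], labels,
                sig_by_metric["outdegree"], sig_by_metric["indegree"],
                part, subject_id=sid, band=band)
            idx_rows.append({
                "subject_id": sid, "group": groups[k], "band": band,
                "OutFP": di.OutFP, "OutPF": di.OutPF,
                "InFP": di.InFP, "InPF": di.InPF,
                "CI_fp": di.CI_fp, "CI_pf": di.CI_pf,
                **{f"size_{k2}": v for k2, v in di.sizes.items()},
            })
    indices = pd.DataFrame(idx_rows)
    timings["indices"] = time.perf_counter() - t0

    # group statistics
    t0 = time.perf_counter()
    contrast_rows = []
    for band in sparse:
        sub = metrics[metrics["band"] == band]
        for measure in ("GE", "LE"):
            cr = stats.planned_contrast(
                sub.loc[sub["group"] == "low", measure].tolist(),
                sub.loc[sub["group"] == "high", measure].tolist(),
                family_size=config.contrast_family_global,
                measure=measure, band=band)
            contrast_rows.append(dataclasses.asdict(cr))
        if not indices.empty:
            isub = indices[indices["band"] == band]
            for measure in ("CI_fp", "CI_pf"):
                lo = isub.loc[isub["group"] == "low", measure].tolist()
                hi = isub.loc[isub["group"] == "high", measure].tolist()
                lo = [v for v in lo if v is not None and np.isfinite(v)]
                hi = [v for v in hi if v is not None and np.isfinite(v)]
                if len(lo) >= 2 and len(hi) >= 2:
                    cr = stats.planned_contrast(
                        lo, hi, family_size=config.contrast_family_directional,
                        measure=measure, band=band)
                    contrast_rows.append(dataclasses.asdict(cr))
    contrasts = pd.DataFrame(contrast_rows)

    omnibus: dict[str, pd.DataFrame] = {}
    for measure in ("GE", "LE") if config.omnibus else ():
        tidy = metrics.rename(columns={measure: "value"})[
            ["subject_id", "group", "band", "value"]]
        omnibus[measure] = stats.omnibus_model(tidy, factors=("group", "band"))
    if config.omnibus and not indices.empty:
        tidy = indices.melt(
            id_vars=["subject_id", "group", "band"],
            value_vars=["CI_fp", "CI_pf"],
            var_name="direction", value_name="value")
        tidy["direction"] = tidy["direction"].str.replace("CI_", "", regex=False)
        if tidy["value"].notna().any():
            omnibus["CI"] = stats.omnibus_model(
                tidy, factors=("group", "band", "direction"))
    timings["stats"] = time.perf_counter() - t0

    report = {
        "config": json.loads(config.to_json()),
        "n_subjects": len(subject_ids),
        "n_rois": len(labels),
        "connectivity": conn_report,
        "mask_density": {b: float(sp.mask.mean()) for b, sp in sparse.items()},
        "retained_edges": {b: sp.retained_count for b, sp in sparse.items()},
        "significant_nodes": {
            f"{band}:{metric}": sig.significant_nodes
            for (band, metric), sig in node_sig.items()},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }

    result = PipelineResult(
        config=config, band_adjacency=band_adj, groups=groups,
        subject_ids=subject_ids, roi_labels=labels, edge_stats=edge_stats,
        sparse=sparse, metrics=metrics, centralities=cent_df,
        node_significance=node_sig, indices=indices, contrasts=contrasts,
        omnibus=omnibus, report=report)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = result.roi_labels
    mat_dir = out_dir / "matrices"
    mat_dir.mkdir(exist_ok=True)
    for band, sp in result.sparse.items():
        pd.DataFrame(sp.mask.astype(int), index=labels, columns=labels).to_csv(
            mat_dir / f"mask_{band}.tsv", sep="\t")
        st = result.edge_stats[band]
        pd.DataFrame(st.t_obs, index=labels, columns=labels).to_csv(
            mat_dir / f"t_{band}.tsv", sep="\t", float_format="%.6g")
        pd.DataFrame(st.p_perm, index=labels, columns=labels).to_csv(
            mat_dir / f"p_{band}.tsv", sep="\t", float_format="%.6g")
        for k, sid in enumerate(result.subject_ids):
            pd.DataFrame(sp.matrices[k], index=labels, columns=labels).to_csv(
                mat_dir / f"{sid}_{band}.tsv", sep="\t", float_format="%.6g")
    result.metrics.to_csv(out_dir / "metrics.csv", index=False,
                          float_format="%.8g")
    result.centralities.to_csv(out_dir / "centralities.csv", index=False,
                               float_format="%.8g")
    result.indices.to_csv(out_dir / "indices.csv", index=False,
                          float_format="%.8g")
    result.contrasts.to_csv(out_dir / "contrasts.csv", index=False,
                            float_format="%.8g")
    sig_rows = []
    for (band, metric), sig in result.node_significance.items():
        for i, lab in enumerate(sig.labels):
            sig_rows.append({"band": band, "metric": metric, "roi": lab,
                             "t": sig.t_obs[i], "p_raw": sig.p_raw[i],
                             "p_bonferroni": sig.p_bonferroni[i],
                             "significant": lab in sig.significant_nodes})
    pd.DataFrame(sig_rows).to_csv(out_dir / "node_significance.csv",
                                  index=False, float_format="%.6g")
    for measure, tab in result.omnibus.items():
        tab.to_csv(out_dir / f"omnibus_{measure}.csv", index=False,
                   float_format="%.6g")
    (out_dir / "report.json").write_text(json.dumps(result.report, indent=2))
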