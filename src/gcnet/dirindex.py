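"""Directional fronto-posterior connectivity indices.

ROIs are partitioned into frontal, posterior (parieto-occipital) and
temporo-central clusters; the temporo-central cluster is excluded.  For each
subject and band, four directional indices average the sparse connectivity
over specific subnetworks anchored on the group-significant nodes:

  OutFP = sum of edges from significant frontal nodes to all posterior
          nodes / (N_p * N_fo)
  OutPF = sum of edges from significant posterior nodes to all frontal
          nodes / (N_f * N_po)
  InFP  = sum of edges from all frontal nodes into significant posterior
          nodes / (N_pi * N_f)
  InPF  = sum of edges from all posterior nodes into significant frontal
          nodes / (N_fi * N_p)

where N_f / N_p are the frontal / posterior cluster sizes and N_fo, N_po,
N_pi, N_fi count the significant frontal/posterior nodes by Outdegree or
Indegree.  The combined indices CI_fp (top-down) and CI_pf (bottom-up)
average the Out and In components.  An index whose significant-node set is
empty is undefined and propagates as missing (None), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .graphmetrics import NodeSignificance

__all__ = [
    "RoiPartition",
    "DirectionalIndices",
    "load_default_atlas",
    "partition_rois",
    "directional_index",
    "combine_indices",
    "compute_directional_indices",
]

CLUSTERS = ("frontal", "posterior", "temporo-central")


@dataclass(frozen=True)
class RoiPartition:
    frontal: tuple[str, ...]
    posterior: tuple[str, ...]
    excluded: tuple[str, ...]  # temporo-central

    @property
    def n_frontal(self) -> int:
        return len(self.frontal)

    @property
    def n_posterior(self) -> int:
        return len(self.posterior)


@dataclass
class DirectionalIndices:
    subject_id: str
    band: str
    OutFP: float | None
    OutPF: float | None
    InFP: float | None
    InPF: float | None
    CI_fp: float | None
    CI_pf: float | None
    sizes: dict[str, int]  # out_fp, out_pf, in_fp, in_pf subnetwork sizes


def load_default_atlas() -> pd.DataFrame:
    """Packaged 68-ROI Desikan-Killiany table with lobe and cluster columns
    (22 frontal, 18 posterior, 28 temporo-central labels)."""
    with resources.files("gcnet.data").joinpath(
            "desikan_killiany_68.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def partition_rois(atlas: pd.DataFrame) -> RoiPartition:
    """Split an atlas table (columns ``label`` and ``cluster``) into the
    three disjoint clusters.  Every label must appear exactly once and carry
    a known cluster."""
    if "label" not in atlas.columns or "cluster" not in atlas.columns:
        raise ValueError("atlas table needs 'label' and 'cluster' columns")
    labels = list(atlas["label"])
    if len(set(labels)) != len(labels):
        dup = [l for l in labels if labels.count(l) > 1]
        raise ValueError(f"duplicate atlas labels: {sorted(set(dup))}")
    unknown = set(atlas["cluster"]) - set(CLUSTERS)
    if unknown:
        raise ValueError(f"unknown cluster(s): {sorted(unknown)}")
    by = {c: tuple(atlas.loc[atlas["cluster"] == c, "label"]) for c in CLUSTERS}
    return RoiPartition(frontal=by["frontal"], posterior=by["posterior"],
                        excluded=by["temporo-central"])


def _index_sets(labels: list[str], part: RoiPartition) -> tuple[list[int], list[int]]:
    pos = {lab: i for i, lab in enumerate(labels)}
    missing = [l for l in part.frontal + part.posterior if l not in pos]
    if missing:
        raise ValueError(f"partition labels absent from matrix: {missing}")
    return [pos[l] for l in part.frontal], [pos[l] for l in part.posterior]


def directional_index(
    A: np.ndarray,
    labels: list[str],
    sig: NodeSignificance,
    part: RoiPartition,
    degree_kind: str,
    direction: str,
) -> tuple[float | None, int]:
    """One directional index for one subject matrix.

    degree_kind 'out' uses Outdegree significance (edges exit significant
    nodes); 'in' uses Indegree significance (edges enter significant nodes).
    direction 'fp' is fronto-posterior (top-down), 'pf' posterior-frontal.
    Returns (value or None, subnetwork size); the value is None exactly when
    the relevant significant-node set is empty.
    """
    if degree_kind not in ("out", "in") or direction not in ("fp", "pf"):
        raise ValueError("degree_kind in {'out','in'}, direction in {'fp','pf'}")
    expected_metric = "outdegree" if degree_kind == "out" else "indegree"
    if sig.metric != expected_metric:
        raise ValueError(
            f"significance computed for {sig.metric}, need {expected_metric}")
    A = np.asarray(A, dtype=float)
    f_idx, p_idx = _index_sets(labels, part)
    sig_set = set(sig.significant_nodes)
    sig_f = [i for i in f_idx if labels[i] in sig_set]
    sig_p = [i for i in p_idx if labels[i] in sig_set]

    if degree_kind == "out" and direction == "fp":
        src, tgt, size = sig_f, p_idx, len(p_idx) * len(sig_f)
    elif degree_kind == "out" and direction == "pf":
        src, tgt, size = sig_p, f_idx, len(f_idx) * len(sig_p)
    elif degree_kind == "in" and direction == "fp":
        src, tgt, size = f_idx, sig_p, len(sig_p) * len(f_idx)
    else:  # in, pf
        src, tgt, size = p_idx, sig_f, len(sig_f) * len(p_idx)

    if size == 0:
        return None, 0
    total = float(A[np.ix_(src, tgt)].sum())
    return total / size, size


def combine_indices(out_idx: float | None, in_idx: float | None,
                    direction: str) -> float | None:
    """CI = mean of the defined Out/In components; a single defined component
    passes through unchanged; both undefined -> undefined."""
    if direction not in ("fp", "pf"):
        raise ValueError("direction must be 'fp' or 'pf'")
    defined = [v for v in (out_idx, in_idx) if v is not None]
    if not defined:
        return None
    return float(np.mean(defined))


def compute_directional_indices(
    A: np.ndarray,
    labels: list[str],
    sig_out: NodeSignificance,
    sig_in: NodeSignificance,
    part: RoiPartition,
    *,
    subject_id: str = "",
    band: str = "",
) -> DirectionalIndices:
    """All four directional indices plus CI_fp / CI_pf for one subject/band."""
    out_fp, s_ofp = directional_index(A, labels, sig_out, part, "out", "fp")
    out_pf, s_opf = directional_index(A, labels, sig_out, part, "out", "pf")
    in_fp, s_ifp = directional_index(A, labels, sig_in, part, "in", "fp")
    in_pf, s_ipf = directional_index(A, labels, sig_in, part, "in", "pf")
    return DirectionalIndices(
        subject_id=subject_id, band=band,
        OutFP=out_fp, OutPF=out_pf, InFP=in_fp, InPF=in_pf,
        CI_fp=combine_indices(out_fp, in_fp, "fp"),
        CI_pf=combine_indices(out_pf, in_pf, "pf"),
        sizes={"out_fp": s_ofp, "out_pf": s_opf, "in_fp": s_ifp, "in_pf": s_ipf},
    )
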