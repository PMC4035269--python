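"""Tissue-specific protease webs from an expression matrix.

Expression is a proteins x tissues matrix of A-values (log-scale average
microarray signal intensity, unitless).  A detection threshold is derived
from negative-control probe intensities as a nearest-rank quantile
(default: the 95th percentile), and a tissue's subnetwork is the induced
subgraph on the proteins whose A-value strictly exceeds the threshold in
that tissue.  The survey then takes each tissue subnetwork's largest weak
component, computes its reachability AUC, and counts how many of a
supplied connector set are expressed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import frozen_auc, reachability
from .graph import ProteaseWebGraph, largest_connected_component

__all__ = [
    "ExpressionMatrix",
    "TissueSurveyRow",
    "load_expression",
    "derive_threshold",
    "tissue_subnetwork",
    "tissue_survey",
    "write_survey_report",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """A-value matrix (rows: accessions, columns: tissues) plus the
    negative-control intensity vector used to derive the threshold."""

    values: pd.DataFrame
    negative_controls: np.ndarray

    def __post_init__(self) -> None:
        self.negative_controls = np.asarray(self.negative_controls,
                                            dtype=float)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    def expressed(self, tissue: str, threshold: float) -> set[str]:
        """Accessions with A-value strictly above threshold in a tissue."""
        if tissue not in self.values.columns:
            raise KeyError(f"unknown tissue {tissue!r}")
        col = self.values[tissue]
        return set(col.index[col > threshold])


@dataclass(frozen=True)
class TissueSurveyRow:
    tissue: str
    n_expressed: int
    lcc_size: int
    auc: float
    connector_presence_count: int


def load_expression(matrix_tsv, controls_tsv) -> ExpressionMatrix:
    """Read the A-value matrix (first column: accession) and the
    single-column negative-control TSV."""
    df = pd.read_csv(matrix_tsv, sep="\t", index_col=0)
    controls = pd.read_csv(controls_tsv, sep="\t")
    return ExpressionMatrix(values=df,
                            negative_controls=controls.iloc[:, 0].to_numpy())


def derive_threshold(negative_controls, q: float = 0.95) -> float:
    """Expression cutoff: nearest-rank q-quantile of the control A-values.

    The threshold is the smallest control value c such that at least a
    fraction q of the controls are <= c — the ceil(q*n)-th order statistic
    (inverse empirical CDF convention).  q = 1 yields the maximum.
    """
    controls = np.asarray(negative_controls, dtype=float)
    if controls.size == 0:
        raise ValueError("negative-control vector is empty")
    if not 0.0 < q <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    rank = max(1, math.ceil(q * controls.size))
    return float(np.sort(controls)[rank - 1])


def tissue_subnetwork(
    web: ProteaseWebGraph,
    expression: ExpressionMatrix,
    tissue: str,
    threshold: float,
) -> ProteaseWebGraph:
    """Induced subgraph on the proteins expressed in one tissue.

    Graph nodes absent from the expression matrix are treated as not
    expressed and dropped; their count is logged.
    """
    expressed = expression.expressed(tissue, threshold)
    nodes = [n for n in web.g.nodes if n in expressed]
    missing = sum(1 for n in web.g.nodes if n not in expression.values.index)
    if missing:
        logger.info("tissue %s: %d graph node(s) absent from the expression "
                    "matrix treated as not expressed", tissue, missing)
    return web.induced_subgraph(nodes, f"tissue:{tissue}")


def tissue_survey(
    web: ProteaseWebGraph,
    expression: ExpressionMatrix,
    threshold: float,
    connector_set: set[str],
    global_reference: bool = False,
) -> list[TissueSurveyRow]:
    """Per-tissue connectivity survey.

    For each tissue: induce the subnetwork, take its largest weak
    component, compute the reachability AUC (normalized to the tissue LCC
    size by default, or to the full web size with ``global_reference``),
    and count the connectors present in the expressed node set.
    """
    unknown = connector_set - set(web.g.nodes)
    if unknown:
        raise KeyError(f"connector(s) not in graph: {sorted(unknown)}")
    rows = []
    for tissue in expression.tissues:
        sub = tissue_subnetwork(web, expression, tissue, threshold)
        expressed_nodes = set(sub.g.nodes)
        if sub.n_nodes == 0:
            rows.append(TissueSurveyRow(tissue, 0, 0, 0.0, 0))
            continue
        lcc = largest_connected_component(sub, mode="weak")
        ref = web.n_nodes if global_reference else lcc.n_nodes
        profile = reachability(lcc, reference_n=ref)
        rows.append(TissueSurveyRow(
            tissue=tissue,
            n_expressed=sub.n_nodes,
            lcc_size=lcc.n_nodes,
            auc=frozen_auc(profile),
            connector_presence_count=len(connector_set & expressed_nodes),
        ))
    return rows


def write_survey_report(rows: list[TissueSurveyRow], tsv_path) -> None:
    lines = ["tissue\tn_expressed\tlcc_size\tauc\tconnector_presence_count"]
    for r in rows:
        lines.append(f"{r.tissue}\t{r.n_expressed}\t{r.lcc_size}"
                     f"\t{r.auc:.6f}\t{r.connector_presence_count}")
    with open(tsv_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
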