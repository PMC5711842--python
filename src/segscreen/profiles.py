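"""Concentration-dependence summaries and compound-parameter networks.

Treatments are classified as lethal / any-defect / no-defect, counted per
(experiment, concentration) cell, summarized as mean +/- SD across
experiments, and tested with a two-factor ANOVA (concentration, experiment;
no interaction term — one observation per cell).  Per-slice bipartite
compound-parameter networks are exported as SIF or GraphML for Cytoscape.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np
from scipy import stats

from .errors import FormatError, ValidationError
from .model import ScreenTable, format_concentration

logger = logging.getLogger(__name__)

TREATMENT_CLASSES = ("lethal", "any_defect", "no_defect")


def classify_treatments(table: ScreenTable) -> Dict[str, str]:
    """Per-treatment class: lethal beats any_defect (any score > 0) beats
    no_defect.  Non-lethal unscored treatments are unclassifiable and omitted
    with a warning."""
    classes: Dict[str, str] = {}
    n_unclassifiable = 0
    for r in table.records:
        if r.lethal:
            classes[r.treatment_id] = "lethal"
        elif r.vector is None:
            n_unclassifiable += 1
        elif r.vector.any_defect:
            classes[r.treatment_id] = "any_defect"
        else:
            classes[r.treatment_id] = "no_defect"
    if n_unclassifiable:
        logger.warning(
            "classify_treatments: %d non-lethal unscored treatments "
            "excluded as unclassifiable", n_unclassifiable,
        )
    return classes


def two_way_anova_no_interaction(
    y: np.ndarray,
) -> Dict[str, Tuple[float, float]]:
    """Two-factor ANOVA without interaction on a (rows=factor A, cols=factor B)
    matrix with one observation per cell.  Returns {factor: (F, p)}.

    Convention: when a factor's sum of squares and the residual both vanish,
    F = 0 and p = 1 (null case); a positive effect over zero residual yields
    F = inf, p = 0.
    """
    y = np.asarray(y, dtype=float)
    a, b = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_a = b * float(np.sum((row_means - grand) ** 2))
    ss_b = a * float(np.sum((col_means - grand) ** 2))
    ss_tot = float(np.sum((y - grand) ** 2))
    ss_res = max(ss_tot - ss_a - ss_b, 0.0)
    df_a, df_b = a - 1, b - 1
    df_res = df_a * df_b
    tiny = 1e-12 * max(ss_tot, 1.0)

    def f_and_p(ss_f: float, df_f: int) -> Tuple[float, float]:
        if ss_f <= tiny:
            return 0.0, 1.0
        if ss_res <= tiny:
            return math.inf, 0.0
        f = (ss_f / df_f) / (ss_res / df_res)
        return float(f), float(stats.f.sf(f, df_f, df_res))

    return {"rows": f_and_p(ss_a, df_a), "cols": f_and_p(ss_b, df_b)}


@dataclass
class ConcentrationProfile:
    #: {(experiment, concentration): {class: count}}
    cell_counts: Dict[Tuple[str, float], Dict[str, int]]
    #: {concentration: {class: (mean, sd)}} across experiments
    summary: Dict[float, Dict[str, Tuple[float, float]]]
    anova_f: Optional[float]
    anova_p: Optional[float]
    anova_f_experiment: Optional[float] = None
    anova_p_experiment: Optional[float] = None
    response: str = "count"

    def to_dict(self) -> dict:
        return {
            "cell_counts": {
                f"{exp}|{format_concentration(conc)}": dict(counts)
                for (exp, conc), counts in sorted(self.cell_counts.items())
            },
            "summary": {
                format_concentration(conc): {
                    cls: {"mean": m, "sd": s}
                    for cls, (m, s) in classes.items()
                }
                for conc, classes in sorted(self.summary.items())
            },
            "anova": {
                "concentration_F": self.anova_f,
                "concentration_p": self.anova_p,
                "experiment_F": self.anova_f_experiment,
                "experiment_p": self.anova_p_experiment,
                "response": self.response,
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def concentration_profile(
    table: ScreenTable, response: str = "count"
) -> ConcentrationProfile:
    """Counts of lethal / any-defect / no-defect treatments per (experiment,
    concentration), mean +/- sample SD across experiments, and the
    concentration-factor two-way ANOVA on per-cell lethal counts (or
    proportions with response='proportion')."""
    if response not in ("count", "proportion"):
        raise ValidationError("response must be 'count' or 'proportion'")
    classes = classify_treatments(table)
    by_id = table.record_map()
    experiments = table.experiments
    concentrations = table.concentrations

    cell_counts: Dict[Tuple[str, float], Dict[str, int]] = {
        (e, c): {cls: 0 for cls in TREATMENT_CLASSES}
        for e in experiments
        for c in concentrations
    }
    for tid, cls in classes.items():
        r = by_id[tid]
        cell_counts[(r.experiment, r.concentration)][cls] += 1

    summary: Dict[float, Dict[str, Tuple[float, float]]] = {}
    for conc in concentrations:
        summary[conc] = {}
        for cls in TREATMENT_CLASSES:
            vals = [cell_counts[(e, conc)][cls] for e in experiments]
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            summary[conc][cls] = (mean, sd)

    anova_f = anova_p = f_exp = p_exp = None
    if len(concentrations) < 2 or len(experiments) < 2:
        logger.warning(
            "concentration_profile: ANOVA skipped (need >= 2 levels per factor)"
        )
    else:
        y = np.array(
            [
                [cell_counts[(e, c)]["lethal"] for c in concentrations]
                for e in experiments
            ],
            dtype=float,
        )
        if response == "proportion":
            totals = np.array(
                [
                    [
                        sum(cell_counts[(e, c)].values()) or 1
                        for c in concentrations
                    ]
                    for e in experiments
                ],
                dtype=float,
            )
            y = y / totals
        res = two_way_anova_no_interaction(y)
        f_exp, p_exp = res["rows"]
        anova_f, anova_p = res["cols"]

    return ConcentrationProfile(
        cell_counts=cell_counts,
        summary=summary,
        anova_f=anova_f,
        anova_p=anova_p,
        anova_f_experiment=f_exp,
        anova_p_experiment=p_exp,
        response=response,
    )


# ---------------------------------------------------------------------------
# Compound-parameter networks
# ---------------------------------------------------------------------------

@dataclass
class ParameterNetwork:
    """Bipartite compound-parameter graph for one (experiment, concentration)
    slice.  Parameter node frequency = number of treatments scoring > 0 on
    that parameter = node degree; edge weight = the ordinal score (1-3);
    lethal treatments appear as flagged, isolated compound nodes."""

    graph: nx.Graph
    experiment: str
    concentration: float

    def parameter_nodes(self) -> List[str]:
        return [
            n for n, d in self.graph.nodes(data=True)
            if d.get("node_type") == "parameter"
        ]

    def compound_nodes(self) -> List[str]:
        return [
            n for n, d in self.graph.nodes(data=True)
            if d.get("node_type") == "compound"
        ]

    def check_invariants(self) -> None:
        for n in self.parameter_nodes():
            freq = self.graph.nodes[n]["frequency"]
            if freq != self.graph.degree(n):
                raise ValidationError(
                    f"parameter {n}: frequency {freq} != degree "
                    f"{self.graph.degree(n)}"
                )


def build_network(
    table: ScreenTable, experiment: str, concentration: float
) -> ParameterNetwork:
    """Build the bipartite network for one screen slice."""
    sl = table.subset(experiment=experiment, concentration=concentration)
    if len(sl) == 0:
        logger.warning(
            "build_network: empty slice (%s, %s uM)",
            experiment, format_concentration(concentration),
        )
    g = nx.Graph()
    schema = table.schema
    param_class = {c: "morphology" for c in schema.morphology_codes}
    param_class.update({c: "segmentation" for c in schema.segmentation_codes})
    for code in schema.codes:
        g.add_node(code, node_type="parameter", param_class=param_class[code],
                   frequency=0)
    for r in sl:
        if r.compound_id in schema.codes:
            raise ValidationError(
                f"compound id {r.compound_id!r} collides with a parameter code"
            )
        if r.lethal:
            g.add_node(r.compound_id, node_type="compound", lethal=True)
            continue
        if r.vector is None:
            logger.warning("build_network: unscored treatment %s skipped",
                           r.treatment_id)
            continue
        g.add_node(r.compound_id, node_type="compound", lethal=False)
        for code, score in zip(schema.codes, r.vector.scores):
            if score > 0:
                g.add_edge(r.compound_id, code, weight=int(score))
                g.nodes[code]["frequency"] += 1
    net = ParameterNetwork(graph=g, experiment=experiment,
                           concentration=float(concentration))
    net.check_invariants()
    return net


def export_network(net: ParameterNetwork, fmt: str, path) -> None:
    """Write the network as SIF (one 'compound<TAB>scores<TAB>parameter' line
    per edge; no edge attributes — a documented SIF dialect limitation) or
    GraphML (full node/edge attributes, round-trippable)."""
    net.check_invariants()
    path = Path(path)
    if fmt.lower() == "sif":
        lines = []
        for u, v in sorted(net.graph.edges()):
            compound, param = (v, u) if (
                net.graph.nodes[u].get("node_type") == "parameter"
            ) else (u, v)
            lines.append(f"{compound}\tscores\t{param}")
        path.write_text("".join(line + "\n" for line in lines),
                        encoding="utf-8")
    elif fmt.lower() == "graphml":
        g = net.graph.copy()
        g.graph["experiment"] = net.experiment
        g.graph["concentration"] = float(net.concentration)
        nx.write_graphml(g, path)
    else:
        raise FormatError(f"unknown network format {fmt!r}")


def read_network_graphml(path) -> ParameterNetwork:
    """Inverse of export_network(..., 'graphml', ...)."""
    g = nx.read_graphml(path)
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    for _, d in g.nodes(data=True):
        if "frequency" in d:
            d["frequency"] = int(d["frequency"])
        if "lethal" in d:
            d["lethal"] = d["lethal"] in (True, "true", "True", "1", 1)
    for _, _, d in g.edges(data=True):
        if "weight" in d:
            d["weight"] = int(d["weight"])
    return ParameterNetwork(
        graph=nx.Graph(g),
        experiment=str(g.graph.get("experiment", "")),
        concentration=float(g.graph.get("concentration", float("nan"))),
    )
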