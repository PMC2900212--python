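"""Pipeline orchestration and genome-scale summary statistics.

Runs the per-gene QC-then-test chain over a collection of promoter/intron
alignment pairs (attrition logged per filter stage), and the downstream
network/enrichment/expression association battery.  Also holds the printed
survey arithmetic: positive-percentage summaries and the 2x2
overlap-independence analysis of promoter vs coding positives.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from . import expression as expr_mod
from .alignment import TripletAlignment
from .enrichment import enrichment_table, hypergeom_enrichment
from .network import (
    build_network,
    centralities,
    central_reference,
    centrality_logistic,
    compare_centrality,
    largest_component,
    quantile_bins,
    top_central,
)
from .qc import (
    NeutralityParams,
    QCThresholds,
    gap_site_fraction,
    human_specific_ratio,
    neutrality_filter,
    sliding_window_filter,
)
from .selection import selection_test

__all__ = [
    "STATUS_COLUMNS",
    "validate_status_table",
    "run_selection_scan",
    "selection_summary",
    "overlap_stats",
    "run_network_association",
    "validate_report",
]

logger = logging.getLogger(__name__)

STATUS_COLUMNS = (
    "gene_id",
    "promoter_analyzed",
    "promoter_positive",
    "coding_analyzed",
    "coding_positive",
    "in_network",
)


def validate_status_table(status: pd.DataFrame) -> None:
    missing = set(STATUS_COLUMNS) - set(status.columns)
    if missing:
        raise ValueError(f"status table lacks columns: {sorted(missing)}")
    for region in ("promoter", "coding"):
        bad = status[f"{region}_positive"] & ~status[f"{region}_analyzed"]
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} genes flagged {region}_positive but not analyzed"
            )


def run_selection_scan(
    cases: dict[str, tuple[TripletAlignment, TripletAlignment]],
    thresholds: QCThresholds | None = None,
    neutrality: NeutralityParams | None = None,
    alpha: float = 0.05,
    n_restarts: int = 3,
    seed: int = 0,
    correct: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """QC filters (window, gap, neutrality) then the LRT, per gene.

    ``cases`` maps gene_id -> (promoter alignment, intron alignment).
    Returns (status table, per-gene results table, attrition counts).
    The window and gap filters are applied to both alignments; the
    neutrality filter to the intronic reference.  Raw p < alpha calls
    positives by default; ``correct="bh"`` adds a Benjamini-Hochberg
    q-value column and calls positives at q < alpha instead.
    """
    thresholds = thresholds or QCThresholds()
    neutrality = neutrality or NeutralityParams()
    attrition = {"input": len(cases), "sliding_window": 0, "gap_fraction": 0, "neutrality": 0, "tested": 0}
    results = []
    status_rows = []
    for gene_id in sorted(cases):
        prom, intron = cases[gene_id]
        stage = None
        if not (
            sliding_window_filter(prom, thresholds).passed
            and sliding_window_filter(intron, thresholds).passed
        ):
            stage = "sliding_window"
        elif (
            gap_site_fraction(prom) > thresholds.max_gap_fraction
            or gap_site_fraction(intron) > thresholds.max_gap_fraction
        ):
            stage = "gap_fraction"
        elif not neutrality_filter(human_specific_ratio(intron), neutrality):
            stage = "neutrality"
        if stage is not None:
            attrition[stage] += 1
            logger.info("gene %s filtered at stage %s", gene_id, stage)
            status_rows.append((gene_id, False, False, False, False, False))
            continue
        attrition["tested"] += 1
        res = selection_test(
            prom, intron, alpha=alpha, gene_id=gene_id, n_restarts=n_restarts, seed=seed
        )
        results.append(res.to_dict())
        status_rows.append(
            (gene_id, True, res.status == "positive", False, False, False)
        )
    status = pd.DataFrame(status_rows, columns=STATUS_COLUMNS)
    results_df = pd.DataFrame(results)
    if correct is not None:
        if correct != "bh":
            raise ValueError(f"unknown correction {correct!r}")
        if not results_df.empty:
            from statsmodels.stats.multitest import multipletests

            results_df["qvalue"] = multipletests(
                results_df["pvalue"], method="fdr_bh"
            )[1]
            results_df["status"] = np.where(
                results_df["qvalue"] < alpha, "positive", "not_positive"
            )
            pos = set(results_df.loc[results_df["status"] == "positive", "gene_id"])
            status["promoter_positive"] = status["gene_id"].isin(pos)
    return status, results_df, attrition


def selection_summary(n_pos: int, n_analyzed: int) -> float:
    """Percentage of positives, rounded half-away-from-zero to one decimal."""
    if not 0 <= n_pos <= n_analyzed or n_analyzed <= 0:
        raise ValueError("need 0 <= n_pos <= n_analyzed with n_analyzed > 0")
    pct = Decimal(100 * n_pos) / Decimal(n_analyzed)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OverlapStats:
    expected: float
    expected_int: int
    odds_ratio: float
    fisher_two_sided_p: float
    table: tuple[tuple[int, int], tuple[int, int]]


def overlap_stats(n_total: int, n_a: int, n_b: int, n_both: int) -> OverlapStats:
    """Independence-expected overlap and Fisher test for two positive gene sets.

    The 2x2 table is (both, a-only; b-only, neither); the expected overlap
    under independence is n_a*n_b/n_total with its integer part reported
    alongside (floor), and the two-sided Fisher p sums all tables with point
    probability <= the observed one.
    """
    if not (0 <= n_both <= min(n_a, n_b) <= max(n_a, n_b) <= n_total):
        raise ValueError("inconsistent counts")
    a = n_both
    b = n_a - n_both
    c = n_b - n_both
    d = n_total - n_a - n_b + n_both
    if n_a == 0 or n_b == 0 or n_a == n_total or n_b == n_total:
        raise ValueError("degenerate margin")
    expected = n_a * n_b / n_total
    odds = (a * d) / (b * c) if b * c > 0 else math.inf if a * d > 0 else 0.0
    if a * d == 0:
        odds = 0.0 if b * c > 0 else odds
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return OverlapStats(
        expected=float(expected),
        expected_int=math.floor(expected),
        odds_ratio=float(odds),
        fisher_two_sided_p=float(p),
        table=((a, b), (c, d)),
    )


#: one-tailed directions per metric: the promoter study set is tested for
#: greater centrality, the coding set for lower; ASPL is inverted because
#: smaller ASPL means more central.
_PROM_DIRECTION = {"degree": "greater", "betweenness": "greater", "aspl": "less", "evc": "greater"}
_COD_DIRECTION = {"degree": "less", "betweenness": "less", "aspl": "greater", "evc": "less"}


def run_network_association(
    status: pd.DataFrame,
    edge_list,
    annotation: dict | None = None,
    expression: pd.DataFrame | None = None,
    include_positives_in_reference: bool = False,
    prom_transform: str = "log",
    cod_transform: str = "identity",
    k_bins: int = 20,
    top_k: int = 10,
    alpha: float = 0.05,
    max_id_mismatch: float = 0.95,
) -> tuple[dict, pd.DataFrame]:
    """Full association battery on the largest network component.

    Centralities -> one-tailed rank-sum comparisons for both study sets and
    all four metrics -> logistic fits of status on EVC (log scale for the
    promoter set, raw for the coding set by default) -> quantile-bin table ->
    top-central sets -> enrichment against the global and central references
    (when an annotation is supplied) -> expression comparisons and Kendall
    correlations (when an expression table is supplied).

    Returns (report dict, centrality table).
    """
    validate_status_table(status)
    net = build_network(edge_list)
    genes = set(status["gene_id"])
    net_nodes = set(net.nodes())
    if genes and len(genes & net_nodes) / len(genes) < (1.0 - max_id_mismatch):
        raise ValueError("status table and network identifiers barely overlap; aborting")
    comp = largest_component(net)
    records = centralities(comp)
    st = status.set_index("gene_id")
    in_comp = [g for g in st.index if g in records.index]

    def study(region: str) -> list:
        return [g for g in in_comp if st.at[g, f"{region}_positive"]]

    def reference(region: str) -> list:
        pool = [g for g in in_comp if st.at[g, f"{region}_analyzed"]]
        if include_positives_in_reference:
            return pool
        pos = set(study(region))
        return [g for g in pool if g not in pos]

    report: dict = {
        "settings": {
            "include_positives_in_reference": include_positives_in_reference,
            "prom_transform": prom_transform,
            "cod_transform": cod_transform,
            "k_bins": k_bins,
            "top_k": top_k,
            "alpha": alpha,
        },
        "network": {
            "n_nodes": int(net.number_of_nodes()),
            "n_edges": int(net.number_of_edges()),
            "component_nodes": int(comp.number_of_nodes()),
            "component_edges": int(comp.number_of_edges()),
        },
        "sets": {},
        "wmw": {},
        "logistic": {},
        "quantile_bins": {},
        "top_central": {},
    }

    directions = {"promoter": _PROM_DIRECTION, "coding": _COD_DIRECTION}
    transforms = {"promoter": prom_transform, "coding": cod_transform}
    for region in ("promoter", "coding"):
        s, r = study(region), reference(region)
        report["sets"][region] = {"study": len(s), "reference": len(r)}
        if not s or not r:
            continue
        report["wmw"][region] = {}
        for metric, direction in directions[region].items():
            res = compare_centrality(records, s, r, metric, direction)
            report["wmw"][region][metric] = {
                "p": res.p,
                "alternative": direction,
                "study_median": res.study_median,
                "reference_median": res.reference_median,
                "method": res.method,
            }
        analyzed = [g for g in in_comp if st.at[g, f"{region}_analyzed"]]
        labels = pd.Series(
            [int(st.at[g, f"{region}_positive"]) for g in analyzed], index=analyzed
        )
        fit = centrality_logistic(records, labels, transform=transforms[region])
        report["logistic"][region] = {
            "coefficient": fit.coefficient if np.isfinite(fit.coefficient) else None,
            "stderr": fit.stderr if np.isfinite(fit.stderr) else None,
            "p": fit.p if np.isfinite(fit.p) else None,
            "transform": fit.transform,
            "n": fit.n,
            "separated": fit.separated,
        }
        vals = records.loc[analyzed, "evc"].to_numpy()
        if np.unique(vals).size >= k_bins:
            bins = quantile_bins(vals, labels.to_numpy(), k=k_bins)
            report["quantile_bins"][region] = {
                "upper_quantile": bins["upper_quantile"].tolist(),
                "frequency": bins["frequency"].tolist(),
                "n": bins["n"].astype(int).tolist(),
            }
        report["top_central"][region] = [str(g) for g in top_central(records, s, k=top_k)]

    central_union = [
        g
        for region in ("promoter", "coding")
        for g in report["top_central"].get(region, [])
    ]
    if annotation is not None and central_union:
        thr = float(records.loc[central_union, "evc"].min())
        central_ref = central_reference(records, thr) | set(central_union)
        analyzed_any = {
            g for g in st.index if st.at[g, "promoter_analyzed"] or st.at[g, "coding_analyzed"]
        }
        pos_any = {
            g for g in st.index if st.at[g, "promoter_positive"] or st.at[g, "coding_positive"]
        }
        global_res = hypergeom_enrichment(
            annotation, analyzed_any, pos_any & analyzed_any, alpha=alpha
        )
        central_study = set(central_union)
        central_res = hypergeom_enrichment(
            annotation, central_ref | central_study, central_study, alpha=alpha
        )
        report["enrichment"] = {
            "global": enrichment_table(global_res, alpha=alpha).to_dict("records"),
            "central": enrichment_table(central_res, alpha=alpha).to_dict("records"),
            "central_reference_evc_threshold": thr,
            "central_reference_size": len(central_ref),
        }

    if expression is not None:
        summaries = expr_mod.summarize_expression(expression)
        report["expression"] = {"wmw": {}, "kendall": {}}
        for region, direction in (("promoter", "greater"), ("coding", "less")):
            s = [g for g in study(region) if g in summaries.index]
            r = [g for g in reference(region) if g in summaries.index]
            if not s or not r:
                continue
            report["expression"]["wmw"][region] = {}
            for which in ("data1", "data2"):
                res = expr_mod.compare_expression(summaries, s, r, which, direction)
                report["expression"]["wmw"][region][which] = {
                    "p": res.p,
                    "alternative": direction,
                    "study_median": res.study_median,
                    "reference_median": res.reference_median,
                }
        common = [g for g in summaries.index if g in records.index]
        if len(common) >= 3:
            for metric in ("degree", "betweenness", "aspl", "evc"):
                report["expression"]["kendall"][metric] = {}
                for which in ("data1", "data2"):
                    tau, p = expr_mod.kendall_tau(
                        records.loc[common, metric].to_numpy(),
                        summaries.loc[common, which].to_numpy(),
                    )
                    report["expression"]["kendall"][metric][which] = {"tau": tau, "p": p}

    validate_report(report)
    return report, records


# --- report schema -----------------------------------------------------------

def _load_schema() -> dict:
    with resources.files("promselnet").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def _check(instance, schema, path="$") -> list[str]:
    errors = []
    t = schema.get("type")
    type_map = {
        "object": dict,
        "array": list,
        "string": str,
        "number": (int, float),
        "integer": int,
        "boolean": bool,
        "null": type(None),
    }
    if t is not None:
        allowed = t if isinstance(t, list) else [t]
        if not any(isinstance(instance, type_map[a]) for a in allowed):
            # bool is an int subclass; reject bools where numbers are expected
            errors.append(f"{path}: expected {t}, got {type(instance).__name__}")
            return errors
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                errors.extend(_check(instance[key], sub, f"{path}.{key}"))
        extra = schema.get("additionalProperties")
        if isinstance(extra, dict):
            known = set(schema.get("properties", {}))
            for key, val in instance.items():
                if key not in known:
                    errors.extend(_check(val, extra, f"{path}.{key}"))
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            errors.extend(_check(item, schema["items"], f"{path}[{i}]"))
    return errors


def validate_report(report: dict) -> None:
    """Check an association report against the shipped JSON schema."""
    errors = _check(report, _load_schema())
    if errors:
        raise ValueError("report schema violations: " + "; ".join(errors[:10]))
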