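"""Cellular phenotype summaries for airway smooth muscle cells.

Percent marker-positive myocytes from gated flow-cytometry event counts with
isotype-control background subtraction, and relative gene expression from
qPCR cycle thresholds by the delta-Ct method (2^-(Ct_gene - Ct_reference),
18S as reference). Gating itself is outside scope: the functions consume
already-gated event counts. GSH enters the cohort table as a measured
covariate and needs no processing here.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = ["percent_positive", "delta_ct", "build_phenotype_table"]


def percent_positive(total: int, positive: int, isotype_pct: float = 0.0) -> float:
    """Percent marker-positive events, isotype background subtracted.

    Returns max(0, 100 * positive/total - isotype_pct); background
    subtraction never drives the percentage negative.
    """
    if total <= 0:
        raise ValueError("total gated events must be positive")
    if positive < 0 or positive > total:
        raise ValueError("positive events must lie in [0, total]")
    if isotype_pct < 0:
        raise ValueError("isotype percentage must be non-negative")
    return max(0.0, 100.0 * positive / total - isotype_pct)


def delta_ct(ct_gene: float, ct_reference: float) -> float:
    """Relative expression 2^-(Ct_gene - Ct_reference)."""
    if not (math.isfinite(ct_gene) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** -(ct_gene - ct_reference)


def build_phenotype_table(panel: pd.DataFrame, expression: pd.DataFrame) -> pd.DataFrame:
    """Merge flow-cytometry and qPCR results into one row per animal.

    ``panel`` columns: animal_id, marker, total_events, positive_events,
    isotype_pct. ``expression`` columns: animal_id, ct_gene, ct_18s.
    Output: one row per animal with pct_<marker> columns and the 2^-dCt
    relative expression.
    """
    pct = panel.assign(
        pct=[
            percent_positive(t, p, i)
            for t, p, i in zip(panel["total_events"], panel["positive_events"], panel["isotype_pct"])
        ]
    )
    wide = pct.pivot(index="animal_id", columns="marker", values="pct")
    wide.columns = [f"pct_{m}" for m in wide.columns]
    expr = expression.set_index("animal_id").reindex(wide.index)
    wide["rel_expression"] = [
        delta_ct(g, r) for g, r in zip(expr["ct_gene"], expr["ct_18s"])
    ]
    return wide.reset_index()
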