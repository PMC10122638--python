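"""Single-cell QC filtering and cluster condition-bias analysis.

Clustering itself (Leiden/UMAP, marker ranking) is out of scope — cluster
labels arrive as input. What this module adds is the droplet-QC rule set
(UMI floor, %mito ceiling, gene-count window; all comparisons strict per
the stated rules), the strict >75% rule for calling a cluster
condition-specific, and the UMI window used to pick high-complexity cells
for per-cluster differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CellRecord",
    "ClusterConditionTable",
    "qc_filter_cells",
    "filter_genes_min_cells",
    "condition_bias",
    "select_de_cells",
]

CELL_COLUMNS = ["cell_id", "cluster", "condition", "umi_count", "pct_mito", "n_genes"]


@dataclass(frozen=True)
class CellRecord:
    cell_id: str
    cluster: str
    condition: str
    umi_count: int
    pct_mito: float
    n_genes: int

    def __post_init__(self) -> None:
        if self.umi_count < 0 or self.n_genes < 0:
            raise ValueError("umi_count and n_genes must be nonnegative")
        if not 0 <= self.pct_mito <= 100:
            raise ValueError("pct_mito must lie in [0, 100]")


@dataclass
class ClusterConditionTable:
    """Per-cluster condition composition with bias labels.

    ``table`` has one row per cluster: counts per condition, ``total``,
    ``frac_<condition>`` columns, ``bias_label`` ("shared" or the name of
    the condition the cluster is specific to) and ``max_fraction``.
    """

    table: pd.DataFrame
    threshold: float

    @property
    def specific_clusters(self) -> dict[str, str]:
        """cluster -> condition for clusters called condition-specific."""
        spec = self.table[self.table["bias_label"] != "shared"]
        return dict(zip(spec.index, spec["bias_label"]))


def _as_frame(cells) -> pd.DataFrame:
    if isinstance(cells, pd.DataFrame):
        missing = set(CELL_COLUMNS) - set(cells.columns)
        if missing:
            raise ValueError(f"cell table missing columns: {sorted(missing)}")
        return cells
    return pd.DataFrame([c.__dict__ for c in cells], columns=CELL_COLUMNS)


def qc_filter_cells(
    cells,
    umi_min: int = 200,
    mito_max_pct: float = 5.0,
    genes_min: int = 10,
    genes_max: int = 2500,
    final_umi_min: int | None = 500,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Droplet QC: keep cells passing every rule; tally removals per rule.

    Rules, all strict where the wording is strict: removed if
    umi < umi_min (or < final_umi_min when the final-pass floor is set),
    removed if pct_mito > mito_max_pct, kept only if n_genes > genes_min,
    removed if n_genes > genes_max. ``final_umi_min=None`` gives the
    first-pass preset (200-UMI floor only).
    """
    df = _as_frame(cells)
    umi_floor = umi_min if final_umi_min is None else max(umi_min, final_umi_min)
    fail_umi = df["umi_count"] < umi_floor
    fail_mito = df["pct_mito"] > mito_max_pct
    fail_genes_low = ~(df["n_genes"] > genes_min)
    fail_genes_high = df["n_genes"] > genes_max
    tally = {
        "low_umi": int(fail_umi.sum()),
        "high_mito": int(fail_mito.sum()),
        "few_genes": int(fail_genes_low.sum()),
        "many_genes": int(fail_genes_high.sum()),
    }
    keep = ~(fail_umi | fail_mito | fail_genes_low | fail_genes_high)
    return df[keep].reset_index(drop=True), tally


def filter_genes_min_cells(gene_presence: pd.Series | dict, min_cells: int = 3):
    """Keep genes expressed in strictly more than ``min_cells`` cells."""
    s = pd.Series(gene_presence)
    if (s < 0).any():
        raise ValueError("presence counts must be nonnegative")
    return list(s[s > min_cells].index)


def condition_bias(cells, threshold: float = 0.75) -> ClusterConditionTable:
    """Label clusters condition-specific when one condition strictly
    exceeds ``threshold`` of the cluster's cells.

    A 75/25 cluster at the default threshold is "shared": the rule is
    *more than* 75%. With more than two conditions the max-fraction
    condition is the one tested.
    """
    df = _as_frame(cells) if not _is_count_table(cells) else None
    if df is not None:
        counts = df.groupby(["cluster", "condition"]).size().unstack(fill_value=0)
    else:
        counts = pd.DataFrame(cells).fillna(0).astype(int)
    if counts.shape[1] < 2:
        raise ValueError("need at least two conditions")
    total = counts.sum(axis=1)
    if (total == 0).any():
        raise ValueError("empty cluster in table")
    fracs = counts.div(total, axis=0)
    max_cond = fracs.idxmax(axis=1)
    max_frac = fracs.max(axis=1)
    bias = max_cond.where(max_frac > threshold, "shared")

    out = counts.copy()
    out["total"] = total
    for cond in counts.columns:
        out[f"frac_{cond}"] = fracs[cond]
    out["max_fraction"] = max_frac
    out["bias_label"] = bias
    return ClusterConditionTable(table=out, threshold=threshold)


def _is_count_table(obj) -> bool:
    return isinstance(obj, pd.DataFrame) and "cell_id" not in obj.columns


def select_de_cells(cells, umi_low: int = 2000, umi_high: int = 4000) -> pd.DataFrame:
    """High-complexity cells for DE input: strictly umi_low < UMI < umi_high."""
    if umi_low >= umi_high:
        raise ValueError("umi_low must be < umi_high")
    df = _as_frame(cells)
    keep = (df["umi_count"] > umi_low) & (df["umi_count"] < umi_high)
    return df[keep].reset_index(drop=True)
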