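"""Per-metabolite accumulation score from directed network imbalance.

For a metabolite M, UpPs are proteins producing M (edges pointing to M) and
DownPs are proteins consuming M (edges leaving M). The accumulation score is

    deltaM = sum(log2FC over UpPs) - sum(log2FC over DownPs)

with fold changes taken between the poor- and well-prognosis subtypes.
Reversible (role=both) partners appear in both sums and cancel exactly.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from mpinet.network import MPINetwork, PathwayCollection, metabolite_neighborhood


def delta_m(
    net: MPINetwork,
    log2fc: Mapping[str, float],
    min_measured: int = 2,
) -> pd.DataFrame:
    """Accumulation table for every metabolite in *net*.

    Proteins absent from *log2fc* are skipped and counted in ``n_missing``.
    Summation order is fixed (sorted protein id) for bitwise reproducibility.
    Metabolites with fewer than *min_measured* measured partners (UpPs plus
    DownPs, reversible partners counted twice) are flagged low-confidence.
    """
    records = []
    for met in net.metabolites:
        ups, downs = metabolite_neighborhood(net, met)
        up_measured = [p for p in sorted(ups) if p in log2fc]
        down_measured = [p for p in sorted(downs) if p in log2fc]
        n_missing = len([p for p in ups | downs if p not in log2fc])
        delta_up = float(sum(log2fc[p] for p in up_measured))
        delta_down = float(sum(log2fc[p] for p in down_measured))
        records.append(
            {
                "metabolite_id": met,
                "n_up": len(up_measured),
                "n_down": len(down_measured),
                "delta_up": delta_up,
                "delta_down": delta_down,
                "deltaM": delta_up - delta_down,
                "n_missing": n_missing,
                "low_confidence": (len(up_measured) + len(down_measured)) < min_measured,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "metabolite_id",
            "n_up",
            "n_down",
            "delta_up",
            "delta_down",
            "deltaM",
            "n_missing",
            "low_confidence",
        ],
    ).set_index("metabolite_id")


def metabolite_gsea(
    acc_table: pd.DataFrame,
    metabolite_sets: PathwayCollection,
    n_permutations: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """Set enrichment on the deltaM-descending metabolite ranking.

    Positive NES indicates relative accumulation of the set's metabolites in
    the poor-prognosis subtype; negative NES indicates consumption.
    """
    from mpinet.enrichment import RankedList, gsea

    if len(acc_table) == 0:
        raise ValueError("accumulation table is empty")
    ranked = RankedList.from_scores(acc_table["deltaM"])
    return gsea(
        ranked,
        metabolite_sets,
        n_permutations=n_permutations,
        seed=seed,
        weight_exponent=weight_exponent,
        min_set_size=min_set_size,
    )


def accumulation_report(
    acc_table: pd.DataFrame,
    top_k: int,
    metabolite_sets: PathwayCollection | None = None,
) -> pd.DataFrame:
    """Top-|deltaM| metabolites with sign annotation and optional pathways."""
    if top_k <= 0:
        return pd.DataFrame(columns=["metabolite_id", "deltaM", "direction", "pathways"])
    ordered = acc_table.sort_values(
        "deltaM", key=lambda s: -s.abs(), kind="mergesort"
    ).head(top_k)
    rows = []
    for met, rec in ordered.iterrows():
        pathways = ""
        if metabolite_sets is not None:
            hits = [pid for pid in metabolite_sets if met in metabolite_sets.members(pid)]
            pathways = ";".join(hits)
        rows.append(
            {
                "metabolite_id": met,
                "deltaM": float(rec["deltaM"]),
                "direction": "accumulated" if rec["deltaM"] > 0 else (
                    "consumed" if rec["deltaM"] < 0 else "unchanged"
                ),
                "pathways": pathways,
            }
        )
    return pd.DataFrame(rows)
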