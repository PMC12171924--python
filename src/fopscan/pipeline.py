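"""End-to-end pipeline: merge -> classify -> summarise -> simulate -> render.

Produces the four surveillance exhibits as CSV (the machine truth, full
precision) plus a stacked-bar figure whose data live in a sidecar CSV so
every graphical claim is numerically testable:

* ``table1.csv`` — product availability and market coverage per category;
* ``table2.csv`` — sales-weighted nutrient portrait per serving;
* ``fig1.csv`` / ``fig1.svg`` — distribution of 0/1/2/3 flagged nutrients;
* ``table3.csv`` — symbol prevalence under the reformulation grid;
* ``metadata.json`` — scheme hash, seed, row counts: enough to reproduce
  the run exactly.

The pipeline is a pure function of (inputs, scheme, seed): re-running
writes byte-identical payloads (no timestamps anywhere).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import matplotlib
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .catalog import (
    MergedSupply,
    load_products,
    load_sales,
    market_coverage,
    merge_by_code,
)
from .errors import PipelineStageError
from .reformulation import DEFAULT_REDUCTIONS, run_scenario_grid
from .rules import CORE_NUTRIENTS, RegulatoryScheme, classify_supply, verdicts_to_frame
from .stats import category_summaries, prevalence_table

logger = logging.getLogger("fopscan")

# deterministic SVG ids across runs
matplotlib.rcParams["svg.hashsalt"] = "fopscan"


@dataclass
class ReportBundle:
    """All pipeline outputs, plus the metadata that reproduces them."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    fig1: pd.DataFrame
    table3: pd.DataFrame
    verdicts: pd.DataFrame
    metadata: dict


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(f"stage '{name}' failed: {exc}") from exc
        return out

    return wrap


def build_reports(
    supply: MergedSupply,
    scheme: RegulatoryScheme,
    reductions: Sequence[float] = DEFAULT_REDUCTIONS,
    missing_policy: Literal["strict", "lenient"] = "strict",
    seed: Optional[int] = None,
) -> ReportBundle:
    """Compute every report frame from an already-merged supply."""
    coverage = _stage("coverage")(market_coverage, supply, "product_count")
    table1 = supply.per_category_counts()
    table1["coverage"] = table1["category"].map(coverage.per_category)
    overall = pd.DataFrame(
        [
            {
                "category": "overall",
                "n_products": int(table1["n_products"].sum()),
                "n_matched": int(table1["n_matched"].sum()),
                "coverage": coverage.overall,
            }
        ]
    )
    table1 = pd.concat([table1, overall], ignore_index=True)
    logger.info("merge: %d products, %d matched", table1["n_products"].iloc[-1], table1["n_matched"].iloc[-1])

    verdicts = _stage("classify")(classify_supply, supply, scheme, missing_policy)
    logger.info("classify: %d verdicts", len(verdicts))

    table2 = _stage("summarize")(category_summaries, supply, "sales_kg")
    fig1 = _stage("summarize")(prevalence_table, verdicts, "unweighted")
    table3 = _stage("simulate")(
        run_scenario_grid, supply, scheme, CORE_NUTRIENTS, tuple(reductions), missing_policy
    )
    logger.info("simulate: %d grid rows", len(table3))

    metadata = {
        "fopscan_version": __version__,
        "scheme_hash": scheme.content_hash(),
        "seed": seed,
        "n_products": int(table1["n_products"].iloc[-1]),
        "n_matched": int(table1["n_matched"].iloc[-1]),
        "reductions": list(reductions),
        "missing_policy": missing_policy,
    }
    return ReportBundle(
        table1=table1,
        table2=table2,
        fig1=fig1,
        table3=table3,
        verdicts=verdicts_to_frame(verdicts),
        metadata=metadata,
    )


def run_pipeline(
    products_path: str | Path,
    sales_path: str | Path,
    scheme: RegulatoryScheme,
    out_dir: str | Path,
    reductions: Sequence[float] = DEFAULT_REDUCTIONS,
    missing_policy: Literal["strict", "lenient"] = "strict",
    seed: Optional[int] = None,
    render: bool = True,
) -> ReportBundle:
    """Run the whole pipeline from CSV inputs and write all reports.

    All frames are computed before anything is written, so a failing stage
    leaves no partial outputs behind.
    """
    products = _stage("load_products")(load_products, products_path)
    sales = _stage("load_sales")(load_sales, sales_path)
    supply = _stage("merge")(merge_by_code, products, sales)
    bundle = build_reports(supply, scheme, reductions, missing_policy, seed)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.table1.to_csv(out / "table1.csv", index=False)
    bundle.table2.to_csv(out / "table2.csv", index=False)
    bundle.fig1.to_csv(out / "fig1.csv", index=False)
    bundle.table3.to_csv(out / "table3.csv", index=False)
    bundle.verdicts.to_csv(out / "verdicts.csv", index=False)
    with open(out / "metadata.json", "w") as fh:
        json.dump(bundle.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if render:
        render_fig1(bundle.fig1, out / "fig1.svg")
    return bundle


def render_fig1(fig1: pd.DataFrame, path: str | Path) -> None:
    """Stacked-bar chart of the 0/1/2/3 flagged-nutrient distribution.

    One bar per category plus the overall bar; segment heights are exactly
    the ``flagged_k`` fractions of the input frame (its CSV is the sidecar).
    Written as SVG with stable ids and no embedded date, so identical input
    yields an identical file.
    """
    frame = fig1.set_index("category")
    fig, ax = plt.subplots(figsize=(10, 0.45 * len(frame) + 1.5))
    left = pd.Series(0.0, index=frame.index)
    colors = ["#c6dbef", "#6baed6", "#2171b5", "#08306b"]
    for k in range(4):
        seg = frame[f"flagged_{k}"]
        ax.barh(frame.index, seg, left=left, color=colors[k], label=f"{k} nutrient{'s' if k != 1 else ''}")
        left = left + seg
    ax.set_xlim(0, 1)
    ax.set_xlabel("share of matched products")
    ax.set_title("Products requiring the 'high in' symbol, by number of flagged nutrients")
    ax.legend(loc="lower right", fontsize=8)
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)
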