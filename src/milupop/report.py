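"""Cohort-level summary tables: the tabular analogues of the usual
Froh/ROH box plots, per-element heterozygosity comparisons, L/H density
fractions and relatedness pair lists."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diversity import HetReport, RelatednessMatrix
from .roh import RohReport
from .segmentation import SegmentationSummary


def froh_cohort_table(reports: list[RohReport],
                      population: dict[str, str] | None = None) -> pd.DataFrame:
    """Froh quartiles per population label (single label 'cohort' by default)."""
    rows = [(population.get(r.sample, "cohort") if population else "cohort",
             r.sample, r.froh) for r in reports]
    df = pd.DataFrame(rows, columns=["population", "sample", "froh"])
    out = df.groupby("population")["froh"].agg(
        n="count", q25=lambda v: np.percentile(v, 25), median="median",
        q75=lambda v: np.percentile(v, 75), min="min", max="max")
    return out.reset_index()


def het_element_table(reports: list[HetReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for cls, rate in r.het_per_kb.items():
            rows.append((r.sample, cls, rate, r.ratio_to_genome[cls],
                         r.het_per_kb_genome))
    return pd.DataFrame(rows, columns=["sample", "element", "het_per_kb",
                                       "ratio_to_genome", "genome_het_per_kb"])


def segmentation_table(summary: SegmentationSummary) -> pd.DataFrame:
    return pd.DataFrame({
        "state": ["L", "H"],
        "fraction_genome": [summary.fraction_genome_L, summary.fraction_genome_H],
        "fraction_snps": [summary.fraction_snps_L, summary.fraction_snps_H],
        "mean_het_per_kb": [summary.mean_het_L, summary.mean_het_H],
    })


def relatedness_table(matrix: RelatednessMatrix) -> pd.DataFrame:
    return matrix.pair_frame()
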