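"""Heterozygosity, pairwise relatedness and deleterious-variant summaries.

Relatedness uses the unadjusted Yang-type moment estimator (the statistic the
VCFtools ``--relatedness`` screen reports): for site *i* with alternate-allele
frequency :math:`p_i` and dosages :math:`x \\in \\{0,1,2\\}`,

.. math:: a_{jk} = \\mathrm{mean}_i \\frac{(x_{ij}-2p_i)(x_{ik}-2p_i)}{2p_i(1-p_i)}

averaged over sites where both samples are called.  By default frequencies
are estimated from the analysed samples themselves — adequate for cohorts,
badly biased for two or three samples (for a duplicated pair judged on its
own frequencies the statistic is identically zero), so known truth
frequencies can be supplied.  Degree classification uses KING-style bands on
:math:`a_{jk}`: > 0.354 duplicate, (0.177, 0.354] 1st, (0.0884, 0.177] 2nd,
(0.0442, 0.0884] 3rd degree, else unrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import FeatureSet, HET, MISSING, ScaffoldSet, VariantTable


class DiversityError(ValueError):
    pass


# degree bands (lower-exclusive, upper-inclusive) on a_jk
DEGREE_THRESHOLDS = {
    "duplicate": 0.354,
    "1st degree": 0.177,
    "2nd degree": 0.0884,
    "3rd degree": 0.0442,
}


def classify_degree(a_jk: float, unrelated_cutoff: float = 0.0442) -> str:
    """Map a relatedness value to a degree label.

    ``unrelated_cutoff`` lets a cohort adopt a stricter notion of "related"
    (e.g. 0.177 to call anything below 1st degree unrelated).
    """
    if a_jk > DEGREE_THRESHOLDS["duplicate"]:
        return "duplicate"
    if a_jk <= unrelated_cutoff:
        return "unrelated"
    if a_jk > DEGREE_THRESHOLDS["1st degree"]:
        return "1st degree"
    if a_jk > DEGREE_THRESHOLDS["2nd degree"]:
        return "2nd degree"
    if a_jk > DEGREE_THRESHOLDS["3rd degree"]:
        return "3rd degree"
    return "unrelated"


@dataclass
class HetReport:
    sample: str
    het_per_kb_genome: float
    het_per_kb: dict[str, float]
    ratio_to_genome: dict[str, float | None]
    het_counts: dict[str, int] = field(default_factory=dict)
    genome_het_count: int = 0


@dataclass
class RelatednessMatrix:
    samples: list[str]
    a: np.ndarray                    # (n, n), diagonal NaN
    classification: dict[tuple[str, str], str]
    n_sites: int

    def pair_frame(self) -> pd.DataFrame:
        rows = []
        for i, s1 in enumerate(self.samples):
            for j in range(i + 1, len(self.samples)):
                s2 = self.samples[j]
                rows.append((s1, s2, self.a[i, j], self.classification[(s1, s2)]))
        return pd.DataFrame(rows, columns=["sample_1", "sample_2", "a_jk", "degree"])


@dataclass
class DeleteriousSummary:
    counts: dict[str, dict[str, int]]          # sample -> {DE, TO, OT}
    percent_deleterious: dict[str, float | None]
    cohort_mean_percent: float | None
    mode: str = "DE/(DE+TO)"


# ---------------------------------------------------------------------------

def _count_het_in_regions(pos0: np.ndarray, het_mask: np.ndarray,
                          intervals: np.ndarray) -> int:
    if len(intervals) == 0 or len(pos0) == 0:
        return 0
    idx = np.searchsorted(intervals[:, 0], pos0, side="right") - 1
    inside = (idx >= 0) & (pos0 < intervals[np.clip(idx, 0, None), 1])
    return int((inside & het_mask).sum())


def heterozygosity_rate(variants: VariantTable, sample: str,
                        scaffolds: ScaffoldSet,
                        regions: dict[str, np.ndarray] | None = None) -> float:
    """Heterozygous-SNP density in SNPs/kb over regions or the whole genome.

    The whole-genome denominator is the summed scaffold length; region
    denominators are summed interval lengths.
    """
    het = variants.sample_genotypes(sample) == HET
    slices = variants.scaffold_slices()
    if regions is None:
        denom_bp = scaffolds.total_length
        count = int(het.sum())
    else:
        denom_bp = int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in regions.values()))
        count = 0
        for scf, iv in regions.items():
            sl = slices.get(scf)
            if sl is None:
                continue
            count += _count_het_in_regions(variants.pos[sl] - 1, het[sl], iv)
    if denom_bp <= 0:
        raise DiversityError("zero-length denominator for heterozygosity rate")
    return count / (denom_bp / 1000.0)


def het_by_element(variants: VariantTable, sample: str, features: FeatureSet,
                   scaffolds: ScaffoldSet) -> HetReport:
    """Per-element heterozygosity and its ratio to the genome-wide rate."""
    genome_rate = heterozygosity_rate(variants, sample, scaffolds)
    het = variants.sample_genotypes(sample) == HET
    slices = variants.scaffold_slices()
    rates: dict[str, float] = {}
    ratios: dict[str, float | None] = {}
    counts: dict[str, int] = {}
    for cls in FeatureSet.CLASSES:
        regions = features.intervals(cls)
        length = features.class_length(cls)
        c = 0
        for scf, iv in regions.items():
            sl = slices.get(scf)
            if sl is None:
                continue
            c += _count_het_in_regions(variants.pos[sl] - 1, het[sl], iv)
        counts[cls] = c
        rates[cls] = c / (length / 1000.0) if length > 0 else 0.0
        if genome_rate > 0:
            ratios[cls] = rates[cls] / genome_rate
        else:
            ratios[cls] = None   # undefined: no heterozygous calls genome-wide
    return HetReport(sample=sample, het_per_kb_genome=genome_rate,
                     het_per_kb=rates, ratio_to_genome=ratios,
                     het_counts=counts, genome_het_count=int(het.sum()))


# ---------------------------------------------------------------------------

def relatedness_matrix(variants: VariantTable, min_maf: float = 0.0,
                       allele_freqs: np.ndarray | None = None,
                       unrelated_cutoff: float = 0.0442) -> RelatednessMatrix:
    """Pairwise Yang-type relatedness with degree classification.

    ``allele_freqs``: optional per-site alternate-allele frequencies (e.g.
    known truth from a simulation); estimated from the sample dosages when
    absent.  Sites with a missing call in a pair are dropped pairwise.
    """
    if variants.n_samples < 2:
        raise DiversityError("need at least two samples")
    g = variants.genotypes.astype(np.float64)   # 0/1/2, MISSING=-1
    called = variants.genotypes != MISSING
    dose = np.where(called, g, np.nan)

    if allele_freqs is None:
        with np.errstate(invalid="ignore"):
            p = np.nanmean(dose, axis=1) / 2.0
    else:
        p = np.asarray(allele_freqs, dtype=np.float64)
        if len(p) != len(variants):
            raise DiversityError("allele_freqs length must match the table")

    maf = np.minimum(p, 1 - p)
    poly = (p > 0) & (p < 1) & (maf >= min_maf)
    if not poly.any():
        raise DiversityError("no polymorphic site after the MAF filter")

    dose = dose[poly]
    p = p[poly]
    denom = 2 * p * (1 - p)
    centred = dose - 2 * p[:, None]
    scaled = centred / np.sqrt(denom)[:, None]    # so a_jk = mean_i s_ij s_ik

    n = variants.n_samples
    a = np.full((n, n), np.nan)
    classification: dict[tuple[str, str], str] = {}
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(scaled[:, i]) & ~np.isnan(scaled[:, j])
            if not both.any():
                raise DiversityError(
                    f"no shared called site for pair ({variants.samples[i]}, "
                    f"{variants.samples[j]})")
            val = float(np.mean(scaled[both, i] * scaled[both, j]))
            a[i, j] = a[j, i] = val
            classification[(variants.samples[i], variants.samples[j])] = \
                classify_degree(val, unrelated_cutoff)
    return RelatednessMatrix(samples=list(variants.samples), a=a,
                             classification=classification,
                             n_sites=int(poly.sum()))


# ---------------------------------------------------------------------------

DELETERIOUS_CLASSES = ("DE", "TO", "OT")


def deleterious_fraction(annotations: pd.DataFrame,
                         mode: str = "DE/(DE+TO)") -> DeleteriousSummary:
    """Per-sample deleterious percentages from a (variant, sample, class) table.

    ``mode`` selects the denominator: ``"DE/(DE+TO)"`` (default) or
    ``"DE/total"``.  The cohort mean is the unweighted mean over samples with
    a defined percentage.
    """
    if mode not in ("DE/(DE+TO)", "DE/total"):
        raise DiversityError(f"unknown mode {mode!r}")
    bad = set(annotations["class"]) - set(DELETERIOUS_CLASSES)
    if bad:
        raise DiversityError(f"unknown annotation classes: {sorted(bad)}")
    counts: dict[str, dict[str, int]] = {}
    for sample, sub in annotations.groupby("sample", sort=True):
        vc = sub["class"].value_counts()
        counts[str(sample)] = {c: int(vc.get(c, 0)) for c in DELETERIOUS_CLASSES}
    pct: dict[str, float | None] = {}
    for sample, c in counts.items():
        denom = (c["DE"] + c["TO"]) if mode == "DE/(DE+TO)" else sum(c.values())
        pct[sample] = 100.0 * c["DE"] / denom if denom > 0 else None
    defined = [v for v in pct.values() if v is not None]
    return DeleteriousSummary(
        counts=counts, percent_deleterious=pct,
        cohort_mean_percent=float(np.mean(defined)) if defined else None,
        mode=mode)
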