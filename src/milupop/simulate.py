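"""Synthetic diploid-genome generators with serialised ground truth.

Every pipeline stage is validated against data produced here: a two-regime
SNP-density genome (blockwise low/high mutation-density states), inbred
samples carrying long homozygous IBD tracts at a target inbreeding
coefficient F, sample pairs at chosen kinship, and per-family
nonsynonymous-substitution tables with planted rapidly evolving GO
categories.

Determinism: each generator component draws from its own
``numpy.random.default_rng([seed, component_id])`` stream with a fixed draw
order, so identical seeds give byte-identical output files and adding a
component never perturbs the others.

Planted truth is calibrated to its nominal level: the state-block and IBD
tract layouts are rejection-resampled until realized coverage is within a
small tolerance of the target stationary fraction / F, so that recovery
tests measure estimator error rather than the layout sampling noise of a
handful of multi-megabase blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import HET, HOM_ALT, HOM_REF, MISSING, ScaffoldSet, VariantTable

# component ids for per-component RNG streams
_RNG_STATES, _RNG_POSITIONS, _RNG_FREQS, _RNG_GENOTYPES, _RNG_FEATURES, \
    _RNG_TRACTS, _RNG_PAIRS, _RNG_FAMILY, _RNG_SITEMETA, _RNG_LRT = range(10)


class SimulationError(ValueError):
    pass


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), component])


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the regimes the pipeline is designed around: state SNP
    densities of 0.03 and 1.26 SNPs/kb with the low state covering half the
    genome, ~2-kb SNP spacing for the ROH substrate, 2-Mb mean IBD tracts,
    and Poisson per-family nonsynonymous counts with two-fold planted
    acceleration.
    """

    seed: int = 0
    # genome geometry
    n_scaffolds: int = 10
    scaffold_length: int = 10_000_000
    # density regime (SNPs/kb); blocks exponential with these mean lengths
    state_mean_low: float = 0.03
    state_mean_high: float = 1.26
    block_mean_low_bp: float = 5_000_000.0
    block_mean_high_bp: float = 5_000_000.0
    state_coverage_tol: float = 0.02
    # inbreeding
    F: float = 0.125
    tract_mean_bp: float = 2_000_000.0
    genotyping_error: float = 0.005
    tract_coverage_tol: float = 0.01
    snp_rate_per_kb: float = 0.5          # uniform substrate for ROH cohorts
    # cohort
    n_samples: int = 5
    # allele frequencies
    beta_a: float = 0.8
    beta_b: float = 0.8
    # feature geometry
    genes_per_scaffold: int = 20
    gene_length_range: tuple[int, int] = (5_000, 20_000)
    exons_per_gene: tuple[int, int] = (3, 8)
    # family evolution table
    n_categories: int = 200
    families_per_category: int = 30
    background_A_rate: float = 6.0
    planted_fold: float = 2.0
    n_planted: int = 10
    nonsyn_sites_range: tuple[int, int] = (500, 1500)
    foreground_lineage: str = "milu"
    background_lineage: str = "cow"

    @property
    def stationary_low(self) -> float:
        return self.block_mean_low_bp / (self.block_mean_low_bp
                                         + self.block_mean_high_bp)


@dataclass
class SyntheticTruth:
    config: SimConfig
    state_intervals: dict[str, list[list[int]]] = field(default_factory=dict)
    ibd_tracts: dict[str, dict[str, list[list[int]]]] = field(default_factory=dict)
    kinship_class: dict[str, str] = field(default_factory=dict)
    planted_go_ids: list[str] = field(default_factory=list)
    allele_freqs: list[float] = field(default_factory=list)
    sample_F: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        cfg = d.pop("config")
        for k in ("gene_length_range", "exons_per_gene", "nonsyn_sites_range"):
            cfg[k] = tuple(cfg[k])
        return cls(config=SimConfig(**cfg), **d)


# ---------------------------------------------------------------------------
# interval processes

def _alternating_blocks(length: int, mean_a: float, mean_b: float,
                        rng: np.random.Generator,
                        start_a_prob: float) -> list[tuple[int, int, int]]:
    """Alternating exponential-length blocks (state 0 = 'a'), tiling [0, length)."""
    out = []
    pos = 0
    state = 0 if rng.random() < start_a_prob else 1
    while pos < length:
        mean = mean_a if state == 0 else mean_b
        ln = max(1, int(round(rng.exponential(mean))))
        end = min(length, pos + ln)
        out.append((pos, end, state))
        pos = end
        state = 1 - state
    return out


def _conditioned_blocks(length_per_scaffold: list[int], mean_a: float,
                        mean_b: float, target_a: float, tol: float,
                        rng: np.random.Generator,
                        max_tries: int = 1000) -> list[list[tuple[int, int, int]]]:
    """Resample a whole-genome block layout until state-0 coverage is near target."""
    total = sum(length_per_scaffold)
    for _ in range(max_tries):
        layout = [_alternating_blocks(L, mean_a, mean_b, rng, target_a)
                  for L in length_per_scaffold]
        cov = sum(e - s for scf in layout for s, e, st in scf if st == 0) / total
        if abs(cov - target_a) <= tol:
            return layout
    raise SimulationError("could not calibrate block layout; widen the tolerance")


# ---------------------------------------------------------------------------
# shared low-level draws

def _draw_freqs(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    p = rng.beta(cfg.beta_a, cfg.beta_b, size=n)
    return np.clip(p, 1e-3, 1 - 1e-3)


def _hwe_genotypes(p: np.ndarray, n_samples: int,
                   rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(2, p[:, None], size=(len(p), n_samples)).astype(np.int8)


def _positions_in_intervals(intervals: list[tuple[int, int, int]],
                            rate_low: float, rate_high: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Poisson SNP positions (0-based) with per-state rates in SNPs/bp."""
    pos = []
    for s, e, st in intervals:
        rate = rate_low if st == 0 else rate_high
        n = rng.poisson(rate * (e - s))
        if n:
            pos.append(rng.integers(s, e, size=n))
    if not pos:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(pos)).astype(np.int64)


# ---------------------------------------------------------------------------

@dataclass
class GenomeBundle:
    scaffolds: ScaffoldSet
    variants: VariantTable
    features: "object"               # FeatureSet
    truth: SyntheticTruth
    gff3_text: str = ""


def simulate_genome(config: SimConfig, out_dir: str | Path | None = None) -> GenomeBundle:
    """Two-regime genome: blockwise L/H SNP density, HWE genotypes, gene models.

    Writes VCF, truth-state BED, GFF3, scaffold table and truth JSON into
    ``out_dir`` when given; identical seeds give byte-identical files.
    """
    cfg = config
    names = tuple(f"scaffold_{i+1}" for i in range(cfg.n_scaffolds))
    lengths = tuple([cfg.scaffold_length] * cfg.n_scaffolds)
    scaffolds = ScaffoldSet(names, lengths)

    rate_low = cfg.state_mean_low / 1000.0
    rate_high = cfg.state_mean_high / 1000.0
    exp_snps = (cfg.stationary_low * rate_low
                + (1 - cfg.stationary_low) * rate_high) * scaffolds.total_length
    if exp_snps < 100:
        raise SimulationError("expected SNP count < 100: degenerate test data")

    layout = _conditioned_blocks(list(lengths), cfg.block_mean_low_bp,
                                 cfg.block_mean_high_bp, cfg.stationary_low,
                                 cfg.state_coverage_tol,
                                 _rng(cfg.seed, _RNG_STATES))

    rng_pos = _rng(cfg.seed, _RNG_POSITIONS)
    rng_freq = _rng(cfg.seed, _RNG_FREQS)
    rng_gt = _rng(cfg.seed, _RNG_GENOTYPES)
    rng_meta = _rng(cfg.seed, _RNG_SITEMETA)

    truth = SyntheticTruth(config=cfg)
    scf_col, pos_col, gt_rows, freq_col = [], [], [], []
    for name, blocks in zip(names, layout):
        truth.state_intervals[name] = [[int(s), int(e), int(st)]
                                       for s, e, st in blocks]
        pos0 = _positions_in_intervals(blocks, rate_low, rate_high, rng_pos)
        p = _draw_freqs(len(pos0), cfg, rng_freq)
        g = _hwe_genotypes(p, cfg.n_samples, rng_gt)
        scf_col.extend([name] * len(pos0))
        pos_col.append(pos0 + 1)
        gt_rows.append(g)
        freq_col.append(p)

    pos_all = np.concatenate(pos_col) if pos_col else np.empty(0, dtype=np.int64)
    n = len(pos_all)
    qual = np.round(np.clip(rng_meta.normal(60.0, 10.0, size=n), 20.0, None), 1)
    depth = rng_meta.poisson(30.0, size=n).astype(float)
    samples = [f"lib{i+2}" for i in range(cfg.n_samples)]
    variants = VariantTable(
        np.array(scf_col, dtype=object), pos_all, qual, depth,
        (np.vstack(gt_rows).astype(np.int8) if gt_rows
         else np.empty((0, cfg.n_samples), np.int8)),
        samples)
    truth.allele_freqs = [float(x) for x in np.concatenate(freq_col)] if freq_col else []

    features, gff3_text = _simulate_features(scaffolds, cfg,
                                             _rng(cfg.seed, _RNG_FEATURES))
    bundle = GenomeBundle(scaffolds=scaffolds, variants=variants,
                          features=features, truth=truth, gff3_text=gff3_text)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def _simulate_features(scaffolds: ScaffoldSet, cfg: SimConfig,
                       rng: np.random.Generator):
    """Uniformly placed non-overlapping gene models with alternating exons."""
    from .genome_io import FeatureSet, merge_intervals, subtract_intervals, \
        complement_intervals

    fs = FeatureSet()
    gff_lines = ["##gff-version 3"]
    for name, length in zip(scaffolds.names, scaffolds.lengths):
        slot = length // max(cfg.genes_per_scaffold, 1)
        exons, genes = [], []
        for gi in range(cfg.genes_per_scaffold):
            glen = int(rng.integers(*cfg.gene_length_range))
            if glen + 2 >= slot:
                glen = slot - 2
            start = gi * slot + int(rng.integers(0, slot - glen))
            end = start + glen
            genes.append([start, end])
            n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
            # split the gene into 2*n_ex - 1 chunks, odd chunks are introns
            cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_ex - 2,
                                      replace=False)) if glen > 2 * n_ex else []
            bounds = [0] + [int(c) for c in cuts] + [glen]
            gid = f"{name}.g{gi+1}"
            gff_lines.append(f"{name}\tsim\tgene\t{start+1}\t{end}\t.\t+\t.\tID={gid}")
            ei = 0
            for ci in range(len(bounds) - 1):
                if ci % 2 == 0:   # exon chunk
                    ei += 1
                    es, ee = start + bounds[ci], start + bounds[ci + 1]
                    exons.append([es, ee])
                    gff_lines.append(f"{name}\tsim\texon\t{es+1}\t{ee}\t.\t+\t.\t"
                                     f"ID={gid}.e{ei};Parent={gid}")
        g = merge_intervals(np.array(genes, dtype=np.int64).reshape(-1, 2))
        e = merge_intervals(np.array(exons, dtype=np.int64).reshape(-1, 2))
        fs.exon[name] = e
        fs.intron[name] = subtract_intervals(g, e)
        fs.other[name] = complement_intervals(g, length)
    return fs, "\n".join(gff_lines) + "\n"


# ---------------------------------------------------------------------------
# inbred samples / ROH substrate

@dataclass
class InbredCohort:
    scaffolds: ScaffoldSet
    variants: VariantTable
    truth: SyntheticTruth


def simulate_inbred_cohort(config: SimConfig,
                           sample_F: dict[str, float] | None = None,
                           out_dir: str | Path | None = None) -> InbredCohort:
    """Cohort on a uniform-density SNP substrate with per-sample IBD tracts.

    Sites are Poisson at ``snp_rate_per_kb``; each sample's genome carries
    alternating-renewal IBD tracts (exponential lengths, mean
    ``tract_mean_bp``) covering fraction F of the genome, forced homozygous
    inside with heterozygous flips at the genotyping error rate, HWE outside.
    """
    cfg = config
    if sample_F is None:
        sample_F = {f"lib{i+2}": cfg.F for i in range(cfg.n_samples)}
    for F in sample_F.values():
        if not (0 <= F < 1):
            raise SimulationError("F must lie in [0, 1)")
    if cfg.F > 0 and cfg.tract_mean_bp < 10 * (1000.0 / cfg.snp_rate_per_kb):
        import warnings
        warnings.warn("tract mean < 10x SNP spacing: ROH caller cannot resolve")

    names = tuple(f"scaffold_{i+1}" for i in range(cfg.n_scaffolds))
    lengths = tuple([cfg.scaffold_length] * cfg.n_scaffolds)
    scaffolds = ScaffoldSet(names, lengths)

    rng_pos = _rng(cfg.seed, _RNG_POSITIONS)
    rng_freq = _rng(cfg.seed, _RNG_FREQS)
    rate = cfg.snp_rate_per_kb / 1000.0
    pos_by_scf = {}
    for name, L in zip(names, lengths):
        n = rng_pos.poisson(rate * L)
        pos_by_scf[name] = np.unique(rng_pos.integers(0, L, size=n)).astype(np.int64)
    n_total = int(sum(len(v) for v in pos_by_scf.values()))
    if n_total < 100:
        raise SimulationError("expected SNP count < 100: degenerate test data")
    freqs = _draw_freqs(n_total, cfg, rng_freq)

    truth = SyntheticTruth(config=cfg, allele_freqs=[float(x) for x in freqs],
                           sample_F=dict(sample_F))
    samples = list(sample_F)
    rng_tracts = _rng(cfg.seed, _RNG_TRACTS)
    rng_gt = _rng(cfg.seed, _RNG_GENOTYPES)

    cols = []
    for sample, F in sample_F.items():
        col, tracts = _simulate_inbred_column(pos_by_scf, freqs, list(lengths),
                                              F, cfg, rng_tracts, rng_gt)
        truth.ibd_tracts[sample] = tracts
        cols.append(col)

    scf_col, pos_col = [], []
    for name in names:
        scf_col.extend([name] * len(pos_by_scf[name]))
        pos_col.append(pos_by_scf[name] + 1)
    rng_meta = _rng(cfg.seed, _RNG_SITEMETA)
    qual = np.round(np.clip(rng_meta.normal(60.0, 10.0, size=n_total), 20.0, None), 1)
    depth = rng_meta.poisson(30.0, size=n_total).astype(float)
    variants = VariantTable(np.array(scf_col, dtype=object),
                            np.concatenate(pos_col), qual, depth,
                            np.column_stack(cols).astype(np.int8), samples)
    cohort = InbredCohort(scaffolds=scaffolds, variants=variants, truth=truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_vcf(variants, scaffolds, out_dir / "cohort.vcf")
        scaffolds.to_table(out_dir / "scaffolds.tsv")
        truth.to_json(out_dir / "truth.json")
        _write_tract_bed(truth, out_dir / "tracts.bed")
    return cohort


def _simulate_inbred_column(pos_by_scf: dict[str, np.ndarray], freqs: np.ndarray,
                            lengths: list[int], F: float, cfg: SimConfig,
                            rng_tracts: np.random.Generator,
                            rng_gt: np.random.Generator):
    """One sample's genotype column plus its true IBD tract intervals."""
    total = sum(lengths)
    names = list(pos_by_scf)
    if F > 0:
        off_mean = cfg.tract_mean_bp * (1 - F) / F
        for _ in range(2000):
            layout = [_alternating_blocks(L, cfg.tract_mean_bp, off_mean,
                                          rng_tracts, F) for L in lengths]
            cov = sum(e - s for scf in layout for s, e, st in scf if st == 0) / total
            if abs(cov - F) <= cfg.tract_coverage_tol:
                break
        else:
            raise SimulationError("could not calibrate IBD tract coverage")
    else:
        layout = [[(0, L, 1)] for L in lengths]

    tracts: dict[str, list[list[int]]] = {}
    col_parts = []
    offset = 0
    for name, L, blocks in zip(names, lengths, layout):
        pos0 = pos_by_scf[name]
        p = freqs[offset:offset + len(pos0)]
        offset += len(pos0)
        on = np.array([[s, e] for s, e, st in blocks if st == 0],
                      dtype=np.int64).reshape(-1, 2)
        tracts[name] = on.tolist()
        g = rng_gt.binomial(2, p).astype(np.int8)       # HWE background
        if len(on):
            idx = np.searchsorted(on[:, 0], pos0, side="right") - 1
            inside = (idx >= 0) & (pos0 < on[np.clip(idx, 0, None), 1])
            hom_alt = rng_gt.random(len(pos0)) < p      # one IBD allele ~ Bern(p)
            g[inside] = np.where(hom_alt[inside], HOM_ALT, HOM_REF).astype(np.int8)
            err = rng_gt.random(len(pos0)) < cfg.genotyping_error
            g[inside & err] = HET
        col_parts.append(g)
    return np.concatenate(col_parts), tracts


# ---------------------------------------------------------------------------
# related pairs

KINSHIP_SHARED_FRACTION = {"duplicate": 1.0, "first": 0.5, "second": 0.25,
                           "unrelated": 0.0}


def simulate_related_pair(config: SimConfig, kinship_class: str,
                          n_sites: int = 50_000, n_blocks: int = 200):
    """Two genotype columns at a chosen kinship plus truth.

    The pair shares one identical-by-descent haplotype on exactly
    ``round(c * n_blocks)`` of ``n_blocks`` equal site blocks, where c is the
    class's genome fraction (duplicate copies both haplotypes everywhere).
    Returns ``(g1, g2, freqs, truth)``.
    """
    if kinship_class not in KINSHIP_SHARED_FRACTION:
        raise SimulationError(f"unknown kinship class {kinship_class!r}")
    c = KINSHIP_SHARED_FRACTION[kinship_class]
    rng = _rng(config.seed, _RNG_PAIRS)
    p = _draw_freqs(n_sites, config, rng)
    h1a = (rng.random(n_sites) < p).astype(np.int8)   # sample 1 haplotypes
    h1b = (rng.random(n_sites) < p).astype(np.int8)
    if kinship_class == "duplicate":
        g1 = h1a + h1b
        g2 = g1.copy()
        shared = np.ones(n_sites, dtype=bool)
    else:
        blocks = np.array_split(np.arange(n_sites), n_blocks)
        k = int(round(c * n_blocks))
        chosen = rng.choice(n_blocks, size=k, replace=False)
        shared = np.zeros(n_sites, dtype=bool)
        for b in chosen:
            shared[blocks[b]] = True
        h2a = np.where(shared, h1a, (rng.random(n_sites) < p)).astype(np.int8)
        h2b = (rng.random(n_sites) < p).astype(np.int8)
        g1 = h1a + h1b
        g2 = h2a + h2b
    truth = SyntheticTruth(config=config,
                           kinship_class={"pair": kinship_class},
                           allele_freqs=[float(x) for x in p])
    return g1.astype(np.int8), g2.astype(np.int8), p, truth


def pair_to_table(g1: np.ndarray, g2: np.ndarray,
                  names: tuple[str, str] = ("A", "B")) -> VariantTable:
    n = len(g1)
    return VariantTable(np.array(["scaffold_1"] * n, dtype=object),
                        np.arange(1, n + 1, dtype=np.int64) * 100,
                        np.full(n, np.nan), np.full(n, np.nan),
                        np.column_stack([g1, g2]).astype(np.int8), list(names))


# ---------------------------------------------------------------------------
# family evolution tables

def simulate_family_table(config: SimConfig):
    """Per-family A/Ka table, GO map and truth with planted fast categories.

    Background A ~ Poisson(lambda) identically in both lineages; the
    foreground values of planted categories are Poisson(fold * lambda).
    Ka = A / nonsynonymous site count (one shared alignment length per
    family).  Returns ``(table, gomap, truth)``.
    """
    cfg = config
    if cfg.planted_fold <= 1.0 and cfg.n_planted > 0:
        raise SimulationError("planted fold must exceed 1 (unidentifiable otherwise)")
    rng = _rng(cfg.seed, _RNG_FAMILY)
    n_fam = cfg.n_categories * cfg.families_per_category
    go_ids = [f"GO:{i+1:07d}" for i in range(cfg.n_categories)]
    planted = list(rng.choice(go_ids, size=cfg.n_planted, replace=False))
    fam_ids = [f"fam{i+1:05d}" for i in range(n_fam)]
    fam_go = np.repeat(np.arange(cfg.n_categories), cfg.families_per_category)

    lam = cfg.background_A_rate
    planted_set = set(planted)
    fg_lam = np.where(np.isin(np.array(go_ids)[fam_go], list(planted_set)),
                      cfg.planted_fold * lam, lam)
    A_fg = rng.poisson(fg_lam)
    A_bg = rng.poisson(np.full(n_fam, lam))
    nsites = rng.integers(cfg.nonsyn_sites_range[0], cfg.nonsyn_sites_range[1],
                          size=n_fam)
    table = pd.DataFrame({
        "family_id": fam_ids,
        f"{cfg.foreground_lineage}_A": A_fg,
        f"{cfg.background_lineage}_A": A_bg,
        f"{cfg.foreground_lineage}_Ka": A_fg / nsites,
        f"{cfg.background_lineage}_Ka": A_bg / nsites,
    })
    gomap = {fam: {go_ids[g]} for fam, g in zip(fam_ids, fam_go)}
    truth = SyntheticTruth(config=cfg, planted_go_ids=sorted(planted_set))
    return table, gomap, truth


# ---------------------------------------------------------------------------
# HMM window sequences and LRT null replicates

def simulate_hmm_windows(n_windows: int, means=(0.03, 1.26), sds=(0.02, 0.30),
                         self_transition: float = 0.995, seed: int = 0,
                         start_probs=(0.5, 0.5)):
    """Gaussian-emission two-state Markov sequence; returns (densities, states)."""
    rng = _rng(seed, _RNG_STATES)
    states = np.empty(n_windows, dtype=np.int8)
    states[0] = rng.choice(2, p=np.asarray(start_probs, float))
    stay = rng.random(n_windows - 1) < self_transition
    for t in range(1, n_windows):
        states[t] = states[t - 1] if stay[t - 1] else 1 - states[t - 1]
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    dens = rng.normal(means[states], sds[states])
    return dens, states


def simulate_branch_site_null(n_genes: int, n_obs: int = 50, seed: int = 0):
    """Null log-likelihood pairs from a boundary-constrained Gaussian MLE.

    Data y ~ N(0,1); the null fixes the mean at 0, the alternative estimates
    mu >= 0 — the same boundary situation that makes the chi-square(1)
    reference conservative for the branch-site test.  Returns a list of
    (gene_id, lnL_alt, lnL_null) triples.
    """
    rng = _rng(seed, _RNG_LRT)
    y = rng.normal(0.0, 1.0, size=(n_genes, n_obs))
    const = -0.5 * n_obs * np.log(2 * np.pi)
    lnl_null = const - 0.5 * (y**2).sum(axis=1)
    mu = np.clip(y.mean(axis=1), 0.0, None)
    lnl_alt = const - 0.5 * ((y - mu[:, None])**2).sum(axis=1)
    return [(f"gene{i+1}", float(a), float(b))
            for i, (a, b) in enumerate(zip(lnl_alt, lnl_null))]


# ---------------------------------------------------------------------------
# writers

def write_vcf(variants: VariantTable, scaffolds: ScaffoldSet,
              path: str | Path) -> None:
    """Minimal deterministic VCF 4.2 writer (GT per sample, site DP in INFO)."""
    gt_str = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=milupop-simulate\n")
        for n, l in zip(scaffolds.names, scaffolds.lengths):
            fh.write(f"##contig=<ID={n},length={l}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(variants.samples) + "\n")
        for i in range(len(variants)):
            qual = variants.qual[i]
            qual_s = "." if np.isnan(qual) else f"{qual:.1f}"
            dp = variants.depth[i]
            info = "." if np.isnan(dp) else f"DP={int(dp)}"
            gts = "\t".join(gt_str[int(g)] for g in variants.genotypes[i])
            fh.write(f"{variants.scaffold[i]}\t{int(variants.pos[i])}\t.\tA\tG\t"
                     f"{qual_s}\tPASS\t{info}\tGT\t{gts}\n")


def _write_tract_bed(truth: SyntheticTruth, path: str | Path) -> None:
    from .genome_io import write_bed
    records = []
    for sample in sorted(truth.ibd_tracts):
        for scf in sorted(truth.ibd_tracts[sample]):
            for s, e in truth.ibd_tracts[sample][scf]:
                records.append((scf, int(s), int(e), sample))
    # grouped per sample then scaffold; write_bed enforces per-call sortedness,
    # so write manually to allow one file for the whole cohort
    with open(path, "w") as fh:
        for scf, s, e, label in records:
            fh.write(f"{scf}\t{s}\t{e}\t{label}\n")


def write_bundle(bundle: GenomeBundle, out_dir: str | Path) -> dict[str, Path]:
    from .genome_io import write_bed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "genome.vcf",
        "states": out_dir / "truth_states.bed",
        "gff3": out_dir / "features.gff3",
        "scaffolds": out_dir / "scaffolds.tsv",
        "truth": out_dir / "truth.json",
    }
    write_vcf(bundle.variants, bundle.scaffolds, paths["vcf"])
    state_records = []
    for scf in bundle.scaffolds.names:
        for s, e, st in bundle.truth.state_intervals[scf]:
            state_records.append((scf, s, e, "L" if st == 0 else "H"))
    write_bed(state_records, paths["states"])
    with open(paths["gff3"], "w") as fh:
        fh.write(bundle.gff3_text)
    bundle.scaffolds.to_table(paths["scaffolds"])
    bundle.truth.to_json(paths["truth"])
    return paths
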