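"""PLINK-style runs-of-homozygosity detection and the Froh inbreeding coefficient.

The scan reproduces the sliding-window logic of PLINK 1.07 ``--homozyg`` with
the flag set used for low-coverage resequencing cohorts
(``--homozyg-window-kb 0 --homozyg-window-snp 65 --homozyg-window-het 1
--homozyg-window-missing 3 --homozyg-window-threshold 0.05 --homozyg-snp 65
--homozyg-kb 100 --homozyg-density 5000 --homozyg-gap 5000``):

1. every window of ``window_snp`` consecutive SNPs qualifies iff it contains
   at most ``window_het`` heterozygous and ``window_missing`` missing calls
   (windows truncated at scaffold ends are not formed);
2. a non-missing SNP is ROH-eligible iff the fraction of qualifying windows
   among the windows that contain it is at least ``window_threshold`` — the
   denominator is the actual number of containing windows, so SNPs near
   scaffold ends are judged on fewer windows;
3. maximal runs of consecutive eligible SNPs become candidate segments
   (missing calls are transparent: they neither qualify nor break a run),
   split wherever adjacent member SNPs lie more than ``gap_kb`` kb apart;
4. candidates survive iff they hold >= ``min_snp`` SNPs, span >= ``min_kb`` kb
   and average at most ``density_kb_per_snp`` kb per SNP.

Segment boundaries are the first and last member SNP positions.  Froh is the
summed segment length divided by the genome effective length (by default the
summed length of scaffolds carrying at least one called SNP for the sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome_io import HET, MISSING, ScaffoldSet, VariantTable


class RohError(ValueError):
    pass


@dataclass(frozen=True)
class RohParams:
    window_snp: int = 65
    window_het: int = 1
    window_missing: int = 3
    window_threshold: float = 0.05
    min_snp: int = 65
    min_kb: float = 100.0
    density_kb_per_snp: float = 5000.0
    gap_kb: float = 5000.0
    window_kb: float = 0.0   # 0 disables the bp-size window constraint

    def __post_init__(self) -> None:
        if min(self.window_snp, self.window_het, self.window_missing,
               self.min_snp) < 0 or min(self.min_kb, self.density_kb_per_snp,
                                        self.gap_kb, self.window_kb) < 0:
            raise RohError("ROH parameters must be non-negative")
        if not (0 < self.window_threshold <= 1):
            raise RohError("window_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class RohSegment:
    scaffold: str
    start: int        # bp position of the first member SNP (1-based)
    end: int          # bp position of the last member SNP
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RohReport:
    sample: str
    segments: list[RohSegment]
    froh: float
    effective_length: int
    total_roh: int
    mean_length: float
    n_segments: int
    fraction_over_1mb: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segments"] = [asdict(s) for s in self.segments]
        return d


def scan_roh(variants: VariantTable, sample: str, scaffolds: ScaffoldSet,
             params: RohParams = RohParams()) -> list[RohSegment]:
    """Detect ROH segments for one sample (vectorised window scan)."""
    col = variants.sample_genotypes(sample)
    slices = variants.scaffold_slices()
    out: list[RohSegment] = []
    for scf in scaffolds.names:
        sl = slices.get(scf)
        if sl is None:
            continue
        g = col[sl]
        pos = variants.pos[sl]
        out.extend(_scan_scaffold(scf, pos, g, params))
    return out


def _scan_scaffold(scf: str, pos: np.ndarray, g: np.ndarray,
                   p: RohParams) -> list[RohSegment]:
    n = len(pos)
    W = p.window_snp
    het = (g == HET).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)
    eligible = np.zeros(n, dtype=bool)
    if n >= W and W > 0:
        chet = np.concatenate(([0], np.cumsum(het)))
        cmis = np.concatenate(([0], np.cumsum(mis)))
        whet = chet[W:] - chet[:-W]          # counts per window start 0..n-W
        wmis = cmis[W:] - cmis[:-W]
        qual = ((whet <= p.window_het) & (wmis <= p.window_missing)).astype(np.int64)
        cq = np.concatenate(([0], np.cumsum(qual)))
        i = np.arange(n)
        lo = np.maximum(0, i - W + 1)
        hi = np.minimum(i, n - W)
        contain = hi - lo + 1
        hits = cq[np.clip(hi + 1, 0, len(cq) - 1)] - cq[np.clip(lo, 0, len(cq) - 1)]
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(contain > 0, hits / np.maximum(contain, 1), 0.0)
        eligible = (rate >= p.window_threshold) & (g != MISSING)

    # runs over the SNP sequence: missing calls are transparent
    segments: list[RohSegment] = []
    run: list[int] = []     # indices of member SNPs (incl. transparent missing)
    def flush(run_idx: list[int]) -> None:
        # trim leading/trailing non-eligible (missing) members
        while run_idx and not eligible[run_idx[0]]:
            run_idx.pop(0)
        while run_idx and not eligible[run_idx[-1]]:
            run_idx.pop()
        if not run_idx:
            return
        # split at gaps > gap_kb between adjacent members
        gap_bp = p.gap_kb * 1000.0
        parts: list[list[int]] = [[run_idx[0]]]
        for a, b in zip(run_idx, run_idx[1:]):
            if pos[b] - pos[a] > gap_bp:
                parts.append([b])
            else:
                parts[-1].append(b)
        for part in parts:
            while part and not eligible[part[0]]:
                part.pop(0)
            while part and not eligible[part[-1]]:
                part.pop()
            if not part:
                continue
            start, end = int(pos[part[0]]), int(pos[part[-1]])
            span = end - start
            n_snps = len(part)
            if n_snps < p.min_snp:
                continue
            if span / 1000.0 < p.min_kb:
                continue
            if span / n_snps > p.density_kb_per_snp * 1000.0:
                continue
            if p.window_kb > 0 and span / 1000.0 < p.window_kb:
                continue
            segments.append(RohSegment(
                scaffold=scf, start=start, end=end, n_snps=n_snps,
                n_het=int(het[part].sum()), n_missing=int(mis[part].sum())))

    for i in range(n):
        if mis[i]:
            if run:
                run.append(i)    # transparent; dropped if terminal
            continue
        if eligible[i]:
            run.append(i)
        else:
            flush(run)
            run = []
    flush(run)
    return segments


def compute_froh(segments: list[RohSegment], effective_length: int) -> float:
    """Total ROH length over genome effective length."""
    if effective_length <= 0:
        raise RohError("effective_length must be positive")
    by_scf: dict[str, list[RohSegment]] = {}
    for s in segments:
        by_scf.setdefault(s.scaffold, []).append(s)
    for scf, segs in by_scf.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise RohError(f"overlapping ROH segments on {scf}; merge first")
    total = sum(s.length for s in segments)
    froh = total / effective_length
    if not (0.0 <= froh <= 1.0):
        raise RohError("Froh outside [0, 1]; check effective length")
    return froh


def effective_length_for_sample(variants: VariantTable, sample: str,
                                scaffolds: ScaffoldSet) -> int:
    """Sum of lengths of scaffolds carrying >= 1 called SNP for the sample."""
    col = variants.sample_genotypes(sample)
    called = col != MISSING
    slices = variants.scaffold_slices()
    total = 0
    for name, length in zip(scaffolds.names, scaffolds.lengths):
        sl = slices.get(name)
        if sl is not None and called[sl].any():
            total += length
    return total


def make_roh_report(variants: VariantTable, sample: str, scaffolds: ScaffoldSet,
                    params: RohParams = RohParams(),
                    effective_length: int | None = None) -> RohReport:
    segments = scan_roh(variants, sample, scaffolds, params)
    if effective_length is None:
        effective_length = effective_length_for_sample(variants, sample, scaffolds)
    froh = compute_froh(segments, effective_length) if effective_length > 0 else 0.0
    lengths = np.array([s.length for s in segments], dtype=float)
    total = int(lengths.sum()) if len(lengths) else 0
    return RohReport(
        sample=sample, segments=segments, froh=froh,
        effective_length=int(effective_length), total_roh=total,
        mean_length=float(lengths.mean()) if len(lengths) else 0.0,
        n_segments=len(segments),
        fraction_over_1mb=(float(lengths[lengths > 1_000_000].sum() / total)
                           if total else 0.0),
    )


def roh_length_summary(reports: list[RohReport]) -> pd.DataFrame:
    """Per-sample ROH length statistics plus cross-sample quartile rows.

    The per-sample rows tabulate what the usual cohort box plots display:
    count, total, mean, median, max and the fraction of ROH length held in
    segments longer than 1 Mb.
    """
    if not reports:
        raise RohError("need at least one report")
    rows = []
    for r in reports:
        lens = np.array([s.length for s in r.segments], dtype=float)
        rows.append({
            "sample": r.sample,
            "n_segments": r.n_segments,
            "total_bp": int(lens.sum()) if len(lens) else 0,
            "mean_bp": float(lens.mean()) if len(lens) else 0.0,
            "median_bp": float(np.median(lens)) if len(lens) else 0.0,
            "max_bp": float(lens.max()) if len(lens) else 0.0,
            "fraction_over_1mb": r.fraction_over_1mb,
            "froh": r.froh,
        })
    df = pd.DataFrame(rows)
    froh = df["froh"].to_numpy()
    mean_bp = df["mean_bp"].to_numpy()
    q = lambda v: np.percentile(v, [25, 50, 75])
    summary = pd.DataFrame({
        "sample": ["cohort_q25", "cohort_q50", "cohort_q75"],
        "froh": q(froh), "mean_bp": q(mean_bp),
    })
    return pd.concat([df, summary], ignore_index=True)


def segments_to_hom_table(reports: list[RohReport]) -> pd.DataFrame:
    """PLINK .hom-style table: sample, scaffold, start, end, n_snps, kb, density."""
    rows = []
    for r in reports:
        for s in r.segments:
            kb = s.length / 1000.0
            rows.append((r.sample, s.scaffold, s.start, s.end, s.n_snps, kb,
                         kb / s.n_snps))
    return pd.DataFrame(rows, columns=["sample", "scaffold", "start", "end",
                                       "n_snps", "kb", "kb_per_snp"])
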