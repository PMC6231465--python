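"""Readers, writers and variant-level filtering for the pipeline's on-disk formats.

All coordinates are held 0-based half-open internally; the 1-based conventions
of VCF and GFF3 are converted at the boundary.  Genotypes are encoded as small
integers (:data:`HOM_REF` etc.) in a dense per-sample matrix so that the
diversity and ROH scans can be vectorised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_GT_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}


class GenomeIOError(ValueError):
    """Malformed or inconsistent genomic input."""


@dataclass(frozen=True)
class ScaffoldSet:
    """Ordered universe of scaffolds with their lengths in base pairs."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise GenomeIOError("scaffold names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise GenomeIOError("scaffold lengths must be positive")

    def __len__(self) -> int:
        return len(self.names)

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[self.names.index(name)]
        except ValueError:
            raise GenomeIOError(f"unknown scaffold {name!r}") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    @classmethod
    def from_table(cls, path: str | Path) -> "ScaffoldSet":
        """Read a two-column (name, length) table, .fai-style."""
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                         names=["name", "length"], dtype={"name": str})
        return cls(tuple(df["name"]), tuple(int(x) for x in df["length"]))

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for n, l in zip(self.names, self.lengths):
                fh.write(f"{n}\t{l}\n")


@dataclass
class VariantTable:
    """Biallelic SNP calls for an ordered sample cohort.

    ``pos`` is 1-based (VCF convention); records are sorted by
    (scaffold, pos) and unique.  ``genotypes`` is an (n_records, n_samples)
    int8 matrix using the module-level genotype codes.  ``qual``/``depth``
    are NaN where the VCF carried no value.
    """

    scaffold: np.ndarray          # object array of str
    pos: np.ndarray               # int64, 1-based
    qual: np.ndarray              # float64
    depth: np.ndarray             # float64
    genotypes: np.ndarray         # int8 (n, n_samples)
    samples: list[str]

    def __post_init__(self) -> None:
        n = len(self.pos)
        if not (len(self.scaffold) == len(self.qual) == len(self.depth) == n
                and self.genotypes.shape[0] == n):
            raise GenomeIOError("column lengths disagree")
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != len(self.samples):
            raise GenomeIOError("genotype matrix does not match sample list")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise GenomeIOError(f"sample {sample!r} not present") from None

    def sample_genotypes(self, sample: str) -> np.ndarray:
        return self.genotypes[:, self.sample_index(sample)]

    def scaffold_slices(self) -> dict[str, slice]:
        """Contiguous row slice per scaffold (table is sorted)."""
        out: dict[str, slice] = {}
        if len(self) == 0:
            return out
        names, starts = np.unique(self.scaffold.astype(str), return_index=True)
        order = np.argsort(starts)
        starts = starts[order]
        names = names[order]
        bounds = list(starts) + [len(self)]
        for i, name in enumerate(names):
            out[str(name)] = slice(int(bounds[i]), int(bounds[i + 1]))
        return out

    def subset_rows(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(self.scaffold[mask], self.pos[mask], self.qual[mask],
                            self.depth[mask], self.genotypes[mask], list(self.samples))

    def validate_sorted(self) -> None:
        seen: dict[str, int] = {}
        prev_scf, prev_pos = None, -1
        for i in range(len(self)):
            scf, p = str(self.scaffold[i]), int(self.pos[i])
            if scf == prev_scf:
                if p <= prev_pos:
                    raise GenomeIOError(
                        f"records unsorted or duplicated at {scf}:{p} (row {i})")
            else:
                if scf in seen:
                    raise GenomeIOError(
                        f"scaffold {scf} occurs in non-contiguous blocks (row {i})")
                seen[scf] = i
            prev_scf, prev_pos = scf, p


@dataclass
class FeatureSet:
    """Genomic element partition: exon / intron / other intervals.

    Intervals are 0-based half-open, stored per class as dicts mapping
    scaffold -> (n, 2) int arrays sorted by start.  After
    :func:`read_features` the three classes partition every scaffold.
    """

    exon: dict[str, np.ndarray] = field(default_factory=dict)
    intron: dict[str, np.ndarray] = field(default_factory=dict)
    other: dict[str, np.ndarray] = field(default_factory=dict)

    CLASSES = ("exon", "intron", "other")

    def intervals(self, cls: str) -> dict[str, np.ndarray]:
        if cls not in self.CLASSES:
            raise GenomeIOError(f"unknown feature class {cls!r}")
        return getattr(self, cls)

    def class_length(self, cls: str) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum()
                       for iv in self.intervals(cls).values()))


# ---------------------------------------------------------------------------
# interval helpers (0-based half-open, sorted, non-overlapping)

def merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent sorted intervals."""
    if len(iv) == 0:
        return iv.reshape(0, 2).astype(np.int64)
    iv = iv[np.argsort(iv[:, 0])]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)

def subtract_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a \\ b for merged-sorted interval arrays."""
    if len(a) == 0:
        return a.reshape(0, 2).astype(np.int64)
    if len(b) == 0:
        return a.astype(np.int64)
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append([cur, min(bs, e)])
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append([cur, e])
    return np.array(out, dtype=np.int64).reshape(-1, 2)

def complement_intervals(iv: np.ndarray, length: int) -> np.ndarray:
    return subtract_intervals(np.array([[0, length]], dtype=np.int64),
                              merge_intervals(iv))


# ---------------------------------------------------------------------------
# VCF

def _map_gt_types(gt_types: np.ndarray) -> np.ndarray:
    # cyvcf2: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    lut = np.array([HOM_REF, HET, MISSING, HOM_ALT], dtype=np.int8)
    return lut[gt_types]


def read_vcf(path: str | Path, samples: list[str] | None = None) -> VariantTable:
    """Read a VCF into a :class:`VariantTable`.

    Only biallelic SNPs are retained; indels and multi-allelic records are
    dropped (the count is logged).  Records must be coordinate-sorted.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise GenomeIOError(f"cannot read VCF: {path}")
    vcf = VCF(str(path), gts012=False)
    all_samples = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in all_samples]
        if missing:
            raise GenomeIOError(f"requested samples absent from VCF: {missing}")
        sel = [all_samples.index(s) for s in samples]
        out_samples = list(samples)
    else:
        sel = list(range(len(all_samples)))
        out_samples = all_samples

    scaffolds: list[str] = []
    pos: list[int] = []
    qual: list[float] = []
    depth: list[float] = []
    gts: list[np.ndarray] = []
    n_dropped = 0
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            n_dropped += 1
            continue
        scaffolds.append(v.CHROM)
        pos.append(v.POS)
        qual.append(float(v.QUAL) if v.QUAL is not None else np.nan)
        dp = v.INFO.get("DP")
        depth.append(float(dp) if dp is not None else np.nan)
        gts.append(_map_gt_types(np.asarray(v.gt_types))[sel])
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)

    table = VariantTable(
        np.array(scaffolds, dtype=object),
        np.array(pos, dtype=np.int64),
        np.array(qual, dtype=np.float64),
        np.array(depth, dtype=np.float64),
        (np.vstack(gts).astype(np.int8) if gts
         else np.empty((0, len(out_samples)), dtype=np.int8)),
        out_samples,
    )
    table.validate_sorted()
    return table


def filter_variants(table: VariantTable, min_qual: float = 0.0,
                    min_depth: float = 0.0,
                    max_depth: float = np.inf) -> VariantTable:
    """Quality/depth filter in the style of ``vcfutils.pl varFilter -Q -d -D``.

    Records with missing QUAL/DP pass a threshold unless that threshold was
    explicitly set (i.e. NaN compares as passing).
    """
    if min_qual < 0 or min_depth < 0:
        raise GenomeIOError("thresholds must be non-negative")
    if min_depth > max_depth:
        raise GenomeIOError("min_depth must not exceed max_depth")
    q_ok = np.isnan(table.qual) | (table.qual >= min_qual)
    d_ok = np.isnan(table.depth) | ((table.depth >= min_depth)
                                    & (table.depth <= max_depth))
    return table.subset_rows(q_ok & d_ok)


# ---------------------------------------------------------------------------
# features

def read_features(path: str | Path, fmt: str, scaffolds: ScaffoldSet) -> FeatureSet:
    """Derive the exon/intron/other partition from gene models.

    ``fmt='gff3'``: gene and exon records are read (1-based closed, converted
    internally); intron = gene span minus exons, other = complement of gene
    spans.  ``fmt='bed'``: 4+ column BED whose name column is the feature
    class (``exon``/``gene``).
    """
    genes: dict[str, list[list[int]]] = {}
    exons: dict[str, list[list[int]]] = {}
    if fmt == "gff3":
        import gffutils

        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                merge_strategy="create_unique", keep_order=True)
        for g in db.features_of_type("gene"):
            genes.setdefault(g.seqid, []).append([g.start - 1, g.end])
        for e in db.features_of_type("exon"):
            exons.setdefault(e.seqid, []).append([e.start - 1, e.end])
    elif fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["scf", "start", "end", "name"], usecols=range(4),
                         dtype={"scf": str, "name": str})
        for _, row in df.iterrows():
            dest = exons if row["name"] == "exon" else genes
            dest.setdefault(row["scf"], []).append([int(row["start"]), int(row["end"])])
    else:
        raise GenomeIOError(f"unknown feature format {fmt!r}")

    fs = FeatureSet()
    for name, length in zip(scaffolds.names, scaffolds.lengths):
        g = merge_intervals(np.array(genes.get(name, []), dtype=np.int64).reshape(-1, 2))
        e = merge_intervals(np.array(exons.get(name, []), dtype=np.int64).reshape(-1, 2))
        if len(g) and ((g[:, 0] < 0).any() or (g[:, 1] > length).any()):
            raise GenomeIOError(f"gene outside scaffold {name}")
        if len(e) and len(subtract_intervals(e, g)):
            raise GenomeIOError(f"exon outside gene span on scaffold {name}")
        if (len(g) and (g[:, 1] <= g[:, 0]).any()) or (len(e) and (e[:, 1] <= e[:, 0]).any()):
            raise GenomeIOError(f"negative-length interval on scaffold {name}")
        fs.exon[name] = e
        fs.intron[name] = subtract_intervals(g, e)
        fs.other[name] = complement_intervals(g, length)
    return fs


# ---------------------------------------------------------------------------
# BED

def write_bed(intervals: list[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write labelled intervals as 4-column BED (0-based half-open)."""
    prev: tuple[str, int] | None = None
    seen: dict[str, int] = {}
    with open(path, "w") as fh:
        for scf, start, end, label in intervals:
            if prev is not None and scf == prev[0] and start < prev[1]:
                raise GenomeIOError(f"unsorted BED interval {scf}:{start}-{end}")
            if scf != (prev[0] if prev else None):
                if scf in seen:
                    raise GenomeIOError(f"unsorted BED: scaffold {scf} recurs")
                seen[scf] = 1
            fh.write(f"{scf}\t{start}\t{end}\t{label}\n")
            prev = (scf, start)


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return out
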