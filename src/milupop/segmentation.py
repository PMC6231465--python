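"""SNP-density genome segmentation.

The genome is scanned with overlapping sliding windows (default 200 kb at
2-kb steps, scaffolds > 300 kb only) and the per-window SNP density in
SNPs/kb is modelled as a two-regime process: a two-component Gaussian
mixture fitted by EM supplies starting values for a two-state Gaussian HMM
fitted by Baum–Welch, whose Viterbi path labels each window low ("L") or
high ("H") density.  Window states are mapped back to base pairs by
step-interval ownership: the 2-kb interval at each window's start inherits
that window's state, with the final window of a scaffold extending to its
window end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome_io import HET, ScaffoldSet, VariantTable

logger = logging.getLogger(__name__)

SD_FLOOR = 1e-4  # SNPs/kb; prevents component collapse in both EM procedures

STATE_LABELS = ("L", "H")


class SegmentationError(ValueError):
    pass


@dataclass
class DensityTrack:
    """Windowed SNP densities per scaffold (SNPs per kb)."""

    window: int
    step: int
    min_scaffold: int
    starts: dict[str, np.ndarray] = field(default_factory=dict)    # 0-based bp
    densities: dict[str, np.ndarray] = field(default_factory=dict)
    scaffold_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return int(sum(len(v) for v in self.densities.values()))

    def all_densities(self) -> np.ndarray:
        if not self.densities:
            return np.empty(0)
        return np.concatenate([self.densities[k] for k in sorted(self.densities)])

    def sequences(self) -> list[np.ndarray]:
        """Per-scaffold density sequences in deterministic (sorted) order."""
        return [self.densities[k] for k in sorted(self.densities)]

    def to_frame(self):
        import pandas as pd
        rows = []
        for scf in sorted(self.densities):
            for s, d in zip(self.starts[scf], self.densities[scf]):
                rows.append((scf, int(s), int(s) + self.step, float(d)))
        return pd.DataFrame(rows, columns=["scaffold", "start", "end", "density"])


@dataclass
class MixtureFit:
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    seed: int | None = None

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise SegmentationError("mixture weights must sum to 1")
        if (self.sds < SD_FLOOR - 1e-12).any():
            raise SegmentationError("mixture sds below variance floor")


@dataclass
class HmmModel:
    """Two-state Gaussian HMM; state 0 is the lower-mean ("L") state."""

    initial: np.ndarray           # (2,)
    transitions: np.ndarray       # (2, 2) row-stochastic
    means: np.ndarray             # (2,)
    sds: np.ndarray               # (2,)
    log_likelihood: float = np.nan
    n_iterations: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        if np.abs(self.transitions.sum(axis=1) - 1.0).max() > 1e-9:
            raise SegmentationError("transition rows must sum to 1")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise SegmentationError("initial probabilities must sum to 1")
        if self.means[0] > self.means[1]:
            raise SegmentationError("state 0 must carry the lower emission mean")


@dataclass
class StateSegments:
    """Merged genomic intervals per scaffold with L/H state labels."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)  # (n,3): start,end,state
    window_states: dict[str, np.ndarray] = field(default_factory=dict)

    def state_length(self, state: int) -> int:
        return int(sum((iv[iv[:, 2] == state, 1] - iv[iv[:, 2] == state, 0]).sum()
                       for iv in self.intervals.values()))

    def total_length(self) -> int:
        return self.state_length(0) + self.state_length(1)

    def to_bed_records(self) -> list[tuple[str, int, int, str]]:
        out = []
        for scf in sorted(self.intervals):
            for s, e, st in self.intervals[scf]:
                out.append((scf, int(s), int(e), STATE_LABELS[int(st)]))
        return out


@dataclass
class SegmentationSummary:
    fraction_genome_L: float
    fraction_genome_H: float
    fraction_snps_L: float
    fraction_snps_H: float
    mean_het_L: float   # het SNPs per kb within L intervals
    mean_het_H: float
    n_snps_outside: int = 0


# ---------------------------------------------------------------------------

def window_density(variants: VariantTable, scaffolds: ScaffoldSet,
                   window: int = 200_000, step: int = 2_000,
                   min_scaffold: int = 300_000) -> DensityTrack:
    """Sliding-window SNP density (SNPs/kb) on scaffolds longer than ``min_scaffold``."""
    if not (window >= step > 0):
        raise SegmentationError("require window >= step > 0")
    track = DensityTrack(window=window, step=step, min_scaffold=min_scaffold)
    slices = variants.scaffold_slices()
    kept = 0
    for name, length in zip(scaffolds.names, scaffolds.lengths):
        if length <= min_scaffold or length < window:
            continue
        kept += 1
        starts = np.arange(0, length - window + 1, step, dtype=np.int64)
        sl = slices.get(name, slice(0, 0))
        pos0 = variants.pos[sl] - 1  # internal 0-based
        counts = (np.searchsorted(pos0, starts + window, side="left")
                  - np.searchsorted(pos0, starts, side="left"))
        track.starts[name] = starts
        track.densities[name] = counts / (window / 1000.0)
        track.scaffold_lengths[name] = int(length)
    if kept == 0:
        logger.warning("window_density: no scaffold long enough; empty track")
    return track


# ---------------------------------------------------------------------------
# Gaussian mixture EM

def _normal_logpdf(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x[:, None] - mean) / sd) ** 2


def _em_once(x: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray,
             tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = _normal_logpdf(x, mu, sd) + np.log(w)
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / nk.sum()
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, SD_FLOOR**2))
        if ll - prev_ll < tol and it > 1:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return w, mu, sd, prev_ll, it, converged


def fit_mixture(track: DensityTrack | np.ndarray, k: int = 2, tol: float = 1e-8,
                max_iter: int = 1000, n_restarts: int = 5,
                seed: int = 0) -> MixtureFit:
    """Fit a k-component Gaussian mixture to the window densities by EM.

    One quantile-split initialisation plus ``n_restarts - 1`` random restarts;
    the best-log-likelihood fit is returned with components sorted by mean.
    """
    x = track.all_densities() if isinstance(track, DensityTrack) else np.asarray(track, float)
    if len(x) < 2 * k:
        raise SegmentationError(f"need at least {2*k} windows to fit {k} components")
    if not np.isfinite(x).all():
        raise SegmentationError("densities must be finite")
    if np.ptp(x) == 0:
        raise SegmentationError(
            "all densities identical: single-regime data, mixture not identifiable")

    rng = np.random.default_rng(seed)
    inits = []
    # quantile split: k equal-mass groups
    xs = np.sort(x)
    groups = np.array_split(xs, k)
    inits.append((np.array([len(g) / len(x) for g in groups]),
                  np.array([g.mean() for g in groups]),
                  np.maximum(np.array([g.std() for g in groups]), SD_FLOOR)))
    lo, hi = x.min(), x.max()
    for _ in range(max(0, n_restarts - 1)):
        mu = np.sort(rng.uniform(lo, hi, size=k))
        inits.append((np.full(k, 1.0 / k), mu,
                      np.full(k, max(x.std(), SD_FLOOR))))

    best = None
    for w0, mu0, sd0 in inits:
        w, mu, sd, ll, it, conv = _em_once(x, w0.copy(), mu0.copy(), sd0.copy(),
                                           tol, max_iter)
        if best is None or ll > best[3]:
            best = (w, mu, sd, ll, it, conv)
    w, mu, sd, ll, it, conv = best
    order = np.argsort(mu)
    return MixtureFit(weights=w[order] / w[order].sum(), means=mu[order],
                      sds=np.maximum(sd[order], SD_FLOOR), log_likelihood=ll,
                      n_iterations=it, converged=conv, seed=seed)


# ---------------------------------------------------------------------------
# two-state Gaussian HMM (scaled forward-backward, Baum-Welch, Viterbi)

def _emission_logp(x: np.ndarray, model_means: np.ndarray, model_sds: np.ndarray) -> np.ndarray:
    return _normal_logpdf(x, model_means, model_sds)   # (T, 2)


def _forward_backward(logb: np.ndarray, initial: np.ndarray, trans: np.ndarray):
    """Scaled forward-backward. Returns (loglik, gamma, xi_sum)."""
    T, K = logb.shape
    b = np.exp(logb - logb.max(axis=1, keepdims=True))
    bscale = logb.max(axis=1)
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = initial * b[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * b[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    loglik = float(np.log(c).sum() + bscale.sum())
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (trans @ (b[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    # xi summed over t: sum_t alpha_t(i) a_ij b_{t+1}(j) beta_{t+1}(j) / c_{t+1}
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        xi = (alpha[t][:, None] * trans) * (b[t + 1] * beta[t + 1])[None, :] / c[t + 1]
        xi_sum += xi
    return loglik, gamma, xi_sum


def forward_loglik(model: HmmModel, obs: np.ndarray) -> float:
    """Exact log-likelihood of one observation sequence under the model."""
    logb = _emission_logp(np.asarray(obs, float), model.means, model.sds)
    ll, _, _ = _forward_backward(logb, model.initial, model.transitions)
    return ll


def fit_hmm(track: DensityTrack | list[np.ndarray], init: MixtureFit,
            tol: float = 1e-6, max_iter: int = 500,
            self_transition_init: float = 0.99) -> HmmModel:
    """Baum–Welch fit of the two-state Gaussian HMM.

    Scaffold sequences are treated as independent realisations of one
    genome-wide model.  Emissions start from the mixture fit; transitions
    start self-biased because long genomic blocks are the object of
    inference; initial state probabilities start at the mixture weights.
    """
    if len(init.means) != 2:
        raise SegmentationError("HMM initialisation requires a 2-component mixture")
    seqs = (track.sequences() if isinstance(track, DensityTrack)
            else [np.asarray(s, float) for s in track])
    seqs = [s for s in seqs if len(s) > 0]
    if not seqs or all(len(s) < 2 for s in seqs):
        raise SegmentationError("need at least one scaffold with >= 2 windows")

    initial = init.weights.copy()
    p = self_transition_init
    trans = np.array([[p, 1 - p], [1 - p, p]])
    means = init.means.copy()
    sds = np.maximum(init.sds.copy(), SD_FLOOR)

    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        tot_ll = 0.0
        g0 = np.zeros(2)
        xi_tot = np.zeros((2, 2))
        g_sum = np.zeros(2)
        gx_sum = np.zeros(2)
        gxx_sum = np.zeros(2)
        for s in seqs:
            logb = _emission_logp(s, means, sds)
            ll, gamma, xi = _forward_backward(logb, initial, trans)
            tot_ll += ll
            g0 += gamma[0]
            xi_tot += xi
            g_sum += gamma.sum(axis=0)
            gx_sum += gamma.T @ s
            gxx_sum += gamma.T @ (s ** 2)
        initial = g0 / g0.sum()
        trans = xi_tot / np.maximum(xi_tot.sum(axis=1, keepdims=True), 1e-300)
        means = gx_sum / np.maximum(g_sum, 1e-300)
        var = gxx_sum / np.maximum(g_sum, 1e-300) - means ** 2
        sds = np.sqrt(np.maximum(var, SD_FLOOR**2))
        if tot_ll - prev_ll < tol and it > 1:
            converged = True
            prev_ll = tot_ll
            break
        prev_ll = tot_ll

    if means[0] > means[1]:  # relabel so state 0 = lower mean ("L")
        perm = np.array([1, 0])
        initial = initial[perm]
        trans = trans[perm][:, perm]
        means = means[perm]
        sds = sds[perm]
    return HmmModel(initial=initial, transitions=trans, means=means, sds=sds,
                    log_likelihood=prev_ll, n_iterations=it, converged=converged)


def viterbi_path(model: HmmModel, obs: np.ndarray) -> np.ndarray:
    """Maximum-probability state path; ties broken toward state 0 (L)."""
    obs = np.asarray(obs, float)
    logb = _emission_logp(obs, model.means, model.sds)
    logA = np.log(np.maximum(model.transitions, 1e-300))
    T = len(obs)
    delta = np.log(np.maximum(model.initial, 1e-300)) + logb[0]
    back = np.zeros((T, 2), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, None] + logA          # cand[i, j]
        # argmax over i with ties to the lower state index
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], [0, 1]] + logb[t]
    path = np.empty(T, dtype=np.int8)
    path[-1] = int(np.argmax(delta))          # np.argmax prefers lower index on ties
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def viterbi_decode(model: HmmModel, track: DensityTrack) -> StateSegments:
    """Decode each scaffold and merge same-state step intervals into segments."""
    if track.n_windows == 0:
        raise SegmentationError("empty density track")
    segs = StateSegments()
    for scf in sorted(track.densities):
        dens = track.densities[scf]
        starts = track.starts[scf]
        path = viterbi_path(model, dens)
        segs.window_states[scf] = path
        ivs = []
        run_start = 0
        for i in range(1, len(path) + 1):
            if i == len(path) or path[i] != path[run_start]:
                seg_start = int(starts[run_start])
                if i == len(path):   # final window extends to its window end
                    seg_end = int(starts[i - 1]) + track.window
                else:
                    seg_end = int(starts[i])
                ivs.append([seg_start, seg_end, int(path[run_start])])
                run_start = i
        segs.intervals[scf] = np.array(ivs, dtype=np.int64).reshape(-1, 3)
    return segs


def summarize_segmentation(segments: StateSegments, variants: VariantTable,
                           het_only: bool = False,
                           sample: str | None = None) -> SegmentationSummary:
    """Genome and SNP fractions per state, and mean het density per state.

    SNP fractions count all SNP records by default (``het_only`` restricts to
    heterozygous calls of ``sample``, or of any sample when unspecified).
    Mean het per state always uses heterozygous calls.
    """
    len_L = segments.state_length(0)
    len_H = segments.state_length(1)
    total = len_L + len_H
    if total == 0:
        raise SegmentationError("segments cover no sequence")

    if sample is not None:
        het_mask = variants.sample_genotypes(sample) == HET
    else:
        het_mask = (variants.genotypes == HET).any(axis=1)

    slices = variants.scaffold_slices()
    counts = np.zeros(2, dtype=np.int64)       # SNPs per state
    het_counts = np.zeros(2, dtype=np.int64)
    outside = 0
    for scf, iv in segments.intervals.items():
        sl = slices.get(scf)
        if sl is None:
            continue
        pos0 = variants.pos[sl] - 1
        hmask = het_mask[sl]
        idx = np.searchsorted(iv[:, 0], pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < iv[np.clip(idx, 0, None), 1])
        outside += int((~ok).sum())
        st = iv[idx[ok], 2]
        sel = hmask[ok] if het_only else np.ones(ok.sum(), dtype=bool)
        np.add.at(counts, st[sel], 1)
        np.add.at(het_counts, st[hmask[ok]], 1)
    if outside:
        logger.info("summarize_segmentation: %d SNPs outside all segments", outside)

    n_tot = counts.sum()
    return SegmentationSummary(
        fraction_genome_L=len_L / total,
        fraction_genome_H=len_H / total,
        fraction_snps_L=counts[0] / n_tot if n_tot else 0.0,
        fraction_snps_H=counts[1] / n_tot if n_tot else 0.0,
        mean_het_L=het_counts[0] / (len_L / 1000.0) if len_L else 0.0,
        mean_het_H=het_counts[1] / (len_H / 1000.0) if len_H else 0.0,
        n_snps_outside=outside,
    )
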