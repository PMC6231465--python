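"""Independent brute-force oracles used by the test suite.

Deliberately written as plain loops / exhaustive enumeration so they share no
code path with the vectorised implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata

from milupop.genome_io import HET, MISSING
from milupop.roh import RohParams


def brute_force_roh(pos, g, params: RohParams):
    """Materialise every SNP window explicitly and apply the ROH rules.

    Returns a list of (start, end, n_snps, n_het, n_missing) tuples.
    """
    pos = list(map(int, pos))
    g = list(map(int, g))
    n = len(pos)
    W = params.window_snp

    qualifying = []
    for w in range(0, n - W + 1):
        hets = sum(1 for i in range(w, w + W) if g[i] == HET)
        miss = sum(1 for i in range(w, w + W) if g[i] == MISSING)
        qualifying.append(hets <= params.window_het and miss <= params.window_missing)

    eligible = []
    for i in range(n):
        if g[i] == MISSING:
            eligible.append(False)
            continue
        containing = [w for w in range(0, n - W + 1) if w <= i <= w + W - 1]
        if not containing:
            eligible.append(False)
            continue
        hits = sum(1 for w in containing if qualifying[w])
        eligible.append(hits / len(containing) >= params.window_threshold)

    # maximal runs; missing genotypes are transparent members
    runs = []
    cur = []
    for i in range(n):
        if g[i] == MISSING:
            if cur:
                cur.append(i)
        elif eligible[i]:
            cur.append(i)
        else:
            if cur:
                runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)

    def trim(idx):
        idx = list(idx)
        while idx and not eligible[idx[0]]:
            idx = idx[1:]
        while idx and not eligible[idx[-1]]:
            idx = idx[:-1]
        return idx

    segments = []
    for run in runs:
        run = trim(run)
        if not run:
            continue
        parts = [[run[0]]]
        for a, b in zip(run, run[1:]):
            if pos[b] - pos[a] > params.gap_kb * 1000.0:
                parts.append([b])
            else:
                parts[-1].append(b)
        for part in parts:
            part = trim(part)
            if not part:
                continue
            start, end = pos[part[0]], pos[part[-1]]
            span = end - start
            if len(part) < params.min_snp:
                continue
            if span / 1000.0 < params.min_kb:
                continue
            if span / len(part) > params.density_kb_per_snp * 1000.0:
                continue
            if params.window_kb > 0 and span / 1000.0 < params.window_kb:
                continue
            segments.append((start, end, len(part),
                             sum(1 for i in part if g[i] == HET),
                             sum(1 for i in part if g[i] == MISSING)))
    return segments


def brute_force_signed_rank_sf(diffs) -> float:
    """P(W+ >= observed) by exhaustive sign enumeration with mid-ranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    count = 0
    for signs in itertools.product((1, -1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s > 0)
        if w >= w_obs - 1e-9:
            count += 1
    return count / 2**n


def enumerate_forward_loglik(initial, trans, means, sds, obs) -> float:
    """log P(obs) as an explicit sum over all state paths."""
    obs = np.asarray(obs, float)
    T = len(obs)
    terms = []
    for path in itertools.product((0, 1), repeat=T):
        lp = np.log(initial[path[0]])
        for a, b in zip(path, path[1:]):
            lp += np.log(trans[a, b])
        for t, s in enumerate(path):
            lp += (-0.5 * np.log(2 * np.pi) - np.log(sds[s])
                   - 0.5 * ((obs[t] - means[s]) / sds[s]) ** 2)
        terms.append(lp)
    m = max(terms)
    return m + np.log(sum(np.exp(t - m) for t in terms))


def enumerate_viterbi(initial, trans, means, sds, obs):
    """Best path by exhaustive enumeration; ties to the lexicographically
    smaller path (all-L first)."""
    obs = np.asarray(obs, float)
    T = len(obs)
    best_lp, best_path = -np.inf, None
    for path in itertools.product((0, 1), repeat=T):
        lp = np.log(initial[path[0]])
        for a, b in zip(path, path[1:]):
            lp += np.log(trans[a, b])
        for t, s in enumerate(path):
            lp += (-0.5 * np.log(2 * np.pi) - np.log(sds[s])
                   - 0.5 * ((obs[t] - means[s]) / sds[s]) ** 2)
        if lp > best_lp + 1e-12:
            best_lp, best_path = lp, path
    return np.array(best_path), best_lp


def path_log_prob(model, obs, path) -> float:
    """Log joint probability of one observation sequence and a state path."""
    obs = np.asarray(obs, float)
    lp = np.log(model.initial[path[0]])
    for a, b in zip(path, path[1:]):
        lp += np.log(model.transitions[a, b])
    for t, s in enumerate(path):
        lp += (-0.5 * np.log(2 * np.pi) - np.log(model.sds[s])
               - 0.5 * ((obs[t] - model.means[s]) / model.sds[s]) ** 2)
    return lp


def random_roh_instance(rng: np.random.Generator, n_max: int = 2000):
    """A genotype/position instance mixing ROH-like and diverse stretches."""
    n = int(rng.integers(30, n_max + 1))
    gaps = rng.integers(200, 6000, size=n)
    # occasional huge gap to exercise the gap-split rule
    big = rng.random(n) < 0.002
    gaps = np.where(big, rng.integers(4_000_000, 7_000_000, size=n), gaps)
    pos = np.cumsum(gaps) + 1
    # two-regime genotype process
    g = np.empty(n, dtype=np.int8)
    state = rng.random() < 0.5
    for i in range(n):
        if rng.random() < 0.01:
            state = not state
        if state:   # ROH-like
            probs = [0.96, 0.015, 0.005, 0.02]   # hom_ref, het, hom_alt, missing
        else:
            probs = [0.45, 0.30, 0.17, 0.08]
        g[i] = rng.choice([0, 1, 2, -1], p=probs)
    return pos.astype(np.int64), g


def enumerate_signed_rank_sf_np(diffs) -> float:
    """Same exhaustive sign enumeration, vectorised over the 2**n patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1   # all sign patterns
    w_all = bits @ ranks
    return float((w_all >= w_obs - 1e-9).mean())
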