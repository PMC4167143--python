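"""Sliding-window Monte Carlo randomness test for one sequence pair.

For every window of ``w`` consecutive sites the observed pair score is ranked
against scores of synthetic window pairs, built by drawing ``w`` residues
uniformly with replacement — independently for each sequence — from that
sequence's residues inside the window extended by ``flank`` columns on each
side (a local composition pool).  A window whose observed score strictly
exceeds at least a fraction ``1 - alpha`` of the permutation scores is judged
non-random (+1), otherwise random (-1); ties count against significance, so a
constant window can never be judged non-random.

Each site accumulates the verdict of every window covering it; the sum is
divided by the window size (sites near the alignment edges, covered by fewer
than ``w`` windows, therefore cannot reach +/-1).  The result is a per-site
profile in [-1, +1]: the :class:`PairProfile`.

Randomness is reproducible and order-independent: every (pair, window) gets
its own stream spawned from the master seed and the canonical pair index, so
profiles are identical whether pairs run serially or in parallel, and
``pair_profile(X, Y) == pair_profile(Y, X)`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .msa_io import Alignment, GapMode, InputError
from .scoring import ScoringScheme, ScoreTable


@dataclass(frozen=True)
class WindowParams:
    """Tuning knobs of the sliding-window test.

    window_size
        Width w of the sliding window (default 6); the step is fixed at 1.
    flank
        Columns of neighborhood added on each side of the window when building
        the resampling pools; ``None`` means ``flank = window_size``.
    n_permutations
        Monte Carlo sample size per window (default 100); must be at least
        ``ceil(1/alpha)`` for the significance criterion to be resolvable.
    alpha
        Significance level of the one-sided rank test (default 0.05).
    seed
        Master seed for all random streams.
    edge_normalize_coverage
        Divide edge sites by their actual window coverage instead of w.
    """

    window_size: int = 6
    flank: int | None = None
    n_permutations: int = 100
    alpha: float = 0.05
    seed: int = 0
    edge_normalize_coverage: bool = False

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise InputError("window_size must be >= 1")
        if self.flank is not None and self.flank < 0:
            raise InputError("flank must be >= 0")
        if not 0 < self.alpha < 1:
            raise InputError("alpha must be in (0, 1)")
        if self.n_permutations < math.ceil(1 / self.alpha):
            raise InputError(
                f"n_permutations must be >= ceil(1/alpha) = {math.ceil(1 / self.alpha)}"
            )

    @property
    def effective_flank(self) -> int:
        return self.window_size if self.flank is None else self.flank

    def with_seed(self, seed: int) -> "WindowParams":
        return replace(self, seed=seed)


@dataclass
class PairProfile:
    """Per-site signed similarity profile for one taxon pair; values in [-1, 1]."""

    taxon_pair: tuple[str, str]
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def windows(n_sites: int, window_size: int) -> list[tuple[int, int]]:
    """All half-open site intervals [i, i+w), step 1."""
    if not 1 <= window_size <= n_sites:
        raise InputError(
            f"window size {window_size} must be within [1, {n_sites}]"
        )
    return [(i, i + window_size) for i in range(n_sites - window_size + 1)]


def _window_rng(seed: int, pair_index: tuple[int, int], start: int) -> np.random.Generator:
    i, j = sorted(pair_index)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(i, j, start))
    return np.random.Generator(np.random.PCG64(ss))


def null_scores(
    x: np.ndarray,
    y: np.ndarray,
    window: tuple[int, int],
    params: WindowParams,
    scheme: ScoringScheme,
    gap_mode: GapMode = GapMode.FIFTH_STATE,
    rng: np.random.Generator | None = None,
    gap_penalty: float | None = None,
    table: ScoreTable | None = None,
) -> np.ndarray:
    """Permutation scores for one window of a residue-row pair.

    ``x`` and ``y`` are full residue rows (or pre-encoded integer codes when a
    ``table`` is supplied).  The returned array has length ``n_permutations``.
    """
    if table is None:
        table = ScoreTable(scheme, _infer_alphabet(x), gap_mode, gap_penalty)
        cx, cy = table.encode(np.asarray(x)), table.encode(np.asarray(y))
    else:
        cx, cy = np.asarray(x), np.asarray(y)
    if rng is None:
        rng = _window_rng(params.seed, (0, 1), window[0])
    start, stop = window
    w = stop - start
    f = params.effective_flank
    lo, hi = max(0, start - f), min(len(cx), stop + f)
    ix = rng.integers(lo, hi, size=(params.n_permutations, w))
    iy = rng.integers(lo, hi, size=(params.n_permutations, w))
    return table.table[cx[ix], cy[iy]].sum(axis=1)


def window_verdict(observed: float, nulls: np.ndarray, alpha: float) -> int:
    """+1 if the observed score strictly beats >= (1-alpha) of the permutation
    scores, else -1.  Ties do not count as beating."""
    nulls = np.asarray(nulls)
    if nulls.size == 0:
        raise InputError("empty null sample")
    better = int((observed > nulls).sum())
    return 1 if better >= (1 - alpha) * nulls.size - 1e-12 else -1


def exact_null_distribution(
    x_pool: np.ndarray, y_pool: np.ndarray, window_size: int, table: ScoreTable
) -> tuple[np.ndarray, np.ndarray]:
    """Exact permutation-score distribution by enumeration.

    Window positions are filled independently and identically, so the window
    null is the ``window_size``-fold convolution of the single-position score
    distribution over all equiprobable (x, y) pool draws.  Returns sorted
    unique scores and their probabilities.
    """
    per_site = table.table[np.ix_(np.asarray(x_pool), np.asarray(y_pool))].ravel()
    vals, counts = np.unique(per_site, return_counts=True)
    probs = counts / counts.sum()
    dist: dict[float, float] = {0.0: 1.0}
    for _ in range(window_size):
        nxt: dict[float, float] = {}
        for s, p in dist.items():
            for v, q in zip(vals, probs):
                key = round(s + v, 9)
                nxt[key] = nxt.get(key, 0.0) + p * q
        dist = nxt
    keys = np.array(sorted(dist))
    return keys, np.array([dist[k] for k in keys])


def exact_verdict(observed: float, values: np.ndarray, probs: np.ndarray, alpha: float) -> int:
    """Verdict under the exact null: +1 iff P(null < observed) >= 1 - alpha."""
    p_less = float(probs[values < observed - 1e-9].sum())
    return 1 if p_less >= 1 - alpha - 1e-12 else -1


def _infer_alphabet(x) -> str:
    res = set(np.asarray(x, dtype="U1").tolist())
    return "nucleotide" if res <= set("ACGTUN-?RYSWKMBDHV") else "amino_acid"


def pair_profile(
    alignment: Alignment,
    taxon_x: str,
    taxon_y: str,
    params: WindowParams,
    scheme: ScoringScheme | None = None,
    gap_mode: GapMode = GapMode.FIFTH_STATE,
    gap_penalty: float | None = None,
) -> PairProfile:
    """Full sliding-window profile for one pair of alignment rows."""
    i, j = alignment.index_of(taxon_x), alignment.index_of(taxon_y)
    if i == j:
        raise InputError("cannot profile a taxon against itself")
    a, b = sorted((i, j))
    m = alignment.n_sites
    w = params.window_size
    if w > m:
        raise InputError(f"window size {w} exceeds alignment length {m}")

    if scheme is None:
        scheme = ScoringScheme.for_alphabet(alignment.alphabet)
    table = ScoreTable(scheme, alignment.alphabet, gap_mode, gap_penalty)
    cx = table.encode(alignment.residues[a])
    cy = table.encode(alignment.residues[b])

    site_scores = table.table[cx, cy]
    cumulative = np.concatenate(([0.0], np.cumsum(site_scores)))
    observed = cumulative[w:] - cumulative[:-w]  # one score per window start

    nperm = params.n_permutations
    threshold = (1 - params.alpha) * nperm - 1e-12
    delta = np.zeros(m + 1)
    for start in range(m - w + 1):
        rng = _window_rng(params.seed, (a, b), start)
        nulls = null_scores(
            cx, cy, (start, start + w), params, scheme, gap_mode, rng=rng, table=table
        )
        sign = 1.0 if (observed[start] > nulls).sum() >= threshold else -1.0
        delta[start] += sign
        delta[start + w] -= sign

    sums = np.cumsum(delta[:-1])
    if params.edge_normalize_coverage:
        coverage = np.minimum(
            np.minimum(np.arange(1, m + 1), np.arange(m, 0, -1)),
            min(w, m - w + 1),
        )
        values = sums / coverage
    else:
        values = sums / w
    return PairProfile(taxon_pair=(alignment.taxa[a], alignment.taxa[b]), values=values)
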