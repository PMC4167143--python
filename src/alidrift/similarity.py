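"""Collapse pair profiles into the pairwise similarity matrix.

The similarity score S_XY of a pair is the arithmetic mean of its profile
values over all sites that are not *globally invariant* (columns in which
every taxon carries the identical canonical state — such columns carry no
information about pair-specific randomness and would dilute the score).
Negative S_XY means the pair's similarity is indistinguishable from random.

Degenerate pairs (no variable site at all) are recorded as NaN, never as 0,
and reported via a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .msa_io import Alignment, GapMode, InputError, alphabet_spec
from .scoring import ScoringScheme
from .window_engine import PairProfile, WindowParams, pair_profile

logger = logging.getLogger(__name__)


class DegeneratePairError(ValueError):
    """A pair has no non-invariant site to average over."""


@dataclass
class SimilarityMatrix:
    """Symmetric N x N matrix of pair scores; diagonal fixed at +1 by
    convention (a self-comparison is meaningless under the test and the
    diagonal is excluded from all downstream statistics)."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise InputError("matrix shape does not match taxon list")

    def index_of(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise InputError(f"taxon {taxon!r} not in matrix") from None

    def get(self, x: str, y: str) -> float:
        return float(self.values[self.index_of(x), self.index_of(y)])

    def to_tsv(self, path) -> None:
        """Header row of taxa, one labeled row per taxon, 4 decimals; missing
        entries written as NA."""
        with open(path, "w") as fh:
            fh.write("\t".join([""] + self.taxa) + "\n")
            for taxon, row in zip(self.taxa, self.values):
                cells = ["NA" if np.isnan(v) else f"{v:.4f}" for v in row]
                fh.write("\t".join([taxon] + cells) + "\n")

    def to_phylip(self, path) -> None:
        """Square PHYLIP-style distance-matrix layout."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for taxon, row in zip(self.taxa, self.values):
                cells = ["NA" if np.isnan(v) else f"{v:.4f}" for v in row]
                fh.write("  ".join([f"{taxon:<10}"] + cells) + "\n")


def global_invariant_mask(alignment: Alignment, gap_mode: GapMode) -> np.ndarray:
    """Boolean mask of globally invariant columns.

    A column is invariant iff every taxon's residue class there is canonical
    and all classes are the identical state.  Any neutral residue (ambiguity
    code; gap under AMBIGUOUS mode) makes the column variable.  Under
    FIFTH_STATE an all-gap column is invariant.
    """
    spec = alphabet_spec(alignment.alphabet)
    res = alignment.residues
    canonical = np.isin(res[0], sorted(spec.canonical))
    if gap_mode is GapMode.FIFTH_STATE:
        # '-' and '?' are one state (missing); unify before comparing columns
        res = res.copy()
        res[np.isin(res, sorted(spec.gaps))] = "-"
        canonical |= res[0] == "-"
    same = (res == res[0]).all(axis=0)
    return same & canonical


def pair_similarity(profile: PairProfile, mask: np.ndarray) -> float:
    """Mean profile value over non-invariant sites."""
    mask = np.asarray(mask, dtype=bool)
    if len(profile.values) != len(mask):
        raise InputError("profile and mask lengths differ")
    kept = profile.values[~mask]
    if kept.size == 0:
        raise DegeneratePairError(
            f"pair {profile.taxon_pair}: no non-invariant site to average over"
        )
    return float(kept.mean())


def _one_pair(alignment, tx, ty, params, scheme, gap_mode, gap_penalty, mask):
    prof = pair_profile(alignment, tx, ty, params, scheme, gap_mode, gap_penalty)
    try:
        return pair_similarity(prof, mask)
    except DegeneratePairError:
        logger.warning("degenerate pair (%s, %s): scored as missing", tx, ty)
        return float("nan")


def similarity_matrix(
    alignment: Alignment,
    params: WindowParams,
    scheme: ScoringScheme | None = None,
    gap_mode: GapMode = GapMode.FIFTH_STATE,
    gap_penalty: float | None = None,
    n_jobs: int = 1,
) -> SimilarityMatrix:
    """Profile and score all N(N-1)/2 unordered pairs.

    Each pair draws its random streams from (seed, pair index, window), so the
    result is identical for any ``n_jobs``.
    """
    if scheme is None:
        scheme = ScoringScheme.for_alphabet(alignment.alphabet)
    n = alignment.n_taxa
    mask = global_invariant_mask(alignment, gap_mode)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    worker = delayed(_one_pair)
    results = Parallel(n_jobs=n_jobs)(
        worker(alignment, alignment.taxa[i], alignment.taxa[j],
               params, scheme, gap_mode, gap_penalty, mask)
        for i, j in pairs
    )
    values = np.eye(n)
    for (i, j), s in zip(pairs, results):
        values[i, j] = values[j, i] = s
    return SimilarityMatrix(taxa=list(alignment.taxa), values=values)
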