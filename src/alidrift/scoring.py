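"""Per-site pair scoring: match/mismatch for nucleotides, substitution
matrices (BLOSUM62, PAM250, PAM500) for amino acids.

Neutral residues (ambiguity codes; gaps under AMBIGUOUS mode) score zero
against everything, keeping observed and permuted window scores on the same
scale.  Under FIFTH_STATE coding the gap is an ordinary identity-matchable
state: gap/gap scores as a match, gap/residue as a mismatch (or a dedicated
``gap_penalty`` under matrix scoring, since published matrices carry no gap
row).

The :class:`ScoreTable` is the integer-coded workhorse used by the window
engine: residue rows are encoded once, after which every window score is a
table gather plus a sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .msa_io import GAP_STATE, NEUTRAL, GapMode, alphabet_spec

MATRIX_NAMES = ("BLOSUM62", "PAM250", "PAM500")


class ScoringError(RuntimeError):
    """Internal scoring inconsistency (unknown state, shape mismatch)."""


@dataclass(frozen=True)
class ScoringScheme:
    """Which per-site scoring rule to use.

    kind
        ``"MATCH_MISMATCH"`` (nucleotides) or ``"MATRIX"`` (amino acids).
    matrix_name
        One of BLOSUM62 / PAM250 / PAM500 when kind is MATRIX.
    match_score, mismatch_score
        Values for the match/mismatch rule; also reused as the gap/gap and
        default gap/residue scores under matrix scoring.
    """

    kind: str = "MATCH_MISMATCH"
    matrix_name: str | None = None
    match_score: float = 1.0
    mismatch_score: float = -1.0

    def __post_init__(self) -> None:
        if self.kind not in ("MATCH_MISMATCH", "MATRIX"):
            raise ValueError(f"unknown scoring kind {self.kind!r}")
        if self.kind == "MATRIX":
            if self.matrix_name not in MATRIX_NAMES:
                raise ValueError(
                    f"matrix_name must be one of {MATRIX_NAMES}, got {self.matrix_name!r}"
                )
        elif self.match_score <= self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")

    @staticmethod
    def for_alphabet(alphabet: str, matrix_name: str = "BLOSUM62") -> "ScoringScheme":
        """Default scheme: match/mismatch for nucleotides, BLOSUM62 for proteins."""
        if alphabet == "nucleotide":
            return ScoringScheme()
        return ScoringScheme(kind="MATRIX", matrix_name=matrix_name)


@lru_cache(maxsize=None)
def load_matrix(name: str) -> tuple[tuple[str, ...], np.ndarray]:
    """Return (states, square score array) for a named substitution matrix."""
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    alph = bseq.ProteinSequence.alphabet
    mat = balign.SubstitutionMatrix(alph, alph, name)
    symbols = list(alph.get_symbols())
    canonical = sorted(alphabet_spec("amino_acid").canonical)
    idx = [symbols.index(s) for s in canonical]
    score = mat.score_matrix()[np.ix_(idx, idx)].astype(float)
    if not np.allclose(score, score.T):
        raise ScoringError(f"matrix {name} is not symmetric")
    return tuple(canonical), score


class ScoreTable:
    """Integer-coded per-site scores for one (scheme, alphabet, gap_mode) run.

    Codes 0..S-1 are canonical states (the gap state last, when gaps are a
    fifth state); code S is the neutral bucket whose row and column are zero.
    """

    def __init__(
        self,
        scheme: ScoringScheme,
        alphabet: str,
        gap_mode: GapMode,
        gap_penalty: float | None = None,
    ):
        spec = alphabet_spec(alphabet)
        if scheme.kind == "MATRIX":
            states, core = load_matrix(scheme.matrix_name)
            states = list(states)
        else:
            states = sorted(spec.canonical)
            k = len(states)
            core = np.full((k, k), scheme.mismatch_score, dtype=float)
            np.fill_diagonal(core, scheme.match_score)

        if gap_penalty is None:
            gap_penalty = scheme.mismatch_score
        states.append(GAP_STATE)
        k = len(states)
        table = np.zeros((k + 1, k + 1), dtype=float)
        table[: k - 1, : k - 1] = core
        if scheme.kind == "MATRIX":
            table[k - 1, : k - 1] = gap_penalty
            table[: k - 1, k - 1] = gap_penalty
            table[k - 1, k - 1] = scheme.match_score
        else:
            table[k - 1, : k - 1] = scheme.mismatch_score
            table[: k - 1, k - 1] = scheme.mismatch_score
            table[k - 1, k - 1] = scheme.match_score
        # row/column k (neutral) stays zero
        self.states = states
        self.neutral_code = k
        self.table = table

        lut = np.full(128, k, dtype=np.int64)  # default: neutral
        for code, st in enumerate(states):
            if st != GAP_STATE:
                lut[ord(st)] = code
        gap_code = k - 1 if gap_mode is GapMode.FIFTH_STATE else k
        for g in spec.gaps:
            lut[ord(g)] = gap_code
        self._lut = lut

    def encode(self, row: np.ndarray) -> np.ndarray:
        """Map a row of single-character residues to integer codes."""
        row = np.ascontiguousarray(row, dtype="U1")
        return self._lut[row.view(np.uint32).astype(np.int64) & 0x7F]

    def code_of(self, state) -> int:
        if state is NEUTRAL:
            return self.neutral_code
        try:
            return self.states.index(state)
        except ValueError:
            raise ScoringError(f"unknown state {state!r}") from None


def site_score(a, b, scheme: ScoringScheme, alphabet: str = "nucleotide",
               gap_mode: GapMode = GapMode.FIFTH_STATE,
               gap_penalty: float | None = None) -> float:
    """Score one pair of residue classes (state names or NEUTRAL)."""
    tab = ScoreTable(scheme, alphabet, gap_mode, gap_penalty)
    return float(tab.table[tab.code_of(a), tab.code_of(b)])


def window_score(x, y, scheme: ScoringScheme, alphabet: str = "nucleotide",
                 gap_mode: GapMode = GapMode.FIFTH_STATE,
                 gap_penalty: float | None = None) -> float:
    """Sum of site scores over two equal-length residue runs."""
    xa = np.asarray(list(x) if isinstance(x, str) else x, dtype="U1")
    ya = np.asarray(list(y) if isinstance(y, str) else y, dtype="U1")
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < 1:
        raise ScoringError("residue runs must be equal-length, non-empty 1-D")
    tab = ScoreTable(scheme, alphabet, gap_mode, gap_penalty)
    return float(tab.table[tab.encode(xa), tab.encode(ya)].sum())
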