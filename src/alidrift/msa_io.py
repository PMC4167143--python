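"""Aligned-FASTA input/output, alphabet detection and residue classification.

An :class:`Alignment` is a rectangular grid of single-character states over a
declared alphabet (nucleotide or amino acid).  Residues fall into three
classes: *canonical* states (the 4 nucleotides or 20 amino acids), *ambiguity*
codes (IUPAC nucleotide codes; amino-acid ``X``, ``B``, ``Z``, ``J``), and
*gap* symbols (``-`` and ``?``, the latter treated as missing data).

Gap handling is a run-level switch (:class:`GapMode`): a gap is either a fifth
(resp. twenty-first) character state that can match another gap, or a neutral
symbol that contributes nothing to any score.  Ambiguity codes are neutral in
both modes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class AlignmentShapeError(ValueError):
    """Sequences in the input do not all have the same length."""


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class GapMode(enum.Enum):
    """How gap symbols are scored.

    FIFTH_STATE
        A gap is an ordinary matchable state: gap/gap is a match,
        gap/residue a mismatch.
    AMBIGUOUS
        A gap is neutral and contributes zero wherever it appears
        (the behaviour selected by the ``-N`` command-line flag).
    """

    FIFTH_STATE = "fifth_state"
    AMBIGUOUS = "ambiguous"


#: Sentinel state name for a gap scored as an ordinary character.
GAP_STATE = "GAP"

#: Sentinel for neutral residues (ambiguity codes; gaps under AMBIGUOUS mode).
NEUTRAL = None

_NUC_CANONICAL = frozenset("ACGT")
_NUC_AMBIGUOUS = frozenset("RYSWKMBDHVN")
_AA_CANONICAL = frozenset("ACDEFGHIKLMNPQRSTVWY")
_AA_AMBIGUOUS = frozenset("XBZJ")
_GAP_SYMBOLS = frozenset("-?")


@dataclass(frozen=True)
class AlphabetSpec:
    """Character tables for one alphabet: canonical, ambiguity and gap sets."""

    name: str
    canonical: frozenset[str]
    ambiguous: frozenset[str]
    gaps: frozenset[str] = _GAP_SYMBOLS

    def __post_init__(self) -> None:
        if (self.canonical & self.ambiguous) or (self.canonical & self.gaps) or (
            self.ambiguous & self.gaps
        ):
            raise ValueError("canonical, ambiguity and gap sets must be disjoint")

    @property
    def valid(self) -> frozenset[str]:
        return self.canonical | self.ambiguous | self.gaps


NUCLEOTIDE = AlphabetSpec("nucleotide", _NUC_CANONICAL, _NUC_AMBIGUOUS)
AMINO_ACID = AlphabetSpec("amino_acid", _AA_CANONICAL, _AA_AMBIGUOUS)

_SPECS = {"nucleotide": NUCLEOTIDE, "amino_acid": AMINO_ACID}


def alphabet_spec(name: str) -> AlphabetSpec:
    try:
        return _SPECS[name]
    except KeyError:
        raise InputError(f"unknown alphabet {name!r}") from None


@dataclass
class Alignment:
    """A multiple sequence alignment.

    Attributes
    ----------
    taxa:
        Ordered, unique, non-empty taxon labels (length N).
    residues:
        N x M array of single upper-case characters.
    alphabet:
        ``"nucleotide"`` or ``"amino_acid"``.
    """

    taxa: list[str]
    residues: np.ndarray
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype="U1")
        if self.residues.ndim != 2:
            raise AlignmentShapeError("residue grid must be 2-dimensional")
        n, m = self.residues.shape
        if n < 2:
            raise InputError("an alignment needs at least 2 sequences")
        if m < 1:
            raise InputError("an alignment needs at least 1 site")
        if len(self.taxa) != n:
            raise InputError("number of labels does not match number of rows")
        if any(not t for t in self.taxa):
            raise InputError("empty taxon label")
        if len(set(self.taxa)) != n:
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise InputError(f"duplicate taxon labels: {', '.join(dupes)}")
        spec = alphabet_spec(self.alphabet)
        bad = set(np.unique(self.residues)) - spec.valid
        if bad:
            raise InputError(
                f"residues not valid for {self.alphabet}: {', '.join(sorted(bad))}"
            )

    @property
    def n_taxa(self) -> int:
        return self.residues.shape[0]

    @property
    def n_sites(self) -> int:
        return self.residues.shape[1]

    def index_of(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise InputError(f"taxon {taxon!r} not in alignment") from None

    def row(self, taxon: str) -> np.ndarray:
        return self.residues[self.index_of(taxon)]


def _records_to_alignment(labels: list[str], seqs: list[str], alphabet: str | None) -> Alignment:
    if not labels:
        raise InputError("no sequence records found")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise AlignmentShapeError(
            f"sequences are not aligned: lengths {sorted(lengths)}"
        )
    grid = np.array([list(s.upper()) for s in seqs], dtype="U1")
    if alphabet is None:
        alphabet = _detect_alphabet_grid(grid)
    if alphabet == "nucleotide":
        grid[grid == "U"] = "T"
    return Alignment(taxa=labels, residues=grid, alphabet=alphabet)


def read_fasta(path, alphabet: str | None = None) -> Alignment:
    """Read an aligned FASTA file.

    Labels are taken up to the first whitespace; sequence order is preserved.
    The alphabet is auto-detected unless given explicitly.
    """
    labels, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        seqs.append(str(rec.seq))
    return _records_to_alignment(labels, seqs, alphabet)


def write_fasta(alignment: Alignment, path) -> None:
    """Write the alignment back out as multi-record FASTA."""
    records = [
        SeqRecord(Seq("".join(row)), id=taxon, description="")
        for taxon, row in zip(alignment.taxa, alignment.residues)
    ]
    SeqIO.write(records, str(path), "fasta")


def concatenate(alignments: list[Alignment]) -> Alignment:
    """Concatenate partitions sharing the same taxa into a supermatrix."""
    if not alignments:
        raise InputError("nothing to concatenate")
    first = alignments[0]
    for aln in alignments[1:]:
        if aln.taxa != first.taxa:
            raise InputError("partitions must list identical taxa in the same order")
        if aln.alphabet != first.alphabet:
            raise InputError("partitions must share one alphabet")
    grid = np.concatenate([a.residues for a in alignments], axis=1)
    return Alignment(taxa=list(first.taxa), residues=grid, alphabet=first.alphabet)


def _detect_alphabet_grid(grid: np.ndarray) -> str:
    flat = grid.ravel()
    non_gap = flat[~np.isin(flat, list(_GAP_SYMBOLS))]
    if non_gap.size == 0:
        raise InputError("alignment contains only gaps; cannot detect alphabet")
    nuc_like = _NUC_CANONICAL | _NUC_AMBIGUOUS | {"U"}
    frac_nuc = np.isin(non_gap, list(nuc_like)).mean()
    name = "nucleotide" if frac_nuc >= 0.95 else "amino_acid"
    spec = alphabet_spec(name)
    bad = set(np.unique(non_gap)) - spec.valid - {"U"}
    if bad:
        raise InputError(
            f"residues {', '.join(sorted(bad))} fit neither nucleotide nor amino-acid alphabet"
        )
    return name


def detect_alphabet(alignment: Alignment) -> str:
    """Classify an alignment as nucleotide or amino acid.

    Nucleotide iff at least 95% of non-gap residues are nucleotide states or
    IUPAC nucleotide ambiguity codes; all-gap rows are ignored.
    """
    return _detect_alphabet_grid(alignment.residues)


def residue_class(residue: str, alphabet: str, gap_mode: GapMode):
    """Classify one residue as a canonical state name or ``NEUTRAL`` (None).

    Ambiguity codes are neutral in both gap modes; the gap symbol is the
    matchable state ``"GAP"`` under FIFTH_STATE and neutral under AMBIGUOUS.
    """
    spec = alphabet_spec(alphabet)
    if residue in spec.canonical:
        return residue
    if residue in spec.gaps:
        return GAP_STATE if gap_mode is GapMode.FIFTH_STATE else NEUTRAL
    if residue in spec.ambiguous:
        return NEUTRAL
    raise InputError(f"residue {residue!r} not valid for alphabet {alphabet}")
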