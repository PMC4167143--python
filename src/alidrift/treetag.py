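"""Project the similarity matrix onto a guide tree.

Every terminal branch is tagged with the mean pair score between its taxon
and all other taxa; every internal branch — i.e. every edge of the unrooted
topology that induces a non-trivial bipartition — is tagged with the mean
pair score over all cross-split pairs (within-side pairs are not included).
A branch whose mean score R is negative is flagged *suspicious*: the
similarity carried across that branch is indistinguishable from random, so
high node support there may be inflated (the signature of long-branch
attraction).

Pairwise scores are treated as independent replicates in the mean; no
covariance correction is attempted.  Missing (NaN) matrix entries are
excluded from both the sum and the count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .msa_io import InputError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


class LabelMismatchError(InputError):
    """Tree leaves not present in the similarity matrix."""


@dataclass(frozen=True)
class Bipartition:
    """An unordered tree split: two disjoint, non-empty taxon sets."""

    side_a: frozenset[str]
    side_b: frozenset[str]

    def __post_init__(self) -> None:
        if not self.side_a or not self.side_b:
            raise InputError("both sides of a bipartition must be non-empty")
        if self.side_a & self.side_b:
            raise InputError("bipartition sides must be disjoint")

    def __eq__(self, other) -> bool:
        return {self.side_a, self.side_b} == {other.side_a, other.side_b}

    def __hash__(self) -> int:
        return hash(frozenset((self.side_a, self.side_b)))

    @property
    def smaller_side(self) -> frozenset[str]:
        return min(self.side_a, self.side_b, key=lambda s: (len(s), sorted(s)))


@dataclass
class BranchReport:
    """Score record for one branch; ``suspicious`` is exactly ``score < 0``."""

    branch_id: str
    kind: str  # "terminal" | "internal"
    score: float
    suspicious: bool
    bipartition: Bipartition | None = None


def read_newick(path_or_string, matrix: SimilarityMatrix | None = None) -> dendropy.Tree:
    """Parse a newick tree, optionally checking leaves against matrix taxa."""
    src = str(path_or_string)
    try:
        if "(" in src and ")" in src:  # a newick string, not a path
            tree = dendropy.Tree.get(data=src, schema="newick",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=src, schema="newick",
                                     preserve_underscores=True)
    except Exception as exc:
        raise InputError(f"cannot parse newick input: {exc}") from exc
    if matrix is not None:
        check_labels(tree, matrix)
    return tree


def check_labels(tree: dendropy.Tree, matrix: SimilarityMatrix) -> None:
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = sorted(leaves - set(matrix.taxa))
    if missing:
        raise LabelMismatchError(
            f"tree leaves absent from similarity matrix: {', '.join(missing)}"
        )
    extra = sorted(set(matrix.taxa) - leaves)
    if extra:
        logger.warning("matrix taxa not in tree (ignored): %s", ", ".join(extra))


def terminal_score(matrix: SimilarityMatrix, taxon: str) -> float:
    """Mean pair score between ``taxon`` and every other matrix taxon."""
    i = matrix.index_of(taxon)
    others = np.delete(matrix.values[i], i)
    kept = others[~np.isnan(others)]
    if kept.size == 0:
        raise InputError(f"all pair scores for {taxon!r} are missing")
    return float(kept.mean())


def internal_score(matrix: SimilarityMatrix, bipartition: Bipartition) -> float:
    """Mean pair score over all cross-split pairs of a bipartition."""
    # canonical side order so the summation order (hence floating-point
    # result) is identical for A|B and B|A
    first = bipartition.smaller_side
    second = (bipartition.side_b if first is bipartition.side_a
              else bipartition.side_a)
    ia = [matrix.index_of(t) for t in sorted(first)]
    ib = [matrix.index_of(t) for t in sorted(second)]
    cross = matrix.values[np.ix_(ia, ib)].ravel()
    kept = cross[~np.isnan(cross)]
    if kept.size == 0:
        raise InputError("all cross-split pair scores are missing")
    return float(kept.mean())


def tree_bipartitions(tree: dendropy.Tree, leaves: set[str] | None = None) -> list[Bipartition]:
    """Non-trivial bipartitions of the unrooted topology, each edge once.

    The two edges incident to a root of degree 2 induce the same split and
    are deduplicated.  For a fully bifurcating unrooted N-taxon tree the
    result has N - 3 entries.
    """
    if leaves is None:
        leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    seen: set[Bipartition] = set()
    out: list[Bipartition] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = frozenset(leaves) - side
        if not other or len(side) < 2 or len(other) < 2:
            continue  # trivial split
        bip = Bipartition(side, other)
        if bip not in seen:
            seen.add(bip)
            out.append(bip)
    return out


def tag_tree(
    tree: dendropy.Tree, matrix: SimilarityMatrix
) -> tuple[list[BranchReport], dendropy.Tree]:
    """Score every terminal and internal branch; annotate the tree in place.

    Terminal scores are attached as leaf-node comments, internal scores as
    internal-node labels, so the annotated tree can be written back to newick.
    """
    check_labels(tree, matrix)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    reports: list[BranchReport] = []

    for leaf in tree.leaf_node_iter():
        r = terminal_score(matrix, leaf.taxon.label)
        reports.append(BranchReport(leaf.taxon.label, "terminal", r, r < 0))
        leaf.comments = [f"R={r:.4f}"]

    scored: set[Bipartition] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = frozenset(leaves) - side
        if not other or len(side) < 2 or len(other) < 2:
            continue
        bip = Bipartition(side, other)
        if bip in scored:
            continue
        scored.add(bip)
        r = internal_score(matrix, bip)
        branch_id = "|".join(sorted(bip.smaller_side))
        reports.append(BranchReport(branch_id, "internal", r, r < 0, bip))
        node.label = f"{r:.4f}"

    return reports, tree


def reports_to_tsv(reports: list[BranchReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("branch\tkind\tscore\tsuspicious\n")
        for rep in reports:
            fh.write(
                f"{rep.branch_id}\t{rep.kind}\t{rep.score:.4f}\t"
                f"{'yes' if rep.suspicious else 'no'}\n"
            )


def write_annotated_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               suppress_item_comments=False, unquoted_underscores=True)
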