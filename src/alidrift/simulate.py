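"""Synthetic alignment generator for tests and benchmarks.

Sequences evolve along a tree under a symmetric equal-exchange model (the
Jukes-Cantor model for nucleotides; its 20-state analogue for amino acids)
with among-site rate variation: a site is invariant with probability
``prop_invariant`` and otherwise carries a continuous Gamma(alpha) rate
multiplier with mean 1.  Optional indels place insertion and deletion events
along each branch at given per-site rates with lengths uniform on
{1..max_length}; the output is padded to a true alignment, so the column
homology is known by construction.

Two benchmark tree presets are provided.  ``setup_a`` is a 4-taxon
Felsenstein-zone quartet: two long terminal branches (length BL2) attached on
opposite sides of a short internal branch (BL1), with short terminal branches
BL3 and RB on the other two taxa.  ``setup_b`` is a 6-taxon tree in which two
long *internal* branches (BL2), separated by a short internal branch (BL1),
each subtend a short-branched taxon (L1, L2; terminal length BL3) whose
sister and remaining taxa (RB1-RB4) sit on short branches of length RB.
Elongating BL2 drives the affected sequences toward saturation, the regime in
which spurious long-branch attraction arises.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .msa_io import Alignment, InputError

_NUC_STATES = np.array(list("ACGT"))
_AA_STATES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class IndelModel:
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    max_length: int = 20

    def __post_init__(self) -> None:
        if self.insertion_rate < 0 or self.deletion_rate < 0:
            raise InputError("indel rates must be >= 0")
        if self.max_length < 1:
            raise InputError("max indel length must be >= 1")


@dataclass(frozen=True)
class SimModel:
    """Substitution + rate-heterogeneity model for the simulator.

    Defaults match the benchmark conditions used throughout the test suite:
    Gamma shape 1.0 and 30% invariant sites.
    """

    alphabet: str = "nucleotide"
    gamma_shape: float = 1.0
    prop_invariant: float = 0.3
    indels: IndelModel | None = None

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0:
            raise InputError("gamma shape must be > 0")
        if not 0 <= self.prop_invariant < 1:
            raise InputError("prop_invariant must be in [0, 1)")
        if self.alphabet not in ("nucleotide", "amino_acid"):
            raise InputError(f"unknown alphabet {self.alphabet!r}")

    @property
    def states(self) -> np.ndarray:
        return _NUC_STATES if self.alphabet == "nucleotide" else _AA_STATES


def setup_a(bl2: float, bl1: float = 0.01, bl3: float = 0.1, rb: float = 0.1) -> str:
    """4-taxon quartet with two long, unrelated terminal branches (L1, L2)."""
    return f"((L1:{bl2},S1:{bl3}):{bl1},L2:{bl2},S2:{rb});"


def setup_b(bl2: float, bl1: float = 0.01, bl3: float = 0.01, rb: float = 0.1) -> str:
    """6-taxon tree with two long internal branches separated by a short one."""
    return (
        f"(((L1:{bl3},RB1:{rb}):{bl2},RB2:{rb}):{bl1},"
        f"((L2:{bl3},RB3:{rb}):{bl2},RB4:{rb}));"
    )


def _site_rates(model: SimModel, n: int, rng: np.random.Generator) -> np.ndarray:
    rates = rng.gamma(model.gamma_shape, 1.0 / model.gamma_shape, size=n)
    invariant = rng.random(n) < model.prop_invariant
    rates[invariant] = 0.0
    return rates


def _evolve_branch(states: np.ndarray, rates: np.ndarray, t: float,
                   k: int, rng: np.random.Generator) -> np.ndarray:
    """Symmetric k-state substitution over branch length t (per-site rates)."""
    if t <= 0 or states.size == 0:
        return states.copy()
    d = t * rates
    p_stay = 1.0 / k + (k - 1.0) / k * np.exp(-k / (k - 1.0) * d)
    change = rng.random(states.size) > p_stay
    out = states.copy()
    n_changed = int(change.sum())
    if n_changed:
        out[change] = (out[change] + rng.integers(1, k, size=n_changed)) % k
    return out


def expected_p_diff(distance: float, model: SimModel) -> float:
    """Closed-form expected proportion of differing sites between two
    sequences at the given total path distance, integrated over the
    invariant + Gamma rate mixture (Gamma moment generating function)."""
    k = len(model.states)
    a = model.gamma_shape
    c = k / (k - 1.0)
    mean_exp = (1.0 + c * distance / a) ** (-a)
    return (1.0 - model.prop_invariant) * (k - 1.0) / k * (1.0 - mean_exp)


def simulate_alignment(tree, model: SimModel, length: int, seed: int) -> Alignment:
    """Evolve an alignment along ``tree`` (newick string or dendropy Tree).

    Leaf labels become taxon labels in tree traversal order.  With indels
    enabled, the result is padded with gap characters; otherwise the output
    length equals ``length`` exactly.
    """
    if length < 1:
        raise InputError("length must be >= 1")
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(seed))))
    k = len(model.states)

    root = tree.seed_node
    root_states = rng.integers(0, k, size=length)
    root_rates = _site_rates(model, length, rng)
    root_cols = list(range(length))
    master: list[int] = list(range(length))
    next_col = length

    node_data = {root: (root_states, root_rates, root_cols)}
    leaf_rows: dict[str, dict[int, int]] = {}
    labels: list[str] = []

    for node in tree.preorder_node_iter():
        if node is root:
            pass
        else:
            p_states, p_rates, p_cols = node_data[node.parent_node]
            t = node.edge.length or 0.0
            states = _evolve_branch(p_states, p_rates, t, k, rng)
            rates = p_rates.copy()
            cols = list(p_cols)
            if model.indels is not None and t > 0:
                states, rates, cols, next_col = _apply_indels(
                    states, rates, cols, master, next_col, t, k, model, rng
                )
            node_data[node] = (states, rates, cols)
        if node.is_leaf():
            states, _, cols = node_data[node]
            label = node.taxon.label
            labels.append(label)
            leaf_rows[label] = dict(zip(cols, states.tolist()))

    order = {c: i for i, c in enumerate(master)}
    m = len(master)
    grid = np.full((len(labels), m), "-", dtype="U1")
    state_chars = model.states
    for r, label in enumerate(labels):
        for col, st in leaf_rows[label].items():
            grid[r, order[col]] = state_chars[st]
    return Alignment(taxa=labels, residues=grid, alphabet=model.alphabet)


def _apply_indels(states, rates, cols, master, next_col, t, k, model, rng):
    ind = model.indels
    n = states.size
    n_ins = rng.poisson(ind.insertion_rate * t * n)
    n_del = rng.poisson(ind.deletion_rate * t * n)
    states = list(states)
    rates = list(rates)
    for _ in range(n_ins):
        pos = int(rng.integers(0, len(states) + 1))
        ln = int(rng.integers(1, ind.max_length + 1))
        new_ids = list(range(next_col, next_col + ln))
        next_col += ln
        anchor = master.index(cols[pos - 1]) + 1 if pos > 0 else 0
        master[anchor:anchor] = new_ids
        cols[pos:pos] = new_ids
        states[pos:pos] = list(rng.integers(0, k, size=ln))
        rates[pos:pos] = list(_site_rates(model, ln, rng))
    for _ in range(n_del):
        if not states:
            break
        ln = min(int(rng.integers(1, ind.max_length + 1)), len(states))
        pos = int(rng.integers(0, len(states) - ln + 1))
        del states[pos:pos + ln]
        del rates[pos:pos + ln]
        del cols[pos:pos + ln]
    return np.array(states, dtype=int), np.array(rates), cols, next_col


def setup_grid(
    preset: str,
    bl2_values,
    replicates: int,
    length: int,
    seed: int,
    model: SimModel | None = None,
    **tree_kwargs,
) -> dict[tuple[float, int], Alignment]:
    """Simulate ``replicates`` alignments for each BL2 value of a preset.

    Per-cell seeds are spawned deterministically from the master seed, so the
    grid is reproducible cell by cell.
    """
    builders = {"setup_a": setup_a, "setup_b": setup_b}
    if preset not in builders:
        raise InputError(f"unknown preset {preset!r}")
    model = model or SimModel()
    out: dict[tuple[float, int], Alignment] = {}
    for bi, bl2 in enumerate(bl2_values):
        newick = builders[preset](bl2=bl2, **tree_kwargs)
        for rep in range(replicates):
            cell_seed = int(
                np.random.SeedSequence(int(seed), spawn_key=(bi, rep)).generate_state(1)[0]
                % (2**31)
            )
            out[(float(bl2), rep)] = simulate_alignment(newick, model, length, cell_seed)
    return out
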