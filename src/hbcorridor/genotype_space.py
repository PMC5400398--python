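"""Bi-allelic genotype spaces, forward mutational pathways, and character polarity.

A panel of *n* amino acid sites, each segregating an ancestral and a derived
residue, spans a hypercube of 2**n genotypes.  An evolutionary transition from
the all-ancestral to the all-derived genotype can follow any of the n!
*forward pathways* — orderings in which each substitution is fixed once,
sequentially, with no reversions.  This module builds the hypercube, decodes
the concatenated-residue genotype labels used throughout (e.g. ``GVAI`` →
``SIVV`` for the four-site nightjar hemoglobin panel), enumerates and filters
pathways, and infers which allele is ancestral at a site by Fitch small
parsimony over a species tree.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

#: Hard guard on panel size: pathway enumeration is n! and the hypercube is
#: 2**n, so anything beyond this is almost certainly a caller mistake.
MAX_PANEL_SITES = 12


class GenotypeDecodeError(ValueError):
    """A genotype label letter matches neither allele at its site."""


@dataclass(frozen=True)
class MutationSite:
    """One bi-allelic amino acid site in a panel.

    ``index`` is the 1-based position of the site in panel order; ``label``
    is the field's conventional substitution name (e.g. ``"Gα4S"``) and
    ``chain`` a free-text locus description.
    """

    index: int
    ancestral_aa: str
    derived_aa: str
    label: str = ""
    chain: str = ""

    def __post_init__(self) -> None:
        if self.ancestral_aa == self.derived_aa:
            raise ValueError(
                f"site {self.index}: ancestral and derived residues are both "
                f"{self.ancestral_aa!r}"
            )
        for aa in (self.ancestral_aa, self.derived_aa):
            if len(aa) != 1 or not aa.isalpha():
                raise ValueError(f"site {self.index}: residue {aa!r} is not a single letter")


@dataclass(frozen=True)
class SitePanel:
    """Ordered collection of mutation sites defining the sequence space."""

    sites: tuple[MutationSite, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        n = len(self.sites)
        if not 1 <= n <= MAX_PANEL_SITES:
            raise ValueError(f"panel must have 1..{MAX_PANEL_SITES} sites, got {n}")
        indices = [s.index for s in self.sites]
        if len(set(indices)) != n:
            raise ValueError(f"site indices are not unique: {indices}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def genotype(self, states: Sequence[bool]) -> "Genotype":
        states = tuple(bool(s) for s in states)
        if len(states) != self.n_sites:
            raise ValueError(f"expected {self.n_sites} states, got {len(states)}")
        label = "".join(
            site.derived_aa if st else site.ancestral_aa
            for site, st in zip(self.sites, states)
        )
        return Genotype(states=states, label=label)

    @property
    def ancestral(self) -> "Genotype":
        return self.genotype((False,) * self.n_sites)

    @property
    def derived(self) -> "Genotype":
        return self.genotype((True,) * self.n_sites)


@dataclass(frozen=True)
class Genotype:
    """A point in the hypercube: per-site ancestral/derived states plus label."""

    states: tuple[bool, ...]
    label: str

    @property
    def hamming_from_ancestral(self) -> int:
        return sum(self.states)

    @property
    def derived_sites(self) -> frozenset[int]:
        """0-based positions (panel order) carrying the derived residue."""
        return frozenset(i for i, s in enumerate(self.states) if s)

    def hamming(self, other: "Genotype") -> int:
        return sum(a != b for a, b in zip(self.states, other.states))


def decode_label(label: str, panel: SitePanel) -> Genotype:
    """Decode a concatenated-residue label (e.g. ``"GIAV"``) to a Genotype.

    Each letter is matched against the ancestral and derived residue of the
    site at the same position; a letter matching neither raises
    :class:`GenotypeDecodeError` naming the offending site.
    """
    if len(label) != panel.n_sites:
        raise GenotypeDecodeError(
            f"label {label!r} has {len(label)} letters for a {panel.n_sites}-site panel"
        )
    states = []
    for pos, (letter, site) in enumerate(zip(label, panel.sites), start=1):
        if letter == site.ancestral_aa:
            states.append(False)
        elif letter == site.derived_aa:
            states.append(True)
        else:
            raise GenotypeDecodeError(
                f"letter {letter!r} at site {pos} matches neither "
                f"{site.ancestral_aa!r} (ancestral) nor {site.derived_aa!r} (derived)"
            )
    return panel.genotype(states)


@dataclass(frozen=True)
class HypercubeSpace:
    """The full 2**n genotype set with Hamming-1 adjacency."""

    panel: SitePanel
    genotypes: tuple[Genotype, ...]
    neighbors: Mapping[str, tuple[str, ...]]

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Each Hamming-1 pair once, endpoints sorted lexicographically."""
        out = set()
        for a, nbrs in self.neighbors.items():
            for b in nbrs:
                out.add(tuple(sorted((a, b))))
        return sorted(out)


def build_space(panel: SitePanel) -> HypercubeSpace:
    """Construct all 2**n genotypes and their single-mutation adjacency."""
    n = panel.n_sites
    genotypes = tuple(
        panel.genotype(states) for states in itertools.product((False, True), repeat=n)
    )
    by_states = {g.states: g for g in genotypes}
    neighbors: dict[str, tuple[str, ...]] = {}
    for g in genotypes:
        nbrs = []
        for i in range(n):
            flipped = list(g.states)
            flipped[i] = not flipped[i]
            nbrs.append(by_states[tuple(flipped)].label)
        neighbors[g.label] = tuple(nbrs)
    return HypercubeSpace(panel=panel, genotypes=genotypes, neighbors=neighbors)


@dataclass(frozen=True)
class Pathway:
    """One forward pathway: a fixation order and its genotype sequence.

    ``order`` holds the panel ``MutationSite.index`` values in the order the
    substitutions are fixed; ``genotype_sequence`` runs from the all-ancestral
    genotype to the all-derived one, consecutive entries differing at exactly
    one site (sequential fixation, no reversions).
    """

    order: tuple[int, ...]
    genotype_sequence: tuple[Genotype, ...]

    @property
    def intermediates(self) -> tuple[Genotype, ...]:
        """Genotypes strictly between the ancestral and derived endpoints."""
        return self.genotype_sequence[1:-1]

    @property
    def steps(self) -> list[tuple[Genotype, Genotype]]:
        seq = self.genotype_sequence
        return list(zip(seq[:-1], seq[1:]))


def enumerate_pathways(panel: SitePanel, max_sites: int = MAX_PANEL_SITES) -> list[Pathway]:
    """All n! forward pathways from the all-ancestral to the all-derived genotype."""
    n = panel.n_sites
    if n > max_sites:
        raise ValueError(f"refusing to enumerate {n}! pathways (guard at n={max_sites})")
    positions = list(range(n))
    pathways = []
    for perm in itertools.permutations(positions):
        states = [False] * n
        seq = [panel.genotype(states)]
        for pos in perm:
            states[pos] = True
            seq.append(panel.genotype(states))
        order = tuple(panel.sites[pos].index for pos in perm)
        pathways.append(Pathway(order=order, genotype_sequence=tuple(seq)))
    return pathways


def pathways_through(
    panel: SitePanel,
    flagged: Iterable[str],
    pathways: Sequence[Pathway] | None = None,
) -> tuple[int, list[Pathway]]:
    """Count (and return) forward pathways with ≥1 *intermediate* in ``flagged``.

    Endpoints never count as intermediates; flagging an endpoint label is an
    error because the question is about intermediate steps only.
    """
    flagged_genotypes = {decode_label(lbl, panel) for lbl in flagged}
    endpoints = {panel.ancestral, panel.derived}
    bad = flagged_genotypes & endpoints
    if bad:
        raise ValueError(
            "endpoint genotypes cannot be flagged as intermediates: "
            + ", ".join(sorted(g.label for g in bad))
        )
    if pathways is None:
        pathways = enumerate_pathways(panel)
    flagged_labels = {g.label for g in flagged_genotypes}
    hits = [
        p for p in pathways if any(g.label in flagged_labels for g in p.intermediates)
    ]
    return len(hits), hits


def count_pathways_through_ie(panel: SitePanel, flagged: Iterable[str]) -> int:
    """Inclusion–exclusion count of pathways with a flagged intermediate.

    Independent of direct enumeration: a pathway visits a fixed set of
    genotypes G1 ⊂ G2 ⊂ … ⊂ Gk (as derived-site sets) iff they form a chain,
    and the number of orderings visiting all of them is the product of
    factorials of the gap sizes.  Signs alternate over subsets of the flagged
    set.  Used as a cross-check against :func:`pathways_through`.
    """
    n = panel.n_sites
    flagged_sets = []
    endpoints = {frozenset(), frozenset(range(n))}
    for lbl in flagged:
        ds = decode_label(lbl, panel).derived_sites
        if ds in endpoints:
            raise ValueError(f"endpoint genotype {lbl!r} cannot be flagged")
        flagged_sets.append(ds)
    total = 0
    for k in range(1, len(flagged_sets) + 1):
        for combo in itertools.combinations(flagged_sets, k):
            chain = sorted(combo, key=len)
            ok = all(a < b for a, b in zip(chain, chain[1:]))  # strict inclusion
            if not ok:
                continue
            sizes = [len(chain[0])]
            sizes += [len(b) - len(a) for a, b in zip(chain, chain[1:])]
            sizes.append(n - len(chain[-1]))
            ways = math.prod(math.factorial(s) for s in sizes)
            total += (-1) ** (k + 1) * ways
    return total


@dataclass(frozen=True)
class PolarityCall:
    """Result of parsimony polarity inference at one site."""

    site_label: str
    ancestral_residue: str
    derived_residue: str
    min_changes: int
    ambiguous: bool
    root_states: frozenset[str] = field(default_factory=frozenset)


def _as_tree(tree: "dendropy.Tree | str | Path") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    try:
        if isinstance(tree, Path) or (isinstance(tree, str) and "(" not in tree):
            return dendropy.Tree.get(
                path=str(tree), schema="newick", preserve_underscores=True
            )
        return dendropy.Tree.get(
            data=str(tree), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"could not parse newick tree: {exc}") from exc


def infer_polarity_fitch(
    tree: "dendropy.Tree | str | Path",
    states: Mapping[str, str],
    focal_taxon: str,
    site_label: str = "",
) -> PolarityCall:
    """Infer character polarity at one site by Fitch small parsimony.

    ``states`` maps every leaf label of ``tree`` to its residue at the site.
    The minimal change count comes from the Fitch down-pass (multifurcations
    are folded pairwise left-to-right, which is exact on binary trees); the
    ancestral residue is the state reconstructed at the root, with
    ``ambiguous=True`` when several root states tie (the lexicographically
    first is then reported).  The derived residue is the focal taxon's.
    """
    t = _as_tree(tree)
    leaves = t.leaf_nodes()
    if len(leaves) < 3:
        raise ValueError(f"need ≥3 taxa for polarity inference, got {len(leaves)}")
    leaf_labels = [lf.taxon.label for lf in leaves]
    missing = [lbl for lbl in leaf_labels if lbl not in states]
    if missing:
        raise KeyError(f"taxa missing from the state table: {missing}")
    if focal_taxon not in states:
        raise KeyError(f"focal taxon {focal_taxon!r} missing from the state table")

    changes = 0
    node_sets: dict[int, frozenset[str]] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            node_sets[id(node)] = frozenset({states[node.taxon.label]})
            continue
        children = node.child_nodes()
        acc = node_sets[id(children[0])]
        for child in children[1:]:
            cset = node_sets[id(child)]
            inter = acc & cset
            if inter:
                acc = inter
            else:
                acc = acc | cset
                changes += 1
        node_sets[id(node)] = acc

    root_states = node_sets[id(t.seed_node)]
    ancestral = min(root_states)
    return PolarityCall(
        site_label=site_label,
        ancestral_residue=ancestral,
        derived_residue=states[focal_taxon],
        min_changes=changes,
        ambiguous=len(root_states) > 1,
        root_states=frozenset(root_states),
    )
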