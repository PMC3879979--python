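"""Parsimony mapping of amino acid changes onto the focal-strain tree.

Change counts per alignment column are minimum substitution counts under
small parsimony (unit cost, any residue to any residue) on a user-supplied
rooted tree.  The minimum is computed by dynamic programming over candidate
states (exact on arbitrary rooted trees, including polytomies); the full
set of most-parsimonious reconstructions (MPRs) is recovered by exhaustive
enumeration over internal-node assignments, which is cheap for the handful
of focal strains this analysis targets.  Downstream code needs every MPR,
not just one, because a parallel/convergent call can hinge on which
reconstruction is chosen.

Residues ``X`` (and ``-`` where focal gaps are allowed through) are treated
as missing: such leaves are unconstrained and contribute no change events.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .alignment_io import GAP, MISSING, GeneAlignment, Phylogeny

__all__ = [
    "ChangeEvent",
    "SiteReconstruction",
    "fitch_min_changes",
    "enumerate_mprs",
    "map_gene_changes",
]

#: residues treated as unconstrained leaves
MISSING_STATES = frozenset({MISSING, GAP, None, ""})

#: fall back to sampled (not exhaustive) MPR enumeration above this many
#: distinct observed states at one site; unreachable with <= 6 focal strains
MAX_EXACT_STATES = 6

_SAMPLED_ASSIGNMENTS = 20_000


@dataclass(frozen=True, order=True)
class ChangeEvent:
    """One amino acid substitution on one branch at one site."""

    site: int
    branch: str
    from_aa: str
    to_aa: str

    def __post_init__(self) -> None:
        if self.from_aa == self.to_aa:
            raise ValueError("change event requires from_aa != to_aa")


@dataclass(frozen=True)
class SiteReconstruction:
    """Per-site parsimony result.

    ``mprs`` holds every distinct most-parsimonious event list (as sorted
    tuples of :class:`ChangeEvent`); each has length ``min_changes``.
    ``defined`` is False for all-missing columns, which carry no information
    and are excluded from change counts.
    """

    site: int
    min_changes: int
    mprs: tuple[tuple[ChangeEvent, ...], ...]
    defined: bool = True


def _clean_states(states: Mapping[str, str | None]) -> dict[str, str | None]:
    return {
        leaf: (None if s in MISSING_STATES else s) for leaf, s in states.items()
    }


def fitch_min_changes(states: Mapping[str, str | None], tree: Phylogeny) -> int:
    """Minimum number of substitutions explaining the leaf states.

    ``states`` maps leaf name to residue; missing-data leaves (``X``,
    ``-``, ``None``) are unconstrained.  Exact on any rooted tree via
    unit-cost dynamic programming restricted to observed states — a
    restriction that provably contains a parsimony optimum.
    """
    states = _clean_states(states)
    observed = sorted({s for s in states.values() if s is not None})
    if not observed:
        raise ValueError("all leaf states missing: site undefined")
    if len(observed) == 1:
        return 0
    k = len(observed)
    index = {s: i for i, s in enumerate(observed)}
    INF = float("inf")
    cost: dict[int, list[float]] = {}
    for node in tree.postorder():
        if not tree.children[node]:
            s = states.get(tree.name[node])
            if s is None:
                cost[node] = [0.0] * k
            else:
                c = [INF] * k
                c[index[s]] = 0.0
                cost[node] = c
        else:
            c = [0.0] * k
            for child in tree.children[node]:
                cc = cost[child]
                best = min(cc)
                for i in range(k):
                    c[i] += min(cc[i], best + 1.0)
            cost[node] = c
    return int(min(cost[tree.root]))


def _assignment_events(
    tree: Phylogeny,
    node_state: list[str | None],
    site: int,
) -> tuple[ChangeEvent, ...]:
    """Events implied by a full node-state assignment, in preorder.

    Missing leaves inherit the parent state and contribute nothing.
    """
    events = []
    for node in tree.preorder():
        parent = tree.parent[node]
        if parent == -1:
            continue
        s = node_state[node]
        if s is None:  # missing leaf: free ride on the parent
            continue
        ps = node_state[parent]
        if s != ps:
            events.append(ChangeEvent(site, tree.name[node], ps, s))
    return tuple(events)


def enumerate_mprs(
    states: Mapping[str, str | None],
    tree: Phylogeny,
    site: int = 0,
    rng: np.random.Generator | None = None,
) -> SiteReconstruction:
    """All most-parsimonious reconstructions for one column.

    Enumerates internal-node assignments over the observed states and keeps
    every assignment reaching the parsimony minimum, deduplicated to
    distinct event lists.  Above :data:`MAX_EXACT_STATES` observed states
    the enumeration switches to seeded random sampling with a warning —
    never triggered on a five-strain alignment.
    """
    states = _clean_states(states)
    observed = sorted({s for s in states.values() if s is not None})
    if not observed:
        return SiteReconstruction(site, 0, (), defined=False)

    leaf_state = {tree.name[i]: states.get(tree.name[i]) for i in tree.leaves}
    internal = tree.internal_nodes
    node_state: list[str | None] = [None] * tree.n_nodes
    for i in tree.leaves:
        node_state[i] = leaf_state[tree.name[i]]

    if len(observed) == 1:
        for i in internal:
            node_state[i] = observed[0]
        return SiteReconstruction(site, 0, ((),))

    if len(observed) > MAX_EXACT_STATES:
        warnings.warn(
            f"site {site}: {len(observed)} observed states exceeds exact "
            f"enumeration bound; sampling {_SAMPLED_ASSIGNMENTS} assignments",
            RuntimeWarning,
            stacklevel=2,
        )
        rng = rng or np.random.default_rng(0)
        combos: list[tuple[str, ...]] = [
            tuple(rng.choice(observed, size=len(internal)))
            for _ in range(_SAMPLED_ASSIGNMENTS)
        ]
    else:
        combos = list(itertools.product(observed, repeat=len(internal)))

    best = None
    best_events: set[tuple[ChangeEvent, ...]] = set()
    for combo in combos:
        for i, s in zip(internal, combo):
            node_state[i] = s
        events = _assignment_events(tree, node_state, site)
        n = len(events)
        if best is None or n < best:
            best = n
            best_events = {tuple(sorted(events))}
        elif n == best:
            best_events.add(tuple(sorted(events)))
    assert best is not None
    return SiteReconstruction(site, best, tuple(sorted(best_events)))


def map_gene_changes(
    aln: GeneAlignment,
    tree: Phylogeny,
    count_mode: str = "parsimony",
    enumerate_multihit_only: bool = False,
) -> list[SiteReconstruction]:
    """Per-column reconstructions for one gene, focal rows only.

    Outgroup rows never enter the parsimony; they matter only for the
    variable-site rule applied elsewhere.  ``count_mode="distinct"``
    replaces the parsimony count with (number of distinct non-missing focal
    residues − 1) — the naive convention — and reports no MPRs.  With
    ``enumerate_multihit_only`` the (comparatively expensive) MPR
    enumeration is skipped for single-change sites, whose lone-event MPRs
    can never constitute a parallel or convergent pair.
    """
    if count_mode not in ("parsimony", "distinct"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    tree.validate_focal(aln.focal_labels)
    focal = {l: aln.rows[l] for l in aln.focal_labels}
    out: list[SiteReconstruction] = []
    for i in range(aln.length):
        column = {l: s[i] for l, s in focal.items()}
        residues = {r for r in column.values() if r not in MISSING_STATES}
        if not residues:
            out.append(SiteReconstruction(i, 0, (), defined=False))
            continue
        if len(residues) == 1:
            out.append(SiteReconstruction(i, 0, ((),)))
            continue
        if count_mode == "distinct":
            out.append(SiteReconstruction(i, len(residues) - 1, ()))
            continue
        if enumerate_multihit_only:
            n = fitch_min_changes(column, tree)
            if n < 2:
                out.append(SiteReconstruction(i, n, ()))
                continue
        out.append(enumerate_mprs(column, tree, site=i))
    return out
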