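"""Site and gene labels: variable, multihit, parallel, convergent.

A column is *variable* when any of the analysed species (focal strains and
outgroups alike) shows a residue variant; a gap in an outgroup row also
counts as a variant, since it demonstrates the site can change.  A column
that experienced two or more substitutions among the focal strains is a
*multihit* site.  Within a most-parsimonious reconstruction, two
substitutions on branches that are not ancestor and descendant of one
another — independent lineages — that reach the same descendant residue
form a *parallel* pair if they also share the ancestral residue, and a
*convergent* pair otherwise.  Convergent and parallel changes are the
classical low-probability signatures of adaptation; a multihit site as such
is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignment_io import GAP, MISSING, GeneAlignment, Phylogeny
from .substitution_inference import (
    SiteReconstruction,
    map_gene_changes,
)

__all__ = [
    "SiteClass",
    "GeneChangeSummary",
    "is_variable",
    "variable_site_mask",
    "classify_site",
    "classify_gene",
    "summarize_genes",
]

VARIABLE_MODES = ("observed", "all_variable", "interpolated")


@dataclass(frozen=True)
class SiteClass:
    site: int
    variable: bool
    n_changes: int
    label: str  # invariant | single_hit | multihit
    parallel: bool
    convergent: bool


@dataclass(frozen=True)
class GeneChangeSummary:
    """Per-gene inputs to the resampling null and the strand contrast.

    ``V`` is the variable-site count under the chosen mode, ``C`` the total
    focal substitution count, ``multihit_sites`` the number of columns with
    two or more focal substitutions.
    """

    gene_id: str
    strand: str
    L: int
    V: int
    C: int
    multihit_sites: int
    has_parallel: bool
    has_convergent: bool

    def __post_init__(self) -> None:
        if not (0 <= self.V <= self.L):
            raise ValueError(f"{self.gene_id}: V={self.V} outside [0, L={self.L}]")
        if self.C < 2 * self.multihit_sites:
            raise ValueError(
                f"{self.gene_id}: C={self.C} < 2*multihit={2 * self.multihit_sites}"
            )


def is_variable(
    focal_states: Iterable[str],
    outgroup_states: Iterable[str] = (),
    mode: str = "observed",
) -> bool:
    """Variable-site rule for one column.

    observed: more than one distinct non-missing residue across all rows,
    or a gap in any outgroup row.  all_variable: every column counts (the
    sensitivity variant in which all sites are assumed variable).
    """
    if mode == "all_variable":
        return True
    if mode != "observed":
        raise ValueError(f"per-column mode must be observed/all_variable, got {mode!r}")
    residues = set()
    for r in focal_states:
        if r not in (MISSING, GAP):
            residues.add(r)
    for r in outgroup_states:
        if r == GAP:
            return True
        if r != MISSING:
            residues.add(r)
    return len(residues) > 1


def variable_site_mask(
    aln: GeneAlignment,
    mode: str = "observed",
    fraction: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Boolean mask of variable columns for one gene.

    ``interpolated`` mode starts from the observed mask and promotes a
    seeded random draw of invariant columns until ``ceil(fraction * L)``
    are variable — the sweep between the observed rule and the
    all-variable extreme.
    """
    L = aln.length
    focal = [aln.rows[l] for l in aln.focal_labels]
    outgroup = [aln.rows[l] for l in aln.outgroup_labels]
    if mode == "all_variable":
        return np.ones(L, dtype=bool)
    mask = np.fromiter(
        (
            is_variable((r[i] for r in focal), (r[i] for r in outgroup), "observed")
            for i in range(L)
        ),
        dtype=bool,
        count=L,
    )
    if mode == "observed":
        return mask
    if mode != "interpolated":
        raise ValueError(f"unknown variable-site mode {mode!r}")
    if fraction is None:
        raise ValueError("interpolated mode needs a fraction")
    target = math.ceil(fraction * L)
    v = int(mask.sum())
    if not (v <= target <= L):
        raise ValueError(
            f"interpolated fraction {fraction} implies {target} variable sites, "
            f"outside [{v}, {L}]"
        )
    if rng is None:
        rng = np.random.default_rng(0)
    invariant = np.flatnonzero(~mask)
    promote = rng.choice(invariant, size=target - v, replace=False)
    mask = mask.copy()
    mask[promote] = True
    return mask


def _mpr_flags(
    recon: SiteReconstruction, tree: Phylogeny
) -> tuple[list[bool], list[bool]]:
    parallel, convergent = [], []
    for events in recon.mprs:
        p = c = False
        for i in range(len(events)):
            for j in range(i + 1, len(events)):
                a, b = events[i], events[j]
                if a.to_aa != b.to_aa:
                    continue
                if not tree.independent_edges(a.branch, b.branch):
                    continue
                if a.from_aa == b.from_aa:
                    p = True
                else:
                    c = True
        parallel.append(p)
        convergent.append(c)
    return parallel, convergent


def classify_site(
    recon: SiteReconstruction,
    tree: Phylogeny,
    policy: str = "all_mprs",
    variable: bool | None = None,
) -> SiteClass:
    """Label one reconstructed column.

    ``policy="all_mprs"`` (default) flags parallel/convergent only when
    every most-parsimonious reconstruction shows the pattern — the
    conservative reading under reconstruction ambiguity; ``"any_mpr"``
    flags when at least one does.
    """
    if policy not in ("all_mprs", "any_mpr"):
        raise ValueError(f"unknown MPR policy {policy!r}")
    n = recon.min_changes
    label = "invariant" if n == 0 else ("single_hit" if n == 1 else "multihit")
    if n < 2 or not recon.mprs:
        return SiteClass(recon.site, bool(variable) if variable is not None else n > 0,
                         n, label, False, False)
    p_flags, c_flags = _mpr_flags(recon, tree)
    combine = all if policy == "all_mprs" else any
    return SiteClass(
        recon.site,
        bool(variable) if variable is not None else True,
        n,
        label,
        combine(p_flags),
        combine(c_flags),
    )


def classify_gene(
    aln: GeneAlignment,
    tree: Phylogeny,
    variable_mode: str = "observed",
    fraction: float | None = None,
    policy: str = "all_mprs",
    rng: np.random.Generator | None = None,
    count_mode: str = "parsimony",
) -> tuple[list[SiteClass], GeneChangeSummary]:
    """Full per-site classification and summary for one gene."""
    mask = variable_site_mask(aln, variable_mode, fraction, rng)
    recons = map_gene_changes(
        aln, tree, count_mode=count_mode, enumerate_multihit_only=True
    )
    sites = [
        classify_site(r, tree, policy=policy, variable=bool(mask[r.site]))
        for r in recons
        if r.defined
    ]
    C = sum(s.n_changes for s in sites)
    multihit = sum(1 for s in sites if s.n_changes >= 2)
    summary = GeneChangeSummary(
        gene_id=aln.gene_id,
        strand=aln.strand,
        L=aln.length,
        V=int(mask.sum()),
        C=C,
        multihit_sites=multihit,
        has_parallel=any(s.parallel for s in sites),
        has_convergent=any(s.convergent for s in sites),
    )
    return sites, summary


def summarize_genes(
    summaries: Sequence[GeneChangeSummary],
    strand_table: Mapping[str, str] | None = None,
) -> tuple[list[GeneChangeSummary], dict]:
    """Aggregate gene summaries into the strand-by-parallel 2x2 table.

    Returns the (strand-resolved) summaries and a dict holding the counts
    of genes with/without parallel changes on each strand.
    """
    resolved: list[GeneChangeSummary] = []
    for s in summaries:
        strand = s.strand
        if strand_table is not None:
            if s.gene_id not in strand_table:
                raise KeyError(f"gene {s.gene_id!r} missing from strand table")
            strand = strand_table[s.gene_id]
        if strand not in ("leading", "lagging"):
            raise ValueError(f"gene {s.gene_id!r} has unknown strand {strand!r}")
        resolved.append(
            s if strand == s.strand else GeneChangeSummary(
                s.gene_id, strand, s.L, s.V, s.C, s.multihit_sites,
                s.has_parallel, s.has_convergent,
            )
        )
    table = {
        "leading_parallel": sum(
            1 for s in resolved if s.strand == "leading" and s.has_parallel
        ),
        "leading_total": sum(1 for s in resolved if s.strand == "leading"),
        "lagging_parallel": sum(
            1 for s in resolved if s.strand == "lagging" and s.has_parallel
        ),
        "lagging_total": sum(1 for s in resolved if s.strand == "lagging"),
    }
    return resolved, table
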