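"""Composite-tree surgery and richness bookkeeping.

Large grass phylogenies are assembled by calibrating subclade trees
separately, rescaling them to the crown ages of a dated backbone, and
grafting them in place of two-tip placeholder clades.  For genus-level
diversification analyses the assembled tree is then collapsed to one
representative tip per genus (or per state-pure block of a mixed C3/C4
genus) carrying the group's total species richness, with very large genera
(> 190 species by default) split among several representatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import dendropy
import numpy as np
import pandas as pd

from .phylo_core import TimeTree, TipData, TreeError, mrca_and_clade

__all__ = [
    "GraftInstruction",
    "RichnessRule",
    "scale_to_root_age",
    "graft",
    "collapse_to_representatives",
    "validate_assignment",
    "largest_remainder_split",
]


# ---------------------------------------------------------------------- #
# scaling
# ---------------------------------------------------------------------- #
def scale_to_root_age(tree: TimeTree, target_root_age: float) -> TimeTree:
    """Rescale every branch length by ``target / current root age``.

    Topology and all ratios of node ages are preserved; the returned tree's
    root age equals the target exactly.
    """
    if target_root_age <= 0:
        raise ValueError("target root age must be > 0")
    cur = tree.root_age
    if cur <= 0:
        raise TreeError("cannot scale a tree with zero root age")
    ratio = target_root_age / cur
    out = tree.copy()
    for edge in out.tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= ratio
    return out.refresh()


# ---------------------------------------------------------------------- #
# grafting
# ---------------------------------------------------------------------- #
@dataclass
class GraftInstruction:
    """Replace a two-tip placeholder clade with a calibrated subtree.

    ``placeholders`` are two tip labels that form a monophyletic pair in
    the backbone; the subtree is rescaled to ``target_crown_age`` and hung
    from the placeholder clade's stem.
    """

    placeholders: tuple[str, str]
    subtree: TimeTree
    target_crown_age: float


def graft(backbone: TimeTree, instruction: GraftInstruction) -> TimeTree:
    """Graft a rescaled subtree in place of its placeholder pair.

    The attachment stem (the branch subtending the placeholder clade) is
    kept; its length becomes ``stem_age - target_crown_age`` so the output
    stays ultrametric and all backbone node ages outside the replaced clade
    are untouched.
    """
    a, b = instruction.placeholders
    out = backbone.copy()
    info = mrca_and_clade(out, [a, b])
    clade_tips = [lf for lf in info.mrca.leaf_iter()]
    if len(clade_tips) != 2:
        raise TreeError(
            f"placeholder pair ({a}, {b}) is not monophyletic: its MRCA spans "
            f"{len(clade_tips)} tips"
        )
    if info.stem_age is None:
        raise TreeError("cannot graft at the root")
    crown = instruction.target_crown_age
    if crown >= info.stem_age:
        raise TreeError(
            f"target crown age {crown} must be younger than the attachment "
            f"stem age {info.stem_age}"
        )
    sub = scale_to_root_age(instruction.subtree, crown)
    parent = info.mrca.parent_node
    parent.remove_child(info.mrca)
    new_root = sub.tree.seed_node
    parent.add_child(new_root)
    new_root.edge.length = info.stem_age - crown
    # merge taxa into one namespace
    out.tree.migrate_taxon_namespace(dendropy.TaxonNamespace())
    out.tree.update_taxon_namespace()
    return out.refresh()


# ---------------------------------------------------------------------- #
# genus collapsing
# ---------------------------------------------------------------------- #
@dataclass
class RichnessRule:
    """Rules for allocating known genus richness onto representative tips.

    ``genus_sizes`` maps genus name to its accepted species count.
    Genera above ``split_threshold`` species are divided among several
    representatives (largest-remainder even split).  Genera listed in
    ``spread_genera`` (polyphyletic, e.g. Panicum) have their total spread
    equally among all their sampled tips before state-pure blocks are
    collapsed.  ``state_counts`` optionally gives (n_C3, n_C4) species
    counts for mixed genera; otherwise a mixed genus's total is split
    between blocks in proportion to sampled tip counts.
    """

    genus_sizes: dict[str, int]
    split_threshold: int = 190
    representative_policy: Callable[[list[str]], str] = field(
        default=lambda labels: min(labels)
    )
    spread_genera: tuple[str, ...] = ()
    state_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    genus_of: Callable[[str], str] = field(
        default=lambda label: label.split("_", 1)[0]
    )

    def __post_init__(self) -> None:
        if self.split_threshold <= 0:
            raise ValueError("split threshold must be > 0")
        for g, n in self.genus_sizes.items():
            if n < 1:
                raise ValueError(f"genus {g} has size {n} < 1")


def largest_remainder_split(total: int, k: int) -> list[int]:
    """Divide ``total`` into ``k`` near-equal integers summing exactly.

    Shares differ by at most one, with the larger shares first
    (550 into 3 -> [184, 183, 183]).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    base, rem = divmod(total, k)
    return [base + 1] * rem + [base] * (k - rem)


def _state_blocks(tree: TimeTree, labels: list[str], states: dict[str, Optional[int]]):
    """Partition a genus's tips into the minimum number of state-pure clades.

    Post-order pass over the tree restricted to the genus's tips: a block is
    a maximal node all of whose genus tips share a state.  Unknown-state
    tips join either block.
    """
    label_set = set(labels)
    # node -> (set of states seen, genus tips below)
    info: dict[int, tuple[set, list[str]]] = {}
    blocks: list[tuple[Optional[int], list[str]]] = []
    root = tree.root
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            lab = TimeTree._label(nd)
            if lab in label_set:
                s = states.get(lab)
                info[id(nd)] = ({s} if s is not None else set(), [lab])
            continue
        seen: set = set()
        labs: list[str] = []
        kid_infos = []
        for c in nd.child_nodes():
            if id(c) in info:
                kid_infos.append((c, info[id(c)]))
                seen |= info[id(c)][0]
                labs += info[id(c)][1]
        if not labs:
            continue
        pure = len(seen) <= 1
        # a node containing foreign tips cannot head a genus block
        n_below = sum(1 for lf in nd.leaf_iter() if TimeTree._label(lf) in label_set)
        contiguous = n_below == len(labs) and n_below == sum(
            1 for _ in nd.leaf_iter()
        )
        if pure and contiguous and nd is not root:
            info[id(nd)] = (seen, labs)
        else:
            # children become blocks
            for c, (cs, cl) in kid_infos:
                blocks.append((next(iter(cs)) if cs else None, cl))
            if nd is root and pure and contiguous:
                # whole tree is the genus; single block
                blocks = [(next(iter(seen)) if seen else None, labs)]
    # any genus tips left hanging directly under an impure node were added
    # above; tips never merged (isolated leaves under root) are in info
    covered = {l for _, ls in blocks for l in ls}
    for key, (cs, cl) in info.items():
        if not set(cl) <= covered and set(cl) & label_set:
            # only keep maximal entries
            if all(not set(cl) < set(other[1]) for other in blocks):
                blocks.append((next(iter(cs)) if cs else None, cl))
                covered |= set(cl)
    # deduplicate nested blocks, keep maximal disjoint cover
    blocks.sort(key=lambda b: -len(b[1]))
    final: list[tuple[Optional[int], list[str]]] = []
    taken: set[str] = set()
    for s, ls in blocks:
        if not set(ls) & taken:
            final.append((s, sorted(ls)))
            taken |= set(ls)
    missing = label_set - taken
    for l in sorted(missing):
        final.append((states.get(l), [l]))
    return final


def collapse_to_representatives(
    tree: TimeTree, tips: TipData, rule: RichnessRule
) -> tuple[TimeTree, TipData]:
    """Collapse a species-level tree to genus representatives with richness.

    Single-state genera keep one representative (``representative_policy``,
    lexicographically first by default) carrying the genus's accepted
    richness; mixed C3/C4 genera are divided into the minimum number of
    state-pure clades, each represented by one tip; genera above the split
    threshold are divided among ``ceil(size / threshold)`` representatives
    by largest-remainder even division.  Richness is conserved exactly.
    """
    states = {
        r.tip_label: (None if pd.isna(r.state) else int(r.state))
        for r in tips.table.itertuples()
    }
    by_genus: dict[str, list[str]] = {}
    for lab in tree.tip_labels:
        by_genus.setdefault(rule.genus_of(lab), []).append(lab)

    keep: dict[str, tuple[Optional[int], int]] = {}  # label -> (state, richness)
    for genus, labels in sorted(by_genus.items()):
        if genus not in rule.genus_sizes:
            raise KeyError(f"richness table missing genus {genus!r}")
        total = rule.genus_sizes[genus]
        gstates = {states.get(l) for l in labels} - {None}
        if genus in rule.spread_genera or len(gstates) > 1:
            blocks = _state_blocks(tree, labels, states)
            if len(gstates) > 1 and any(
                s is None and len(ls) > 1 for s, ls in blocks
            ):
                pass  # unknown-state blocks allowed; richness still allocated
            if genus in rule.state_counts and len(gstates) > 1:
                n0, n1 = rule.state_counts[genus]
                shares = _allocate_by_state(blocks, n0, n1)
            else:
                # spread equally among tips, then sum per block
                per_tip = largest_remainder_split(total, len(labels))
                order = sorted(labels)
                tip_share = dict(zip(order, per_tip))
                shares = [sum(tip_share[l] for l in ls) for _, ls in blocks]
            for (s, ls), share in zip(blocks, shares):
                rep = rule.representative_policy(ls)
                keep[rep] = (s, max(share, 1))
        elif total > rule.split_threshold:
            k = min(int(np.ceil(total / rule.split_threshold)), len(labels))
            shares = largest_remainder_split(total, k)
            # spread representatives across the genus: first k in label order
            reps = sorted(labels)[:k]
            s = next(iter(gstates)) if gstates else None
            for rep, share in zip(reps, shares):
                keep[rep] = (s, share)
        else:
            rep = rule.representative_policy(labels)
            s = next(iter(gstates)) if gstates else None
            keep[rep] = (s, total)

    out = tree.copy()
    keep_set = set(keep)
    drop = [l for l in out.tip_labels if l not in keep_set]
    if drop:
        out.tree.prune_taxa_with_labels([l.replace("_", " ") for l in drop])
        out.tree.prune_taxa_with_labels(drop)
    out.refresh()
    df = pd.DataFrame(
        {
            "tip_label": list(keep),
            "state": pd.array([keep[l][0] for l in keep], dtype="Int64"),
            "richness": [keep[l][1] for l in keep],
        }
    )
    newtips = TipData(df, sampling_mode="unresolved", f=tips.f)
    return out, newtips


def _allocate_by_state(blocks, n0: int, n1: int) -> list[int]:
    shares = [0] * len(blocks)
    for target_state, n in ((0, n0), (1, n1)):
        idx = [i for i, (s, _) in enumerate(blocks) if s == target_state]
        if not idx:
            if n > 0:
                raise TreeError(
                    f"mixed-state genus has {n} species of state {target_state} "
                    "but no state-consistent block"
                )
            continue
        parts = largest_remainder_split(n, len(idx))
        for i, p in zip(idx, parts):
            shares[i] = p
    return shares


# ---------------------------------------------------------------------- #
# validation report
# ---------------------------------------------------------------------- #
@dataclass
class AssignmentReport:
    total_assigned: int
    n_tips: int
    known_total: Optional[int]
    coverage: Optional[float]
    sampling_fraction: float

    def to_dict(self) -> dict:
        return {
            "total_assigned": self.total_assigned,
            "n_tips": self.n_tips,
            "known_total": self.known_total,
            "coverage": self.coverage,
            "sampling_fraction": self.sampling_fraction,
        }


def validate_assignment(
    tips: TipData, known_total: Optional[int] = None
) -> AssignmentReport:
    """Report assigned richness totals and sampling-fraction consistency.

    ``coverage`` is assigned/known (e.g. 11,554 of ~12,100 grass species =
    95.5%); ``sampling_fraction`` is sampled tips / assigned species, the f
    that proportional-mode SSE likelihoods should record.
    """
    total = tips.total_richness
    n = len(tips.table)
    cov = total / known_total if known_total else None
    return AssignmentReport(
        total_assigned=total,
        n_tips=n,
        known_total=known_total,
        coverage=cov,
        sampling_fraction=n / total if total else float("nan"),
    )
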