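"""Tree data model, standard-format I/O, and elementary tree computations.

Trees are rooted, time-calibrated (branch lengths in million years, My) and
ultrametric: every tip sits at age 0 and node ages are measured backward from
the present.  The :class:`TimeTree` class wraps a :class:`dendropy.Tree` and
caches node ages; all downstream analyses (state-dependent birth-death
likelihoods, rate-shift detection, sister contrasts) consume it.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TimeTree",
    "TipData",
    "LttCurve",
    "CladeInfo",
    "read_tree",
    "read_tree_set",
    "write_tree",
    "write_tree_set",
    "ltt_curve",
    "mrca_and_clade",
]

#: relative ultrametricity tolerance: tips may deviate from age zero by
#: this fraction of the root age before a tree is rejected.
TOL_ULTRA_REL = 1e-6


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


class TimeTree:
    """A rooted ultrametric phylogeny with ages in million years.

    Parameters
    ----------
    tree:
        A rooted ``dendropy.Tree``.  Branch lengths are interpreted as
        durations in My.  The tree is kept by reference; callers that need
        an independent copy should pass ``tree.clone(depth=1)``.
    force_ultrametrize:
        If the tip depths differ by more than ``TOL_ULTRA_REL * root_age``,
        adjust terminal branch lengths proportionally so that every tip
        lands exactly at age 0 instead of rejecting the tree.
    """

    def __init__(self, tree: dendropy.Tree, force_ultrametrize: bool = False):
        if tree.seed_node is None:
            raise TreeError("empty tree")
        self._tree = tree
        self._validate_lengths()
        self._compute_ages(force_ultrametrize=force_ultrametrize)
        self._check_labels()

    # ------------------------------------------------------------------ #
    # construction helpers
    # ------------------------------------------------------------------ #
    @classmethod
    def from_newick(cls, newick: str, force_ultrametrize: bool = False) -> "TimeTree":
        try:
            t = dendropy.Tree.get(
                data=newick, schema="newick", rooting="force-rooted"
            )
        except Exception as exc:
            raise TreeError(f"unreadable newick: {exc}") from exc
        return cls(t, force_ultrametrize=force_ultrametrize)

    def copy(self) -> "TimeTree":
        return TimeTree(self._tree.clone(depth=1))

    # ------------------------------------------------------------------ #
    # internal validation
    # ------------------------------------------------------------------ #
    def _validate_lengths(self) -> None:
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
            if edge.length < 0:
                raise TreeError(f"negative branch length {edge.length}")

    def _compute_ages(self, force_ultrametrize: bool = False) -> None:
        root = self._tree.seed_node
        # depth from root
        depth = {root: 0.0}
        for nd in self._tree.preorder_node_iter():
            if nd is root:
                continue
            depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
        tip_depths = [depth[lf] for lf in self._tree.leaf_node_iter()]
        root_age = max(tip_depths)
        if root_age <= 0:
            raise TreeError("root age must be > 0 (zero-length tree)")
        tol = TOL_ULTRA_REL * root_age
        spread = root_age - min(tip_depths)
        if spread > tol:
            if not force_ultrametrize:
                raise TreeError(
                    f"tree is not ultrametric: tip depth spread {spread:.6g} "
                    f"exceeds tolerance {tol:.6g}; pass force_ultrametrize=True "
                    "to stretch terminal branches"
                )
            for lf in self._tree.leaf_node_iter():
                lf.edge.length += root_age - depth[lf]
                depth[lf] = root_age
        for nd in self._tree.preorder_node_iter():
            nd.age = root_age - depth[nd]
        for lf in self._tree.leaf_node_iter():
            lf.age = 0.0
        self._root_age = root_age
        n_poly = sum(
            1 for nd in self._tree.preorder_internal_node_iter()
            if len(nd.child_nodes()) > 2
        )
        self.n_polytomies = n_poly

    def _check_labels(self) -> None:
        labels = [self._label(lf) for lf in self._tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels after normalization: {dupes[:5]}")

    @staticmethod
    def _label(leaf: dendropy.Node) -> str:
        if leaf.taxon is not None and leaf.taxon.label is not None:
            return leaf.taxon.label.replace(" ", "_")
        return (leaf.label or "").replace(" ", "_")

    # ------------------------------------------------------------------ #
    # basic accessors
    # ------------------------------------------------------------------ #
    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def root_age(self) -> float:
        return self._root_age

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def tip_labels(self) -> list[str]:
        return [self._label(lf) for lf in self._tree.leaf_node_iter()]

    def leaf_nodes(self) -> list[dendropy.Node]:
        return list(self._tree.leaf_node_iter())

    def find_tip(self, label: str) -> dendropy.Node:
        for lf in self._tree.leaf_node_iter():
            if self._label(lf) == label:
                return lf
        raise KeyError(f"tip label not found: {label}")

    def total_branch_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self._tree.preorder_edge_iter()
            if e.head_node is not self._tree.seed_node
        )

    def is_bifurcating(self) -> bool:
        return self.n_polytomies == 0

    def resolve_polytomies(self) -> "TimeTree":
        """Arbitrarily resolve polytomies with zero-length branches (in place).

        SSE likelihoods are defined on bifurcations; grafted composite trees
        may contain soft polytomies, which are broken deterministically in
        child order.
        """
        if self.n_polytomies:
            warnings.warn(
                f"resolving {self.n_polytomies} polytomies with zero-length branches"
            )
            self._tree.resolve_polytomies(limit=2, update_bipartitions=False)
            self._compute_ages()
        return self

    def refresh(self) -> "TimeTree":
        """Recompute ages after external surgery on the wrapped tree."""
        self._validate_lengths()
        self._compute_ages()
        self._check_labels()
        return self

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #
    def as_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_internal_node_labels=False,
        )
        return s.strip() + ("\n" if not s.endswith("\n") else "")

    def write(self, path: str, schema: str = "newick") -> None:
        write_tree(self, path, schema=schema)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TimeTree(n_tips={self.n_tips}, root_age={self.root_age:.4g})"


# ---------------------------------------------------------------------- #
# tip data
# ---------------------------------------------------------------------- #
@dataclass
class TipData:
    """Per-tip binary photosynthetic state, assigned richness and sampling mode.

    ``state`` is 0 (C3), 1 (C4) or ``pd.NA`` (unknown).  ``richness`` is the
    positive number of extant species the tip stands for; in proportional
    (sampling-frequency) mode every tip has richness 1 and the global
    sampling fraction ``f`` enters the SSE tip initial conditions, while in
    unresolved-clade mode richness > 1 tips are treated as clades of known
    size attached at their stem.
    """

    table: pd.DataFrame  # columns: tip_label, state, richness
    sampling_mode: str = "proportional"  # or "unresolved"
    f: float = 1.0

    def __post_init__(self) -> None:
        req = {"tip_label", "state", "richness"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"tip table must have columns {sorted(req)}")
        if not (0.0 < self.f <= 1.0):
            raise ValueError("sampling fraction f must be in (0, 1]")
        if self.sampling_mode not in ("proportional", "unresolved"):
            raise ValueError(f"unknown sampling mode {self.sampling_mode!r}")
        t = self.table
        if (t["richness"] < 1).any():
            raise ValueError("every tip richness must be >= 1")
        bad = t["state"].dropna()
        if not bad.isin([0, 1]).all():
            raise ValueError("states must be 0, 1 or NA")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_dict(
        cls,
        states: dict[str, object],
        richness: Optional[dict[str, int]] = None,
        sampling_mode: str = "proportional",
        f: float = 1.0,
    ) -> "TipData":
        labels = list(states)
        df = pd.DataFrame(
            {
                "tip_label": labels,
                "state": pd.array(
                    [states[l] for l in labels], dtype="Int64"
                ),
                "richness": [
                    int(richness.get(l, 1)) if richness else 1 for l in labels
                ],
            }
        )
        return cls(df, sampling_mode=sampling_mode, f=f)

    @classmethod
    def read_tsv(
        cls, path: str, sampling_mode: str = "proportional", f: float = 1.0
    ) -> "TipData":
        df = pd.read_csv(path, sep="\t", dtype={"tip_label": str})
        df["state"] = pd.array(df["state"], dtype="Int64")
        df["richness"] = df["richness"].astype(int)
        return cls(df, sampling_mode=sampling_mode, f=f)

    def write_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    def state_of(self, label: str):
        row = self.table.loc[self.table.tip_label == label]
        if row.empty:
            raise KeyError(f"no tip data for {label}")
        v = row["state"].iloc[0]
        return None if pd.isna(v) else int(v)

    def richness_of(self, label: str) -> int:
        row = self.table.loc[self.table.tip_label == label]
        if row.empty:
            raise KeyError(f"no tip data for {label}")
        return int(row["richness"].iloc[0])

    @property
    def total_richness(self) -> int:
        return int(self.table["richness"].sum())

    def subset(self, labels: Iterable[str]) -> "TipData":
        labels = set(labels)
        return TipData(
            self.table[self.table.tip_label.isin(labels)].copy(),
            sampling_mode=self.sampling_mode,
            f=self.f,
        )


# ---------------------------------------------------------------------- #
# LTT
# ---------------------------------------------------------------------- #
@dataclass
class LttCurve:
    """Lineage-through-time step function: (age, count) from the root to 0."""

    ages: np.ndarray  # decreasing, root age first
    counts: np.ndarray  # non-decreasing toward the present

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.ages) != len(self.counts):
            raise ValueError("ages and counts must align")

    @property
    def final_count(self) -> int:
        return int(self.counts[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "lineages": self.counts})


def ltt_curve(
    tree: TimeTree,
    tips: Optional[TipData] = None,
    state: Optional[int] = None,
) -> LttCurve:
    """Lineage-through-time curve of an ultrametric tree.

    With ``tips`` and ``state`` given, only branches whose descendant tips
    include at least one tip of that state are counted — the C3-only /
    C4-only accumulation curves of the grass analyses.
    """
    keep: Optional[set[int]] = None
    if state is not None:
        if tips is None:
            raise ValueError("state filtering requires TipData")
        wanted = set(
            tips.table.loc[tips.table.state == state, "tip_label"].tolist()
        )
        keep = set()
        # mark nodes with >=1 descendant tip in the wanted state
        for nd in tree.tree.postorder_node_iter():
            if nd.is_leaf():
                if TimeTree._label(nd) in wanted:
                    keep.add(id(nd))
            else:
                if any(id(c) in keep for c in nd.child_nodes()):
                    keep.add(id(nd))
        if not keep:
            raise ValueError(f"no tips in state {state}")

    def counted(nd) -> bool:
        return keep is None or id(nd) in keep

    # each counted internal node with >=2 counted children adds (k-1) lineages
    events = []  # (age, increment)
    root = tree.root
    for nd in tree.tree.preorder_internal_node_iter():
        if not counted(nd):
            continue
        kids = [c for c in nd.child_nodes() if counted(c)]
        if len(kids) >= 2:
            events.append((nd.age, len(kids) - 1))
    events.sort(key=lambda t: -t[0])
    if not events:
        # single lineage throughout
        return LttCurve(np.array([tree.root_age, 0.0]), np.array([1, 1]))
    # convention: (event age, lineage count entering that event), closed
    # with (0, final count) — a 3-tip tree gives (2,1), (1,2), (0,3)
    ages = [age for age, _ in events] + [0.0]
    counts = [1]
    for _, inc in events:
        counts.append(counts[-1] + inc)
    return LttCurve(np.array(ages), np.array(counts))


# ---------------------------------------------------------------------- #
# clades
# ---------------------------------------------------------------------- #
@dataclass
class CladeInfo:
    mrca: dendropy.Node
    crown_age: float
    stem_age: Optional[float]  # None when the MRCA is the root
    subtree: TimeTree


def mrca_and_clade(tree: TimeTree, tips: Sequence[str]) -> CladeInfo:
    """MRCA of a label set with crown/stem ages and the induced subtree."""
    tips = list(tips)
    if not tips:
        raise ValueError("empty label set")
    nodes = [tree.find_tip(l) for l in tips]
    if len(nodes) == 1:
        mrca = nodes[0]
    else:
        # walk ancestor sets
        anc = set()
        nd = nodes[0]
        while nd is not None:
            anc.add(id(nd))
            nd = nd.parent_node
        mrca = None
        for other in nodes[1:]:
            nd = other
            while id(nd) not in anc:
                nd = nd.parent_node
            # restrict anc to ancestors of nd
            lineage = set()
            up = nd
            while up is not None:
                lineage.add(id(up))
                up = up.parent_node
            anc &= lineage
            mrca = nd
        nd = nodes[0]
        while id(nd) not in anc:
            nd = nd.parent_node
        mrca = nd
    stem = mrca.parent_node.age if mrca.parent_node is not None else None
    sub = dendropy.Tree(seed_node=mrca.extract_subtree())
    sub.seed_node.edge.length = None
    return CladeInfo(
        mrca=mrca,
        crown_age=mrca.age,
        stem_age=stem,
        subtree=TimeTree(sub),
    )


# ---------------------------------------------------------------------- #
# I/O
# ---------------------------------------------------------------------- #
def read_tree(
    path: str,
    schema: str = "newick",
    index: int = 0,
    force_ultrametrize: bool = False,
) -> TimeTree:
    """Read one rooted time tree from a Newick or Nexus file.

    ``index`` selects a tree from a multi-tree file; the convention is
    0-based (index 57 returns the 58th tree).
    """
    if schema not in ("newick", "nexus"):
        raise ValueError(f"unsupported schema {schema!r}")
    trees = dendropy.TreeList.get(path=path, schema=schema, rooting="force-rooted")
    if not trees:
        raise TreeError(f"no trees found in {path}")
    if not (0 <= index < len(trees)):
        raise IndexError(f"tree index {index} out of range for {len(trees)} trees")
    return TimeTree(trees[index], force_ultrametrize=force_ultrametrize)


def read_tree_set(
    path: str, schema: str = "newick", force_ultrametrize: bool = False
) -> list[TimeTree]:
    trees = dendropy.TreeList.get(path=path, schema=schema, rooting="force-rooted")
    return [TimeTree(t, force_ultrametrize=force_ultrametrize) for t in trees]


def write_tree(tree: TimeTree, path: str, schema: str = "newick") -> None:
    if schema == "newick":
        with open(path, "w") as fh:
            fh.write(tree.as_newick())
    elif schema == "nexus":
        tree.tree.write(path=path, schema="nexus")
    else:
        raise ValueError(f"unsupported schema {schema!r}")


def write_tree_set(trees: Sequence[TimeTree], path: str) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_newick())
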