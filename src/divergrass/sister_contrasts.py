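"""Sister-clade richness contrasts between C4 clades and their C3 sisters.

Under irreversible-gain parsimony a C4 origin is the most recent common
ancestor of a maximal connected set of C4 tips.  Each origin whose sister
clade contains no C4 tips yields a directly comparable pair; log species
richness is then compared across pairs with an exact Wilcoxon signed-rank
test (null distribution by enumeration of sign patterns, midranks for
ties, normal approximation with continuity correction for large n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .phylo_core import TimeTree, TipData

__all__ = ["SisterPair", "WilcoxonResult", "extract_pairs", "signed_rank_test"]

EXACT_N_MAX = 25


@dataclass(frozen=True)
class SisterPair:
    """A C4 clade and its entirely-C3 sister, with summed richness."""

    focal: str  # C4 clade label (first tip)
    focal_richness: int
    sister: str  # C3 clade label
    sister_richness: int

    def __post_init__(self) -> None:
        if self.focal_richness < 1 or self.sister_richness < 1:
            raise ValueError("richness must be >= 1")


def extract_pairs(tree: TimeTree, tips: TipData) -> list[SisterPair]:
    """All C4 origins whose sister clade is entirely C3.

    A maximal node whose descendant tips are all C4 marks one origin; the
    pair is kept iff the other child of its parent contains only C3 tips
    (unknown-state tips disqualify a sister).  Richness sums over clade
    tips.
    """
    states = {
        r.tip_label: (None if pd.isna(r.state) else int(r.state))
        for r in tips.table.itertuples()
    }
    richness = {r.tip_label: int(r.richness) for r in tips.table.itertuples()}
    # per node: set of states below, total richness, first label
    below: dict[int, tuple[set, int, str]] = {}
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            lab = TimeTree._label(nd)
            s = states.get(lab)
            below[id(nd)] = (
                {s} if s is not None else {None},
                richness.get(lab, 1),
                lab,
            )
        else:
            ss: set = set()
            tot = 0
            lab = ""
            for c in nd.child_nodes():
                cs, ct, cl = below[id(c)]
                ss |= cs
                tot += ct
                if not lab:
                    lab = cl
            below[id(nd)] = (ss, tot, lab)
    if 1 not in below[id(tree.root)][0]:
        raise ValueError("tree has no C4 tips")

    pairs: list[SisterPair] = []
    # preorder: a maximal all-C4 node is one whose parent is not all-C4
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        ss, tot, lab = below[id(nd)]
        if ss != {1}:
            continue
        pss = below[id(nd.parent_node)][0]
        if pss == {1}:
            continue  # not maximal
        sibs = [c for c in nd.parent_node.child_nodes() if c is not nd]
        sister_states: set = set()
        sister_tot = 0
        sister_lab = ""
        for s in sibs:
            cs, ct, cl = below[id(s)]
            sister_states |= cs
            sister_tot += ct
            if not sister_lab:
                sister_lab = cl
        if sister_states == {0}:
            pairs.append(
                SisterPair(
                    focal=lab,
                    focal_richness=tot,
                    sister=sister_lab,
                    sister_richness=sister_tot,
                )
            )
    return pairs


# ---------------------------------------------------------------------- #
# exact Wilcoxon signed-rank
# ---------------------------------------------------------------------- #
@dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    n_used: int  # pairs after dropping zero differences
    p_greater: float  # one-sided, focal > sister
    p_less: float
    p_two_sided: float
    method: str  # "exact" or "normal"

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of |d| and signs, zero differences already removed."""
    absd = np.abs(diffs)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(len(diffs))
    sorted_abs = absd[order]
    i = 0
    while i < len(diffs):
        j = i
        while j + 1 < len(diffs) and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks, np.sign(diffs)


def _exact_tail(ranks: np.ndarray, w_obs: float) -> tuple[float, float]:
    """P(W+ >= w) and P(W+ <= w) by dynamic programming over sign patterns.

    Ranks are midranks (possibly half-integral); doubling makes them
    integers so the null distribution of 2*W+ is a convolution of
    two-point distributions — equivalent to full enumeration of the 2^n
    equiprobable sign patterns.
    """
    scaled = np.round(ranks * 2).astype(int)
    total = scaled.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for s in scaled:
        nxt = dist.copy()
        nxt[s:] += dist[: total + 1 - s]
        dist = nxt / 2.0
    w2 = int(round(w_obs * 2))
    p_ge = float(dist[w2:].sum())
    p_le = float(dist[: w2 + 1].sum())
    return p_ge, p_le


def signed_rank_test(
    pairs: Sequence[SisterPair],
    log_base: float = math.e,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on log richness differences.

    Differences ``log(focal) - log(sister)``; zero differences are dropped
    with n reduced (standard convention), tied absolute differences get
    midranks.  Exact enumeration for n <= 25, otherwise normal
    approximation with continuity and tie corrections.  The p-value is
    invariant to the logarithm base (ranks and signs are unchanged).
    """
    if not pairs:
        raise ValueError("at least one pair required")
    diffs = np.array(
        [
            (math.log(p.focal_richness) - math.log(p.sister_richness))
            / math.log(log_base)
            for p in pairs
        ]
    )
    diffs = diffs[diffs != 0.0]
    n = len(diffs)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks, signs = _signed_ranks(diffs)
    w_plus = float(ranks[signs > 0].sum())
    if n <= EXACT_N_MAX:
        p_ge, p_le = _exact_tail(ranks, w_plus)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        # tie correction
        _, counts = np.unique(ranks, return_counts=True)
        var -= np.sum(counts**3 - counts) / 48.0
        sd = math.sqrt(var)
        p_ge = float(norm.sf((w_plus - mean - 0.5) / sd))
        p_le = float(norm.cdf((w_plus - mean + 0.5) / sd))
        method = "normal"
    p_two = min(1.0, 2.0 * min(p_ge, p_le))
    return WilcoxonResult(
        statistic=w_plus,
        n_used=n,
        p_greater=p_ge,
        p_less=p_le,
        p_two_sided=p_two,
        method=method,
    )


def pairs_to_frame(pairs: Sequence[SisterPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "focal": p.focal,
                "focal_richness": p.focal_richness,
                "sister": p.sister,
                "sister_richness": p.sister_richness,
            }
            for p in pairs
        ]
    )
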