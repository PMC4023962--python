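"""Binary-state speciation-extinction (BiSSE) likelihood and model fitting.

The model assigns state-dependent speciation (lambda_i), extinction (mu_i)
and transition (q01: C3->C4, q10: C4->C3) rates to a binary character on an
ultrametric tree.  Likelihoods follow the standard pruning construction:
tip initial conditions (proportional sampling-frequency mode, or unresolved
clades of known richness), ODE integration backward along every branch, and
``D_i <- lambda_i D_i^left D_i^right`` at nodes.  A constrained model family
(equal-diversification, equal-speciation, equal-extinction, full) supports
likelihood-ratio tests of whether the C4 state diversifies faster.

All rates are in events / lineage / My.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse
import scipy.sparse.linalg
import scipy.stats

from ._sse_core import integrate_branch, prune_loglik
from .phylo_core import TimeTree, TipData, TreeError

__all__ = [
    "BisseParams",
    "ModelSpec",
    "BisseODEState",
    "BisseFit",
    "MODEL_PRESETS",
    "tip_init",
    "branch_integrate",
    "unresolved_clade_init",
    "BisseLikelihood",
    "tree_loglik",
    "fit_model",
    "compare_models",
    "replicate_analysis",
]

PARAM_NAMES = ("lambda0", "lambda1", "mu0", "mu1", "q01", "q10")

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_CAP_EXTRA = 200
DEFAULT_MASS_TOL = 1e-7


# ---------------------------------------------------------------------- #
# parameters and model family
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class BisseParams:
    """The six BiSSE rates (My^-1): state 0 = C3, state 1 = C4."""

    lambda0: float
    lambda1: float
    mu0: float
    mu1: float
    q01: float
    q10: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "BisseParams":
        return cls(*[float(x) for x in a])

    @property
    def net_rates(self) -> tuple[float, float]:
        """Net diversification (r0, r1) = (lambda_i - mu_i)."""
        return (self.lambda0 - self.mu0, self.lambda1 - self.mu1)

    def swapped(self) -> "BisseParams":
        """Relabel states 0 <-> 1."""
        return BisseParams(
            self.lambda1, self.lambda0, self.mu1, self.mu0, self.q10, self.q01
        )


#: Named equality-constraint presets.  Each model is a partition of the six
#: rates into groups constrained equal; k = number of groups.
MODEL_PRESETS: dict[str, tuple[tuple[str, ...], ...]] = {
    "full": tuple((n,) for n in PARAM_NAMES),
    "equal_diversification": (
        ("lambda0", "lambda1"),
        ("mu0", "mu1"),
        ("q01",),
        ("q10",),
    ),
    "equal_speciation": (
        ("lambda0", "lambda1"),
        ("mu0",),
        ("mu1",),
        ("q01",),
        ("q10",),
    ),
    "equal_extinction": (
        ("lambda0",),
        ("lambda1",),
        ("mu0", "mu1"),
        ("q01",),
        ("q10",),
    ),
}

MODEL_ALIASES = {
    "equal": "equal_diversification",
    "eqdiv": "equal_diversification",
    "eqspec": "equal_speciation",
    "eqext": "equal_extinction",
}


@dataclass(frozen=True)
class ModelSpec:
    """Equality constraints among the six rates."""

    name: str
    groups: tuple[tuple[str, ...], ...]

    @classmethod
    def preset(cls, name: str) -> "ModelSpec":
        key = MODEL_ALIASES.get(name, name)
        if key not in MODEL_PRESETS:
            raise KeyError(
                f"unknown model {name!r}; presets: {sorted(MODEL_PRESETS)}"
            )
        return cls(key, MODEL_PRESETS[key])

    @property
    def k(self) -> int:
        return len(self.groups)

    def expand(self, theta: Sequence[float]) -> BisseParams:
        """Map a free-parameter vector (one value per group) to full rates."""
        vals = {}
        for g, v in zip(self.groups, theta):
            for name in g:
                vals[name] = float(v)
        return BisseParams(**vals)

    def reduce(self, params: BisseParams) -> np.ndarray:
        """Group-representative values (first member of each group)."""
        return np.array([getattr(params, g[0]) for g in self.groups])

    def nested_in(self, other: "ModelSpec") -> bool:
        """True if this (more constrained) model is nested in ``other``."""
        if self.k > other.k:
            return False
        mine = [set(g) for g in self.groups]
        return all(
            any(set(g) <= m for m in mine) for g in other.groups
        )


# ---------------------------------------------------------------------- #
# ODE state and elementary operations
# ---------------------------------------------------------------------- #
@dataclass
class BisseODEState:
    """(E0, E1, D0, D1) plus an accumulated log-scale factor for D."""

    e: np.ndarray  # shape (2,)
    d: np.ndarray  # shape (2,)
    log_scale: float = 0.0

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if np.any(self.e < -1e-12) or np.any(self.e > 1 + 1e-12):
            raise ValueError("E components must lie in [0, 1]")
        if np.any(self.d < 0):
            raise ValueError("D components must be >= 0")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.e, self.d])


def tip_init(state: Optional[int], f: float = 1.0) -> BisseODEState:
    """Tip initial conditions in proportional (sampling-frequency) mode.

    ``D_i = f`` for the observed state (both, when the state is unknown) and
    ``E_i = 1 - f``: an extant species is sampled with probability f.
    """
    if not (0.0 < f <= 1.0):
        raise ValueError("sampling fraction f must be in (0, 1]")
    d = np.zeros(2)
    if state is None:
        d[:] = f
    elif state in (0, 1):
        d[state] = f
    else:
        raise ValueError(f"state must be 0, 1 or None, got {state!r}")
    return BisseODEState(e=np.full(2, 1.0 - f), d=d)


def branch_integrate(
    state: BisseODEState,
    params: BisseParams,
    duration: float,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> BisseODEState:
    """Integrate one branch backward in time, renormalizing on underflow."""
    if duration < 0:
        raise ValueError("duration must be >= 0")
    y0 = state.as_vector()
    y = integrate_branch(y0, params.as_array(), float(duration), rtol, atol)
    if np.any(np.isnan(y)):
        raise FloatingPointError("branch ODE integration failed")
    d = y[2:]
    # D that decayed below the integration noise floor may come out as a
    # tiny negative number; clamp it, but never mask a real defect
    if np.any(d < -1e-8 * max(np.max(np.abs(d)), 1.0)):
        raise FloatingPointError(f"negative D after integration: {d}")
    d = np.clip(d, 0.0, None)
    log_scale = state.log_scale
    m = max(d[0], d[1])
    if 0 < m < 1e-50:
        d /= m
        log_scale += math.log(m)
    return BisseODEState(e=np.clip(y[:2], 0.0, 1.0), d=d, log_scale=log_scale)


# ---------------------------------------------------------------------- #
# unresolved clades
# ---------------------------------------------------------------------- #
def _pair_index(cap: int):
    pairs = [(a, b) for a in range(cap + 1) for b in range(cap + 1 - a)]
    idx = {p: i for i, p in enumerate(pairs)}
    return pairs, idx


def _master_generator(params: BisseParams, cap: int) -> scipy.sparse.csr_matrix:
    """Truncated master-equation generator over joint counts (n0, n1).

    Transitions: state-i speciation (rate n_i * lambda_i), extinction
    (n_i * mu_i) and character flips (n0 q01, n1 q10).  Mass crossing the
    truncation boundary is lost, which is what the leak check measures.
    """
    pairs, idx = _pair_index(cap)
    rows, cols, vals = [], [], []
    l0, l1, m0, m1, q01, q10 = params.as_array()
    for i, (a, b) in enumerate(pairs):
        out = a * (l0 + m0 + q01) + b * (l1 + m1 + q10)
        if out:
            rows.append(i)
            cols.append(i)
            vals.append(-out)
        moves = (
            (a * l0, (a + 1, b)),
            (b * l1, (a, b + 1)),
            (a * m0, (a - 1, b)),
            (b * m1, (a, b - 1)),
            (a * q01, (a - 1, b + 1)),
            (b * q10, (a + 1, b - 1)),
        )
        for rate, tgt in moves:
            if rate and tgt in idx:
                rows.append(idx[tgt])
                cols.append(i)
                vals.append(rate)
    n = len(pairs)
    return scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def unresolved_clade_init(
    richness_total: int,
    per_state_counts: Optional[tuple[int, int]],
    stem_to_present: float,
    params: BisseParams,
    cap: Optional[int] = None,
    mass_tol: float = DEFAULT_MASS_TOL,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> BisseODEState:
    """Initial conditions for a terminally unresolved clade of known size.

    ``D_i`` is the probability, under the two-state birth-death-transition
    process started from one lineage in state i at the clade's attachment
    age, of exactly the observed species richness (and state tallies, when
    given) at present, obtained by integrating the truncated master
    equation over joint counts up to ``cap``.  The returned state is
    already propagated over the clade's terminal branch: the caller must
    not integrate it again.
    """
    if richness_total < 1:
        raise ValueError("richness must be >= 1")
    if per_state_counts is not None:
        n0, n1 = per_state_counts
        if n0 < 0 or n1 < 0 or n0 + n1 != richness_total:
            raise ValueError("per-state counts must be >= 0 and sum to richness")
    if cap is None:
        cap = richness_total + DEFAULT_CAP_EXTRA
    if cap < richness_total:
        raise ValueError("cap must be >= observed richness")
    t = float(stem_to_present)
    if t < 0:
        raise ValueError("duration must be >= 0")

    d = np.zeros(2)
    if t == 0.0:
        if per_state_counts is None:
            if richness_total == 1:
                d[:] = 1.0
            # richness > 1 at duration 0 is impossible -> D stays 0
        else:
            if per_state_counts == (1, 0):
                d[0] = 1.0
            elif per_state_counts == (0, 1):
                d[1] = 1.0
        e = np.zeros(2)
        return BisseODEState(e=e, d=d)

    pairs, idx = _pair_index(cap)
    A = _master_generator(params, cap)
    for start_state in (0, 1):
        p0 = np.zeros(len(pairs))
        p0[idx[(1, 0) if start_state == 0 else (0, 1)]] = 1.0
        pt = scipy.sparse.linalg.expm_multiply(A * t, p0)
        leak = 1.0 - pt.sum()
        if leak > mass_tol:
            raise FloatingPointError(
                f"probability mass {leak:.3g} beyond cap {cap} exceeds "
                f"mass_tol {mass_tol:g}; raise the cap"
            )
        if per_state_counts is not None:
            d[start_state] = pt[idx[per_state_counts]]
        else:
            n = richness_total
            d[start_state] = sum(
                pt[idx[(a, n - a)]] for a in range(n + 1)
            )
    # E_i over the same span with complete sampling inside the clade
    y = integrate_branch(
        np.array([0.0, 0.0, 0.0, 0.0]), params.as_array(), t, rtol, atol
    )
    return BisseODEState(e=np.clip(y[:2], 0.0, 1.0), d=np.clip(d, 0.0, None))


# ---------------------------------------------------------------------- #
# tree likelihood
# ---------------------------------------------------------------------- #
class BisseLikelihood:
    """Callable BiSSE log-likelihood for one (tree, tip data) pair.

    Flattens the tree once into post-order arrays; each call evaluates the
    likelihood at a parameter set.  In unresolved mode, tip initial
    conditions are recomputed per call (they depend on the rates).
    """

    def __init__(
        self,
        tree: TimeTree,
        tips: TipData,
        root_mode: str = "weighted",
        condition_on_survival: bool = False,
        rtol: float = DEFAULT_RTOL,
        atol: float = DEFAULT_ATOL,
        cap_extra: int = DEFAULT_CAP_EXTRA,
        mass_tol: float = DEFAULT_MASS_TOL,
    ):
        if root_mode not in ("weighted", "flat", "equilibrium", "given0", "given1"):
            raise ValueError(f"unknown root mode {root_mode!r}")
        if not tree.is_bifurcating():
            raise TreeError(
                "BiSSE likelihood requires a bifurcating tree; call "
                "resolve_polytomies() first"
            )
        self.tree = tree
        self.tips = tips
        self.root_mode = root_mode
        self.condition_on_survival = condition_on_survival
        self.rtol = rtol
        self.atol = atol
        self.cap_extra = cap_extra
        self.mass_tol = mass_tol
        self._flatten()

    def _flatten(self) -> None:
        nodes = list(self.tree.tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        left = np.full(n, -1, dtype=np.int64)
        right = np.full(n, -1, dtype=np.int64)
        elen = np.zeros(n)
        order = np.arange(n, dtype=np.int64)
        tip_rows: list[tuple[int, str, float]] = []  # (node idx, label, stem span)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                elen[i] = nd.edge.length or 0.0
            kids = nd.child_nodes()
            if kids:
                left[i] = index[id(kids[0])]
                right[i] = index[id(kids[1])]
            else:
                tip_rows.append((i, TimeTree._label(nd), elen[i]))
        self._left, self._right, self._elen, self._order = left, right, elen, order
        self._tip_rows = tip_rows
        self._n_nodes = n
        # static initial conditions for proportional mode
        tstates = {
            r.tip_label: (None if pd.isna(r.state) else int(r.state))
            for r in self.tips.table.itertuples()
        }
        trich = {r.tip_label: int(r.richness) for r in self.tips.table.itertuples()}
        missing = [lab for _, lab, _ in tip_rows if lab not in tstates]
        if missing:
            raise KeyError(f"tip table missing labels: {missing[:5]}")
        self._tip_states = tstates
        self._tip_richness = trich
        if self.tips.sampling_mode == "proportional":
            init = np.zeros((n, 4))
            logw = np.zeros(n)
            f = self.tips.f
            for i, lab, _ in tip_rows:
                st = tip_init(tstates[lab], f)
                init[i, :2] = st.e
                init[i, 2:] = st.d
            self._static_init = init
            self._static_logw = logw
            self._eff_elen = elen
        else:
            self._static_init = None
            self._unresolved = [
                (i, lab, span)
                for i, lab, span in tip_rows
            ]
            eff = elen.copy()
            for i, lab, _ in tip_rows:
                eff[i] = 0.0  # unresolved inits already span the tip branch
            self._eff_elen = eff

    # ------------------------------------------------------------------ #
    def _tip_conditions(self, params: BisseParams):
        if self._static_init is not None:
            return self._static_init, self._static_logw, self._eff_elen
        n = self._n_nodes
        init = np.zeros((n, 4))
        logw = np.zeros(n)
        for i, lab, span in self._unresolved:
            rich = self._tip_richness[lab]
            state = self._tip_states[lab]
            counts = None
            if state is not None:
                counts = (rich, 0) if state == 0 else (0, rich)
            st = unresolved_clade_init(
                rich,
                counts,
                span,
                params,
                cap=rich + self.cap_extra,
                mass_tol=self.mass_tol,
                rtol=self.rtol,
                atol=self.atol,
            )
            init[i, :2] = st.e
            init[i, 2:] = st.d
        return init, logw, self._eff_elen

    def __call__(self, params: BisseParams) -> float:
        init, logw, elen = self._tip_conditions(params)
        y, logfac, ok = prune_loglik(
            self._order,
            self._left,
            self._right,
            elen,
            init,
            logw,
            params.as_array(),
            self.rtol,
            self.atol,
        )
        if not ok:
            return -np.inf
        e, d = y[:2], y[2:].copy()
        lam = np.array([params.lambda0, params.lambda1])
        if self.condition_on_survival:
            denom = lam * (1.0 - e) ** 2
            if np.any(denom <= 0):
                return -np.inf
            d = d / denom
        tot = d.sum()
        if tot <= 0 or not np.isfinite(tot):
            return -np.inf
        if self.root_mode == "weighted":
            w = d / tot
        elif self.root_mode == "flat":
            w = np.array([0.5, 0.5])
        elif self.root_mode == "equilibrium":
            qs = params.q01 + params.q10
            w = (
                np.array([params.q10, params.q01]) / qs
                if qs > 0
                else np.array([0.5, 0.5])
            )
        elif self.root_mode == "given0":
            w = np.array([1.0, 0.0])
        else:
            w = np.array([0.0, 1.0])
        lik = float(np.dot(w, d))
        if lik <= 0:
            return -np.inf
        return math.log(lik) + logfac


def tree_loglik(
    tree: TimeTree,
    tips: TipData,
    params: BisseParams,
    root_mode: str = "weighted",
    condition_on_survival: bool = False,
    **kwargs,
) -> float:
    """BiSSE log-likelihood of a tree and tip data at fixed rates."""
    return BisseLikelihood(
        tree, tips, root_mode=root_mode,
        condition_on_survival=condition_on_survival, **kwargs
    )(params)


# ---------------------------------------------------------------------- #
# fitting
# ---------------------------------------------------------------------- #
@dataclass
class BisseFit:
    spec: ModelSpec
    params: BisseParams
    lnL: float
    converged: bool
    n_starts: int
    seed: int
    messages: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def net_rates(self) -> tuple[float, float]:
        return self.params.net_rates

    def aic(self) -> float:
        return 2 * self.k - 2 * self.lnL

    def to_dict(self) -> dict:
        d = {n: getattr(self.params, n) for n in PARAM_NAMES}
        r0, r1 = self.net_rates
        d.update(
            model=self.spec.name, k=self.k, lnL=self.lnL, r0=r0, r1=r1,
            converged=self.converged, seed=self.seed,
        )
        return d


def _parsimony_changes(tree: TimeTree, states: dict[str, Optional[int]]) -> int:
    """Fitch parsimony count of state changes (unknowns treated as {0,1})."""
    changes = 0
    sets: dict[int, frozenset] = {}
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            s = states.get(TimeTree._label(nd))
            sets[id(nd)] = frozenset({0, 1}) if s is None else frozenset({s})
            continue
        kids = [sets[id(c)] for c in nd.child_nodes()]
        inter = frozenset.intersection(*kids)
        if inter:
            sets[id(nd)] = inter
        else:
            sets[id(nd)] = frozenset.union(*kids)
            changes += 1
    return changes


def moment_start(tree: TimeTree, tips: TipData) -> BisseParams:
    """Deterministic starting rates from birth-death moment heuristics.

    Net rate from ln(effective n)/root age (a crown Kendall-Moran style
    estimate), relative extinction 0.5, transition rates from the Fitch
    parsimony change count over the total branch length.
    """
    n_eff = max(tips.total_richness / tips.f if tips.f > 0 else tips.total_richness, 3)
    T = tree.root_age
    r = max(math.log(n_eff / 2.0) / T, 1e-4)
    lam = 2.0 * r
    mu = lam - r
    states = {
        row.tip_label: (None if pd.isna(row.state) else int(row.state))
        for row in tips.table.itertuples()
    }
    q = max(_parsimony_changes(tree, states), 1) / max(
        tree.total_branch_length(), 1e-9
    )
    return BisseParams(lam, lam, mu, mu, q, q)


_LOG_LO, _LOG_HI = -15.0, 3.0


def fit_model(
    tree: TimeTree,
    tips: TipData,
    spec: ModelSpec | str,
    root_mode: str = "weighted",
    condition_on_survival: bool = False,
    n_starts: int = 5,
    seed: int = 0,
    maxiter: int = 300,
    likelihood: Optional[BisseLikelihood] = None,
    start: Optional[BisseParams] = None,
) -> BisseFit:
    """Maximize the constrained BiSSE likelihood from deterministic starts.

    Optimization runs in log-rate space with a bounded quasi-Newton method
    (L-BFGS-B); starts are seeded lognormal perturbations of a birth-death
    moment estimate, the first start unperturbed.
    """
    if isinstance(spec, str):
        spec = ModelSpec.preset(spec)
    lik = likelihood or BisseLikelihood(
        tree, tips, root_mode=root_mode,
        condition_on_survival=condition_on_survival,
    )
    base = start or moment_start(tree, tips)
    theta0 = np.log(np.maximum(spec.reduce(base), 1e-6))
    rng = np.random.default_rng(seed)

    def neg(th: np.ndarray) -> float:
        p = spec.expand(np.exp(th))
        val = lik(p)
        return -val if np.isfinite(val) else 1e10

    best = None
    messages = []
    for s in range(max(n_starts, 1)):
        th = theta0 if s == 0 else theta0 + rng.normal(0.0, 0.5, size=spec.k)
        th = np.clip(th, _LOG_LO, _LOG_HI)
        res = scipy.optimize.minimize(
            neg,
            th,
            method="L-BFGS-B",
            bounds=[(_LOG_LO, _LOG_HI)] * spec.k,
            options={"maxiter": maxiter},
        )
        messages.append(f"start {s}: f={-res.fun:.6f} {res.message}")
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e9:
        raise RuntimeError("no optimizer start converged to a finite likelihood")
    params = spec.expand(np.exp(best.x))
    return BisseFit(
        spec=spec,
        params=params,
        lnL=-float(best.fun),
        converged=bool(best.success),
        n_starts=n_starts,
        seed=seed,
        messages=messages,
    )


# ---------------------------------------------------------------------- #
# model comparison
# ---------------------------------------------------------------------- #
def compare_models(fits: Sequence[BisseFit], n_obs: Optional[int] = None) -> pd.DataFrame:
    """Nested likelihood-ratio tests and AIC/AICc over a set of fits.

    For each nested pair the LRT statistic is 2 * delta lnL with df equal
    to the difference in free parameters, compared to a chi-squared null.
    The returned frame has one row per model plus one per nested pair; the
    best-AICc model is flagged ``preferred``.
    """
    rows = []
    aiccs = []
    for f in fits:
        aicc = f.aic()
        if n_obs is not None and n_obs - f.k - 1 > 0:
            aicc += 2 * f.k * (f.k + 1) / (n_obs - f.k - 1)
        aiccs.append(aicc)
    best = int(np.argmin(aiccs))
    for i, f in enumerate(fits):
        rows.append(
            {
                "kind": "model",
                "model": f.spec.name,
                "against": "",
                "k": f.k,
                "lnL": f.lnL,
                "AIC": f.aic(),
                "AICc": aiccs[i],
                "statistic": np.nan,
                "df": np.nan,
                "p_value": np.nan,
                "preferred": i == best,
            }
        )
    for i, fa in enumerate(fits):
        for j, fb in enumerate(fits):
            if i == j or not fa.spec.nested_in(fb.spec) or fa.k >= fb.k:
                continue
            stat = max(2.0 * (fb.lnL - fa.lnL), 0.0)
            df = fb.k - fa.k
            p = float(scipy.stats.chi2.sf(stat, df)) if stat > 0 else 1.0
            rows.append(
                {
                    "kind": "lrt",
                    "model": fb.spec.name,
                    "against": fa.spec.name,
                    "k": fb.k,
                    "lnL": fb.lnL,
                    "AIC": np.nan,
                    "AICc": np.nan,
                    "statistic": stat,
                    "df": df,
                    "p_value": p,
                    "preferred": False,
                }
            )
    return pd.DataFrame(rows)


def lrt(fit_constrained: BisseFit, fit_full: BisseFit) -> tuple[float, int, float]:
    """Likelihood-ratio statistic, df and chi-squared p for one nested pair."""
    if not fit_constrained.spec.nested_in(fit_full.spec):
        raise ValueError(
            f"{fit_constrained.spec.name} is not nested in {fit_full.spec.name}"
        )
    stat = max(2.0 * (fit_full.lnL - fit_constrained.lnL), 0.0)
    df = fit_full.k - fit_constrained.k
    p = float(scipy.stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p


# ---------------------------------------------------------------------- #
# replicate analysis over tree sets
# ---------------------------------------------------------------------- #
@dataclass
class ReplicateResult:
    fits: pd.DataFrame  # one row per (tree, model)
    lrt_stats: pd.DataFrame  # full vs equal-diversification per tree
    failures: list[tuple[int, str]]

    def net_rate_histogram(self, bins: int = 20) -> dict:
        """Histogram data of full-model net rates by state (Fig-2 style)."""
        full = self.fits[self.fits.model == "full"]
        out = {}
        for state, col in (("C3", "r0"), ("C4", "r1")):
            vals = full[col].to_numpy()
            counts, edges = np.histogram(vals, bins=bins)
            out[state] = {"counts": counts.tolist(), "edges": edges.tolist()}
        return out

    def lrt_histogram(self, bins: int = 20) -> dict:
        vals = self.lrt_stats["statistic"].dropna().to_numpy()
        counts, edges = np.histogram(vals, bins=bins)
        df = int(self.lrt_stats["df"].iloc[0]) if len(self.lrt_stats) else 2
        refs = {
            alpha: float(scipy.stats.chi2.ppf(1 - alpha, df))
            for alpha in (0.05, 0.01, 0.005)
        }
        return {"counts": counts.tolist(), "edges": edges.tolist(),
                "reference_lines": refs}


def replicate_analysis(
    trees: Sequence[TimeTree],
    tips: TipData,
    specs: Sequence[ModelSpec | str] = ("equal_diversification", "full"),
    seed: int = 0,
    n_starts: int = 3,
    **fit_kwargs,
) -> ReplicateResult:
    """Fit each model on each tree of a replicate set (posterior stand-in).

    Individual tree failures are recorded, not fatal.  Emits per-tree fits
    plus the LRT statistic of the fullest vs the most constrained model,
    the comparison shown as replicate histograms with chi-squared
    significance reference lines.
    """
    specs = [ModelSpec.preset(s) if isinstance(s, str) else s for s in specs]
    if len(trees) < 2:
        warnings.warn("replicate analysis with < 2 trees gives a degenerate histogram")
    rows, lrt_rows, failures = [], [], []
    for ti, tree in enumerate(trees):
        try:
            fits = [
                fit_model(
                    tree, tips, sp, seed=seed + ti, n_starts=n_starts, **fit_kwargs
                )
                for sp in specs
            ]
        except Exception as exc:  # noqa: BLE001 - per-tree failures recorded
            failures.append((ti, str(exc)))
            continue
        for f in fits:
            rows.append({"tree": ti, **f.to_dict()})
        by_k = sorted(fits, key=lambda f: f.k)
        if by_k[0].k < by_k[-1].k and by_k[0].spec.nested_in(by_k[-1].spec):
            stat, df, p = lrt(by_k[0], by_k[-1])
            lrt_rows.append({"tree": ti, "statistic": stat, "df": df, "p_value": p})
    return ReplicateResult(
        fits=pd.DataFrame(rows),
        lrt_stats=pd.DataFrame(lrt_rows),
        failures=failures,
    )
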