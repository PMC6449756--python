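"""Felsenstein pruning likelihood and branch-length optimization.

Gaps and ``X`` are treated as missing data: a leaf with missing data
contributes a partial-likelihood vector of ones, so an all-gap column adds
exactly zero to the log-likelihood.  Site patterns are compressed with
multiplicity weights, conditional likelihoods are max-rescaled per node to
avoid underflow, and every branch is optimized by bracketed one-dimensional
maximization on [1e-8, 10].

The per-branch objective uses the standard edge decomposition of a
reversible model: for a branch (parent, c),

    L(t) = sum_p w_p log( A_c(p,:) . P(t) . B_c(p,:) )

where ``B_c`` is the conditional likelihood of the data below ``c`` and
``A_c`` collects the rest of the tree (with the stationary frequencies
folded in at the root).  Optimizing branches along a preorder sweep keeps the
log-likelihood non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .seqdata import MISSING, Alignment
from .substmodels import N_STATES, SubstModel
from .trees import PhyloTree, TreeNode

MIN_BL = 1e-8
MAX_BL = 10.0
DEFAULT_BL = 0.1


@dataclass
class EngineFit:
    """A fitted tree: topology + branch lengths and its log-likelihood."""

    tree: PhyloTree
    log_likelihood: float
    model: SubstModel
    converged: bool = True


class PatternData:
    """Site-pattern-compressed alignment columns for a set of rows."""

    def __init__(self, names: list[str], matrix: np.ndarray,
                 weights: np.ndarray, first_column: np.ndarray, n_cols: int):
        self.names = names
        self.matrix = matrix            # (n_rows, n_patterns) int8
        self.weights = weights          # (n_patterns,) float
        self.first_column = first_column
        self.n_cols = n_cols
        self.index = {n: i for i, n in enumerate(names)}


def compress_alignment(aln: Alignment) -> PatternData:
    enc = aln.encoded()
    patterns, first, counts = np.unique(enc, axis=1, return_index=True,
                                        return_counts=True)
    return PatternData(aln.ids(), patterns, counts.astype(float), first,
                       aln.n_cols)


class TreeLikelihood:
    """Likelihood computations for one tree over pattern-compressed data.

    The tree is used live (no copy): tree edits invalidate caches, so callers
    re-instantiate or call :meth:`invalidate` after rearrangements.
    """

    def __init__(self, tree: PhyloTree, data: PatternData, model: SubstModel):
        self.tree = tree
        self.data = data
        self.model = model
        leaf_names = tree.leaf_names()
        if set(leaf_names) != set(data.names):
            missing = set(leaf_names) ^ set(data.names)
            raise ValueError(f"tree leaves and alignment rows differ: {missing}")
        self._B: dict[int, np.ndarray] = {}
        self._logB: dict[int, np.ndarray] = {}
        self._K = model.n_rates
        self._P = data.matrix.shape[1]

    def invalidate(self) -> None:
        self._B.clear()
        self._logB.clear()

    # ---- conditional likelihoods (below each node) ---------------------
    def _leaf_partial(self, node: TreeNode) -> np.ndarray:
        states = self.data.matrix[self.data.index[node.name]]
        out = np.zeros((self._K, self._P, N_STATES))
        miss = states == MISSING
        out[:, miss, :] = 1.0
        obs = ~miss
        out[:, obs, :] = 0.0
        idx = np.nonzero(obs)[0]
        out[:, idx, states[idx].astype(int)] = 1.0
        return out

    def _edge_message(self, child: TreeNode) -> tuple[np.ndarray, np.ndarray]:
        """(message, logscale) of child's subtree seen from its parent."""
        B, logB = self._below(child)
        t = _branch_length(child)
        Ps = self.model.transition_matrices(t)
        M = B @ Ps.transpose(0, 2, 1)
        return M, logB

    def _below(self, node: TreeNode) -> tuple[np.ndarray, np.ndarray]:
        key = id(node)
        if key in self._B:
            return self._B[key], self._logB[key]
        if node.is_leaf:
            B = self._leaf_partial(node)
            logB = np.zeros((self._K, self._P))
        else:
            B = np.ones((self._K, self._P, N_STATES))
            logB = np.zeros((self._K, self._P))
            for c in node.children:
                M, logM = self._edge_message(c)
                B = B * M
                logB = logB + logM
            B, logB = _rescale(B, logB)
        self._B[key] = B
        self._logB[key] = logB
        return B, logB

    def _refresh_below(self) -> None:
        self._B.clear()
        self._logB.clear()
        for node in self.tree.postorder():
            self._below(node)

    def log_likelihood(self) -> float:
        self._refresh_below()
        B, logB = self._below(self.tree.root)
        site = B @ self.model.pi
        return self._total(site, logB)

    def _total(self, site: np.ndarray, logscale: np.ndarray) -> float:
        with np.errstate(divide="ignore"):
            logs = np.log(site) + logscale
        if self._K == 1:
            per_pattern = logs[0]
        else:
            m = logs.max(axis=0)
            per_pattern = m + np.log(np.mean(np.exp(logs - m), axis=0))
        if not np.all(np.isfinite(per_pattern)):
            bad = int(self.data.first_column[~np.isfinite(per_pattern)][0])
            raise ArithmeticError(
                f"non-finite site likelihood at alignment column {bad}")
        return float(per_pattern @ self.data.weights)

    # ---- branch-length optimization ------------------------------------
    def _edge_objective(self, A: np.ndarray, logA: np.ndarray,
                        B: np.ndarray, logB: np.ndarray):
        w = self.data.weights
        K = self._K

        def f(t: float) -> float:
            Ps = self.model.transition_matrices(t)
            site = ((A @ Ps) * B).sum(axis=2)
            with np.errstate(divide="ignore"):
                logs = np.log(site) + logA + logB
            if K == 1:
                per_pattern = logs[0]
            else:
                m = logs.max(axis=0)
                per_pattern = m + np.log(np.mean(np.exp(logs - m), axis=0))
            return float(per_pattern @ w)

        return f

    def _optimize_edge(self, f, t0: float, xatol: float,
                       warm: bool = False) -> tuple[float, float]:
        """Maximize f over [MIN_BL, MAX_BL]; never accept a worse value.

        With ``warm=True`` the bracket is first narrowed around the current
        value (replicate refits start near the optimum); if the maximizer
        lands on the narrow boundary the full bracket is searched.
        """
        base = f(t0)
        neg = lambda t: -f(t)
        if warm:
            lo = max(MIN_BL, t0 / 5.0)
            hi = min(MAX_BL, max(t0 * 5.0, t0 + 0.05))
            res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                  options={"xatol": xatol})
            margin = 1e-3 * (hi - lo)
            if (res.x - lo < margin and lo > MIN_BL * 2) or \
                    (hi - res.x < margin and hi < MAX_BL / 2):
                res = minimize_scalar(neg, bounds=(MIN_BL, MAX_BL),
                                      method="bounded",
                                      options={"xatol": xatol})
        else:
            res = minimize_scalar(neg, bounds=(MIN_BL, MAX_BL),
                                  method="bounded", options={"xatol": xatol})
        if -res.fun > base:
            return float(res.x), float(-res.fun)
        return t0, base

    def optimize_branch_lengths(self, tol: float = 1e-4, max_rounds: int = 20,
                                xatol: float = 1e-6, warm: bool = False
                                ) -> EngineFit:
        """Iterated per-branch maximization until the round gain is < tol."""
        for node in self.tree.postorder():
            if node.parent is not None:
                if node.length is None:
                    node.length = DEFAULT_BL
                node.length = min(max(node.length, MIN_BL), MAX_BL)
        last = self.log_likelihood()
        converged = False
        for _ in range(max_rounds):
            self._sweep(xatol, warm=warm)
            current = self.log_likelihood()
            if current - last < tol:
                converged = True
                last = max(current, last)
                break
            last = current
        return EngineFit(tree=self.tree, log_likelihood=last,
                         model=self.model, converged=converged)

    def _sweep(self, xatol: float, warm: bool = False) -> None:
        self._refresh_below()
        pi = self.model.pi[None, None, :]
        root = self.tree.root
        A0 = np.broadcast_to(pi, (self._K, self._P, N_STATES)).copy()
        logA0 = np.zeros((self._K, self._P))
        self._descend(root, A0, logA0, xatol, warm)

    def _descend(self, node: TreeNode, A: np.ndarray, logA: np.ndarray,
                 xatol: float, warm: bool = False) -> None:
        messages = {}
        for c in node.children:
            messages[id(c)] = self._edge_message(c)
        for c in node.children:
            Ac = A.copy()
            logAc = logA.copy()
            for s in node.children:
                if s is c:
                    continue
                M, logM = messages[id(s)]
                Ac = Ac * M
                logAc = logAc + logM
            Ac, logAc = _rescale(Ac, logAc)
            B, logB = self._below(c)
            f = self._edge_objective(Ac, logAc, B, logB)
            new_t, _ = self._optimize_edge(f, c.length, xatol, warm=warm)
            if new_t != c.length:
                c.length = new_t
                messages[id(c)] = self._edge_message(c)
            if not c.is_leaf:
                Ps = self.model.transition_matrices(c.length)
                D = Ac @ Ps
                D, logD = _rescale(D, logAc)
                self._descend(c, D, logD, xatol, warm)

    def optimize_single_edge(self, child: TreeNode, xatol: float = 1e-6
                             ) -> float:
        """Optimize only the branch above ``child``; returns the new lnL."""
        self._refresh_below()
        A, logA = self._away(child)
        B, logB = self._below(child)
        f = self._edge_objective(A, logA, B, logB)
        new_t, ll = self._optimize_edge(f, _branch_length(child), xatol)
        child.length = new_t
        return ll

    def _away(self, target: TreeNode) -> tuple[np.ndarray, np.ndarray]:
        path = []
        n = target
        while n is not None:
            path.append(n)
            n = n.parent
        path.reverse()  # root ... target
        pi = self.model.pi[None, None, :]
        A = np.broadcast_to(pi, (self._K, self._P, N_STATES)).copy()
        logA = np.zeros((self._K, self._P))
        for depth, node in enumerate(path[:-1]):
            nxt = path[depth + 1]
            for s in node.children:
                if s is nxt:
                    continue
                M, logM = self._edge_message(s)
                A = A * M
                logA = logA + logM
            A, logA = _rescale(A, logA)
            if nxt is not target:
                Ps = self.model.transition_matrices(nxt.length)
                A = A @ Ps
        return A, logA


def _branch_length(node: TreeNode) -> float:
    if node.length is None:
        raise ValueError(f"branch length unset above node {node.name!r}")
    if node.length < 0:
        raise ValueError(f"negative branch length {node.length}")
    return node.length


def _rescale(B: np.ndarray, logB: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = B.max(axis=2)
    safe = np.where(m > 0, m, 1.0)
    return B / safe[:, :, None], logB + np.log(safe)


# ---- public, validated entry points ------------------------------------

def log_likelihood(tree: PhyloTree, msa: Alignment, model: SubstModel) -> float:
    """Pruning log-likelihood (natural log) of the alignment on the tree."""
    for node in tree.postorder():
        if node.parent is not None:
            _branch_length(node)
    return TreeLikelihood(tree, compress_alignment(msa), model).log_likelihood()


def optimize_branch_lengths(tree: PhyloTree, msa: Alignment, model: SubstModel,
                            tol: float = 1e-4, xatol: float = 1e-6,
                            max_rounds: int = 20) -> EngineFit:
    """Optimize all branch lengths on a copy of ``tree``."""
    work = tree.copy()
    tl = TreeLikelihood(work, compress_alignment(msa), model)
    return tl.optimize_branch_lengths(tol=tol, xatol=xatol,
                                      max_rounds=max_rounds)
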