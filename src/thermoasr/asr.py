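"""Tree likelihood and marginal ancestral sequence reconstruction.

The likelihood is the standard pruning recursion over a rooted tree: each
node carries, per alignment column and rate category, the probability of the
data below it conditional on its state.  Gaps and ambiguity codes at leaves
are missing data (all-ones partial vectors), so ancestral states are still
reconstructed at every column.  Per-node, per-column scaling keeps 20-state
partials from underflowing on deep trees.

Marginal reconstruction adds the complementary "outside" pass: for node v,
P(x_v = a | data) ∝ (probability of data above v given a) × (partial below
v given a), mixed over rate categories with weights proportional to each
category's column likelihood.  This is the empirical-Bayes posterior
amino-acid probability per site; the MAP residue per column is reported with
alphabetical tie-breaking for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import IdentityError, TreeError
from .io import AMINO_ACIDS, Alignment, PhyloTree
from .models import N_STATES, SubstitutionModel

#: per-column log-likelihood floor substituted for impossible data
LOG_ZERO = -1e10

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
# amino-acid indices sorted by letter, for alphabetical MAP tie-breaking
_ALPHA_ORDER = sorted(range(N_STATES), key=lambda i: AMINO_ACIDS[i])
_ALPHA_LETTERS = [AMINO_ACIDS[i] for i in _ALPHA_ORDER]


@dataclass
class AncestralProfile:
    """Per-column posterior distribution over the 20 residues at one node."""

    node: str
    probabilities: np.ndarray  # (n_columns, 20), PAML residue order
    map_sequence: str
    map_posterior: np.ndarray  # (n_columns,)


def _encode(alignment: Alignment, labels: list[str]) -> np.ndarray:
    """Integer-code rows for the given labels; −1 marks gap/ambiguity."""
    codes = np.empty((len(labels), alignment.n_columns), dtype=np.int16)
    for r, label in enumerate(labels):
        row = alignment.row(label)
        codes[r] = [_AA_INDEX.get(ch, -1) for ch in row]
    return codes


class _Engine:
    """Shared state for one (tree, alignment, model) likelihood problem."""

    def __init__(self, tree: PhyloTree, alignment: Alignment, model: SubstitutionModel):
        if not tree.rooted:
            raise TreeError("likelihood requires a rooted tree; root it first (MAD)")
        leaf_labels = tree.leaf_labels()
        missing = set(leaf_labels) - set(alignment.ids)
        if missing:
            raise IdentityError(f"leaves without sequences: {sorted(missing)}")
        self.tree = tree
        self.model = model
        self.n_cols = alignment.n_columns
        self.nodes = list(tree.preorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.post = self.nodes[::-1]  # children before parents
        self.leaf_codes = dict(zip(leaf_labels, _encode(alignment, leaf_labels)))
        self.rates = model.category_rates

    def _leaf_partial(self, node) -> np.ndarray:
        codes = self.leaf_codes[node.label]
        partial = np.zeros((self.n_cols, N_STATES))
        observed = codes >= 0
        partial[observed, codes[observed]] = 1.0
        partial[~observed] = 1.0  # missing data
        return partial

    def down_pass(self):
        """Conditional partials per category, with per-node column scaling.

        Returns (partials, contribs, logscale, col_loglik):
          partials[r][i]  — (cols, 20) partial at node i, category r
          contribs[r][i]  — (cols, 20) P_i(t)·partial_i, i.e. node i's branch
                            already applied, as seen from its parent
          logscale[r]     — (cols,) accumulated log scaling at the root
          col_loglik      — (cols,) log-likelihood per column, categories mixed
        """
        k = self.model.k
        partials = [[None] * len(self.nodes) for _ in range(k)]
        contribs = [[None] * len(self.nodes) for _ in range(k)]
        root_scale = []
        cat_col_ll = np.empty((k, self.n_cols))
        pi = self.model.frequencies
        for r in range(k):
            rate = self.rates[r]
            logscale = [np.zeros(self.n_cols) for _ in self.nodes]
            for node in self.post:
                i = self.index[id(node)]
                if node.is_leaf:
                    part = self._leaf_partial(node)
                else:
                    part = np.ones((self.n_cols, N_STATES))
                    for child in node.children:
                        ci = self.index[id(child)]
                        part = part * contribs[r][ci]
                        logscale[i] += logscale[ci]
                    scale = part.max(axis=1)
                    safe = np.where(scale > 0, scale, 1.0)
                    part = part / safe[:, None]
                    with np.errstate(divide="ignore"):
                        logscale[i] += np.where(scale > 0, np.log(safe), LOG_ZERO)
                partials[r][i] = part
                if node is not self.tree.root:
                    P = self.model.transition_matrix(node.length * rate)
                    contribs[r][i] = part @ P.T
            ri = self.index[id(self.tree.root)]
            site = partials[r][ri] @ pi
            cat_col_ll[r] = np.where(site > 0, np.log(np.where(site > 0, site, 1.0)), LOG_ZERO)
            cat_col_ll[r] += logscale[ri]
            root_scale.append(logscale[ri])
        # mix categories with equal prior weight 1/k
        m = cat_col_ll.max(axis=0)
        col_loglik = m + np.log(np.exp(cat_col_ll - m).mean(axis=0))
        bad = col_loglik <= LOG_ZERO / 2
        if np.any(bad):
            warnings.warn(
                f"{int(bad.sum())} column(s) have zero likelihood "
                "(degenerate data, e.g. conflicting states across a zero-length branch)",
                RuntimeWarning,
            )
            col_loglik = np.maximum(col_loglik, LOG_ZERO)
        return partials, contribs, cat_col_ll, col_loglik

    def log_likelihood(self) -> float:
        *_, col_loglik = self.down_pass()
        return float(col_loglik.sum())

    def marginal_profiles(self) -> tuple[dict[str, AncestralProfile], float]:
        partials, contribs, cat_col_ll, col_loglik = self.down_pass()
        k = self.model.k
        pi = self.model.frequencies
        # per-column posterior weight of each rate category
        w = np.exp(cat_col_ll - cat_col_ll.max(axis=0))
        w /= w.sum(axis=0)

        posteriors = {i: np.zeros((self.n_cols, N_STATES)) for i, n in enumerate(self.nodes) if not n.is_leaf}
        for r in range(k):
            rate = self.rates[r]
            outside = [None] * len(self.nodes)
            ri = self.index[id(self.tree.root)]
            outside[ri] = np.broadcast_to(pi, (self.n_cols, N_STATES))
            for node in self.nodes:  # preorder: parents before children
                i = self.index[id(node)]
                if not node.is_leaf:
                    unnorm = outside[i] * partials[r][i]
                    total = unnorm.sum(axis=1, keepdims=True)
                    total[total == 0] = 1.0
                    posteriors[i] += w[r][:, None] * (unnorm / total)
                for child in node.children:
                    if child.is_leaf:
                        continue
                    g = outside[i].copy()
                    for sib in node.children:
                        if sib is not child:
                            g *= contribs[r][self.index[id(sib)]]
                    P = self.model.transition_matrix(child.length * rate)
                    g = g @ P
                    scale = g.max(axis=1, keepdims=True)
                    scale[scale == 0] = 1.0
                    outside[self.index[id(child)]] = g / scale

        profiles: dict[str, AncestralProfile] = {}
        for node in self.nodes:
            if node.is_leaf:
                continue
            i = self.index[id(node)]
            probs = posteriors[i]
            probs = probs / probs.sum(axis=1, keepdims=True)
            alpha_view = probs[:, _ALPHA_ORDER]
            best = alpha_view.argmax(axis=1)
            map_seq = "".join(_ALPHA_LETTERS[j] for j in best)
            map_post = alpha_view[np.arange(self.n_cols), best]
            label = node.label
            if not label:
                raise IdentityError("internal nodes must be labeled before reconstruction")
            profiles[label] = AncestralProfile(label, probs, map_seq, map_post)
        return profiles, float(col_loglik.sum())


def tree_log_likelihood(
    tree: PhyloTree, alignment: Alignment, model: SubstitutionModel
) -> float:
    """Log-likelihood of the alignment on a rooted tree under the model,
    summed over columns and mixed over equal-prior rate categories."""
    return _Engine(tree, alignment, model).log_likelihood()


def marginal_ancestral_profiles(
    tree: PhyloTree, alignment: Alignment, model: SubstitutionModel
) -> dict[str, AncestralProfile]:
    """Marginal posterior residue distributions at every internal node.

    Internal nodes are labeled (preorder ``N1…``) if they are not already.
    """
    if any(not n.label for n in tree.internal_nodes()):
        tree.assign_internal_labels()
    profiles, _ = _Engine(tree, alignment, model).marginal_profiles()
    return profiles


@dataclass
class AlphaEstimate:
    alpha: float
    log_likelihood: float
    at_boundary: bool


def estimate_alpha(
    tree: PhyloTree,
    alignment: Alignment,
    model: SubstitutionModel,
    bounds: tuple[float, float] = (0.02, 100.0),
    tol: float = 1e-4,
) -> AlphaEstimate:
    """Maximum-likelihood gamma shape by bounded Brent search.

    The returned log-likelihood is never below the starting model's; a fit
    that runs into either bound is flagged (``at_boundary``) rather than
    treated as converged.
    """
    def negll(alpha: float) -> float:
        return -tree_log_likelihood(tree, alignment, model.with_alpha(alpha))

    res = minimize_scalar(negll, bounds=bounds, method="bounded", options={"xatol": tol})
    alpha, ll = float(res.x), -float(res.fun)
    ll0 = tree_log_likelihood(tree, alignment, model)
    if ll0 > ll:
        alpha, ll = model.alpha, ll0
    at_boundary = alpha - bounds[0] < 10 * tol or bounds[1] - alpha < max(10 * tol, 1e-2 * bounds[1])
    if at_boundary:
        warnings.warn(
            f"gamma-shape estimate {alpha:.4g} sits at the search boundary {bounds}",
            RuntimeWarning,
        )
    return AlphaEstimate(alpha, ll, at_boundary)


def optimize_branch_lengths(
    tree: PhyloTree,
    alignment: Alignment,
    model: SubstitutionModel,
    max_length: float = 20.0,
    tol: float = 1e-3,
    max_sweeps: int = 20,
) -> tuple[PhyloTree, float]:
    """Coordinate-wise ML branch lengths (Brent per branch, sweeps to
    convergence).  Returns a new tree; the input is untouched.  Off by
    default in the pipeline — input lengths are normally taken as fixed."""
    work = tree.copy()
    edges = [n for n in work.preorder() if n is not work.root]
    ll = tree_log_likelihood(work, alignment, model)
    for _ in range(max_sweeps):
        for node in edges:
            orig = node.length

            def negll(x: float, node=node) -> float:
                node.length = x
                return -tree_log_likelihood(work, alignment, model)

            res = minimize_scalar(
                negll, bounds=(0.0, max_length), method="bounded", options={"xatol": 1e-4}
            )
            if -res.fun >= ll:
                node.length = float(res.x)
                new_ll = -float(res.fun)
            else:  # numerical non-improvement: keep previous length
                new_ll = -negll(orig)
        gain = new_ll - ll
        ll = new_ll
        if gain < tol:
            break
    return work, ll
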