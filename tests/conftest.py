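"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own algorithms: tree
likelihoods and marginals are computed by exhaustive enumeration over all
internal-state assignments, matrix exponentials by scipy's scaling-and-
squaring, discrete-gamma rates by numerical quadrature, and MAD positions by
dense grid search.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from thermoasr import Alignment, SubstitutionModel, parse_newick
from thermoasr.io import AMINO_ACIDS

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def four_leaf_tree():
    return parse_newick("((A:0.2,B:0.4)X:0.3,(C:0.1,D:0.5)Y:0.6)R;")


@pytest.fixture
def four_leaf_alignment():
    return Alignment(["A", "B", "C", "D"], ["RKD", "QNA", "RKD", "GG-"])


@pytest.fixture
def lg_k2_model():
    return SubstitutionModel.from_name("LG", alpha=0.7, k=2)


# ---------------------------------------------------------------------------
# enumeration oracle for likelihood and marginals on tiny rooted trees
# ---------------------------------------------------------------------------

def _codes(alignment: Alignment, label: str) -> list[int]:
    return [AMINO_ACIDS.index(c) if c in AMINO_ACIDS else -1 for c in alignment.row(label)]


def enum_column_likelihoods(tree, alignment, model) -> np.ndarray:
    """Per-column likelihoods by summing over every internal-state assignment
    and rate category (equal category priors)."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    idx = {id(n): i for i, n in enumerate(internals)}
    pi = model.frequencies
    rates = model.category_rates
    ncol = alignment.n_columns
    out = np.zeros(ncol)
    for rate in rates:
        P = {
            id(n): model.transition_matrix(n.length * rate)
            for n in tree.preorder()
            if n is not tree.root
        }
        for col in range(ncol):
            total = 0.0
            for assign in itertools.product(range(20), repeat=len(internals)):
                prob = pi[assign[idx[id(tree.root)]]]
                for node in tree.preorder():
                    if node is tree.root:
                        continue
                    a = assign[idx[id(node.parent)]]
                    if node.is_leaf:
                        c = _codes(alignment, node.label)[col]
                        prob *= 1.0 if c < 0 else P[id(node)][a, c]
                    else:
                        prob *= P[id(node)][a, assign[idx[id(node)]]]
                total += prob
            out[col] += total / len(rates)
    return out


def enum_marginal_posterior(tree, alignment, model, node_label: str, col: int) -> np.ndarray:
    """Posterior state distribution at one internal node and column, by
    enumeration (categories mixed by their likelihood share)."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    idx = {id(n): i for i, n in enumerate(internals)}
    target = next(i for i, n in enumerate(internals) if n.label == node_label)
    pi = model.frequencies
    post = np.zeros(20)
    for rate in model.category_rates:
        P = {
            id(n): model.transition_matrix(n.length * rate)
            for n in tree.preorder()
            if n is not tree.root
        }
        for assign in itertools.product(range(20), repeat=len(internals)):
            prob = pi[assign[idx[id(tree.root)]]]
            for node in tree.preorder():
                if node is tree.root:
                    continue
                a = assign[idx[id(node.parent)]]
                if node.is_leaf:
                    c = _codes(alignment, node.label)[col]
                    prob *= 1.0 if c < 0 else P[id(node)][a, c]
                else:
                    prob *= P[id(node)][a, assign[idx[id(node)]]]
            post[assign[target]] += prob
    return post / post.sum()


def quadrature_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Category mean rates by numerical integration of the gamma density."""
    from scipy import integrate, stats

    dist = stats.gamma(a=alpha, scale=1.0 / alpha)
    bounds = [0.0] + [dist.ppf(i / k) for i in range(1, k)] + [np.inf]
    rates = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        val, _ = integrate.quad(lambda x: x * dist.pdf(x), lo, hi, limit=200)
        rates.append(val * k)
    rates = np.array(rates)
    return rates / rates.mean()
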