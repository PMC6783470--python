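"""Empirical amino-acid substitution models with discrete-gamma rate
heterogeneity.

A model is a reversible 20-state continuous-time Markov chain assembled from
a symmetric exchangeability matrix (LG shipped as packaged data, WAG
optional) and a vector of equilibrium frequencies — either the model's own or
alignment-empirical "+F" frequencies.  The rate matrix is normalized to one
expected substitution per site so branch lengths read as substitutions/site.

Among-site rate variation uses the standard k-category discrete-gamma
approximation: equal-probability slices of a Gamma(alpha, alpha) distribution,
each represented by its conditional mean rate, normalized to average 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc, gammaincinv

from .errors import RangeError
from .io import AMINO_ACIDS, Alignment

N_STATES = 20


def _load_dat(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML-style lower-triangle exchangeability table + frequencies."""
    text = resources.files("thermoasr.data").joinpath(f"{name}.dat").read_text()
    chunks = text.split()
    vals = np.array([float(x) for x in chunks])
    if vals.size != 190 + 20:
        raise RangeError(f"{name}.dat: expected 210 numbers, got {vals.size}")
    R = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            R[i, j] = R[j, i] = vals[k]
            k += 1
    freqs = vals[190:]
    return R, freqs / freqs.sum()


_EXCHANGE_CACHE: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def load_exchangeabilities(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (exchangeability matrix, model frequencies) for ``LG`` or ``WAG``."""
    key = name.lower()
    if key not in ("lg", "wag"):
        raise RangeError(f"unknown substitution model {name!r}; available: LG, WAG")
    if key not in _EXCHANGE_CACHE:
        _EXCHANGE_CACHE[key] = _load_dat(key)
    R, f = _EXCHANGE_CACHE[key]
    return R.copy(), f.copy()


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability Gamma(alpha, alpha) slices.

    Each category's rate is the conditional mean of its quantile slice,
    computed in closed form from the regularized incomplete gamma function;
    rates are nondecreasing and average exactly 1.
    """
    if not (alpha > 0):
        raise RangeError(f"gamma shape must be positive, got {alpha}")
    if int(k) != k or k < 1:
        raise RangeError(f"category count must be a positive integer, got {k}")
    k = int(k)
    if k == 1:
        return np.ones(1)
    # slice boundaries: quantiles of Gamma(shape=alpha, rate=alpha)
    probs = np.arange(1, k) / k
    bounds = gammaincinv(alpha, probs) / alpha
    # E[X · 1{a<X<b}] for Gamma(alpha, alpha) is I(alpha+1, alpha·b) − I(alpha+1, alpha·a)
    upper = gammainc(alpha + 1, alpha * bounds)
    cum = np.concatenate(([0.0], upper, [1.0]))
    rates = k * np.diff(cum)
    return rates / rates.mean()


def empirical_frequencies(alignment: Alignment, smoothing: float = 1.0) -> np.ndarray:
    """"+F" frequencies: residue counts over the alignment with add-one
    smoothing (gaps and ambiguity codes not counted)."""
    counts = np.full(N_STATES, smoothing)
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for row in alignment.rows:
        for ch in row:
            i = index.get(ch)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()


@dataclass
class SubstitutionModel:
    """A reversible amino-acid CTMC plus discrete-gamma rate categories.

    Q is built as ``Q_ij = R_ij · π_j`` (i ≠ j), diagonal set so rows sum to
    zero, then scaled so the expected substitution rate at equilibrium,
    ``−Σ_i π_i Q_ii``, equals 1.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float = 1.0
    k: int = 10
    name: str = "custom"
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        R = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if R.shape != (N_STATES, N_STATES):
            raise RangeError(f"exchangeability matrix must be 20×20, got {R.shape}")
        if not np.allclose(R, R.T):
            raise RangeError("exchangeability matrix must be symmetric")
        if np.any(R < 0):
            raise RangeError("exchangeabilities must be nonnegative")
        if pi.shape != (N_STATES,):
            raise RangeError("frequency vector must have 20 entries")
        if np.any(pi <= 0):
            raise RangeError("all equilibrium frequencies must be positive")
        if abs(pi.sum() - 1.0) > 1e-12:
            pi = pi / pi.sum()
        if not (self.alpha > 0):
            raise RangeError(f"gamma shape must be positive, got {self.alpha}")
        if self.k < 1:
            raise RangeError(f"need at least one rate category, got {self.k}")
        self.exchangeabilities = R
        self.frequencies = pi

    @classmethod
    def from_name(
        cls,
        name: str = "LG",
        alignment: Alignment | None = None,
        alpha: float = 1.0,
        k: int = 10,
    ) -> "SubstitutionModel":
        """Build e.g. ``LG+F+G10``: empirical frequencies if an alignment is
        given, otherwise the model's own."""
        R, model_freqs = load_exchangeabilities(name)
        pi = empirical_frequencies(alignment) if alignment is not None else model_freqs
        label = f"{name.upper()}{'+F' if alignment is not None else ''}+G{k}"
        return cls(R, pi, alpha=alpha, k=k, name=label)

    # -- rate matrix --------------------------------------------------------

    @property
    def rate_matrix(self) -> np.ndarray:
        """The normalized generator Q (one expected substitution per site)."""
        pi = self.frequencies
        Q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        Q[np.diag_indices(N_STATES)] = -Q.sum(axis=1)
        mu = -float(np.dot(pi, np.diag(Q)))
        return Q / mu

    def _eigensystem(self):
        # Q is similar to the symmetric matrix diag(√π) Q diag(1/√π);
        # eigendecompose once and cache.
        if self._eig is None:
            pi = self.frequencies
            sqrt_pi = np.sqrt(pi)
            S = self.rate_matrix * (sqrt_pi[:, None] / sqrt_pi[None, :])
            S = 0.5 * (S + S.T)  # enforce exact symmetry against round-off
            w, V = np.linalg.eigh(S)
            left = V.T * sqrt_pi[None, :]      # V^T diag(√π)
            right = V / sqrt_pi[:, None]       # diag(1/√π) V
            self._eig = (w, right, left)
        return self._eig

    def transition_matrix(self, distance: float) -> np.ndarray:
        """P(t) = exp(Q·distance); rows sum to 1, entries clipped at 0."""
        if distance < 0:
            raise RangeError(f"negative evolutionary distance {distance}")
        if distance == 0:
            return np.eye(N_STATES)
        w, right, left = self._eigensystem()
        P = (right * np.exp(w * distance)[None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    @property
    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.k)

    def with_alpha(self, alpha: float) -> "SubstitutionModel":
        m = SubstitutionModel(
            self.exchangeabilities, self.frequencies, alpha=alpha, k=self.k, name=self.name
        )
        m._eig = self._eig  # Q unchanged; reuse the cached eigensystem
        return m


def transition_matrix(model: SubstitutionModel, distance: float) -> np.ndarray:
    """Functional alias for :meth:`SubstitutionModel.transition_matrix`."""
    return model.transition_matrix(distance)
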