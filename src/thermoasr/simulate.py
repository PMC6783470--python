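"""Synthetic data with recorded ground truth.

Two emulations, matching the statistical structure the analysis assumes:

* a calibration panel — species with known OGTs whose sequence CvP bias
  follows a linear CvP–OGT law, with an over-represented 37 °C mesophile
  group and optional off-line psychrophiles; and
* alignments evolved along a known tree under a latent OGT trajectory:
  OGT diffuses from the root as Brownian motion, each node's OGT is
  translated into equilibrium amino-acid frequencies through the inverse of
  the calibration line, and sequences evolve non-stationarily (each branch
  uses its child's frequencies with shared LG exchangeabilities).

Every generator is deterministic under its seed, and every latent quantity
(node OGTs, node frequencies, target CvPs) is recorded in a
:class:`SyntheticTruth` so parameter-recovery tests can compare estimates
against what was actually simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CHARGED, POLAR, CalibrationModel, HUA2019, predict_ogt
from .errors import RangeError, TreeError
from .io import AMINO_ACIDS, Alignment, Node, OGTRecord, PhyloTree
from .models import N_STATES, SubstitutionModel, discrete_gamma_rates, load_exchangeabilities

_CHARGED_IDX = np.array([i for i, aa in enumerate(AMINO_ACIDS) if aa in CHARGED])
_POLAR_IDX = np.array([i for i, aa in enumerate(AMINO_ACIDS) if aa in POLAR])
_OTHER_IDX = np.array(
    [i for i, aa in enumerate(AMINO_ACIDS) if aa not in CHARGED and aa not in POLAR]
)

#: OGT clamp for simulated trajectories, °C
OGT_FLOOR, OGT_CEIL = 5.0, 110.0


@dataclass
class SyntheticTruth:
    """Ground truth accompanying one simulated dataset."""

    tree: PhyloTree | None = None
    node_ogt: dict[str, float] = field(default_factory=dict)
    node_frequencies: dict[str, np.ndarray] = field(default_factory=dict)
    node_sequences: dict[str, str] = field(default_factory=dict)
    target_cvp: dict[tuple[str, str], float] = field(default_factory=dict)
    realized_cvp: dict[tuple[str, str], float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def simulate_yule_tree(n_leaves: int, mean_branch_length: float, seed: int) -> PhyloTree:
    """Pure-birth topology by uniform leaf splitting; i.i.d. exponential
    branch lengths with the given mean.  Leaves are ``T1…Tn``; internal
    nodes are labeled ``N1…`` in preorder."""
    if n_leaves < 3:
        raise RangeError(f"need at least 3 leaves, got {n_leaves}")
    if not (mean_branch_length > 0):
        raise RangeError("mean branch length must be positive")
    rng = np.random.default_rng(seed)
    root = Node()
    leaves = [root.add_child(Node()), root.add_child(Node())]
    while len(leaves) < n_leaves:
        split = leaves.pop(rng.integers(len(leaves)))
        leaves.append(split.add_child(Node()))
        leaves.append(split.add_child(Node()))
    tree_nodes = PhyloTree.__new__(PhyloTree)  # labels not assigned yet
    tree_nodes.root = root
    order = [n for n in tree_nodes.preorder() if n is not root]
    lengths = rng.exponential(mean_branch_length, size=len(order))
    for node, ln in zip(order, lengths):
        node.length = float(ln)
    for i, leaf in enumerate([n for n in tree_nodes.preorder() if n.is_leaf], start=1):
        leaf.label = f"T{i}"
    tree = PhyloTree(root)
    tree.assign_internal_labels()
    return tree


def simulate_ogt_trajectory(
    tree: PhyloTree, root_ogt: float, sigma: float, seed: int
) -> dict[str, float]:
    """Brownian OGT along the tree: child = parent + N(0, sigma²·branch),
    clamped to [5, 110] °C.  ``sigma`` is in °C per √(substitutions/site)."""
    if not tree.rooted:
        raise TreeError("OGT trajectory needs a rooted tree")
    if sigma < 0:
        raise RangeError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    ogt: dict[int, float] = {id(tree.root): float(root_ogt)}
    out: dict[str, float] = {}
    for node in tree.preorder():
        if node is not tree.root:
            parent = ogt[id(node.parent)]
            step = rng.normal(0.0, sigma * np.sqrt(node.length)) if sigma > 0 else 0.0
            ogt[id(node)] = float(np.clip(parent + step, OGT_FLOOR, OGT_CEIL))
        if not node.label:
            raise TreeError("all nodes must be labeled before simulating OGTs")
        out[node.label] = ogt[id(node)]
    return out


def frequency_cvp(freqs: np.ndarray) -> float:
    """CvP bias (percentage points) of a residue frequency vector."""
    return 100.0 * float(freqs[_CHARGED_IDX].sum() - freqs[_POLAR_IDX].sum())


def composition_for_ogt(
    target_ogt: float,
    calibration: CalibrationModel = HUA2019,
    base_frequencies: np.ndarray | None = None,
    min_frequency: float = 1e-4,
) -> np.ndarray:
    """Frequencies whose CvP maps to ``target_ogt`` under the calibration.

    Probability mass is shifted between the polar and charged sets
    (proportionally within each set); the 12 unclassified residues are left
    untouched, so the CvP signal is isolated from other composition changes.
    """
    if calibration.slope == 0:
        raise RangeError("calibration slope is zero; OGT cannot be inverted")
    if base_frequencies is None:
        base_frequencies = load_exchangeabilities("LG")[1]
    pi = np.asarray(base_frequencies, dtype=float)
    if pi.shape != (N_STATES,) or np.any(pi <= 0):
        raise RangeError("base frequencies must be 20 positive values")
    pi = pi / pi.sum()

    target_x = (target_ogt - calibration.intercept) / calibration.slope
    mass = float(pi[_CHARGED_IDX].sum() + pi[_POLAR_IDX].sum())
    p_charged = (mass + target_x / 100.0) / 2.0
    p_polar = mass - p_charged

    out = pi.copy()
    out[_CHARGED_IDX] = pi[_CHARGED_IDX] * (p_charged / pi[_CHARGED_IDX].sum())
    out[_POLAR_IDX] = pi[_POLAR_IDX] * (p_polar / pi[_POLAR_IDX].sum())
    if np.any(out < min_frequency):
        lo = predict_ogt(calibration, -100.0 * mass * (1 - 1e-3))
        hi = predict_ogt(calibration, 100.0 * mass * (1 - 1e-3))
        lo, hi = min(lo, hi), max(lo, hi)
        raise RangeError(
            f"target OGT {target_ogt} °C needs a frequency below {min_frequency}; "
            f"roughly feasible OGT interval for these base frequencies: "
            f"[{lo:.1f}, {hi:.1f}] °C"
        )
    out = out / out.sum()
    return out


def simulate_alignment(
    tree: PhyloTree,
    node_frequencies: dict[str, np.ndarray],
    n_columns: int,
    exchangeabilities: np.ndarray | None = None,
    alpha: float = 1.0,
    k: int = 4,
    seed: int = 0,
) -> tuple[Alignment, SyntheticTruth]:
    """Evolve an ungapped alignment along the tree, non-stationarily.

    The root sequence is drawn i.i.d. from the root node's frequencies; on
    each branch every column evolves by the transition matrix built from the
    CHILD node's frequencies (shared exchangeabilities).  Each column's rate
    category is drawn once at the root and inherited, matching the
    discrete-gamma likelihood's assumption.  No indels.
    """
    if n_columns < 1:
        raise RangeError("need at least one column")
    if not tree.rooted:
        raise TreeError("simulation needs a rooted tree")
    if exchangeabilities is None:
        exchangeabilities = load_exchangeabilities("LG")[0]
    for node in tree.preorder():
        if node.label not in node_frequencies:
            raise RangeError(f"no frequencies supplied for node {node.label!r}")

    rng = np.random.default_rng(seed)
    rates = discrete_gamma_rates(alpha, k)
    categories = rng.integers(k, size=n_columns)
    col_rates = rates[categories]

    models = {
        label: SubstitutionModel(exchangeabilities, freqs, alpha=alpha, k=k)
        for label, freqs in node_frequencies.items()
    }

    states: dict[int, np.ndarray] = {}
    root_pi = np.asarray(node_frequencies[tree.root.label], dtype=float)
    states[id(tree.root)] = rng.choice(N_STATES, size=n_columns, p=root_pi / root_pi.sum())

    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[id(node.parent)]
        child_states = np.empty(n_columns, dtype=np.int64)
        model = models[node.label]
        for r in range(k):
            cols = np.where(categories == r)[0]
            if cols.size == 0:
                continue
            P = model.transition_matrix(node.length * rates[r])
            cum = P.cumsum(axis=1)
            u = rng.random(cols.size)
            child_states[cols] = (u[:, None] > cum[parent_states[cols]]).sum(axis=1)
        states[id(node)] = child_states

    leaves = tree.leaves()
    ids = [l.label for l in leaves]
    rows = ["".join(AMINO_ACIDS[s] for s in states[id(l)]) for l in leaves]
    aln = Alignment(ids, rows)
    truth = SyntheticTruth(
        tree=tree,
        node_frequencies={lab: np.asarray(f, dtype=float) for lab, f in node_frequencies.items()},
        node_sequences={
            n.label: "".join(AMINO_ACIDS[s] for s in states[id(n)]) for n in tree.preorder()
        },
        params={
            "n_columns": n_columns,
            "alpha": alpha,
            "k": k,
            "seed": seed,
            "category_rates": col_rates.tolist(),
        },
    )
    return aln, truth


def _sequence_from_counts(counts: np.ndarray, rng: np.random.Generator) -> str:
    residues = np.repeat(np.arange(N_STATES), counts)
    rng.shuffle(residues)
    return "".join(AMINO_ACIDS[s] for s in residues)


def _counts_for_cvp(target_cvp: float, length: int, base: np.ndarray) -> np.ndarray:
    """Integer residue counts whose CvP is the closest count-grid value to
    ``target_cvp`` (quantization |error| ≤ 100/length percentage points)."""
    base = base / base.sum()
    counts = np.floor(base * length).astype(int)
    # largest-remainder completion to exactly `length`
    rem = base * length - counts
    for i in np.argsort(-rem)[: length - counts.sum()]:
        counts[i] += 1
    n_classified = int(counts[_CHARGED_IDX].sum() + counts[_POLAR_IDX].sum())
    n_charged = int(round((n_classified + target_cvp / 100.0 * length) / 2.0))
    n_charged = min(max(n_charged, 0), n_classified)
    _redistribute(counts, _CHARGED_IDX, n_charged, base)
    _redistribute(counts, _POLAR_IDX, n_classified - n_charged, base)
    return counts


def _redistribute(counts: np.ndarray, idx: np.ndarray, total: int, base: np.ndarray) -> None:
    w = base[idx] / base[idx].sum()
    sub = np.floor(w * total).astype(int)
    rem = w * total - sub
    for i in np.argsort(-rem)[: total - sub.sum()]:
        sub[i] += 1
    counts[idx] = sub


def make_calibration_panel(
    n_species: int = 37,
    ogt_range: tuple[float, float] = (40.0, 100.0),
    noise_sd: float = 0.0,
    n_at_37: int = 18,
    n_psychrophiles: int = 0,
    true_slope: float = HUA2019.slope,
    true_intercept: float = HUA2019.intercept,
    seq_length: int = 20000,
    seed: int = 0,
) -> tuple[list[OGTRecord], Alignment, SyntheticTruth]:
    """A calibration panel emulating the skew of real OGT surveys.

    ``n_at_37`` species sit at exactly 37 °C (the over-represented mesophile
    group); psychrophiles get OGTs below 20 °C, a flag, and a CvP displaced
    off the calibration line (they evolve under different constraints);
    remaining species draw OGTs uniformly from ``ogt_range``.  Each species'
    target CvP is the true line's value plus Normal(0, noise_sd) noise, and
    its sequence realizes that target on the residue-count grid (within
    100/seq_length percentage points); exact targets are in the truth.
    """
    if n_species < 3:
        raise RangeError("panel needs at least 3 species")
    if n_at_37 + n_psychrophiles > n_species:
        raise RangeError("n_at_37 + n_psychrophiles exceeds n_species")
    rng = np.random.default_rng(seed)
    base = load_exchangeabilities("LG")[1]

    ogts: list[tuple[float, bool]] = [(37.0, False)] * n_at_37
    ogts += [(float(rng.uniform(2.0, 15.0)), True) for _ in range(n_psychrophiles)]
    n_rest = n_species - n_at_37 - n_psychrophiles
    ogts += [(float(rng.uniform(*ogt_range)), False) for _ in range(n_rest)]

    records: list[OGTRecord] = []
    ids, rows = [], []
    truth = SyntheticTruth(
        params={
            "true_slope": true_slope,
            "true_intercept": true_intercept,
            "noise_sd": noise_sd,
            "seq_length": seq_length,
            "seed": seed,
        }
    )
    for i, (ogt, psy) in enumerate(ogts, start=1):
        taxon = f"S{i}"
        target = (ogt - true_intercept) / true_slope
        if psy:
            target += 3.0  # psychrophiles sit off the line by construction
        if noise_sd > 0:
            target += float(rng.normal(0.0, noise_sd))
        counts = _counts_for_cvp(target, seq_length, base)
        seq = _sequence_from_counts(counts, rng)
        records.append(OGTRecord(taxon, ogt, "1", psy))
        ids.append(taxon)
        rows.append(seq)
        truth.target_cvp[(taxon, "1")] = target
        realized = 100.0 * (counts[_CHARGED_IDX].sum() - counts[_POLAR_IDX].sum()) / seq_length
        truth.realized_cvp[(taxon, "1")] = float(realized)
    return records, Alignment(ids, rows), truth


def make_ogt_dataset(
    n_leaves: int = 32,
    n_columns: int = 3000,
    mean_branch_length: float = 0.15,
    root_ogt: float = 95.0,
    sigma: float = 8.0,
    alpha: float = 0.8,
    k: int = 4,
    calibration: CalibrationModel = HUA2019,
    seed: int = 0,
) -> tuple[PhyloTree, Alignment, list[OGTRecord], SyntheticTruth]:
    """End-to-end dataset: Yule tree, Brownian OGT trajectory, per-node
    compositions from the inverted calibration line, non-stationary
    alignment, and an exact leaf OGT table.  Defaults are the package's
    standard recovery-suite conditions."""
    tree = simulate_yule_tree(n_leaves, mean_branch_length, seed)
    node_ogt = simulate_ogt_trajectory(tree, root_ogt, sigma, seed + 1)
    base = load_exchangeabilities("LG")[1]
    node_freqs = {
        label: composition_for_ogt(ogt, calibration, base)
        for label, ogt in node_ogt.items()
    }
    R = load_exchangeabilities("LG")[0]
    aln, truth = simulate_alignment(tree, node_freqs, n_columns, R, alpha, k, seed + 2)
    truth.node_ogt = node_ogt
    truth.params.update(
        {
            "root_ogt": root_ogt,
            "sigma": sigma,
            "mean_branch_length": mean_branch_length,
            "n_leaves": n_leaves,
        }
    )
    records = [OGTRecord(label, node_ogt[label]) for label in aln.ids]
    return tree, aln, records, truth
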