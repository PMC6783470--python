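"""CvP bias and the linear CvP → optimal-growth-temperature calibration.

The CvP bias of a protein is the difference between the proportions of
charged residues (R, K, D, E) and polar non-charged residues (Q, N, S, T),
expressed here in percentage points.  It is an established composition proxy
for thermal adaptation: thermophile proteins trade polar surface residues for
charged ones, so CvP rises with optimal growth temperature (OGT).

Calibration is ordinary least squares of OGT on CvP over a panel of extant
taxa with known OGTs, with two corrections applied before fitting:
psychrophiles are excluded (their composition evolves under different
constraints), and the heavily over-represented mesophile group — taxa whose
reported OGT is exactly 37 °C, largely host-associated isolates — is collapsed
to a single point at the group's mean CvP so it cannot dominate the fit.

A published calibration for concatenated McrABG markers,
``OGT = 6.7548 · CvP + 13.858`` (R² = 0.7288), ships as the named default
``"hua2019"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .errors import (
    ClassificationError,
    DegenerateInputError,
    IdentityError,
    InsufficientDataError,
    RangeError,
    SingularFitError,
)
from .io import AMBIGUOUS, AMINO_ACIDS, GAP, OGTRecord

#: charged residues: arginine, lysine, aspartate, glutamate
CHARGED = frozenset("RKDE")
#: polar non-charged residues: glutamine, asparagine, serine, threonine
POLAR = frozenset("QNST")


def classify_residue(aa: str) -> str:
    """Classify one canonical residue as ``"charged"``, ``"polar"`` or ``"other"``.

    Gaps and ambiguity codes are not classifiable; callers must exclude them
    before counting.
    """
    if len(aa) != 1 or aa.upper() not in AMINO_ACIDS:
        raise ClassificationError(f"not a canonical amino acid: {aa!r}")
    aa = aa.upper()
    if aa in CHARGED:
        return "charged"
    if aa in POLAR:
        return "polar"
    return "other"


def cvp_bias(sequence: str) -> float:
    """CvP bias of a (possibly gapped) protein sequence, in percentage points.

    Returns ``100 · (n_charged − n_polar) / n_counted`` where ``n_counted``
    counts canonical residues only; gaps and X/B/Z are excluded from both
    numerator and denominator so they neither create nor dilute the bias.
    """
    seq = sequence.upper()
    n_charged = n_polar = n_counted = 0
    for ch in seq:
        if ch == GAP or ch in AMBIGUOUS or ch == ".":
            continue
        if ch not in AMINO_ACIDS:
            raise ClassificationError(f"illegal residue {ch!r} in sequence")
        n_counted += 1
        if ch in CHARGED:
            n_charged += 1
        elif ch in POLAR:
            n_polar += 1
    if n_counted == 0:
        raise DegenerateInputError("no canonical residues left after removing gaps/ambiguity")
    return 100.0 * (n_charged - n_polar) / n_counted


@dataclass
class CalibrationModel:
    """A linear CvP → OGT map with fit diagnostics.

    slope is in °C per CvP percentage point, intercept in °C.  ``n_points``
    is 0 for published models whose panel is not shipped.
    """

    slope: float
    intercept: float
    r_squared: float = float("nan")
    n_points: int = 0
    p_value: float = float("nan")
    note: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise RangeError("calibration coefficients must be finite")
        if math.isfinite(self.r_squared) and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise RangeError(f"r_squared {self.r_squared} outside [0, 1]")


#: the published concatenated-McrABG calibration (117-genome methanogen panel)
HUA2019 = CalibrationModel(
    slope=6.7548,
    intercept=13.858,
    r_squared=0.7288,
    n_points=0,
    note="published McrABG CvP-OGT regression (hua2019)",
)

NAMED_CALIBRATIONS: dict[str, CalibrationModel] = {"hua2019": HUA2019}


def get_calibration(name: str) -> CalibrationModel:
    try:
        return NAMED_CALIBRATIONS[name]
    except KeyError:
        raise IdentityError(
            f"unknown calibration {name!r}; available: {sorted(NAMED_CALIBRATIONS)}"
        ) from None


@dataclass(frozen=True)
class CalibrationPoint:
    """One (CvP, OGT) point entering the regression; ``sources`` lists the
    (taxon, copy_id) pairs collapsed into it."""

    cvp: float
    ogt: float
    sources: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not (-100.0 <= self.cvp <= 100.0):
            raise RangeError(f"CvP {self.cvp} outside [-100, 100]")


def build_calibration_points(
    records: list[OGTRecord],
    cvps: dict[tuple[str, str], float],
    *,
    exclude_psychrophiles: bool = True,
    collapse_ogt: float | None = 37.0,
    collapse_duplicates: bool = False,
) -> list[CalibrationPoint]:
    """Turn OGT records plus per-(taxon, copy) CvP values into fit points.

    Steps, in order: drop psychrophiles (default on); one provisional point
    per remaining (taxon, copy); replace every group of points sharing the
    collapse temperature (default 37 °C) — or, with ``collapse_duplicates``,
    every group sharing any duplicated OGT — by a single point at the group's
    mean CvP; sort by (OGT, CvP).
    """
    kept = [r for r in records if not (exclude_psychrophiles and r.psychrophile)]
    if not kept:
        raise DegenerateInputError("no records left after psychrophile exclusion")

    provisional: list[tuple[float, float, tuple[str, str]]] = []
    for rec in kept:
        key = (rec.taxon, rec.copy_id)
        if key not in cvps:
            raise IdentityError(f"no CvP value supplied for {key}")
        provisional.append((cvps[key], rec.ogt, key))

    collapse_temps: set[float] = set()
    if collapse_duplicates:
        ogts = [p[1] for p in provisional]
        collapse_temps = {t for t in ogts if ogts.count(t) > 1}
    elif collapse_ogt is not None:
        collapse_temps = {collapse_ogt}

    points: list[CalibrationPoint] = []
    for temp in sorted(collapse_temps):
        group = [p for p in provisional if p[1] == temp]
        if not group:
            continue
        mean_cvp = sum(p[0] for p in group) / len(group)
        points.append(
            CalibrationPoint(mean_cvp, temp, tuple(sorted(p[2] for p in group)))
        )
    for cvp, ogt, key in provisional:
        if ogt not in collapse_temps:
            points.append(CalibrationPoint(cvp, ogt, (key,)))

    points.sort(key=lambda p: (p.ogt, p.cvp))
    return points


def fit_calibration(points: list[CalibrationPoint]) -> CalibrationModel:
    """Ordinary least squares of OGT on CvP.

    Requires at least 3 points spanning at least 2 distinct CvP values.
    R² is the squared Pearson correlation; the slope's two-sided t-test
    p-value is carried as a diagnostic.
    """
    if len(points) < 3:
        raise InsufficientDataError(f"need ≥ 3 calibration points, got {len(points)}")
    xs = [p.cvp for p in points]
    ys = [p.ogt for p in points]
    if len(set(xs)) < 2:
        raise SingularFitError("all CvP values identical; slope is undefined")
    res = stats.linregress(xs, ys)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_points=len(points),
        p_value=float(res.pvalue),
        note="fitted from calibration panel",
    )


def predict_ogt(model: CalibrationModel, cvp: float) -> float:
    """Predicted OGT (°C) at a given CvP bias (percentage points)."""
    if not math.isfinite(cvp):
        raise RangeError(f"non-finite CvP {cvp}")
    return model.slope * cvp + model.intercept


def expected_cvp(profile) -> float:
    """Posterior-expected CvP of an ancestral profile, in percentage points.

    ``100 · mean over columns of (P(charged) − P(polar))`` under the
    per-column posterior distributions; equals :func:`cvp_bias` of the
    sequence when every column is a point mass.
    """
    probs = profile.probabilities
    total = probs.sum(axis=1)
    if abs(float(total.max()) - 1.0) > 1e-9 or abs(float(total.min()) - 1.0) > 1e-9:
        raise DegenerateInputError("profile columns must each sum to 1")
    charged_idx = [i for i, aa in enumerate(AMINO_ACIDS) if aa in CHARGED]
    polar_idx = [i for i, aa in enumerate(AMINO_ACIDS) if aa in POLAR]
    diff = probs[:, charged_idx].sum(axis=1) - probs[:, polar_idx].sum(axis=1)
    return 100.0 * float(diff.mean())


def export_calibration_tsv(model: CalibrationModel, points: list[CalibrationPoint], path) -> None:
    """Write the fitted coefficients plus the point list as a TSV."""
    with open(path, "w") as fh:
        fh.write(f"# slope\t{model.slope:.6f}\n")
        fh.write(f"# intercept\t{model.intercept:.6f}\n")
        fh.write(f"# r_squared\t{model.r_squared:.6f}\n")
        fh.write(f"# n_points\t{model.n_points}\n")
        fh.write("cvp\togt_celsius\tsources\n")
        for p in points:
            src = ",".join(f"{t}|{c}" for t, c in p.sources)
            fh.write(f"{p.cvp:.6f}\t{p.ogt:.6f}\t{src}\n")
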