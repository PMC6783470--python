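"""End-to-end orchestration: root → (optional model fitting) → marginal
ancestral reconstruction → per-node CvP → OGT prediction.

Two ancestral CvP variants are always computed side by side, because the
codeml-style workflow this emulates could have used either: the CvP of the
MAP ancestral sequence (the headline value) and the posterior-expected CvP
(averaging the composition over the per-site posteriors).  Leaves report
their observed alignment-row CvP, and their predicted OGT next to the tabled
one, so calibration residuals are visible.

Identical inputs, config and seed give byte-identical TSV outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .asr import (
    AncestralProfile,
    estimate_alpha,
    marginal_ancestral_profiles,
    optimize_branch_lengths,
)
from .calibration import (
    CalibrationModel,
    CalibrationPoint,
    build_calibration_points,
    cvp_bias,
    expected_cvp,
    export_calibration_tsv,
    fit_calibration,
    get_calibration,
    predict_ogt,
)
from .errors import DegenerateInputError, IdentityError, ThermoASRError, TreeError
from .io import (
    Alignment,
    OGTRecord,
    PhyloTree,
    write_node_annotations,
)
from .mad import export_candidates_tsv, mad_root
from .models import SubstitutionModel


@dataclass
class PipelineConfig:
    """Everything that parameterizes one pipeline run."""

    model: str = "LG+F+G10"
    calibration: str | None = None  # named calibration; None = fit from table
    rooting: str = "mad"  # "mad" | "pre-rooted"
    branch_lengths: str = "fixed"  # "fixed" | "optimize"
    alpha: float | str = "estimate"  # numeric value | "estimate"
    collapse_ogt: float | None = 37.0
    exclude_psychrophiles: bool = True
    mask_gappy_columns: bool = False  # drop columns with <50% residues from CvP
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.rooting not in ("mad", "pre-rooted"):
            raise ThermoASRError(f"unknown rooting mode {self.rooting!r}")
        if self.branch_lengths not in ("fixed", "optimize"):
            raise ThermoASRError(f"unknown branch-length mode {self.branch_lengths!r}")
        if isinstance(self.alpha, str) and self.alpha != "estimate":
            raise ThermoASRError(f"alpha must be a number or 'estimate', got {self.alpha!r}")


@dataclass
class NodeOGTAnnotation:
    """Per-node CvP and predicted OGT."""

    node: str
    is_leaf: bool
    cvp_map: float
    cvp_expected: float
    ogt_map: float
    ogt_expected: float
    observed_cvp: float | None = None
    observed_ogt: float | None = None


@dataclass
class PipelineResult:
    tree: PhyloTree
    annotations: dict[str, NodeOGTAnnotation]
    calibration: CalibrationModel
    calibration_points: list[CalibrationPoint]
    model: SubstitutionModel
    log: list[str]
    manifest: dict


def _parse_model_string(spec: str) -> tuple[str, bool, int]:
    """``LG+F+G10`` → (matrix name, use empirical frequencies, k)."""
    parts = spec.upper().split("+")
    name = parts[0]
    plus_f = "F" in parts[1:]
    k = 10
    for p in parts[1:]:
        if p.startswith("G") and len(p) > 1:
            k = int(p[1:])
    return name, plus_f, k


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _match_cvp_key(record: OGTRecord, alignment: Alignment) -> str | None:
    """Alignment id for an OGT record: ``taxon`` or ``taxon|copy_id``."""
    composite = f"{record.taxon}|{record.copy_id}"
    if composite in alignment.ids:
        return composite
    if record.taxon in alignment.ids and record.copy_id == "1":
        return record.taxon
    if record.taxon in alignment.ids:
        return record.taxon
    return None


def _row_cvp(alignment: Alignment, sid: str, mask: list[bool] | None) -> float:
    row = alignment.row(sid)
    if mask is not None:
        row = "".join(ch for ch, keep in zip(row, mask) if keep)
    return cvp_bias(row)


def run_pipeline(
    alignment: Alignment,
    tree: PhyloTree,
    ogt_records: list[OGTRecord] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full ancestral-OGT inference.

    If ``config.calibration`` names a built-in model (e.g. ``"hua2019"``)
    the OGT table is optional; otherwise a table is required and the
    calibration is fitted from the leaves' CvP values.
    """
    config = config or PipelineConfig()
    log: list[str] = []
    tree = tree.copy()

    def say(msg: str) -> None:
        log.append(msg)

    say(f"thermoasr {__version__} pipeline, seed={config.seed}")
    say(f"alignment: {alignment.n_sequences} sequences × {alignment.n_columns} columns")

    missing = set(tree.leaf_labels()) - set(alignment.ids)
    if missing:
        raise IdentityError(f"tree leaves without alignment rows: {sorted(missing)}")

    # ---- rooting ----------------------------------------------------------
    if config.rooting == "mad":
        tree, candidates, ambiguity = mad_root(tree)
        say(f"MAD rooting: {len(candidates)} branches scored, "
            f"best score {candidates[0].score:.6g}, ambiguity {ambiguity:.4f}")
        self_candidates = candidates
    else:
        if not tree.rooted:
            raise TreeError("rooting mode 'pre-rooted' requires a rooted input tree")
        self_candidates = []
        say("rooting: input tree taken as pre-rooted")
    tree.assign_internal_labels()

    # ---- calibration ------------------------------------------------------
    mask = None
    if config.mask_gappy_columns:
        ncol = alignment.n_columns
        mask = [
            sum(1 for row in alignment.rows if row[c] not in "-XBZ") * 2 >= alignment.n_sequences
            for c in range(ncol)
        ]
        say(f"column mask: keeping {sum(mask)}/{ncol} columns with ≥50% residues")

    points: list[CalibrationPoint] = []
    if config.calibration is not None:
        calib = get_calibration(config.calibration)
        say(f"calibration: named model {config.calibration!r} "
            f"(slope {calib.slope}, intercept {calib.intercept})")
    else:
        if not ogt_records:
            raise DegenerateInputError(
                "no OGT table given and no named calibration selected"
            )
        cvps: dict[tuple[str, str], float] = {}
        usable: list[OGTRecord] = []
        for rec in ogt_records:
            sid = _match_cvp_key(rec, alignment)
            if sid is None:
                say(f"calibration: taxon {rec.taxon!r} (copy {rec.copy_id}) "
                    "has no alignment row; skipped")
                continue
            cvps[(rec.taxon, rec.copy_id)] = _row_cvp(alignment, sid, mask)
            usable.append(rec)
        points = build_calibration_points(
            usable,
            cvps,
            exclude_psychrophiles=config.exclude_psychrophiles,
            collapse_ogt=config.collapse_ogt,
        )
        calib = fit_calibration(points)
        say(f"calibration: fitted on {calib.n_points} points, slope {calib.slope:.4f}, "
            f"intercept {calib.intercept:.4f}, R² {calib.r_squared:.4f}")

    # ---- substitution model ----------------------------------------------
    name, plus_f, k = _parse_model_string(config.model)
    alpha0 = config.alpha if isinstance(config.alpha, (int, float)) else 1.0
    model = SubstitutionModel.from_name(
        name, alignment if plus_f else None, alpha=float(alpha0), k=k
    )
    say(f"substitution model: {model.name}")

    if config.alpha == "estimate":
        est = estimate_alpha(tree, alignment, model)
        model = model.with_alpha(est.alpha)
        say(f"gamma shape: estimated alpha {est.alpha:.4f} "
            f"(logL {est.log_likelihood:.2f}{', at boundary' if est.at_boundary else ''})")
    else:
        say(f"gamma shape: fixed alpha {model.alpha}")

    if config.branch_lengths == "optimize":
        tree, ll = optimize_branch_lengths(tree, alignment, model)
        say(f"branch lengths: re-estimated by ML (logL {ll:.2f})")
    else:
        say("branch lengths: fixed input lengths")

    # ---- ancestral reconstruction ----------------------------------------
    profiles = marginal_ancestral_profiles(tree, alignment, model)
    say(f"ancestral reconstruction: {len(profiles)} internal nodes")

    # ---- per-node CvP and OGT --------------------------------------------
    observed_ogt: dict[str, float] = {}
    for rec in ogt_records or []:
        sid = _match_cvp_key(rec, alignment)
        if sid is not None:
            observed_ogt[sid] = rec.ogt

    annotations: dict[str, NodeOGTAnnotation] = {}
    for node in tree.preorder():
        if node.is_leaf:
            cvp = _row_cvp(alignment, node.label, mask)
            annotations[node.label] = NodeOGTAnnotation(
                node=node.label,
                is_leaf=True,
                cvp_map=cvp,
                cvp_expected=cvp,
                ogt_map=predict_ogt(calib, cvp),
                ogt_expected=predict_ogt(calib, cvp),
                observed_cvp=cvp,
                observed_ogt=observed_ogt.get(node.label),
            )
        else:
            prof = profiles[node.label]
            map_seq = prof.map_sequence
            if mask is not None:
                keep = np.array(mask)
                map_seq = "".join(ch for ch, k_ in zip(map_seq, mask) if k_)
                prof_for_exp = AncestralProfile(
                    prof.node, prof.probabilities[keep], map_seq, prof.map_posterior[keep]
                )
            else:
                prof_for_exp = prof
            cvp_map = cvp_bias(map_seq)
            cvp_exp = expected_cvp(prof_for_exp)
            annotations[node.label] = NodeOGTAnnotation(
                node=node.label,
                is_leaf=False,
                cvp_map=cvp_map,
                cvp_expected=cvp_exp,
                ogt_map=predict_ogt(calib, cvp_map),
                ogt_expected=predict_ogt(calib, cvp_exp),
            )
    say(f"annotated {len(annotations)} nodes")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {k_: v for k_, v in asdict(config).items()},
        "alignment_digest": _digest("".join(alignment.ids) + "".join(alignment.rows)),
        "tree_digest": _digest(tree.newick()),
        "calibration": {
            "slope": calib.slope,
            "intercept": calib.intercept,
            "r_squared": calib.r_squared,
            "n_points": calib.n_points,
        },
    }

    result = PipelineResult(tree, annotations, calib, points, model, log, manifest)
    if config.out_dir:
        _write_outputs(result, self_candidates, Path(config.out_dir))
    return result


def _annotation_table(result: PipelineResult) -> dict[str, dict]:
    table: dict[str, dict] = {}
    for label, ann in result.annotations.items():
        table[label] = {
            "is_leaf": ann.is_leaf,
            "cvp_map": ann.cvp_map,
            "cvp_expected": ann.cvp_expected,
            "ogt_map": ann.ogt_map,
            "ogt_expected": ann.ogt_expected,
            "observed_cvp": ann.observed_cvp,
            "observed_ogt": ann.observed_ogt,
        }
    return table


def _write_outputs(result: PipelineResult, candidates, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_node_annotations(
        result.tree,
        _annotation_table(result),
        out_dir / "annotations.tsv",
        out_dir / "annotated_tree.nwk",
    )
    export_calibration_tsv(
        result.calibration, result.calibration_points, out_dir / "calibration.tsv"
    )
    if candidates:
        export_candidates_tsv(candidates, out_dir / "root_candidates.tsv")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(result.log) + "\n")


def summarize_clade_ogt(
    result: PipelineResult, clade_leaves
) -> tuple[NodeOGTAnnotation, bool]:
    """Annotation of the MRCA of a leaf set, plus a flag set when the MRCA
    is the root (the selector spans the root split)."""
    clade_leaves = set(clade_leaves)
    if not clade_leaves:
        raise IdentityError("empty clade selector")
    node = result.tree.mrca(clade_leaves)
    return result.annotations[node.label], node is result.tree.root
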