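"""Fit a CvP→OGT calibration from a synthetic panel of species.

Builds a 37-species panel with the survey skew real OGT tables show
(18 mesophiles reported at exactly 37 °C, two flagged psychrophiles),
applies the two corrections — psychrophile exclusion and collapsing the
37 °C group to its mean CvP — and fits ordinary least squares of OGT on
CvP bias.
"""

from thermoasr import (
    build_calibration_points,
    cvp_bias,
    fit_calibration,
    make_calibration_panel,
)

records, alignment, truth = make_calibration_panel(
    n_species=37, n_at_37=18, n_psychrophiles=2, noise_sd=0.5, seed=42
)

cvps = {(rec.taxon, rec.copy_id): cvp_bias(alignment.row(rec.taxon)) for rec in records}
points = build_calibration_points(records, cvps)  # exclusion + 37 °C collapse
model = fit_calibration(points)

print(f"panel: {len(records)} species → {len(points)} calibration points "
      f"(18 mesophiles collapsed to 1, 2 psychrophiles excluded)")
print(f"fit:   OGT = {model.slope:.4f}·CvP + {model.intercept:.4f}")
print(f"       R² = {model.r_squared:.4f}, slope p-value = {model.p_value:.2e}")
print()
print("Each CvP percentage point (excess of charged R/K/D/E over polar")
print("Q/N/S/T residues) predicts ~6.8 °C higher optimal growth temperature;")
print("the generating line was OGT = 6.7548·CvP + 13.858, recovered up to")
print("the panel's composition noise.")
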