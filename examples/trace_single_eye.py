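"""Trace one cornea and locate its four best-focus planes.

Builds the cohort-mean cornea (front/back conic surfaces from central radii
and asphericities), traces a 1001-ray collimated fan over the mean pupil,
and reports, for each merit function, the best focal plane, the corneal
power referenced to the front apex, and the per-eye keratometer index.
"""

from corneatrace import CRITERIA, CorneaModel, best_focus_all, build_fan, trace_eye

# cohort-mean biometry: R_f, Q_f (front), R_b, Q_b (back), CCT 547 um, PUP
cornea = CorneaModel.from_biometry(R_f=7.733, Q_f=-0.3141, R_b=6.534, Q_b=-0.007, CCT=0.547)
traced = trace_eye(cornea, build_fan(aperture_diameter=4.408, n_rays=1001))
result = best_focus_all(traced)

print(f"{'criterion':<10}{'z_F [mm]':>10}{'CP [dpt]':>10}{'n_K':>9}")
for c in CRITERIA:
    print(f"BFP-{c:<6}{result.z_F[c]:>10.4f}{result.CP[c]:>10.2f}{result.n_K[c]:>9.4f}")

print(
    "\nThe wavefront-optimal plane (fixed 6-mm zone) sits closest to the"
    "\ncornea; the spot planes follow in the order TSD < RMS < MA. Powers"
    "\nare the aqueous vergence 1336/z_F at each plane; n_K is the"
    "\nkeratometer index that would reproduce each power from R_f alone."
)
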