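"""TBARS titration: SVD unmixing, omega scores, pI50 and competition slope.

Generates a synthetic lipid-peroxidation titration (imipramine-like drug
crossed with the scavenger Trolox), unmixes the spectra by SVD, converts the
purified omega scores to the inhibition ordinate, and recovers the drug's
pI50 at each Trolox level plus the cross-competition slope dpI50/d[TRO].
"""

from membrox.synth import InhibitionTruth, TbarsModel, gen_tbars_titration
from membrox.workflows import analyze_titration

truth = InhibitionTruth(pI50_drug=3.7, pI50_tro=4.9, cross_slope_drug_per_tro=-48e-3)
matrix = gen_tbars_titration(
    truth,
    drug_concs=[0.0, 0.08, 0.16, 0.24, 0.32, 0.40],   # mM, as in the assay design
    tro_concs=[0.0, 5.0, 10.0, 15.0, 20.0, 25.0],      # uM Trolox
    model=TbarsModel(noise_sd=0.003, seed=0),
)
print(f"titration matrix: {matrix.m} wavelengths x {matrix.n} spectra "
      "(samples + full-inhibition reference + MDA calibration standards)")

analysis = analyze_titration(matrix)
print(f"omega0 = {analysis.omega0:.3f}, omega_inf = {analysis.omega_inf:.3f} "
      "(uninhibited / fully inhibited score asymptotes)")
for tro, fit in analysis.fits.items():
    print(f"  [TRO] = {tro:4.0f} uM   IC50 = {fit.ic50:6.3f} mM   pI50 = {fit.pI50:.2f}")

comp = analysis.competition
print(f"competition slope dpI50/d[TRO] = {comp.slope * 1e3:.1f} x 10^-3 per uM "
      f"(truth {truth.cross_slope_drug_per_tro * 1e3:.0f}); "
      f"intercept pI50 = {comp.intercept:.2f} (truth {truth.pI50_drug})")
# The negative slope is the signature of competition: the scavenger masks
# the drug's apparent inhibitory potency as its concentration rises.
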