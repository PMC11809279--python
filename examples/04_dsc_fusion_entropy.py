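"""DSC: onset melting temperature, fusion enthalpy and entropy, Walden excess.

Generates a synthetic endotherm on a sloped baseline and runs the tangent
onset construction, baseline-subtracted peak integration, and the Clausius
entropy, comparing the fusion entropy against Walden's constant
(56.5 J K^-1 mol^-1 for non-associating organic melts).
"""

from membrox.dsc import WALDEN_CONSTANT, analyze_thermogram
from membrox.synth import gen_thermogram

tg = gen_thermogram(Tm=380.0, dH=17000.0, width=2.0, baseline=(0.2, 0.002),
                    molar_mass=280.0, sample_mass=10.0)
res = analyze_thermogram(tg)
print(f"onset Tm   = {res.Tm:7.2f} K   (generator truth {tg.meta['true_onset_K']:.2f} K)")
print(f"dH_fus     = {res.dH:7.0f} J/mol (truth {tg.meta['true_dH_J_mol']:.0f})")
print(f"dS_fus     = {res.dS:7.2f} J/K/mol = dH / Tm")
print(f"Walden excess = {res.walden_excess:+.2f} J/K/mol vs {WALDEN_CONSTANT}")
# A fusion entropy below Walden's constant (negative excess) indicates
# molecular association/rigidity in the melt; above it, extra flexibility.
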