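"""CDOM absorption descriptors: a254, spectral slopes and slope ratio.

Synthesizes two-exponential absorption spectra for a southern and a
northern archetype and prints a254, the 275-295 nm and 350-400 nm
exponential slopes and their ratio Sr (inversely related to DOM
molecular weight).
"""

from riverdom import absorption_coefficient, slope_ratio, \
    specific_absorbance, spectral_slope
from riverdom.synth import generate_absorption

south = generate_absorption(a440_true=0.6, s_true=0.030,
                            second=(0.70, 0.012), sample_id="south")
north = generate_absorption(a440_true=2.4, s_true=0.030,
                            second=(0.35, 0.012), sample_id="north")

for spec, c_org in ((south, 0.25), (north, 1.05)):
    a254 = absorption_coefficient(spec, 254.0)
    s_uv = spectral_slope(spec, (275.0, 295.0))
    s_vis = spectral_slope(spec, (350.0, 400.0))
    print(f"{spec.sample_id}: a254 = {a254:.1f} 1/m, "
          f"a254/C_org = {specific_absorbance(a254, c_org):.1f} 1/m/mM")
    print(f"  S(275-295) = {s_uv.s:.4f} 1/nm, S(350-400) = {s_vis.s:.4f} "
          f"1/nm, Sr = {slope_ratio(spec):.2f}")
# Higher Sr in the south marks steeper UV slopes relative to the
# visible, i.e. lower-molecular-weight chromophores.
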