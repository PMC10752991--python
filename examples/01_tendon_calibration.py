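"""Fit serial-elastic tendon parameters to a reference stress-strain curve.

Generates a surrogate tendon curve (toe region to 1.5 % strain, linear
region with a 2.4 GPa modulus, necking beyond 4 %), fits the three
tendon parameters on the 0-3 % strain window, and reports the windowed
NMAE scores and the Young's modulus of the fitted material.
"""

from jfisim import SEEParams, fit_see, model_stress_strain, windowed_nmae
from jfisim.synthetic import TendonReferenceSpec, gen_tendon_reference

FMAX, CSA = 90.0, 3e-6  # one FDP strand; Fmax/CSA = 30 MPa

ref = gen_tendon_reference(TendonReferenceSpec(), seed=0)
default = SEEParams()  # (0.4 Fmax, 0.0425, 0.017)
fit = fit_see(ref, FMAX, CSA, init=default)

m_default = model_stress_strain(default, FMAX, CSA, ref.strains)
print("tendon parameter fit (0-3 % strain window)")
print(f"  fitted dF_SEE,0 = {fit.see.dF_see_0_frac:.3f} * Fmax")
print(f"  fitted dU_SEE,nll = {fit.see.dU_see_nll:.4f}")
print(f"  fitted dU_SEE,l   = {fit.see.dU_see_l:.4f}")
print(f"  NMAE3 fitted  = {fit.nmae3:6.2f} %   (default: "
      f"{windowed_nmae(m_default, ref, 0.03):6.2f} %)")
print(f"  NMAE5 fitted  = {fit.nmae5:6.2f} %   (default: "
      f"{windowed_nmae(m_default, ref, 0.05):6.2f} %)")
print(f"  Young's modulus fitted  = {fit.E / 1e9:.2f} GPa (reference linear "
      "region: 2.40 GPa)")
# NMAE5 exceeds NMAE3 because the serial element has no necking branch:
# it stays linear where the reference softens, overestimating stress.
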