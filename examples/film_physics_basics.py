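"""Worked film-physics numbers: Sauerbrey mass, thickness, and the Voigt model.

Builds nothing — these are the closed-form relations applied to headline
frequency shifts from supported-lipid-bilayer (SLB) experiments.
"""

from qcmdslb import (
    ViscoelasticFilm,
    bilayer_thickness_corrected,
    decay_length,
    rigid_film_response,
    sauerbrey_mass,
    sauerbrey_thickness,
    viscoelastic_film_response,
)

# A complete rigid SLB from a 5-component neuronal lipid mixture plateaus
# near dF = -30 Hz.  The Sauerbrey mass includes the ~102 ng/cm^2 hydration
# water layer between substrate and bilayer; subtracting it leaves the
# lipid bilayer thickness.
mass = sauerbrey_mass(-30.0)
thick, _ = bilayer_thickness_corrected(-30.0)
print(f"SLB asymptote -30.0 Hz: Sauerbrey mass = {mass:.0f} ng/cm^2, "
      f"bilayer thickness = {thick:.1f} nm")

# The multi-overtone extrapolation of an adsorbing vesicle layer gives a
# zero-dissipation intercept near -113 Hz; Sauerbrey at that intercept is
# the height of the deformed vesicles.
print(f"intercept -113 Hz -> deformed vesicle height = "
      f"{sauerbrey_thickness(-113.0, rho=1.0):.1f} nm")

# Rigid films are overtone-independent; soft films split across overtones
# because the acoustic decay length shrinks with the overtone number.
print("\nacoustic decay length in water (nm):",
      {n: round(decay_length(n), 1) for n in (3, 7, 11)})
soft = ViscoelasticFilm(m_f=2000.0, g_storage=1e5, g_loss=3e4)
print("soft vesicle layer (m=2000 ng/cm^2, G'=1e5 Pa, G''=3e4 Pa):")
for n in (3, 7, 11):
    df, dd = viscoelastic_film_response(soft, n)
    print(f"  n={n:2d}: dF = {df:7.2f} Hz, dD = {dd:5.2f} x1e-6")
df, dd = rigid_film_response(2000.0)
print(f"  rigid film of the same mass: dF = {df:.2f} Hz on every overtone, dD = 0")
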