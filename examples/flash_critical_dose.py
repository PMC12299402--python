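"""Locate the FLASH critical dose from the fitted cf(d) dose law.

The late-time coefficient cf of the single-dose kill rate
F(t) = c0 + c1 e^{-c2 t} - cf t acts as an order parameter: cf > 0 means
the tumor eventually regrows, cf < 0 means complete response.  The
packaged dose law cf(d) = a - b (d - d_ref)^p was fitted across FLASH
dose arms; its root is the critical dose.
"""

from tumorkin import GompertzParams, cf_of_dose, flash_critical_dose, regrowth_time
from tumorkin import fixtures

law = fixtures.flash_dose_law()
print("cf(d) = %.6g - %.3g (d - %g)^%g  [day^-2, d in Gy]"
      % (law.a, law.b, law.d_ref, law.p))
for d in (15.0, 20.0, 25.0):
    print("  cf(%4.1f Gy) = %+.5f day^-2" % (d, cf_of_dose(law, d)))

dc = flash_critical_dose(law)
print("critical dose (sign change of cf): %.1f Gy" % dc)
print()

# below the critical dose the trajectory rejoins the untreated trend at t*
gp = GompertzParams(V0=1.0, V_inf=5.0, k=0.1)
fp15 = fixtures.flash_params("15_gy_flash")
fp25 = fixtures.flash_params("25_gy_flash")
print("15 Gy arm: cf = %+.5f -> regrowth at t* = %.0f days" %
      (fp15.cf, regrowth_time(gp, fp15)))
print("25 Gy arm: cf = %+.5f -> regrowth time: %s (complete response branch)" %
      (fp25.cf, regrowth_time(gp, fp25)))
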