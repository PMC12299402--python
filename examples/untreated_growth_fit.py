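"""Fit Gompertz growth parameters to a noisy untreated volume series.

Generates twice-weekly-style measurements of a tumor growing toward a
carrying capacity of five times its initial volume, corrupts them with
2.5% multiplicative measurement noise, and refits the growth law.
"""

import math

import numpy as np

from tumorkin import (
    FitConfig,
    GompertzParams,
    NoiseModel,
    fit_model,
    gen_gl,
    gompertz_ratio_model,
    identifiability_check,
)

truth = GompertzParams(V0=1.0, V_inf=5.0, k=0.03)  # k in day^-1
times = np.linspace(0.0, 120.0, 8)
traj = gen_gl(truth, times, NoiseModel(rel_sd=0.025, seed=1))

fit = fit_model(traj, gompertz_ratio_model, FitConfig(normalize=False))

print("planted: ln(V_inf/V0) = %.4f, k = %.4f /day" % (truth.log_ratio, truth.k))
print(
    "fitted : ln(V_inf/V0) = %.4f +/- %.4f, k = %.4f +/- %.4f /day"
    % (
        fit.params["log_vinf_ratio"],
        fit.sd["log_vinf_ratio"],
        fit.params["k"],
        fit.sd["k"],
    )
)
print("chi2/dof = %.3f  (1-SD errors from the chi-square covariance)" % fit.chi2_per_dof)
print("identifiability:", identifiability_check(fit))
print()
print(
    "The fitted carrying-capacity ratio is exp(%.3f) = %.2f: the tumor"
    % (fit.params["log_vinf_ratio"], math.exp(fit.params["log_vinf_ratio"]))
)
print("would saturate at about that multiple of its initial volume if untreated.")
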