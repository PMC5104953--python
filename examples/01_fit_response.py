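"""Fit yield-response curves to one year of a synthetic N-rate trial.

Builds a 2-year experiment, fits the quadratic and quadratic-plateau forms
to the first continuous-corn group, and shows which the selection rule
keeps.
"""

import numpy as np

from nresponse import (
    fit_quadratic,
    fit_quadratic_plateau,
    generate_experiment,
    predict_yield,
    select_model,
)

exp = generate_experiment(n_years=2, seed=42)
(year, rotation), group = next(exp.trial.groups("corn"))

fq = fit_quadratic(group)
fqp = fit_quadratic_plateau(group)
best = select_model(fq, fqp)

print(f"{year} {rotation}: quadratic          ss_res={fq.ss_res:9.0f}  R2={fq.r2:.3f}  p={fq.p_value:.2e}")
print(f"{year} {rotation}: quadratic-plateau  ss_res={fqp.ss_res:9.0f}  R2={fqp.r2:.3f}  join x0={fqp.x0:.0f} kg N/ha")
print(f"selected form: {best.form}")
for rate in (0, 134, 268):
    print(f"  predicted yield at {rate:3d} kg N/ha: {predict_yield(best, rate):7.0f} kg/ha")

# The selected curve is the basis for every optimum-N calculation: its
# slope falling to the N:grain price ratio marks the economic optimum.
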