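"""Derive economic optimum N rates two ways and pool them into site means.

The regression route solves d(yield)/dN = price ratio on the fitted curve;
the return-to-N (RTN) route scans predicted yields on a 5 kg N grid for the
point where the marginal net return crosses zero.
"""

from nresponse import (
    annual_optima,
    generate_experiment,
    optima_to_frame,
    site_mean,
)

exp = generate_experiment(n_years=16, seed=7)

yearly = annual_optima(exp.trial)  # regression EONR per year x rotation
rtn_yearly = annual_optima(exp.trial, method="rtn")

frame = optima_to_frame(yearly).merge(
    exp.truth[["year", "rotation", "true_eonr"]], on=["year", "rotation"]
)
print(frame.head(6).round(1).to_string(index=False))

for rot in ("CC", "SC"):
    ests = [e for e in yearly if e.rotation == rot]
    across = site_mean(ests, exp.trial, "across_years", rotation=rot)
    pooled = site_mean(None, exp.trial, "pooled", rotation=rot)
    print(
        f"{rot}: across-years EONR {across.mean_eonr:5.1f} +/- {across.sd_eonr:4.1f} kg N/ha "
        f"({across.n_years} yr) | pooled-response EONR {pooled.mean_eonr:5.1f} kg N/ha"
    )

# Across-years averages yearly optima (SD shows inter-annual spread);
# pooling averages yields per rate first, the shape used for regional
# N-rate recommendations.
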