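"""One cell of the Monte-Carlo study: unbalanced observation counts.

300 subjects, 75% with 10 occasions and 25% with 30.  Per replicate both
methods produce subject-level (mean, variability) regressors; stage-2 OLS
regresses the true subject outcome on them and we track the bias of the
coefficients (truth 0.5/0.5) and the coverage of their 95% CIs.  Reduced
to 100 replicates so the script runs in ~20 s; the full study uses 500.
"""

from melsim import SCENARIOS, DgpConfig, MelsSettings, run_condition

dgp = DgpConfig(sd_logscale=0.7)  # calibrated spread of the true log-scales
settings = MelsSettings(n_quad=15, n_quad_fit=5, compute_se=False)

results = run_condition(
    SCENARIOS["S1-1"], n_replicates=100, seed=1, dgp=dgp, settings=settings
)

print(f"{'method':6s} {'bias(mean)':>11s} {'bias(var)':>10s} {'cover(mean)':>12s} {'cover(var)':>11s}")
for r in results:
    print(
        f"{r.method:6s} {r.bias1:+11.3f} {r.bias2:+10.3f} "
        f"{r.coverage1:11.1f}% {r.coverage2:10.1f}%"
    )
print(
    "\nThe summary-statistic regressors are attenuated (negative bias) and their"
    "\nCIs undercover, most severely for the mean coefficient; the EB regressors"
    "\nstay near the 0.5 truth with close-to-nominal 95% coverage."
)
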