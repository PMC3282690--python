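"""Attach likelihood-ratio confidence intervals to a fitted model.

A 90% interval for one parameter collects every value at which the data
log-likelihood sits within chi^2_1(0.90)/2 = 1.35 units of its maximum.
"Conditional" intervals hold the other parameters at their MLE values;
"profile" intervals re-maximize them at every scan point and are the more
honest (and more expensive) choice when parameters are correlated.

Run:  python examples/02_confidence_intervals.py
"""

import smtrace as st

params = st.two_state_params(k12=0.3, k21=0.3, snr=5.0)
cfg = st.SimulationConfig(params=params, snr=5.0, c=10_000, n_traces=1, seed=314)
trace, _ = st.simulate_trace(cfg, 0)

fit = st.fit_hmm(trace, st.builtin_models()["2-state"], seed=0)
print(f"MLE: k12 = {fit.params.A[0, 1]:.4f}")

for mode in ("conditional", "profile"):
    ci = st.confidence_interval(trace, fit, "k12", level=0.90, mode=mode)
    print(f"{mode:>12}: 90% CI = ({ci.lo:.4f}, {ci.hi:.4f})")

# intervals for several parameters at once, attached to the fit itself
st.confidence_intervals(trace, fit, ["k12", "k21", "mu[1][1]", "mu[2][1]"])
for name, ci in fit.cis.items():
    flag = " (clipped)" if ci.clipped_lo or ci.clipped_hi else ""
    print(f"  {name:10s} in ({ci.lo:9.4f}, {ci.hi:9.4f}){flag}")

# a short, noisy trace gives wide, possibly clipped intervals: the interval
# width is the per-molecule error bar later used to weight clustering
short_cfg = st.SimulationConfig(
    params=params, length_mode="fixed", T=100, n_traces=1, seed=7
)
short_trace, _ = st.simulate_trace(short_cfg, 0)
short_fit = st.fit_hmm(short_trace, st.builtin_models()["2-state"], seed=0)
ci = st.confidence_interval(short_trace, short_fit, "k12")
print(f"\nT=100 trace: k12 = {ci.mle:.3f}, 90% CI = ({ci.lo:.3f}, {ci.hi:.3f})")
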