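"""Simulate a two-state molecule and recover its kinetics with an HMM.

A single molecule hops between two conformations with per-step transition
probabilities k12 = k21 = 0.3.  Its fluorescence is shot-noise limited
(Poisson counts), and raising the excitation power (higher SNR) bleaches the
fluorophore sooner, so the trace length is T = c / SNR with c = 10,000.

Run:  python examples/01_simulate_and_fit.py
"""

import smtrace as st

# --- simulate ---------------------------------------------------------------
params = st.two_state_params(k12=0.3, k21=0.3, snr=5.0)
print("state means:", params.emissions.mu.ravel())  # low state at 100 counts

cfg = st.SimulationConfig(params=params, snr=5.0, c=10_000, n_traces=1, seed=42)
trace, hidden_states = st.simulate_trace(cfg, 0)
print(f"trace length T = {trace.T} (photobleaching: 10,000 / SNR 5)")

# --- fit --------------------------------------------------------------------
model = st.builtin_models()["2-state"]
fit = st.fit_hmm(trace, model, seed=0)
print(f"converged in {fit.n_iter} iterations, loglik = {fit.loglik:.1f}")
print(f"fitted k12 = {fit.params.A[0, 1]:.3f}  (truth 0.3)")
print(f"fitted k21 = {fit.params.A[1, 0]:.3f}  (truth 0.3)")
print("fitted means:", fit.params.emissions.mu.ravel().round(1))

# --- idealization -----------------------------------------------------------
# posterior state probabilities give a soft idealized trajectory
ideal = fit.posteriors.argmax(axis=1)
agreement = (ideal == hidden_states).mean()
print(f"posterior idealization matches the true path at {agreement:.1%} of steps")

# --- persistence ------------------------------------------------------------
# traces go to a self-describing TSV; fits to a JSON keyed by trace id
st.write_traces(st.TraceSet([trace]), "example_traces.tsv")
from smtrace.results import fit_to_dict

st.write_results({trace.id: fit_to_dict(fit, trace)}, "example_fits.json")
print("wrote example_traces.tsv and example_fits.json")
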