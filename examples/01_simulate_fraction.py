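"""Simulate one tracked treatment fraction and inspect its log streams.

Generates a 30-minute fraction for a typical mid-size thoracic mover:
a cos^4-shaped breathing trace with period jitter and baseline drift,
live X-ray seed images once a minute, and correlation/prediction error
streams with known generating distributions.
"""

from ptvmargin import SimulationParams, simulate_fraction

params = SimulationParams(random_seed=1)
fraction, truth = simulate_fraction(params)

print(f"live X-ray images : {len(fraction.live_images)} (one per minute)")
print(f"model samples     : {len(fraction.correlation)} at {params.model_rate_hz} Hz")
print(f"seed CoM (CT)     : {fraction.fiducials.com().round(2)} mm")
print()
print("Ground truth the estimators should recover:")
print(f"  U_deformation = {truth.u_deformation:.1f} mm (CoM inside the CTV)")
print(f"  U_seeds       = {truth.u_seeds:.2f} mm")
print(f"  U_correlation = {truth.u_correlation.round(2)} mm (SI, LAT, AP)")
print(f"  U_prediction  = {truth.u_prediction.round(2)} mm")
print(f"  Rm            = {truth.rm.round(2)} mm peak-to-trough")
# The generating values are what the step estimators and motion-range
# statistics are validated against in the other examples.
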