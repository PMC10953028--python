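"""Measuring the actual corkscrew trajectory with projection scans.

Gradient chains delay and distort the nominal sinusoids; even a 1 us
timing shift visibly corrupts wave reconstructions.  The calibration
acquires projections at known offsets with and without the wave
gradients: the phase difference at offset r is -2 pi k_wave(t) r, so a
least-squares slope fit over offsets recovers k_wave(t) per axis.
"""

import numpy as np

import wavetof as wt
from wavetof.trajectory import trajectory_from_waveform

params = wt.WaveParams(g_max=10.0, n_cyc=15, bw_per_pixel=121.0, n_read=64)
nominal = wt.synthesize_waveforms(params)
imperfect = wt.apply_imperfection(
    nominal,
    wt.GradientImperfection(delay_us=1.0, eddy_amps=(0.01,), eddy_taus_ms=(0.8,)),
)
traj_nominal = trajectory_from_waveform(nominal, params, 200.0)
traj_true = trajectory_from_waveform(imperfect, params, 200.0)

scans = wt.simulate_calibration_scans(traj_true, noise_sigma=0.005)
estimate = wt.estimate_trajectory(scans, kx=traj_true.kx)

peak = np.abs(traj_true.ky_wave).max()
err_est = np.abs(estimate.ky_wave - traj_true.ky_wave).max() / peak
err_nom = np.abs(traj_nominal.ky_wave - traj_true.ky_wave).max() / peak

print(f"peak wave deflection          : {peak:.1f} cycles/m")
print(f"nominal-vs-true discrepancy   : {100 * err_nom:.2f} % of peak")
print(f"calibrated-estimate error     : {100 * err_est:.2f} % of peak")
print()
print("The calibrated trajectory tracks the delayed/distorted truth far")
print("more closely than the nominal waveform, which is why the wave")
print("reconstruction uses the measured PSF rather than the design one.")
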