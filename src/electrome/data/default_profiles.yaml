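# Default generating profiles for the four water-availability treatments.
# Baselines: power-spectral exponent beta (power ~ 1/f^beta) and standard
# deviation (mV) chosen so resting oscillations stay within +-0.05 mV.
# Spike rates are order-of-magnitude choices (no quantitative rates are
# published for this design); amplitudes stay below +-0.5 mV at rest and
# reach the 5-10 mV range only after the osmotic stimuli.
treatments:
  water:
    baseline_beta: 1.76
    baseline_sigma: 0.02
    pre_spikes:  {events_per_hour: 6,  amplitude_exponent: 2.5,
                  amplitude_min: 0.05, amplitude_max: 0.5,
                  waveform: ap_like, duration_s: 4.0}
    post_spikes: {events_per_hour: 8,  amplitude_exponent: 2.5,
                  amplitude_min: 0.05, amplitude_max: 0.5,
                  waveform: ap_like, duration_s: 4.0}
  nutrient:
    baseline_beta: 1.75
    baseline_sigma: 0.02
    pre_spikes:  {events_per_hour: 6,  amplitude_exponent: 2.5,
                  amplitude_min: 0.05, amplitude_max: 0.5,
                  waveform: ap_like, duration_s: 4.0}
    post_spikes: {events_per_hour: 12, amplitude_exponent: 2.5,
                  amplitude_min: 0.05, amplitude_max: 1.0,
                  waveform: ap_like, duration_s: 4.0}
  peg:
    baseline_beta: 1.65
    baseline_sigma: 0.02
    post_beta: 2.12          # spectrum darkens after the osmotic shock
    post_sigma: 0.05
    pre_spikes:  {events_per_hour: 6,  amplitude_exponent: 2.5,
                  amplitude_min: 0.05, amplitude_max: 0.5,
                  waveform: ap_like, duration_s: 4.0}
    post_spikes: {events_per_hour: 60, amplitude_exponent: 2.2,
                  amplitude_min: 0.05, amplitude_max: 8.0,
                  waveform: vp_like, duration_s: 45.0}
  nacl:
    baseline_beta: 1.90
    baseline_sigma: 0.02
    post_sigma: 0.04
    pre_spikes:  {events_per_hour: 6,  amplitude_exponent: 2.5,
                  amplitude_min: 0.05, amplitude_max: 0.5,
                  waveform: ap_like, duration_s: 4.0}
    post_spikes: {events_per_hour: 80, amplitude_exponent: 2.2,
                  amplitude_min: 0.05, amplitude_max: 10.0,
                  waveform: ap_like, duration_s: 6.0}
    burst: {start_s: 0, end_s: 1500, rate_multiplier: 4}   # first 25 min
    slow_waves: {period_s: 600, amplitude_mV: 1.5, count: 4}
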