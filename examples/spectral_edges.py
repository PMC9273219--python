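"""Power spectra and the 40% spectral edge of young vs aged trials.

Computes each worm's 120-neuron periodogram set, the unit-power condition
mean, and the 40% spectral edge (the frequency below which 40% of total
power resides). A higher edge means the population's activity has shifted
toward faster dynamics — the aged preset should sit above the young one.
"""

import numpy as np

import wormdyn as w

for day in (1, 9):
    psds = []
    edges = []
    for i in range(3):
        traces, _ = w.generate_population(w.age_preset(day, seed=200 + i))
        dff = w.normalize_dff(traces)
        psd = w.compute_psd(dff)
        psds.append(psd)
        edges.append(w.spectral_edge(psd, q=0.40).edge_hz)
    mean_psd, cumulative = w.mean_normalized_psd(psds)
    half = mean_psd.freqs[np.argmax(cumulative >= 0.5)]
    print(f"day {day}: per-worm 40% edges = "
          f"{', '.join(f'{e * 1000:.1f}' for e in edges)} mHz | "
          f"condition-mean half-power frequency = {half * 1000:.1f} mHz")
print("\n(higher edge = relatively more high-frequency activity)")
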