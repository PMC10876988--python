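"""Build a labeled training dataset by decomposition and recombination.

Simulated source spectra stand in for a measured pool: each is split into
noise, baseline and peak fragments by an 8-level db8 wavelet transform;
ideal (peaks-only) spectra are then assembled from 5-20 pooled fragments
and paired with references carrying controlled noise and baseline severity.
"""

import numpy as np

from ramanprep import SynthesisConfig, build_component_pools, build_dataset
from ramanprep.synthesis import generate_mathsim_sources

cfg = SynthesisConfig(n_spectra=500, seed=42).with_severity("baseline_dominated")
rng = np.random.default_rng(42)

sources = generate_mathsim_sources(50, cfg, rng)
pools = build_component_pools(sources)
print(f"decomposed {len(sources)} source spectra into "
      f"{len(pools.noises)} noise sets, {len(pools.baselines)} baseline sets "
      f"and {len(pools.peaks)} peak fragments")

coll = build_dataset(cfg, "recombination", pools)
peaks_per_spectrum = [len(m) for m in coll.manifests]
snrs = [p.snr_db for p in coll.pairs]
print(f"assembled {len(coll)} (reference, ideal) pairs on a "
      f"{cfg.grid_len}-point grid over {cfg.wavenumber_range} cm^-1")
print(f"peaks per ideal spectrum: min {min(peaks_per_spectrum)}, "
      f"max {max(peaks_per_spectrum)} (target range 5-20)")
print(f"reference SNR: {np.min(snrs):.1f} to {np.max(snrs):.1f} dB "
      f"(baseline-dominated severity)")
# Each pair satisfies x = y + alpha*noise + beta*baseline exactly; the
# labels are what a perfect preprocessor should return for each reference.
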