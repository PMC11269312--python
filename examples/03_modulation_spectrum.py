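"""Modulation power spectra and the pain-minus-discomfort difference map.

Computes each cry's MPS (amplitude of the 2D Fourier transform of the
normalized log spectrogram in 1 s windows), forms the pairwise
pain-minus-discomfort dB difference per baby, and averages.  Evaluated at
each baby's own pitch ridge (~1/f0 cyc/kHz), pain cries lose power at the
ridge and gain power in the flanking spectral modulations -- the signature of
a wider, less stable pitch.
"""

import numpy as np

from crysig import (
    GeneratorConfig,
    average_mps,
    generate_corpus,
    mps_difference,
    mps_from_recording,
    peak_spectral_modulation,
)

cfg = GeneratorConfig(
    n_babies=6,
    pain_per_baby=4,
    discomfort_count_range=(4, 4),
    duration_mean_s=2.5,
    duration_sd_s=0.2,
    sample_rate=11025,
    seed=3,
)
recordings, _ = generate_corpus(cfg)

per_baby = {}
for rec in recordings:
    per_baby.setdefault(rec.baby_id, {"discomfort": [], "pain": []})[
        rec.condition
    ].append(mps_from_recording(rec))

at_ridge, flank = [], []
for baby, conds in sorted(per_baby.items()):
    avg_disc = average_mps(conds["discomfort"])
    ridge = peak_spectral_modulation(avg_disc)
    diff = mps_difference(average_mps(conds["pain"]), avg_disc)
    sm = diff.spectral_modulations
    tmask = np.abs(diff.temporal_modulations) <= 20
    profile = diff.values_db[tmask].mean(axis=0)
    at_ridge.append(profile[np.argmin(np.abs(sm - ridge))])
    flank.append(profile[(sm > ridge + 0.5) & (sm < ridge + 2.5)].mean())
    print(f"{baby}: pitch ridge {ridge:.2f} cyc/kHz (~{1000 / ridge:.0f} Hz), "
          f"pain - discomfort at ridge {at_ridge[-1]:+.1f} dB, flanks {flank[-1]:+.1f} dB")

print(f"\naverage over babies: at ridge {np.mean(at_ridge):+.1f} dB, "
      f"flanks {np.mean(flank):+.1f} dB")
# negative at the ridge, positive in the flanks: pain spreads each baby's
# pitch energy over a wider band of spectral modulations
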