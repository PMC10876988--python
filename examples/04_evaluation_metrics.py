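"""The evaluation metric suite on small worked examples.

Spectral errors (RMSE, L-infinity), classification accuracy indexes,
log-scale quantification error, spectral SNR and masked image contrast.
"""

import numpy as np

from ramanprep import (
    ClassificationScores,
    Spectrum,
    WavenumberAxis,
    classification_metrics,
    image_contrast_metrics,
    linf,
    paired_test,
    quantification_error,
    rmse,
    snr_spec,
)

print("RMSE([0,0],[3,4])          =", rmse([0, 0], [3, 4]))          # sqrt(12.5)
print("Linf([1,2],[4,0])          =", linf([1, 2], [4, 0]))          # 3

rep = classification_metrics(ClassificationScores([0.8, 0.4], [0.6, 0.2], threshold=0.5))
print("AUC({0.8,0.4} vs {0.6,0.2}) =", rep["auc"])                   # 0.75

print("E_Q one decade off          =", quantification_error([1e-5], [1e-4]))  # 1.0

ax = np.linspace(400, 3200, 512)
inten = np.where((ax >= 2800) & (ax < 3200), 100.0,
                 np.where((ax >= 1800) & (ax < 2800), 1.0, 0.0))
print("SNR_spec at 100:1           =", snr_spec(Spectrum(WavenumberAxis(ax), inten)), "dB")

sig = np.zeros((4, 4), dtype=bool)
sig[:2] = True
raw = np.full((4, 4), 10.0)
raw[~sig] = np.tile([0.0, 4.0], 4)
print("CNR (C_sig 10, C_bg 2, sd 2)=", image_contrast_metrics(raw, raw, sig, ~sig)["cnr_raw"])

a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
print("Wilcoxon p, 5 positive diffs=", paired_test(a, a - 0.1, "signed_rank"))  # 0.0625
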