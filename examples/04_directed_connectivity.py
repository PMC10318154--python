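"""Estimate directed connectivity with the dual Kalman filter and TPDC.

Simulates a unidirectional coupling (source 0 drives source 1 with weight
0.5), estimates time-varying MVAR coefficients with the dual Kalman filter,
computes band TPDC, and validates edges with the window-shuffle bootstrap
and the time-reversal technique.
"""

import numpy as np

from dicsnet import (SourceScenario, bootstrap_significance, build_graph,
                     dual_ekf, generate_mvar_sources, time_reversal_check,
                     tpdc)
from dicsnet.spectral import get_band

A = np.zeros((2, 2, 2))
A[0] = [[0.5, 0.0], [0.5, 0.5]]   # A[0][1, 0] = 0.5: source 0 -> source 1
A[1] = [[-0.2, 0.0], [0.0, -0.2]]
scenario = SourceScenario(
    positions=[[0, 0, 30], [20, -30, 10]],
    orientations=np.tile([1.0, 0, 0], (2, 1)),
    mvar_coeffs=A, innovation_cov=np.eye(2),
    band_profiles=[None, None], seed=11)
x = generate_mvar_sources(scenario, 60.0, 256.0)

band = get_band("alpha")
model = dual_ekf(x, 2, 256.0)
result = tpdc(model, band)
print("band-averaged TPDC (rows = target, cols = driver):")
print(np.round(result.band_matrix, 3))

thr = bootstrap_significance(x, 2, 256.0, band, n_boot=100, seed=0,
                             estimator="ekf", reduction="percentile")
trt = time_reversal_check(x, 2, 256.0, band, estimator="ekf", seed=0)
graph = build_graph(result, thr, trt)

print("\nsignificant, time-reversal-validated edges:")
for e in graph.edges:
    arrow = "<->" if e.bidirectional else "->"
    print(f"  {e.source} {arrow} {e.target}: TPDC {e.strength:.3f}")
print("\nTPDC is column-normalized |A(f)| in [0, 1]; the off-diagonal "
      "floor (~0.1 here) is the dual filter's coefficient jitter, which is "
      "why the surrogate threshold is built with the same estimator.")
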