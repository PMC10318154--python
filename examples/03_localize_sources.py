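"""Localize coupled sources with the iterative DICS search.

Simulates two alpha-band sources with directed coupling at 0 dB SNR, scans
a 10-mm source grid with the LCMV/DICS beamformer, and reports each
significant coherent source with its statistic and surrogate threshold.
"""

import numpy as np

from dicsnet import (HeadModel, SourceScenario, build_grid, compute_leadfield,
                     fibonacci_sensors, find_coherent_sources,
                     generate_mvar_sources, project_to_sensors)
from dicsnet.preprocess import epoch
from dicsnet.spectral import get_band

head = HeadModel()
grid = build_grid(head, spacing=10.0)
leadfield = compute_leadfield(head, fibonacci_sensors(32), grid)

true_positions = [[20.0, -40.0, 20.0], [-20.0, 30.0, 25.0]]
scenario = SourceScenario(
    positions=true_positions,
    orientations=[[1.0, 0, 0], [0, 1.0, 0]],
    mvar_coeffs=np.array([[[0.3, 0.0], [0.5, 0.3]]]),  # source 0 drives 1
    innovation_cov=np.eye(2),
    band_profiles=[(10.0, 2.0), (10.0, 2.0)], snr_db=0.0, seed=3)

x = generate_mvar_sources(scenario, 60.0, 1024.0)
rec = project_to_sensors(x, scenario, leadfield, snr_db=0.0, srate=1024.0)
eps = epoch(rec, 1.0)

sset = find_coherent_sources(eps, get_band("alpha"), leadfield, n_max=3,
                             n_perm=200, seed=0)
print(f"found {len(sset)} significant alpha sources "
      f"(true positions: {true_positions}):")
for k, src in enumerate(sset.sources, 1):
    print(f"  S{k}: {src.statistic:<9} amplitude {src.amplitude:.3f} "
          f"(surrogate threshold {src.threshold:.3f}) at "
          f"{np.round(src.position, 0)} mm")
print("\nThe first source is the strongest band-power voxel; later sources "
      "maximize coherence to its pooled signal after the found topographies "
      "are projected out.  Coherence amplitudes are magnitude-squared, "
      "in [0, 1].")
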