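"""Generate one synthetic fMRI subject and inspect its motion trace.

Builds miniature tissue-probability maps (a WM blob wrapped in GM and
CSF), a 4-D BOLD run whose voxels share latent signals within
ground-truth parcels, and a realignment table with two deliberate
motion spikes; then shows where framewise displacement (FD) exceeds the
0.5 mm scrubbing threshold.
"""

import numpy as np

from wmconn import SyntheticVolumeSpec, make_bold_volume, make_tissue_maps
from wmconn.preprocess import framewise_displacement, scrub

spec = SyntheticVolumeSpec(fd_spike_times=(30, 70), fd_spike_mm=1.0, seed=11)
wm, gm, csf = make_tissue_maps(spec)
bold, motion = make_bold_volume(spec, wm)

print(f"grid {spec.grid_dims}, {spec.n_timepoints} frames, TR {spec.tr} s")
print(f"voxels with WM probability > 0.9: {(wm > 0.9).sum()}")
print(f"max voxelwise tissue-probability sum: {(wm + gm + csf).max():.3f}")

fd = framewise_displacement(motion)
censor = scrub(fd)
print(f"FD spikes (> 0.5 mm) at frames: {np.flatnonzero(fd.fd > 0.5).tolist()}")
print(f"frames kept after scrubbing: {censor.n_kept}/{len(censor.keep)}")
# each spike removes itself, one forward neighbour and two back neighbours
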