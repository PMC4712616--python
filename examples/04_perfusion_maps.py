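"""DSC perfusion quantification: arrival, AIF, truncated-SVD CBF/CBV/MTT.

The bolus arrival volume is detected on the brain-mean intensity curve, the
signal is converted to contrast concentration, arterial voxels are selected
automatically, and the tissue curves are deconvolved against the AIF.
"""

import numpy as np

from msquant.perfusion import (DscSeries, detect_arrival, perfusion_maps,
                               select_aif, signal_to_concentration,
                               volume_mean_series)
from msquant.phantom import PhantomSpec, generate_phantom

bundle = generate_phantom(PhantomSpec(seed=0))
dsc = DscSeries(bundle.dsc, bundle.brain_mask)

curve = volume_mean_series(dsc)
arrival = detect_arrival(curve, fraction=0.1)
print(f"contrast arrival at volume {arrival} (truth {bundle.truth_arrival})")

conc = signal_to_concentration(dsc, arrival, skip=1)
aif = select_aif(conc, bundle.brain_mask, n_voxels=10)
in_artery = sum(bundle.truth_artery.data[v] == 1 for v in aif.voxels)
print(f"AIF from {len(aif.voxels)} voxels, {in_artery} inside the true artery")

result = perfusion_maps(conc, aif, dsc.tr_s, bundle.brain_mask,
                        svd_threshold=0.05, arrival_index=arrival)
wm = (bundle.truth_tissue_labels.data == 3) & (bundle.truth_artery.data == 0)
for name, vol, truth in (("CBF", result.cbf, 0.01), ("CBV", result.cbv, 0.04),
                         ("MTT", result.mtt, 4.0)):
    est = np.median(np.asarray(vol.data)[wm])
    print(f"WM {name}: {est:.4f} (truth {truth}, error "
          f"{100 * abs(est - truth) / truth:.1f}%)")
# Maps are relative (no hematocrit/density constants); MTT = CBV/CBF by the
# central volume theorem, here in seconds.
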