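"""Grow FLAIR lesion ROIs and classify them from T1 / Gd-T1 intensities.

Each lesion's mean intensity is compared with thresholds derived from the
normal-appearing white matter (NAWM): mean ± Mf·SD per modality.  Above the
Gd-T1 high threshold = enhancing (acute); below the T1 low threshold =
hypointense.  The four combinations give classes C1-C4.
"""

from msquant.lesions import (NAWM_REF, Roi, RoiSet, classification_thresholds,
                             classify_lesions, grow_lesion_roi, nawm_stats,
                             write_roiset)
from msquant.phantom import PhantomSpec, generate_phantom

bundle = generate_phantom(PhantomSpec(seed=0))

nawm = Roi(id=0, voxels=bundle.nawm_ref_voxels, class_code=NAWM_REF,
           label_text="NAWM reference")
rois = [nawm] + [grow_lesion_roi(bundle.flair, seed, local_factor=0.5, roi_id=i)
                 for i, seed in sorted(bundle.lesion_seeds.items())]

mean, sd = nawm_stats(bundle.t1, nawm)
thr = classification_thresholds(mean, sd, mf=2.0)
print(f"NAWM on T1: mean {mean:.1f}, SD {sd:.1f} -> "
      f"window [{thr.thre_low:.1f}, {thr.thre_high:.1f}]")

classified = classify_lesions(RoiSet(rois), bundle.t1, bundle.gd_t1, mf=2.0)
for roi in classified.lesions():
    truth = bundle.truth_classes[roi.id]
    print(f"lesion {roi.id}: {roi.class_code} (truth {truth}) "
          f"{roi.n_voxels} voxels  {roi.label_text.split(':')[0]}")

path = write_roiset(classified, "scratch/lesions_demo.roi")
print(f"ROI file (human-editable, reload after manual revision): {path}")
# C1/C2 are Gd-enhancing (acute); C4 is the chronic 'black hole'.
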