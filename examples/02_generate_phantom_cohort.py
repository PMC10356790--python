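"""Generate the default phantom cohort and inspect its structure.

The cohort emulates template-aligned scans: every volume shares one smooth
background, the positive class carries an additive lesion sphere at one
fixed template position, and both classes carry distractor spheres of
identical appearance at random positions — so patch appearance alone is
almost non-discriminative and position is the real cue.
"""

import numpy as np

import patchbag as pb

cfg = pb.PhantomConfig(seed=7)
volumes, mask = pb.generate_cohort(cfg)
labels = np.array([v.label for v in volumes])

print(f"cohort: {len(volumes)} volumes of extent {cfg.extent}, "
      f"{int((labels == 1).sum())} positive / {int((labels == 0).sum())} negative")
print(f"lesion: center {cfg.lesion_center}, radius {cfg.lesion_radius}, "
      f"{int(mask.sum())} voxels ({100 * mask.mean():.2f}% of the volume)")

inside_pos = np.mean([v.data[mask].mean() for v in volumes if v.label == 1])
inside_neg = np.mean([v.data[mask].mean() for v in volumes if v.label == 0])
outside_pos = np.mean([v.data[~mask].mean() for v in volumes if v.label == 1])
outside_neg = np.mean([v.data[~mask].mean() for v in volumes if v.label == 0])
print(f"mean intensity inside the lesion mask:  positives {inside_pos:+.3f}, "
      f"negatives {inside_neg:+.3f} (difference ~ lesion amplitude "
      f"{cfg.lesion_amplitude})")
print(f"mean intensity outside the lesion mask: positives {outside_pos:+.3f}, "
      f"negatives {outside_neg:+.3f} (no class difference)")

# write a small cohort to disk in the manifest layout the trainer consumes
out = pb.write_cohort(volumes[:8], mask, "scratch/example_cohort")
print(f"wrote 8 volumes + lesion mask + manifest to {out.parent}/")
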