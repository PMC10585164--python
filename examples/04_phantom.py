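"""Generate a synthetic head-phantom cohort and inspect its structure.

The generator emulates the statistics the compound loss is designed for:
bilateral lobe-like foreground regions occupying a small pixel fraction,
plus "pole" slices whose foreground is only a few pixels. Subjects are
split 7:1:2 into train/val/test at the subject level.
"""

from collections import Counter

from lobeseg.phantom import PhantomSpec, generate_cohort, split_subjects

print("70 subjects at 7:1:2 ->", dict(Counter(split_subjects(70, seed=0).values())))

spec = PhantomSpec(image_size=(64, 64), n_subjects=12, slices_per_subject=6, seed=4)
cohort = generate_cohort(spec)
m = cohort.manifest
print(f"cohort           {len(m)} slices from {spec.n_subjects} subjects")
print(f"fg fraction      {cohort.foreground_fraction:.4%} (class imbalance regime)")
print(f"pole slices      {int(m['is_pole'].sum())} "
      f"({m['is_pole'].mean():.0%} of slices, <= {spec.pole_area_px} fg px each)")
print("partition sizes  ",
      m.groupby("partition")["subject"].nunique().to_dict(), "subjects")

img, mask, is_pole = cohort.images[0], cohort.masks[0], bool(m.loc[0, "is_pole"])
print(f"slice 0          pole={is_pole}, fg px={int(mask.sum())}, "
      f"intensity range [{img.min():.2f}, {img.max():.2f}]")
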