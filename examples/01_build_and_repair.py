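"""Build a synthetic diseased aorta and digitally repair it.

Creates the canonical 12-branch healthy template, applies a type-B-like
dissection (parallel true/false lumen chains with two tears) plus a
celiac-trunk ostial stenosis, and then repairs the result back into a
near-healthy reference geometry.
"""

from aortaflow import (LesionKind, LesionSpec, apply_lesion,
                       build_healthy_template, repair)

healthy = build_healthy_template()
print(f"healthy template: {len(healthy.segments)} segments, "
      f"{len(healthy.outlets)} outlets: {sorted(healthy.outlets)}")

dissected = apply_lesion(healthy, LesionSpec(
    LesionKind.DISSECTION, target="trunk", stations=(4, 8),
    tear_stations=(4, 8), fl_branches=("RRA",)))
diseased = apply_lesion(dissected, LesionSpec(
    LesionKind.OSTIAL_STENOSIS, target="CT", area_ratio=0.25))
tags = sorted(s.lumen_tag.value for s in diseased.segments
              if s.lumen_tag.value != "NONE")
print(f"diseased: {len(diseased.segments)} segments; lumen tags: {tags}")
print(f"stenosed segments: {[s.id for s in diseased.stenosed_segments()]}")

reference = repair(diseased)
print(f"repaired reference: {len(reference.segments)} segments, "
      f"tags {sorted(t.value for t in reference.lumen_tags())}, "
      f"stenoses {len(reference.stenosed_segments())}")
# The repair merges the false lumen away, removes the tears, restores
# the trunk radii by interpolation from the unaffected stations and
# deletes the stenosis spec — the segment count returns to the healthy
# template's and every radius matches it to machine precision.
worst = max(abs(a.radius - b.radius)
            for a, b in zip(sorted(reference.segments, key=lambda s: s.id),
                            sorted(healthy.segments, key=lambda s: s.id)))
print(f"max radius deviation from healthy template: {worst:.2e} cm")
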