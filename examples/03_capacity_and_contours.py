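"""Cranial capacity by endocast warping, plus contour and occipital metrics.

The capacity of a specimen whose endocranial cavity cannot be segmented
is estimated by warping a reference endocast through the thin-plate
spline that maps the reference's landmarks onto the target's. The same
specimen is then sliced into contour polylines along its length axis,
and occipital metrics (lambda-asteria angle, maximum breadth) are taken.
"""

import numpy as np

from virtucrania.capacity import (
    SemilandmarkSet,
    project_surface_semilandmarks,
    slide_semilandmarks,
)
from virtucrania.capacity import estimate_capacity
from virtucrania.contours import define_slicing_frame, generate_polylines
from virtucrania.meshes import mesh_volume
from virtucrania.occipital import lambda_asteria_angle, max_cranial_breadth
from virtucrania.synthetic import (
    generate_endocast,
    generate_population,
    generate_template,
)

template = generate_template(seed=7)
population = generate_population(template, n=12, seed=11)
reference, target = population[1], population[2]

# fixed-landmark capacity transfer, checked against the known truth
endo_ref = generate_endocast(reference)
ref_set = SemilandmarkSet(fixed=reference.landmarks, surface_semis=np.empty((0, 3)))
tgt_set = SemilandmarkSet(fixed=target.landmarks, surface_semis=np.empty((0, 3)))
estimate = estimate_capacity(endo_ref, ref_set, tgt_set, use_semis=False)
truth = mesh_volume(generate_endocast(target))
print(f"capacity of {target.specimen_id}: estimated {estimate:.1f} cc, "
      f"true {truth:.1f} cc ({(estimate - truth) / truth:+.2%})")

# densify the correspondence with slid surface semilandmarks
tpl_set = SemilandmarkSet(fixed=template.landmarks,
                          surface_semis=template.occipital_semis)
proj_ref = project_surface_semilandmarks(
    tpl_set, template.mesh, reference.mesh, reference.landmarks)
proj_tgt = project_surface_semilandmarks(
    tpl_set, template.mesh, target.mesh, target.landmarks)
slid_tgt = slide_semilandmarks(proj_tgt, target.mesh, proj_ref, iterations=3)
estimate_semis = estimate_capacity(endo_ref, proj_ref, slid_tgt)
print(f"with {len(slid_tgt.surface_semis)} slid semilandmarks: "
      f"{estimate_semis:.1f} cc ({(estimate_semis - truth) / truth:+.2%})")

# contour polylines along the glabella-opisthocranion axis, 2 mm spacing
lm = target.landmarks
frame = define_slicing_frame(lm.get("glabella"), lm.get("opisthocranion"),
                             spacing=2.0)
sections = generate_polylines(target.mesh, frame)
n_polys = sum(len(s.polylines) for s in sections)
n_closed = sum(p.closed for s in sections for p in s.polylines)
print(f"\n{len(sections)} slicing planes -> {n_polys} polylines "
      f"({n_closed} closed)")
mid = sections[len(sections) // 2]
print(f"mid-vault contour at {mid.offset_mm:.0f} mm: "
      f"perimeter {mid.polylines[0].perimeter:.1f} mm")

# occipital metrics
angle = lambda_asteria_angle(lm)
breadth = max_cranial_breadth(
    target.mesh, plane_origin=np.zeros(3), plane_normal=np.array([0.0, 1, 0]))
print(f"\nlambda-asteria angle {angle:.1f} deg, "
      f"maximum cranial breadth {breadth.breadth_mm:.1f} mm")
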