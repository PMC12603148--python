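"""Mesh an airway mask and render its 12-view snapshot ring.

The mask becomes a triangulated surface (marching cubes, vertices in mm);
12 orthographic cameras spaced 30 degrees apart on a 150 mm ring about the
cranio-caudal axis each produce a 224 x 224 Lambertian-shaded silhouette.
PNGs are written to ./rendered_views/.
"""

import numpy as np

from lucent.phantom import PhantomSpec, generate_tree, rasterize_phantom
from lucent.render import extract_mesh, render_viewset, save_viewset

spec = PhantomSpec()
_, mask = rasterize_phantom(generate_tree(spec), spec)

mesh = extract_mesh(mask, spec.spacing_mm)
print(f"mesh: {len(mesh.vertices)} vertices, {len(mesh.faces)} faces, "
      f"watertight={mesh.is_watertight}")

vs = render_viewset(mask, spec.spacing_mm, n_views=12, radius_mm=150.0, size=224)
paths = save_viewset(vs, "rendered_views", "phantom")
cover = [(img > 0).mean() * 100 for img in vs.images]
print(f"12 views at 224x224; silhouette coverage per view: "
      f"{np.round(cover, 1)} % of pixels")
print(f"wrote {len(paths)} PNGs to rendered_views/ "
      "(azimuths 000..330, 30-degree steps)")
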