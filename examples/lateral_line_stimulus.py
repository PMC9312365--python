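"""Pressure-coefficient stimulus along horned vs streamlined body contours.

Solves head-on potential flow around two 2-D body outlines with a
source-panel method, places canal pores every 2% of body length along the
dorsal path, and compares the adjacent-pore pressure-coefficient
difference (the canal-neuromast stimulus proxy) in the head region.
"""

import numpy as np

from cavehydro import (
    FluidProperties,
    FreeStream,
    delta_cp_profile,
    integrate_drag,
    place_pores,
    solve_panel_flow,
)
from cavehydro.synth import ContourGenParams, gen_contour

stream = FreeStream(u=0.0157, fluid=FluidProperties())  # typical coasting speed

for family in ("streamlined", "horned"):
    contour = gen_contour(ContourGenParams(family=family, n_vertices=240))
    sol = solve_panel_flow(contour, stream)
    chain = place_pores(contour, sol, spacing=0.02)
    prof = delta_cp_profile(chain)
    head = prof[prof.head_region]
    height = contour.vertices[:, 1].max() - contour.vertices[:, 1].min()
    drag = integrate_drag(sol, contour, stream, reference_area=height)
    print(
        f"{family:12s}: {len(contour)} panels, {len(chain)} pores, "
        f"stagnation Cp = {sol.cp.max():.3f}, "
        f"head-region max |dCp| = {np.abs(head.delta_cp).max():.3f}, "
        f"|Cd| residual = {abs(drag.cd):.4f}"
    )
# The horned contour shows a markedly larger |dCp| jump within 0.3 BL of
# the snout: the dorsal horn amplifies the pressure-difference stimulus
# available to head-region canal neuromasts. The |Cd| residual is the
# d'Alembert check: ideal-flow pressure drag vanishes on a closed body.
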