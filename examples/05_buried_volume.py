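"""Percent buried volume (%Vbur) of the carbene pocket.

Computes the standard %Vbur (3.5 Å probe sphere, Bondi radii × 1.17)
around the carbene-bearing Rh of a noise-free template, whole-sphere and
per prochiral hemisphere, and shows the analytic single-atom check.
"""

import numpy as np

import paddleface as pf

frame, topo = pf.build_template(pf.GeneratorSpec.re_blocked())

whole = pf.buried_volume(frame, topo, mesh=0.1)
v_re = pf.buried_volume(frame, topo, mesh=0.1, hemisphere="Re")
v_si = pf.buried_volume(frame, topo, mesh=0.1, hemisphere="Si")
print(f"%Vbur around carbene Rh: whole-sphere {whole:.1f}%  "
      f"Re hemisphere {v_re:.1f}%  Si hemisphere {v_si:.1f}%")

# analytic sanity check: one carbon centred in the probe sphere covers
# (1.989/3.5)^3 of its volume = 18.35%
single = pf.Frame(("C",), np.zeros((1, 3)))
v = pf.buried_volume(single, None, center=np.zeros(3), exclude=[], mesh=0.1)
print(f"single centred carbon: {v:.2f}% (analytic 18.35%)")
# The Re hemisphere of the Re-blocked template is more buried than the Si
# hemisphere — the volumetric view of the same steric bias that d(Re)/d(Si)
# measures.
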