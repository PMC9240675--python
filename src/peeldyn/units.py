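"""Internal unit system.

All numerics inside the package run in (μm, s, pN) with energies in
pN·μm = 1e-18 J.  In these units every quantity of the model is within a
few orders of magnitude of unity (kBT ≈ 4.11e-3 pN·μm, membrane tension
~ 2.5e2 pN per unit depth, bond stiffness 2.5e2 pN/μm), which keeps the
finite-element/finite-volume assemblies well conditioned.  The public
:class:`~peeldyn.parameters.ParameterSet` accepts the conventional mixed
units used in the membrane-adhesion literature (J, N/m, μm²/s, ...) and
converts once at construction.

With a ribbon depth ``l_lat`` the two-dimensional line model maps 2D
number densities (molecules/μm²) to line densities (molecules/μm) by
multiplication with ``l_lat`` [μm]; tensions (N/m) map to line forces
(pN) by ``× l_lat × 1e6``.
"""

# energy: J -> pN·μm
J_TO_PNUM = 1e18
# force: N -> pN
N_TO_PN = 1e12
# stiffness / tension: N/m -> pN/μm
NPM_TO_PNPUM = 1e6
# length: m -> μm
M_TO_UM = 1e6
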