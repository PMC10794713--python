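"""Thermal stability and mass bookkeeping for a 48-subunit cubic particle.

Extracts Tm from six replicate synthetic DSF curves (derivative-minimum
convention) and works through the particle-mass arithmetic: expected
48-mer shell mass, and the cargo mass implied by a measured ~1.3 MDa
particle.
"""

import numpy as np

from capsidmorph.stability import (
    MassObservation,
    call_mass_peak,
    expected_assembly_mass,
    infer_cargo_mass,
    mda_to_kda,
    replicate_tm,
)
from capsidmorph.synthetic import MeltCurveSpec, gen_melt_curve

curves = [
    gen_melt_curve(MeltCurveSpec(tm_true=55.0, noise_sd=10.0, seed=s)) for s in range(6)
]
out = replicate_tm(curves, smooth_window=5)
print(f"Tm = {out['mean']:.1f} +/- {out['sd']:.1f} degC (N = {out['n']} replicates)")

shell = expected_assembly_mass(48, 22.3)
print(f"\n48 subunits x 22.3 kDa monomer = {shell:.1f} kDa expected shell mass")

rng = np.random.default_rng(0)
peak = call_mass_peak(rng.normal(1300.0, 60.0, size=5000), bin_width=25.0)
print(f"mass-photometry peak: {peak.peak_mass:.0f} kDa (sd {peak.sd:.0f}, n={peak.n_in_peak})")

cargo = infer_cargo_mass(
    MassObservation(measured_mass=mda_to_kda(1.3), n_subunits=48, monomer_mass=22.3)
)
print(
    f"measured 1.3 MDa - expected shell {shell:.1f} kDa = {cargo:.1f} kDa of "
    "additional central cargo inside the cube"
)
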