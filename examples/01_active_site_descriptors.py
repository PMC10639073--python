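"""Build an idealized ribonucleotide-bound active site and measure its
geometric descriptors.

The fixture places a steric-gate tyrosine (Y645), a finger-domain sensor
asparagine (N828), catalytic aspartates and an incoming UTP at requested
geometry; the descriptors module then reads that geometry back.
"""

import polsensor as ps

params = ps.SiteParams(sugar="ribo", sensor_angle=120.0, gate_distance=4.0,
                       catalytic_gap=7.5, coplanarity=12.0)
structure, site = ps.make_active_site(params)

print(f"atoms in fixture:        {len(structure)}")
print(f"sensor angle (deg):      {ps.sensor_angle(structure, site):7.2f}")
print(f"gate distance (A):       {ps.gate_distance(structure, site):7.2f}")
print(f"catalytic gap (A):       {ps.catalytic_gap(structure, site):7.2f}")
print(f"base-pair tilt (deg):    {ps.base_pair_coplanarity(structure, site):7.2f}")
print(f"sensor state:            {ps.classify_state(ps.sensor_angle(structure, site))}")

# A sensor angle of 120 deg is well below the 140 deg classification
# boundary: this ribonucleotide-bound site is in the 'unlocked' sensor
# conformation, with the gate distance pushed out by the 2'-OH clash.
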