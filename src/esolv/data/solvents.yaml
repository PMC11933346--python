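# Solvent registry: nominal literature values at 298 K.
# Permittivities and viscosities are standard handbook placeholders and may be
# overridden by supplying a custom registry file of the same shape.
water:            {relative_permittivity: 78.4,  viscosity_cP: 0.89}
heavy water:      {relative_permittivity: 78.1,  viscosity_cP: 1.10}
DMSO:             {relative_permittivity: 46.7,  viscosity_cP: 1.99}
methanol:         {relative_permittivity: 32.7,  viscosity_cP: 0.54}
ethanol:          {relative_permittivity: 24.5,  viscosity_cP: 1.07}
1-propanol:       {relative_permittivity: 20.5,  viscosity_cP: 1.95}
2-propanol:       {relative_permittivity: 19.9,  viscosity_cP: 2.04}
1-butanol:        {relative_permittivity: 17.5,  viscosity_cP: 2.54}
1-pentanol:       {relative_permittivity: 13.9,  viscosity_cP: 3.62}
1-hexanol:        {relative_permittivity: 13.3,  viscosity_cP: 4.58}
1-heptanol:       {relative_permittivity: 11.8,  viscosity_cP: 5.81}
1-octanol:        {relative_permittivity: 10.3,  viscosity_cP: 7.29}
ethylene glycol:  {relative_permittivity: 37.0,  viscosity_cP: 16.1}
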