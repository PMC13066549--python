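# Default spectral parameters.  These are literature-typical stand-ins,
# NOT fitted values; every number can be overridden from a user config.
classes:
  chl_a:
    site_energy: 14900.0      # cm^-1
    dipole_strength: 4.0      # Debye
    lineshape_fwhm: 350.0     # cm^-1
    stokes_shift: 120.0       # cm^-1
  chl_b:
    site_energy: 15385.0
    dipole_strength: 3.4
    lineshape_fwhm: 350.0
    stokes_shift: 120.0
temperature: 300.0            # K
screening_factor: 0.8         # dimensionless
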