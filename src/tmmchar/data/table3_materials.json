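{
  "description": "Measured properties of the developed tissue-mimicking materials; parenthesized values in the source table are standard deviations, stored under std_devs. Printed impedances are presumed computed from unrounded inputs: they differ from the product of the rounded printed density and speed by up to 0.01 MRayls.",
  "materials": [
    {
      "name": "muscle_without_fiber",
      "tissue": "muscle",
      "speed_m_s": 1578.3,
      "attenuation_dB_cm_MHz": 0.50,
      "density_g_cm3": 1.04,
      "impedance_MRayls": 1.64,
      "youngs_modulus_kPa": 81.6,
      "youngs_modulus_tension_kPa": 81.3,
      "std_devs": {
        "speed_m_s": 4.8,
        "attenuation_dB_cm_MHz": 1.44,
        "density_g_cm3": 0.02,
        "youngs_modulus_kPa": 9.0,
        "youngs_modulus_tension_kPa": 2.2
      },
      "notes": "Source text quotes 0.25 dB/cm/MHz for this material's attenuation while its table prints 0.50 (1.44); both are transcribed as-is (table value authoritative here), not reconciled. The attenuation SD exceeding the mean is likewise transcribed verbatim."
    },
    {
      "name": "muscle_with_fiber",
      "tissue": "muscle",
      "speed_m_s": 1587.7,
      "attenuation_dB_cm_MHz": 5.56,
      "density_g_cm3": 1.06,
      "impedance_MRayls": 1.69,
      "youngs_modulus_kPa": 75.7,
      "youngs_modulus_tension_kPa": 75.6,
      "std_devs": {
        "speed_m_s": 16.0,
        "attenuation_dB_cm_MHz": 2.79,
        "density_g_cm3": 0.03,
        "youngs_modulus_kPa": 4.2,
        "youngs_modulus_tension_kPa": 1.7
      },
      "notes": "High attenuation attributed to scattering by the embedded collagen-dextran fiber network."
    },
    {
      "name": "soft_tissue",
      "tissue": "soft_tissue",
      "speed_m_s": 1533.4,
      "attenuation_dB_cm_MHz": 0.59,
      "density_g_cm3": 1.07,
      "impedance_MRayls": 1.65,
      "youngs_modulus_kPa": null,
      "std_devs": {
        "speed_m_s": 0.4,
        "attenuation_dB_cm_MHz": 0.01,
        "density_g_cm3": 0.01
      },
      "notes": "Liquid (evaporated-milk) material: acoustic path is the full transmitter-to-hydrophone distance; no modulus is defined."
    },
    {
      "name": "adipose",
      "tissue": "adipose",
      "speed_m_s": 1507.1,
      "attenuation_dB_cm_MHz": 0.48,
      "density_g_cm3": 1.00,
      "impedance_MRayls": 1.50,
      "youngs_modulus_kPa": 81.2,
      "std_devs": {
        "speed_m_s": 1.5,
        "attenuation_dB_cm_MHz": 0.31,
        "density_g_cm3": 0.02,
        "youngs_modulus_kPa": 10.2
      },
      "notes": "Modulus deliberately above the adipose literature range for handling robustness."
    },
    {
      "name": "skin",
      "tissue": "skin",
      "speed_m_s": 1445.3,
      "attenuation_dB_cm_MHz": 2.15,
      "density_g_cm3": 1.03,
      "impedance_MRayls": 1.49,
      "youngs_modulus_kPa": 1512.7,
      "std_devs": {
        "speed_m_s": 2.8,
        "attenuation_dB_cm_MHz": 0.86,
        "density_g_cm3": 0.01,
        "youngs_modulus_kPa": 55.1
      },
      "notes": "Urethane-rubber panel: acoustic properties trade off against the prioritized mechanical match (speed ~6% below the literature lower bound)."
    }
  ]
}
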