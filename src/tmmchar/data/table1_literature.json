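{
  "description": "Literature target ranges for mechanical and acoustic properties of human tissues (muscle here is bladder-wall smooth muscle). Bounds are inclusive; null marks a property with no reported range.",
  "ranges": [
    {"tissue": "muscle", "property": "youngs_modulus_kPa", "low": 70, "high": 430},
    {"tissue": "muscle", "property": "speed_m_s", "low": 1547, "high": 1616},
    {"tissue": "muscle", "property": "attenuation_dB_cm_MHz", "low": 0.23, "high": 1.09},
    {"tissue": "muscle", "property": "density_g_cm3", "low": 1.04, "high": 1.18},
    {"tissue": "muscle", "property": "impedance_MRayls", "low": 1.65, "high": 1.74},
    {"tissue": "soft_tissue", "property": "youngs_modulus_kPa", "low": null, "high": null},
    {"tissue": "soft_tissue", "property": "speed_m_s", "low": 1540, "high": 1540},
    {"tissue": "soft_tissue", "property": "attenuation_dB_cm_MHz", "low": 0.5, "high": 0.75},
    {"tissue": "soft_tissue", "property": "density_g_cm3", "low": 1.06, "high": 1.06},
    {"tissue": "soft_tissue", "property": "impedance_MRayls", "low": 1.63, "high": 1.63},
    {"tissue": "adipose", "property": "youngs_modulus_kPa", "low": 3, "high": 24},
    {"tissue": "adipose", "property": "speed_m_s", "low": 1450, "high": 1478},
    {"tissue": "adipose", "property": "attenuation_dB_cm_MHz", "low": 0.29, "high": 0.48},
    {"tissue": "adipose", "property": "density_g_cm3", "low": 0.81, "high": 0.96},
    {"tissue": "adipose", "property": "impedance_MRayls", "low": 1.35, "high": 1.65},
    {"tissue": "skin", "property": "youngs_modulus_kPa", "low": 1000, "high": 2000},
    {"tissue": "skin", "property": "speed_m_s", "low": 1537, "high": 1720},
    {"tissue": "skin", "property": "attenuation_dB_cm_MHz", "low": 0.44, "high": 1.84},
    {"tissue": "skin", "property": "density_g_cm3", "low": 1.10, "high": 1.13},
    {"tissue": "skin", "property": "impedance_MRayls", "low": 1.53, "high": 1.68}
  ]
}
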